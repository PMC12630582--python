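"""Restriction-motif enumeration, genome scanning, and the CGCG-fragment catalog.

A methylation-sensitive restriction enzyme such as BstUI (CG^CG) cleaves an
EM-converted library only where both CpGs of its recognition site were
methylated and therefore escaped conversion.  The genomic unit of analysis is
the *fragment*: the region between two consecutive motif occurrences on the
same contig, whose *insert* (the sequence strictly between the motifs) is the
part whose methylation the flanking cuts report on.

Coordinates are 0-based, half-open throughout; BED conventions apply on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "reverse_complement",
    "canonical",
    "Motif",
    "GenomeSequence",
    "Interval",
    "CGCGFragment",
    "MotifScreenRow",
    "enumerate_cg_motifs",
    "scan_motif",
    "build_catalog",
    "gc_content",
    "observed_expected_cpg",
    "screen_motifs",
    "fragments_in_regions",
    "coverage_profile",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Canonical representative of a motif: lexicographic min of the sequence
    and its reverse complement.  Idempotent and strand-symmetric."""
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


@dataclass(frozen=True)
class Motif:
    """A canonical CG-containing recognition sequence.

    The stored sequence is always the lexicographic minimum of itself and its
    reverse complement, so each double-stranded site has one representative.
    """

    sequence: str

    def __post_init__(self) -> None:
        if not set(self.sequence) <= _VALID_BASES:
            raise ValueError(f"motif contains non-ACGT characters: {self.sequence!r}")
        if "CG" not in self.sequence:
            raise ValueError(f"motif must contain a CG dinucleotide: {self.sequence!r}")
        if self.sequence != canonical(self.sequence):
            raise ValueError(
                f"motif must be canonical (lexicographic min of itself and its "
                f"reverse complement): {self.sequence!r}"
            )

    @classmethod
    def from_sequence(cls, seq: str) -> "Motif":
        """Build a motif from either strand's spelling."""
        return cls(canonical(seq.upper()))

    @property
    def is_palindrome(self) -> bool:
        return self.sequence == reverse_complement(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def enumerate_cg_motifs(min_len: int, max_len: int) -> List[Motif]:
    """Enumerate every canonical CG-containing motif with length in
    ``[min_len, max_len]``.

    Exhaustive over all k-mers; a k-mer and its reverse complement count as
    one motif.  Lengths below 2 yield nothing (no room for a CG).
    """
    if not 1 <= min_len <= max_len:
        raise ValueError("require 1 <= min_len <= max_len")
    seen = set()
    out: List[Motif] = []
    for k in range(max(min_len, 2), max_len + 1):
        for tup in product("ACGT", repeat=k):
            s = "".join(tup)
            if "CG" not in s:
                continue
            c = canonical(s)
            if c not in seen:
                seen.add(c)
                out.append(Motif(c))
    return out


class GenomeSequence:
    """Ordered mapping of contig name to uppercase A/C/G/T/N sequence."""

    def __init__(self, records: Mapping[str, str]):
        if not records:
            raise ValueError("genome must contain at least one contig")
        self._records: Dict[str, str] = {}
        for name, seq in records.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            self._records[name] = seq.upper()

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._records.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def contigs(self) -> List[str]:
        return list(self._records)

    def __getitem__(self, contig: str) -> str:
        return self._records[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._records

    def __iter__(self):
        return iter(self._records)

    def items(self):
        return self._records.items()

    def length(self, contig: str) -> int:
        return len(self._records[contig])

    def total_length(self) -> int:
        return sum(len(s) for s in self._records.values())


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CGCGFragment:
    """Catalog entry: two consecutive motif occurrences and the insert between.

    ``cut_start``/``cut_end`` give the physical fragment boundaries under the
    CG^CG cut convention (cut in the middle of each 4-mer site): the captured
    molecule spans ``[cut_start, cut_end)`` and carries a terminal CG at each
    end.
    """

    id: str
    contig: str
    left_motif: Interval
    right_motif: Interval
    insert: Interval
    insert_length: int
    gc_content: float
    n_cpg: int
    obs_exp_cpg: float
    blacklisted: bool = False
    contains_n: bool = False

    @property
    def cut_start(self) -> int:
        return self.left_motif.start + (self.left_motif.length // 2)

    @property
    def cut_end(self) -> int:
        return self.right_motif.start + (self.right_motif.length // 2)

    @property
    def span(self) -> Interval:
        """Full motif-to-motif extent (used for blacklist overlap)."""
        return Interval(self.contig, self.left_motif.start, self.right_motif.end)


@dataclass(frozen=True)
class MotifScreenRow:
    motif: Motif
    n_fragments: int
    n_overlapping_cgi: int


def scan_motif(genome: GenomeSequence, motif) -> List[Interval]:
    """All exact occurrences of a motif or its reverse complement.

    Overlapping occurrences are kept; a palindrome matching both strands at
    the same position is reported once.  N bases never match.  ``motif`` may
    be a :class:`Motif` or any recognition sequence string.
    """
    seq_pat = motif.sequence if isinstance(motif, Motif) else str(motif).upper()
    patterns = [seq_pat]
    rc = reverse_complement(seq_pat)
    if rc != seq_pat:
        patterns.append(rc)
    k = len(seq_pat)
    out: List[Interval] = []
    for contig, seq in genome.items():
        starts = set()
        for pat in patterns:
            # lookahead keeps overlapping matches
            starts.update(m.start() for m in re.finditer(f"(?={re.escape(pat)})", seq))
        out.extend(Interval(contig, s, s + k) for s in sorted(starts))
    return out


def gc_content(seq: str) -> float:
    """Fraction of G+C bases."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def observed_expected_cpg(seq: str) -> float:
    """Observed/expected CpG ratio: observed CpG count divided by
    (#C x #G) / length.  Zero when the sequence has no C or no G."""
    if not seq:
        raise ValueError("empty sequence")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c * n_g == 0:
        return 0.0
    return seq.count("CG") / (n_c * n_g / len(seq))


def _blacklist_trees(blacklist: Iterable[Interval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    return trees


def build_catalog(
    genome: GenomeSequence,
    motif: Motif,
    min_insert: int = 50,
    max_insert: int = 300,
    blacklist: Sequence[Interval] = (),
    occurrences: Optional[Sequence[Interval]] = None,
) -> List[CGCGFragment]:
    """Catalog of fragments between consecutive motif occurrences.

    A fragment is retained iff its insert length is within
    ``[min_insert, max_insert]`` (inclusive), the insert contains no N, and
    the motif-to-motif span overlaps no blacklist interval by >= 1 bp.
    Fragment ids are ``contig:insert_start-insert_end``.
    """
    if occurrences is None:
        occurrences = scan_motif(genome, motif)
    trees = _blacklist_trees(blacklist)
    out: List[CGCGFragment] = []
    by_contig: Dict[str, List[Interval]] = {}
    for occ in occurrences:
        by_contig.setdefault(occ.contig, []).append(occ)
    for contig, occs in by_contig.items():
        seq = genome[contig]
        tree = trees.get(contig)
        for left, right in zip(occs, occs[1:]):
            ins_len = right.start - left.end
            if ins_len < max(min_insert, 1) or ins_len > max_insert:
                continue
            ins_seq = seq[left.end : right.start]
            if "N" in ins_seq:
                continue
            if tree is not None and tree.overlap(left.start, right.end):
                continue
            out.append(
                CGCGFragment(
                    id=f"{contig}:{left.end}-{right.start}",
                    contig=contig,
                    left_motif=left,
                    right_motif=right,
                    insert=Interval(contig, left.end, right.start),
                    insert_length=ins_len,
                    gc_content=gc_content(ins_seq),
                    n_cpg=ins_seq.count("CG"),
                    obs_exp_cpg=observed_expected_cpg(ins_seq),
                )
            )
    return out


def screen_motifs(
    genome: GenomeSequence,
    motifs: Sequence[Motif],
    islands: Sequence[Interval],
    min_insert: int = 50,
    max_insert: int = 300,
) -> List[MotifScreenRow]:
    """Per-motif fragment counts and CpG-island overlap counts.

    Island overlap means >= 1 bp overlap between a fragment's insert and any
    island interval.  Rows are sorted by island-overlap count, descending.
    """
    trees = _blacklist_trees(islands)
    rows: List[MotifScreenRow] = []
    for motif in motifs:
        frags = build_catalog(genome, motif, min_insert, max_insert)
        n_cgi = 0
        for f in frags:
            tree = trees.get(f.contig)
            if tree is not None and tree.overlap(f.insert.start, f.insert.end):
                n_cgi += 1
        rows.append(MotifScreenRow(motif, len(frags), n_cgi))
    rows.sort(key=lambda r: (-r.n_overlapping_cgi, -r.n_fragments, r.motif.sequence))
    return rows


def fragments_in_regions(
    catalog: Sequence[CGCGFragment], regions: Sequence[Interval], mode: str = "overlap"
) -> List[str]:
    """Ids of catalog fragments located in any of the regions.

    ``mode='overlap'``: insert overlaps a region by >= 1 bp (the CpG-island
    association convention).  ``mode='within'``: the full motif-to-motif span
    lies inside one region — the right notion for ground-truth membership,
    since a fragment straddling a region boundary has flanking motifs whose
    methylation the region does not control.
    """
    if mode not in ("overlap", "within"):
        raise ValueError("mode must be 'overlap' or 'within'")
    trees = _blacklist_trees(regions)
    out = []
    for f in catalog:
        tree = trees.get(f.contig)
        if tree is None:
            continue
        if mode == "overlap":
            if tree.overlap(f.insert.start, f.insert.end):
                out.append(f.id)
        else:
            span = f.span
            if any(iv.begin <= span.start and span.end <= iv.end
                   for iv in tree.overlap(span.start, span.end)):
                out.append(f.id)
    return out


def coverage_profile(
    intervals: Sequence[Interval],
    anchors: Sequence[Interval],
    flank: int,
) -> np.ndarray:
    """Mean per-position coverage around anchor midpoints, as percentages.

    Returns a vector of length ``2 * flank + 1`` indexed by offset from the
    anchor midpoint ``(start + end) // 2``; the values sum to 100 over the
    window (all-zero if nothing overlaps any window).
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    # per-contig coverage depth via difference arrays
    maxend: Dict[str, int] = {}
    for iv in list(intervals) + list(anchors):
        maxend[iv.contig] = max(maxend.get(iv.contig, 0), iv.end + flank + 1)
    diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in maxend.items()}
    for iv in intervals:
        d = diff[iv.contig]
        d[iv.start] += 1
        d[iv.end] -= 1
    cov = {c: np.cumsum(d[:-1]) for c, d in diff.items()}
    profile = np.zeros(2 * flank + 1, dtype=float)
    for anchor in anchors:
        mid = anchor.midpoint
        lo, hi = mid - flank, mid + flank + 1
        c = cov[anchor.contig]
        window = np.zeros(2 * flank + 1, dtype=float)
        src_lo, src_hi = max(lo, 0), min(hi, len(c))
        if src_lo < src_hi:
            window[src_lo - lo : src_hi - lo] = c[src_lo:src_hi]
        profile += window
    profile /= len(anchors)
    total = profile.sum()
    if total > 0:
        profile = profile / total * 100.0
    return profile
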