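"""Protocol read filters, fragment counting, and methylation-fraction statistics.

Filtering mirrors the sequencing-data workflow of the enrichment protocol:
reads with any conversion failure at a non-CpG cytosine are removed, reads
whose terminal restriction half-sites are not intact (or that match no catalog
fragment exactly) are removed, and reads retaining an uncut CGCG anywhere in
their converted sequence are removed.  The three filters are evaluated
independently, so their order never changes the retained set.

Counting assigns each retained read to the catalog fragment whose cut-site
pair equals the read's coordinates exactly; per-sample library size is the
number of retained reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .reference_catalog import CGCGFragment, Interval
from .simulate import MethylRead

__all__ = [
    "REASON_NONCONVERSION",
    "REASON_UNASSIGNED",
    "REASON_MOTIF_INTEGRITY",
    "REASON_INTERNAL_MOTIF",
    "REASON_RETAINED",
    "FragmentCountMatrix",
    "RegionMethylation",
    "build_cut_site_index",
    "filter_nonconversion",
    "filter_motif_integrity",
    "filter_internal_motif",
    "apply_filters",
    "count_fragments",
    "process_cohort",
    "qc_min_fragments",
    "read_level_methylation",
    "MethylationPileup",
    "region_amf",
    "delta_amf",
]

REASON_NONCONVERSION = "nonconversion"
REASON_UNASSIGNED = "unassigned"
REASON_MOTIF_INTEGRITY = "motif_integrity"
REASON_INTERNAL_MOTIF = "internal_motif"
REASON_RETAINED = "retained"


@dataclass
class FragmentCountMatrix:
    """Fragments x samples raw counts with per-sample library sizes.

    ``library_sizes`` equals the number of retained reads per sample;
    ``unassigned`` tallies retained reads matching no catalog fragment (zero
    when the standard filters ran, since they discard unassigned reads).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    unassigned: pd.Series

    @property
    def fragment_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path, sizes_path) -> None:
        self.counts.rename_axis("fragment_id").to_csv(counts_path, sep="\t")
        pd.DataFrame(
            {
                "sample_id": self.library_sizes.index,
                "library_size": self.library_sizes.values,
                "unassigned": self.unassigned.reindex(self.library_sizes.index).values,
            }
        ).to_csv(sizes_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, sizes_path) -> "FragmentCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sizes = pd.read_csv(sizes_path, sep="\t")
        return cls(
            counts=counts,
            library_sizes=pd.Series(
                sizes["library_size"].values, index=sizes["sample_id"], name="library_size"
            ),
            unassigned=pd.Series(
                sizes["unassigned"].values, index=sizes["sample_id"], name="unassigned"
            ),
        )


@dataclass(frozen=True)
class RegionMethylation:
    region_id: str
    n_meth: int
    n_unmeth: int

    @property
    def amf(self) -> Optional[float]:
        t = self.n_meth + self.n_unmeth
        return self.n_meth / t if t else None


def build_cut_site_index(catalog: Sequence[CGCGFragment]) -> Dict[Tuple[str, int, int], str]:
    """Map (contig, cut_start, cut_end) to fragment id for exact assignment."""
    return {(f.contig, f.cut_start, f.cut_end): f.id for f in catalog}


def filter_nonconversion(read: MethylRead, max_failures: int = 0) -> bool:
    """Keep a read iff its count of unconverted non-CpG cytosines does not
    exceed ``max_failures`` (default: any failure discards)."""
    return read.nonconverted_ch <= max_failures


def filter_motif_integrity(
    read: MethylRead, cut_site_index: Mapping[Tuple[str, int, int], str]
) -> bool:
    """Keep a read iff it matches a catalog fragment's cut-site pair exactly
    and both terminal half-sites read CG (terminal CpGs unconverted).

    An unassigned read is discarded; :func:`apply_filters` records it under a
    distinct reason code.
    """
    if (read.contig, read.start, read.end) not in cut_site_index:
        return False
    s = read.converted_seq
    return len(s) >= 4 and s.startswith("CG") and s.endswith("CG")


def filter_internal_motif(read: MethylRead) -> bool:
    """Keep a read iff its converted sequence retains no full CGCG site.

    A captured fragment carries only the inner CG of each flanking site, so
    any complete CGCG in the read is an uncut (still-methylated) internal
    site.
    """
    return "CGCG" not in read.converted_seq


def apply_filters(
    reads: Iterable[MethylRead],
    cut_site_index: Mapping[Tuple[str, int, int], str],
    max_failures: int = 0,
) -> Tuple[List[MethylRead], Counter]:
    """Apply the three protocol filters; return retained reads and accounting.

    The retained set is the conjunction of the three independent filters
    (order-free).  For accounting, each discarded read is attributed to one
    reason, checked in the fixed order nonconversion -> unassigned ->
    motif integrity -> internal motif, so that
    ``retained + sum(discards) == input``.
    """
    retained: List[MethylRead] = []
    acct: Counter = Counter()
    for read in reads:
        ok_conv = filter_nonconversion(read, max_failures)
        assigned = (read.contig, read.start, read.end) in cut_site_index
        ok_motif = filter_motif_integrity(read, cut_site_index)
        ok_internal = filter_internal_motif(read)
        if ok_conv and ok_motif and ok_internal:
            retained.append(read)
            acct[REASON_RETAINED] += 1
        elif not ok_conv:
            acct[REASON_NONCONVERSION] += 1
        elif not assigned:
            acct[REASON_UNASSIGNED] += 1
        elif not ok_motif:
            acct[REASON_MOTIF_INTEGRITY] += 1
        else:
            acct[REASON_INTERNAL_MOTIF] += 1
    return retained, acct


ReadsInput = Union[
    Sequence[MethylRead],
    Mapping[str, Sequence[MethylRead]],
    Sequence[Tuple[str, Sequence[MethylRead]]],
]


def _group_reads(reads: ReadsInput) -> Dict[str, List[MethylRead]]:
    if isinstance(reads, Mapping):
        return {k: list(v) for k, v in reads.items()}
    reads = list(reads)
    if reads and isinstance(reads[0], tuple):
        out: Dict[str, List[MethylRead]] = {}
        for sid, rs in reads:
            if sid in out:
                raise ValueError(f"duplicate sample id: {sid!r}")
            out[sid] = list(rs)
        return out
    grouped: Dict[str, List[MethylRead]] = {}
    for r in reads:
        grouped.setdefault(r.sample_id, []).append(r)
    return grouped


def count_fragments(reads: ReadsInput, catalog: Sequence[CGCGFragment]) -> FragmentCountMatrix:
    """Count retained reads per catalog fragment and sample.

    A read increments exactly the fragment whose cut-site pair equals
    ``(read.start, read.end)``; non-matching reads are tallied as unassigned.
    Accepts a flat read list (grouped by ``sample_id``), a mapping
    ``sample_id -> reads``, or ``(sample_id, reads)`` pairs.
    """
    index = build_cut_site_index(catalog)
    frag_ids = [f.id for f in catalog]
    grouped = _group_reads(reads)
    samples = list(grouped)
    counts = pd.DataFrame(0, index=frag_ids, columns=samples, dtype=np.int64)
    lib = pd.Series(0, index=samples, dtype=np.int64, name="library_size")
    unassigned = pd.Series(0, index=samples, dtype=np.int64, name="unassigned")
    for sid, rs in grouped.items():
        tally: Counter = Counter()
        n_un = 0
        for r in rs:
            fid = index.get((r.contig, r.start, r.end))
            if fid is None:
                n_un += 1
            else:
                tally[fid] += 1
        if tally:
            idx = list(tally)
            counts.loc[idx, sid] = [tally[f] for f in idx]
        lib[sid] = len(rs)
        unassigned[sid] = n_un
    return FragmentCountMatrix(counts=counts, library_sizes=lib, unassigned=unassigned)


def process_cohort(
    samples: Union[Mapping[str, Sequence[MethylRead]], Iterable[Tuple]],
    catalog: Sequence[CGCGFragment],
    max_failures: int = 0,
) -> Tuple[FragmentCountMatrix, pd.DataFrame]:
    """Filter and count a whole cohort, one sample at a time.

    Accepts a mapping ``sample_id -> reads`` or any iterable of tuples whose
    first and last elements are the sample id and the read list (the
    streaming cohort generator's items qualify), so deep cohorts never need
    all samples in memory at once.  Returns the count matrix and a
    per-sample filter-accounting table.
    """
    index = build_cut_site_index(catalog)
    frag_ids = [f.id for f in catalog]
    columns: Dict[str, pd.Series] = {}
    libs: Dict[str, int] = {}
    unassigned: Dict[str, int] = {}
    acct_rows = []
    items = samples.items() if isinstance(samples, Mapping) else (
        (t[0], t[-1]) for t in samples
    )
    for sid, reads in items:
        if sid in libs:
            raise ValueError(f"duplicate sample id: {sid!r}")
        kept, acct = apply_filters(reads, index, max_failures)
        tally: Counter = Counter()
        n_un = 0
        for r in kept:
            fid = index.get((r.contig, r.start, r.end))
            if fid is None:
                n_un += 1
            else:
                tally[fid] += 1
        col = pd.Series(0, index=frag_ids, dtype=np.int64)
        if tally:
            col[list(tally)] = list(tally.values())
        columns[sid] = col
        libs[sid] = len(kept)
        unassigned[sid] = n_un
        row = {"sample_id": sid, "input_reads": len(reads)}
        for reason in (REASON_RETAINED, REASON_NONCONVERSION, REASON_UNASSIGNED,
                       REASON_MOTIF_INTEGRITY, REASON_INTERNAL_MOTIF):
            row[reason] = acct.get(reason, 0)
        acct_rows.append(row)
    matrix = FragmentCountMatrix(
        counts=pd.DataFrame(columns, index=frag_ids),
        library_sizes=pd.Series(libs, dtype=np.int64, name="library_size"),
        unassigned=pd.Series(unassigned, dtype=np.int64, name="unassigned"),
    )
    return matrix, pd.DataFrame(acct_rows).fillna(0)


def qc_min_fragments(matrix: FragmentCountMatrix, min_unique: int = 2000) -> pd.Series:
    """Per-sample QC: pass iff the sample covers at least ``min_unique``
    distinct fragments with nonzero counts."""
    covered = (matrix.counts > 0).sum(axis=0)
    return covered >= min_unique


def read_level_methylation(read: MethylRead) -> Optional[float]:
    """Fraction of methylated CpG calls in the read; None with no CpG."""
    n = len(read.cpg_calls)
    if n == 0:
        return None
    return read.cpg_calls.count("M") / n


class MethylationPileup:
    """Per-site pooled methylated/unmethylated call counts over many reads."""

    def __init__(self, contigs: Sequence[str], positions: np.ndarray, contig_codes: np.ndarray,
                 meth: np.ndarray):
        order = np.lexsort((positions, contig_codes))
        self._contigs = list(contigs)
        codes = contig_codes[order]
        self._pos = np.ascontiguousarray(positions[order])
        meth = meth[order]
        # cumulative methylated-call count for O(log n) region queries
        self._cum = np.concatenate([[0], np.cumsum(meth)])
        # per-contig block boundaries in the sorted arrays
        self._blocks = {
            c: (int(np.searchsorted(codes, i, side="left")),
                int(np.searchsorted(codes, i, side="right")))
            for i, c in enumerate(self._contigs)
        }

    @classmethod
    def from_reads(cls, reads: Sequence[MethylRead]) -> "MethylationPileup":
        contigs = sorted({r.contig for r in reads})
        code = {c: i for i, c in enumerate(contigs)}
        pos_parts, code_parts, meth_parts = [], [], []
        for r in reads:
            if len(r.cpg_positions) == 0:
                continue
            pos_parts.append(np.asarray(r.cpg_positions, dtype=np.int64))
            code_parts.append(np.full(len(r.cpg_positions), code[r.contig], dtype=np.int32))
            meth_parts.append(
                np.frombuffer(r.cpg_calls.encode("ascii"), dtype=np.uint8) == ord("M")
            )
        if pos_parts:
            return cls(
                contigs,
                np.concatenate(pos_parts),
                np.concatenate(code_parts),
                np.concatenate(meth_parts).astype(np.int64),
            )
        return cls(contigs, np.empty(0, np.int64), np.empty(0, np.int32), np.empty(0, np.int64))

    def region_counts(self, region: Interval) -> Tuple[int, int]:
        """(methylated, unmethylated) call counts at CpG sites whose C lies
        within the region."""
        if region.contig not in self._blocks:
            return 0, 0
        block_lo, block_hi = self._blocks[region.contig]
        block = self._pos[block_lo:block_hi]
        a = block_lo + int(np.searchsorted(block, region.start, side="left"))
        b = block_lo + int(np.searchsorted(block, region.end, side="left"))
        n_m = int(self._cum[b] - self._cum[a])
        return n_m, int((b - a) - n_m)


def region_amf(reads: Sequence[MethylRead], region: Interval,
               region_id: Optional[str] = None) -> RegionMethylation:
    """Pooled average methylation fraction over a region.

    All CpG calls whose genomic position lies in the region are pooled across
    reads; with no coverage the AMF is None (never zero).
    """
    pileup = MethylationPileup.from_reads(list(reads))
    n_m, n_u = pileup.region_counts(region)
    return RegionMethylation(region_id or f"{region.contig}:{region.start}-{region.end}",
                             n_m, n_u)


def delta_amf(
    reads_a: Sequence[MethylRead],
    reads_b: Sequence[MethylRead],
    fragments: Sequence[CGCGFragment],
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-fragment differential methylation (sample b minus sample a).

    ``motif_delta`` averages the AMF difference over the two flanking motif
    regions; ``insert_delta`` is the difference over the insert.  Fragments
    with undefined AMF in any required region (in either sample) are dropped
    and their ids returned.
    """
    pile_a = MethylationPileup.from_reads(list(reads_a))
    pile_b = MethylationPileup.from_reads(list(reads_b))
    rows, dropped = [], []
    for f in fragments:
        regions = (f.left_motif, f.right_motif, f.insert)
        amfs = []
        ok = True
        for pile in (pile_a, pile_b):
            vals = []
            for region in regions:
                n_m, n_u = pile.region_counts(region)
                if n_m + n_u == 0:
                    ok = False
                    break
                vals.append(n_m / (n_m + n_u))
            if not ok:
                break
            amfs.append(vals)
        if not ok:
            dropped.append(f.id)
            continue
        d_left = amfs[1][0] - amfs[0][0]
        d_right = amfs[1][1] - amfs[0][1]
        d_insert = amfs[1][2] - amfs[0][2]
        rows.append(
            {
                "fragment_id": f.id,
                "motif_delta": 0.5 * (d_left + d_right),
                "insert_delta": d_insert,
            }
        )
    return pd.DataFrame(rows, columns=["fragment_id", "motif_delta", "insert_delta"]), dropped
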