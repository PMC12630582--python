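"""Synthetic genomes, methylomes, EM-converted molecules, and digested libraries.

The generator emulates the experimental chain end to end with known ground
truth:

1. a genome with CpG-island structure (GC- and CpG-rich islands on a lower-CpG
   background, with CGCG sites clustered the way CpG-retaining sequence
   clusters them);
2. a methylome per sample class -- islands hypomethylated in the normal class,
   a chosen fraction of islands hypermethylated in the tumour class, a highly
   methylated background, and processive (first-order Markov) within-molecule
   methylation;
3. enzymatic conversion of each sheared molecule (unmethylated C reads as T at
   ``conversion_rate``; methylated CpG C survives except at
   ``overconversion_rate``);
4. restriction digestion of the converted molecule: only CGCG sites whose both
   CpGs still read C are cleavable, each cleaved with ``cut_efficiency``;
   pieces cut at both ends form the enriched library, pieces with at most one
   cut survive adapter cleanup with probability ``chimera_leak``.

All randomness flows through explicit seeds; identical seeds give identical
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng

from .reference_catalog import (
    CGCGFragment,
    GenomeSequence,
    Interval,
)

__all__ = [
    "GenomeSpec",
    "MethylomeSpec",
    "LibraryParams",
    "MethylRead",
    "SpikeInDesign",
    "generate_genome",
    "assign_methylation",
    "simulate_em_molecules",
    "digest_molecules",
    "simulate_spikein_cohort",
    "iter_spikein_cohort",
    "attach_rho",
    "BetaMap",
    "GenomeIndex",
]

_A, _C, _G, _T = (np.uint8(ord(b)) for b in "ACGT")


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the synthetic reference.

    Densities are CpG dinucleotides per bp.  Background CpGs are planted with
    a paired component (a fraction of planting events drop a CGCG rather than
    a lone CG) so that restriction sites cluster, as they do in CpG-retaining
    genomic sequence; ``background_motif_pair_weight`` controls that fraction.
    """

    n_contigs: int = 5
    contig_length: int = 1_000_000
    n_islands: int = 200
    island_length_mean: int = 1500
    island_cpg_density: float = 0.10
    background_cpg_density: float = 0.04
    island_gc: float = 0.60
    background_gc: float = 0.41
    background_motif_pair_weight: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.background_cpg_density < self.island_cpg_density < 0.5):
            raise ValueError("require 0 < background_cpg_density < island_cpg_density < 0.5")
        if self.n_contigs < 1 or self.contig_length < 1000:
            raise ValueError("need >= 1 contig of >= 1 kb")


@dataclass(frozen=True)
class MethylomeSpec:
    """Per-class methylation structure.

    ``processivity_rho`` is the probability that a CpG copies its upstream
    neighbour's state within a molecule (first-order persistence); the
    complement redraws from the site's marginal beta.
    """

    class_label: str = "normal"
    island_beta_normal: float = 0.03
    island_beta_tumor_marker: float = 0.95
    background_beta: float = 0.80
    marker_island_fraction: float = 0.20
    processivity_rho: float = 0.90

    def __post_init__(self) -> None:
        if self.class_label not in ("normal", "tumor"):
            raise ValueError("class_label must be 'normal' or 'tumor'")
        if not self.island_beta_normal < self.island_beta_tumor_marker:
            raise ValueError("island_beta_normal must be < island_beta_tumor_marker")
        if not 0 <= self.processivity_rho < 1:
            raise ValueError("processivity_rho must be in [0, 1)")


@dataclass(frozen=True)
class LibraryParams:
    """Library preparation and digestion efficiencies."""

    molecule_length_mean: float = 180.0
    molecule_length_sd: float = 40.0
    conversion_rate: float = 0.998
    overconversion_rate: float = 0.002
    cut_efficiency: float = 0.90
    chimera_leak: float = 0.05
    depth: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "overconversion_rate", "cut_efficiency", "chimera_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.molecule_length_mean <= 0:
            raise ValueError("molecule_length_mean must be positive")


@dataclass(slots=True)
class MethylRead:
    """A converted molecule or digested sub-fragment with per-CpG calls.

    ``cpg_calls`` holds one character per reference CpG site fully contained
    in ``[start, end)`` (``M`` = read as C, ``u`` = read as T), in genomic
    order; ``cpg_positions`` gives the matching reference coordinates.
    """

    sample_id: str
    contig: str
    start: int
    end: int
    converted_seq: str
    cpg_calls: str
    origin_class: str
    origin_fragment_id: Optional[str] = None
    nonconverted_ch: int = 0
    has_both_cuts: bool = False
    cpg_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64), repr=False)


@dataclass(frozen=True)
class SpikeInDesign:
    fractions: Tuple[float, ...] = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 0.1)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def _random_bases(rng: Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _place_islands(
    rng: Generator, contig_length: int, lengths: Sequence[int], margin: int = 200
) -> List[Tuple[int, int]]:
    placed: List[Tuple[int, int]] = []
    for L in lengths:
        ok = False
        for _ in range(2000):
            s = int(rng.integers(margin, contig_length - L - margin))
            if all(s >= e + margin or s + L + margin <= b for b, e in placed):
                placed.append((s, s + L))
                ok = True
                break
        if not ok:
            raise ValueError("island specification infeasible for contig length")
    return sorted(placed)


def _ensure_island_pair(arr: np.ndarray, start: int, end: int) -> None:
    """Guarantee at least one consecutive CGCG pair with a 50-300 bp insert."""
    seq = arr[start:end]
    hits = np.where(
        (seq[:-3] == _C) & (seq[1:-2] == _G) & (seq[2:-1] == _C) & (seq[3:] == _G)
    )[0]
    if len(hits) >= 2:
        inserts = hits[1:] - (hits[:-1] + 4)
        if np.any((inserts >= 50) & (inserts <= 300)):
            return
    width = 110
    if end - start < width + 20:
        raise ValueError("island too short to host a fragment")
    s0 = start + (end - start - width) // 2
    window = arr[s0 : s0 + width]
    cg = np.where((window[:-1] == _C) & (window[1:] == _G))[0]
    window[cg + 1] = _A
    for pos in (s0, s0 + width - 4):
        arr[pos : pos + 4] = np.frombuffer(b"CGCG", dtype=np.uint8)


def generate_genome(
    spec: GenomeSpec,
) -> Tuple[GenomeSequence, List[Interval], Dict[str, np.ndarray]]:
    """Build the synthetic reference.

    Returns the genome, the island annotation, and the per-contig sorted
    arrays of CpG positions.  Deterministic given ``spec.seed``; every island
    is guaranteed to contain at least one catalogable fragment.
    """
    rng = default_rng(spec.seed)
    motif = np.frombuffer(b"CGCG", dtype=np.uint8)
    records: Dict[str, str] = {}
    islands: List[Interval] = []
    cpg_sites: Dict[str, np.ndarray] = {}

    # round-robin island allocation across contigs
    per_contig = [spec.n_islands // spec.n_contigs] * spec.n_contigs
    for i in range(spec.n_islands % spec.n_contigs):
        per_contig[i] += 1

    for ci in range(spec.n_contigs):
        name = f"chr{ci + 1}"
        L = spec.contig_length
        arr = _random_bases(rng, L, spec.background_gc)

        n_isl = per_contig[ci]
        lengths = np.clip(
            np.rint(rng.normal(spec.island_length_mean, 0.2 * spec.island_length_mean, n_isl)),
            400,
            int(2.0 * spec.island_length_mean),
        ).astype(int)
        if lengths.sum() + (n_isl + 1) * 200 > 0.7 * L:
            raise ValueError("islands exceed contig capacity")
        coords = _place_islands(rng, L, list(lengths))
        contig_islands = [Interval(name, s, e) for s, e in coords]
        islands.extend(contig_islands)

        for iv in contig_islands:
            arr[iv.start : iv.end] = _random_bases(rng, iv.length, spec.island_gc)

        # background CpG planting, with a paired (CGCG) component
        w = spec.background_motif_pair_weight
        rate = spec.background_cpg_density / (1.0 + w)
        n_events = rng.poisson(rate * L)
        pos = rng.integers(0, L - 4, size=n_events)
        in_island = np.zeros(L, dtype=bool)
        for iv in contig_islands:
            in_island[max(iv.start - 4, 0) : iv.end + 4] = True
        pos = pos[~in_island[pos]]
        paired = rng.random(len(pos)) < w
        for p in pos[~paired]:
            arr[p : p + 2] = motif[:2]
        for p in pos[paired]:
            arr[p : p + 4] = motif

        # island CpG planting (single CGs) plus forced, regularly spaced motifs
        for iv in contig_islands:
            n_cg = rng.poisson(spec.island_cpg_density * iv.length)
            p_isl = rng.integers(iv.start, iv.end - 2, size=n_cg)
            for p in p_isl:
                arr[p : p + 2] = motif[:2]
            p = iv.start + int(rng.integers(10, 40))
            while p + 4 <= iv.end - 10:
                arr[p : p + 4] = motif
                p += 4 + int(rng.integers(55, 131))
            _ensure_island_pair(arr, iv.start, iv.end)

        records[name] = arr.tobytes().decode("ascii")
        cpg_sites[name] = np.where((arr[:-1] == _C) & (arr[1:] == _G))[0].astype(np.int64)

    return GenomeSequence(records), islands, cpg_sites


# ---------------------------------------------------------------------------
# Methylome assignment
# ---------------------------------------------------------------------------


def assign_methylation(
    cpg_sites: Mapping[str, np.ndarray],
    islands: Sequence[Interval],
    spec: MethylomeSpec,
    seed: int = 0,
) -> Tuple[Dict[str, np.ndarray], List[Interval]]:
    """Per-site methylation probabilities (beta) for one sample class.

    The hypermethylated marker-island subset is drawn from ``seed`` alone, so
    calling this with the same seed for the normal and tumour classes yields a
    shared ground-truth marker set (returned as the second element).
    """
    rng = default_rng(seed)
    n_marker = int(round(spec.marker_island_fraction * len(islands)))
    marker_idx = set(
        rng.choice(len(islands), size=n_marker, replace=False).tolist() if n_marker else []
    )
    marker_islands = [islands[i] for i in sorted(marker_idx)]

    beta: Dict[str, np.ndarray] = {
        contig: np.full(len(pos), spec.background_beta, dtype=float)
        for contig, pos in cpg_sites.items()
    }
    for i, iv in enumerate(islands):
        pos = cpg_sites[iv.contig]
        lo = np.searchsorted(pos, iv.start)
        hi = np.searchsorted(pos, iv.end - 1)
        if spec.class_label == "tumor" and i in marker_idx:
            beta[iv.contig][lo:hi] = spec.island_beta_tumor_marker
        else:
            beta[iv.contig][lo:hi] = spec.island_beta_normal
    return BetaMap(beta, spec.processivity_rho), marker_islands


# ---------------------------------------------------------------------------
# Genome index (internal precomputation)
# ---------------------------------------------------------------------------


class GenomeIndex:
    """Precomputed arrays for fast molecule simulation over one genome."""

    def __init__(self, genome: GenomeSequence, catalog: Optional[Sequence[CGCGFragment]] = None):
        self.genome = genome
        self.contigs: List[str] = genome.contigs
        self.seqs: Dict[str, np.ndarray] = {
            c: np.frombuffer(genome[c].encode("ascii"), dtype=np.uint8) for c in self.contigs
        }
        self.lengths = np.array([len(self.seqs[c]) for c in self.contigs], dtype=np.int64)
        self.cpg_pos: Dict[str, np.ndarray] = {}
        self.c_pos: Dict[str, np.ndarray] = {}
        self.motif_pos: Dict[str, np.ndarray] = {}
        self.motif_cpg_idx: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for c in self.contigs:
            seq = self.seqs[c]
            cpg = np.where((seq[:-1] == _C) & (seq[1:] == _G))[0].astype(np.int64)
            self.cpg_pos[c] = cpg
            self.c_pos[c] = np.where(seq == _C)[0].astype(np.int64)
            mot = np.where(
                (seq[:-3] == _C) & (seq[1:-2] == _G) & (seq[2:-1] == _C) & (seq[3:] == _G)
            )[0].astype(np.int64)
            self.motif_pos[c] = mot
            self.motif_cpg_idx[c] = (
                np.searchsorted(cpg, mot),
                np.searchsorted(cpg, mot + 2),
            )
        self.cut_pairs: Dict[Tuple[str, int, int], str] = {}
        if catalog is not None:
            self.cut_pairs = {(f.contig, f.cut_start, f.cut_end): f.id for f in catalog}


# ---------------------------------------------------------------------------
# Molecule simulation core
# ---------------------------------------------------------------------------


def _chain_states(
    rng: Generator,
    n_sites: np.ndarray,
    beta_flat: np.ndarray,
    rho: float,
    over_rate: float,
    conv_rate: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Markov methylation states and read-as-C mask for flattened chains.

    ``n_sites`` gives the chain length per molecule; ``beta_flat`` the
    per-site marginals in molecule order.
    """
    total = int(n_sites.sum())
    if total == 0:
        e = np.empty(0, dtype=bool)
        return e, e.copy()
    seg_start = np.cumsum(n_sites) - n_sites
    within = np.arange(total) - np.repeat(seg_start, n_sites)
    base = rng.random(total) < beta_flat
    copy = rng.random(total) < rho
    anchor = np.where((within == 0) | ~copy, np.arange(total), -1)
    anchor = np.maximum.accumulate(anchor)
    states = base[anchor]
    over = rng.random(total) < over_rate
    fail = rng.random(total) < (1.0 - conv_rate)
    # base read as C: methylated and not overconverted, or unmethylated but unconverted
    c_mask = np.where(states, ~over, fail)
    return states, c_mask


def _materialize_read(
    index: GenomeIndex,
    contig: str,
    s: int,
    e: int,
    positions: np.ndarray,
    c_sub: np.ndarray,
    beta_arr: np.ndarray,
    params: LibraryParams,
    rng: Generator,
    sample_id: str,
    origin_class: str,
    origin_fragment_id: Optional[str],
    has_both_cuts: bool,
) -> MethylRead:
    """Build the converted sequence and calls for one interval.

    ``positions``/``c_sub`` are the fully contained CpG sites and their
    read-as-C outcomes; CH conversion failures are drawn here.
    """
    seq = index.seqs[contig]
    arr = seq[s:e].copy()
    rel = positions - s
    arr[rel[~c_sub]] = _T

    # CpG cytosine dangling at the last base (its G lies outside the interval)
    cpg = index.cpg_pos[contig]
    if arr[-1] == _C:
        j = np.searchsorted(cpg, e - 1)
        if j < len(cpg) and cpg[j] == e - 1:
            b = beta_arr[j]
            p_read_c = b * (1.0 - params.overconversion_rate) + (1.0 - b) * (
                1.0 - params.conversion_rate
            )
            if rng.random() >= p_read_c:
                arr[-1] = _T

    # non-CpG cytosines: convert, count failures (both position lists are
    # sorted, so membership resolves with one searchsorted pass)
    cp = index.c_pos[contig]
    c_in = cp[np.searchsorted(cp, s) : np.searchsorted(cp, e)]
    lo = np.searchsorted(cpg, s)
    hi = np.searchsorted(cpg, e)  # CpG-context Cs have position <= e-1
    cpg_c = cpg[lo:hi]
    if len(cpg_c):
        j = np.minimum(np.searchsorted(cpg_c, c_in), len(cpg_c) - 1)
        ch = c_in[cpg_c[j] != c_in]
    else:
        ch = c_in
    failed = rng.random(len(ch)) < (1.0 - params.conversion_rate)
    arr[ch[~failed] - s] = _T

    calls = np.where(c_sub, np.uint8(ord("M")), np.uint8(ord("u"))).astype(np.uint8)
    return MethylRead(
        sample_id=sample_id,
        contig=contig,
        start=int(s),
        end=int(e),
        converted_seq=arr.tobytes().decode("ascii"),
        cpg_calls=calls.tobytes().decode("ascii"),
        origin_class=origin_class,
        origin_fragment_id=origin_fragment_id,
        nonconverted_ch=int(failed.sum()),
        has_both_cuts=has_both_cuts,
        cpg_positions=positions.astype(np.int64),
    )


def _draw_molecule_coords(
    index: GenomeIndex, params: LibraryParams, n: int, rng: Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform molecule starts, truncated-normal lengths."""
    probs = index.lengths / index.lengths.sum()
    cidx = rng.choice(len(index.contigs), size=n, p=probs)
    lens = np.maximum(
        np.rint(rng.normal(params.molecule_length_mean, params.molecule_length_sd, n)), 50
    ).astype(np.int64)
    starts = (rng.random(n) * (index.lengths[cidx] - 1)).astype(np.int64)
    ends = np.minimum(starts + lens, index.lengths[cidx])
    return cidx, starts, ends


def simulate_em_molecules(
    genome,
    beta: Mapping[str, np.ndarray],
    params: LibraryParams,
    n: int,
    seed: int = 0,
    sample_id: str = "sample",
    origin_class: str = "normal",
) -> List[MethylRead]:
    """Simulate ``n`` EM-converted (undigested) molecules.

    ``genome`` may be a :class:`GenomeSequence` or a prebuilt
    :class:`GenomeIndex`; ``beta`` maps contig to per-CpG-site marginal
    methylation aligned with the genome's CpG positions.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rng = default_rng(seed)
    cidx, starts, ends = _draw_molecule_coords(index, params, n, rng)
    reads: List[MethylRead] = []
    for ci, contig in enumerate(index.contigs):
        sel = np.where(cidx == ci)[0]
        if len(sel) == 0:
            continue
        s_arr, e_arr = starts[sel], ends[sel]
        cpg = index.cpg_pos[contig]
        lo = np.searchsorted(cpg, s_arr)
        hi = np.searchsorted(cpg, e_arr - 1)  # fully contained sites: pos <= end-2
        counts = hi - lo
        site_idx = np.repeat(lo, counts) + (
            np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
        )
        beta_flat = beta[contig][site_idx]
        states, c_mask = _chain_states(
            rng,
            counts,
            beta_flat,
            _rho_of(beta),
            params.overconversion_rate,
            params.conversion_rate,
        )
        off = np.concatenate([[0], np.cumsum(counts)])
        for k in range(len(sel)):
            seg = slice(off[k], off[k + 1])
            reads.append(
                _materialize_read(
                    index,
                    contig,
                    int(s_arr[k]),
                    int(e_arr[k]),
                    cpg[lo[k] : hi[k]],
                    c_mask[seg],
                    beta[contig],
                    params,
                    rng,
                    sample_id,
                    origin_class,
                    None,
                    False,
                )
            )
    return reads


def _rho_of(beta: Mapping[str, np.ndarray]) -> float:
    """Processivity attached to a beta mapping (see :func:`attach_rho`)."""
    return getattr(beta, "rho", _DEFAULT_RHO)


_DEFAULT_RHO = MethylomeSpec().processivity_rho


class BetaMap(dict):
    """Contig -> per-site beta array, carrying the processivity used to
    correlate neighbouring CpGs within a molecule."""

    def __init__(self, data: Mapping[str, np.ndarray], rho: float = _DEFAULT_RHO):
        super().__init__(data)
        self.rho = float(rho)


def attach_rho(beta: Mapping[str, np.ndarray], rho: float) -> BetaMap:
    """Bundle a methylome's processivity with its per-site betas."""
    return BetaMap(beta, rho)


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


def _find_overlapping(seq: str, pat: str) -> List[int]:
    out, i = [], seq.find(pat)
    while i != -1:
        out.append(i)
        i = seq.find(pat, i + 1)
    return out


def _slice_read(mol: MethylRead, ps: int, pe: int, has_both: bool, origin_fid) -> MethylRead:
    """Sub-read of a molecule over molecule-relative offsets [ps, pe)."""
    a, b = mol.start + ps, mol.start + pe
    mask = (mol.cpg_positions >= a) & (mol.cpg_positions <= b - 2)
    calls_arr = np.frombuffer(mol.cpg_calls.encode("ascii"), dtype=np.uint8)[mask]
    sub_seq = mol.converted_seq[ps:pe]
    # CH conversion failures inside the piece: a C whose following base (in the
    # molecule) is not G sits in non-CpG context; a molecule-final C is
    # ambiguous and not counted.
    n_fail = 0
    mseq = mol.converted_seq
    for off in range(ps, pe):
        if mseq[off] == "C" and off + 1 < len(mseq) and mseq[off + 1] != "G":
            n_fail += 1
    return MethylRead(
        sample_id=mol.sample_id,
        contig=mol.contig,
        start=a,
        end=b,
        converted_seq=sub_seq,
        cpg_calls=calls_arr.tobytes().decode("ascii"),
        origin_class=mol.origin_class,
        origin_fragment_id=origin_fid,
        nonconverted_ch=n_fail,
        has_both_cuts=has_both,
        cpg_positions=mol.cpg_positions[mask],
    )


def digest_molecules(
    molecules: Sequence[MethylRead],
    params: LibraryParams,
    catalog: Sequence[CGCGFragment],
    seed: int = 0,
    return_discarded: bool = False,
):
    """Restriction-digest converted molecules into the enriched library.

    Every CGCG occurrence in the *converted* sequence (i.e. a site whose both
    CpGs escaped conversion) is cleaved independently with ``cut_efficiency``
    at its midpoint.  Pieces with cuts at both ends are always emitted; pieces
    with at most one cut end survive cleanup with probability
    ``chimera_leak``.  With ``return_discarded`` the removed pieces are also
    returned, so a molecule's pieces always reconstruct it.
    """
    rng = default_rng(seed)
    cut_pairs = {(f.contig, f.cut_start, f.cut_end): f.id for f in catalog}
    library: List[MethylRead] = []
    discarded: List[MethylRead] = []
    for mol in molecules:
        occ = _find_overlapping(mol.converted_seq, "CGCG")
        cuts = [o + 2 for o in occ if rng.random() < params.cut_efficiency]
        bounds = [0] + cuts + [len(mol.converted_seq)]
        n_cut = len(cuts)
        for i in range(len(bounds) - 1):
            ps, pe = bounds[i], bounds[i + 1]
            if pe <= ps:
                continue
            has_both = 0 < i < n_cut
            if has_both:
                fid = cut_pairs.get((mol.contig, mol.start + ps, mol.start + pe))
                library.append(_slice_read(mol, ps, pe, True, fid))
            elif rng.random() < params.chimera_leak:
                library.append(_slice_read(mol, ps, pe, False, None))
            elif return_discarded:
                discarded.append(_slice_read(mol, ps, pe, False, None))
    if return_discarded:
        return library, discarded
    return library


# ---------------------------------------------------------------------------
# Fused sample simulation (molecules + digestion without materializing
# every undigested molecule)
# ---------------------------------------------------------------------------


def _simulate_recap_sample(
    index: GenomeIndex,
    beta_normal: Mapping[str, np.ndarray],
    beta_tumor: Mapping[str, np.ndarray],
    fraction: float,
    params: LibraryParams,
    rng: Generator,
    sample_id: str,
) -> List[MethylRead]:
    """One digested library at a given tumour-molecule fraction.

    Logically equivalent to ``simulate_em_molecules`` followed by
    ``digest_molecules`` (cleavable converted-sequence CGCG occurrences
    correspond one-to-one to reference CGCG sites whose both CpGs read C),
    but only emitted pieces are materialized.
    """
    n = params.depth
    rho = _rho_of(beta_normal)
    cidx, starts, ends = _draw_molecule_coords(index, params, n, rng)
    tumor = rng.random(n) < fraction
    reads: List[MethylRead] = []

    for ci, contig in enumerate(index.contigs):
        sel = np.where(cidx == ci)[0]
        if len(sel) == 0:
            continue
        s_arr, e_arr, tum = starts[sel], ends[sel], tumor[sel]
        cpg = index.cpg_pos[contig]
        mot = index.motif_pos[contig]
        mi1, mi2 = index.motif_cpg_idx[contig]
        m = len(sel)

        lo = np.searchsorted(cpg, s_arr)
        hi = np.searchsorted(cpg, e_arr - 1)
        counts = hi - lo
        total = int(counts.sum())
        seg_off = np.concatenate([[0], np.cumsum(counts)])
        site_idx = np.repeat(lo, counts) + (
            np.arange(total) - np.repeat(seg_off[:-1], counts)
        )
        tum_flat = np.repeat(tum, counts)
        beta_flat = np.where(
            tum_flat, beta_tumor[contig][site_idx], beta_normal[contig][site_idx]
        )
        states, c_mask = _chain_states(
            rng, counts, beta_flat, rho, params.overconversion_rate, params.conversion_rate
        )

        # candidate restriction sites fully inside each molecule
        qa = np.searchsorted(mot, s_arr)
        qb = np.searchsorted(mot, e_arr - 3)
        qc = np.maximum(qb - qa, 0)
        qtotal = int(qc.sum())
        q_off = np.concatenate([[0], np.cumsum(qc)])
        q_mol = np.repeat(np.arange(m), qc)
        q_idx = np.repeat(qa, qc) + (np.arange(qtotal) - np.repeat(q_off[:-1], qc))
        flat1 = seg_off[q_mol] + (mi1[q_idx] - lo[q_mol])
        flat2 = seg_off[q_mol] + (mi2[q_idx] - lo[q_mol])
        cleavable = c_mask[flat1] & c_mask[flat2]
        cut = cleavable & (rng.random(qtotal) < params.cut_efficiency)

        n_cuts = np.bincount(q_mol[cut], minlength=m)

        def emit(mol_k: int, a: int, b: int, both: bool, fid) -> None:
            j1 = np.searchsorted(cpg, a)
            j2 = np.searchsorted(cpg, b - 1)
            seg = slice(seg_off[mol_k] + (j1 - lo[mol_k]), seg_off[mol_k] + (j2 - lo[mol_k]))
            barr = beta_tumor[contig] if tum[mol_k] else beta_normal[contig]
            reads.append(
                _materialize_read(
                    index,
                    contig,
                    a,
                    b,
                    cpg[j1:j2],
                    c_mask[seg],
                    barr,
                    params,
                    rng,
                    sample_id,
                    "tumor" if tum[mol_k] else "normal",
                    fid,
                    both,
                )
            )

        # molecules without cuts: whole molecule is a chimera candidate
        no_cut = np.where(n_cuts == 0)[0]
        leak = rng.random(len(no_cut)) < params.chimera_leak
        for k in no_cut[leak]:
            emit(int(k), int(s_arr[k]), int(e_arr[k]), False, None)

        # molecules with cuts: assemble pieces
        for k in np.where(n_cuts > 0)[0]:
            qs = slice(q_off[k], q_off[k + 1])
            cut_pos = mot[q_idx[qs][cut[qs]]] + 2
            bounds = np.concatenate([[s_arr[k]], cut_pos, [e_arr[k]]])
            nc = len(cut_pos)
            for i in range(len(bounds) - 1):
                a, b = int(bounds[i]), int(bounds[i + 1])
                if b <= a:
                    continue
                both = 0 < i < nc
                if both:
                    fid = index.cut_pairs.get((contig, a, b))
                    emit(int(k), a, b, True, fid)
                elif rng.random() < params.chimera_leak:
                    emit(int(k), a, b, False, None)
    return reads


def iter_spikein_cohort(
    genome,
    beta_normal: Mapping[str, np.ndarray],
    beta_tumor: Mapping[str, np.ndarray],
    design: SpikeInDesign,
    params: LibraryParams,
    catalog: Optional[Sequence[CGCGFragment]] = None,
):
    """Lazily yield ``(sample_id, fraction, replicate, reads)`` per library.

    Streaming form of :func:`simulate_spikein_cohort` for deep cohorts where
    holding every sample's reads at once would be wasteful.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, catalog)
    if catalog is not None and not index.cut_pairs:
        index.cut_pairs = {(f.contig, f.cut_start, f.cut_end): f.id for f in catalog}
    for fi, f in enumerate(design.fractions):
        for rep in range(design.replicates):
            sid = f"f{f:g}_r{rep + 1}"
            rng = default_rng([design.seed, params.seed, fi, rep])
            yield sid, f, rep + 1, _simulate_recap_sample(
                index, beta_normal, beta_tumor, f, params, rng, sid
            )


def simulate_spikein_cohort(
    genome,
    beta_normal: Mapping[str, np.ndarray],
    beta_tumor: Mapping[str, np.ndarray],
    design: SpikeInDesign,
    params: LibraryParams,
    catalog: Optional[Sequence[CGCGFragment]] = None,
) -> Tuple[Dict[str, List[MethylRead]], pd.DataFrame]:
    """Digested libraries for a spike-in titration.

    Each molecule is tumour-derived with probability equal to its sample's
    fraction, before conversion and digestion.  Returns
    ``{sample_id: reads}`` plus a truth table (sample, fraction, replicate,
    seed) for downstream evaluation.
    """
    samples: Dict[str, List[MethylRead]] = {}
    rows = []
    for sid, f, rep, reads in iter_spikein_cohort(
        genome, beta_normal, beta_tumor, design, params, catalog
    ):
        samples[sid] = reads
        rows.append(
            {"sample_id": sid, "fraction": f, "replicate": rep,
             "seed": f"{design.seed}.{params.seed}"}
        )
    return samples, pd.DataFrame(rows)
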