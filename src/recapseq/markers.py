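"""Hypermethylated-marker selection from fragment counts or AMF profiles.

Count-based selection normalizes to counts per million (CPM), computes a
log2 fold change with a pseudo-count, and tests each fragment with a
conditional exact test on pooled counts: given the total ``t = y1 + y2``,
``y1`` follows a binomial law with success probability proportional to the
first group's pooled library size (the phi = 0 limit), or the conditional law
induced by two negative-binomial counts with common dispersion ``phi`` and
means proportional to the library sizes.  P-values are two-sided by tail
doubling and adjusted by Benjamini-Hochberg.

AMF-based selection reproduces the methylation-fraction thresholds used for
whole-methylome (EM-seq) data: hypomethylated in the reference sample and
hypermethylated in the case sample, with strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .read_processing import FragmentCountMatrix

__all__ = [
    "MarkerRecord",
    "DispersionEstimate",
    "cpm_normalize",
    "estimate_dispersion",
    "exact_count_test",
    "bh_fdr",
    "select_count_markers",
    "select_amf_markers",
    "hypergeometric_overlap",
]


@dataclass(frozen=True)
class MarkerRecord:
    fragment_id: str
    log2fc: float
    p_value: float
    fdr: float
    mean_cpm_group1: float
    mean_cpm_group2: float


@dataclass(frozen=True)
class DispersionEstimate:
    """Common negative-binomial dispersion; 0 is the binomial/Poisson limit."""

    phi: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be nonnegative")


def cpm_normalize(matrix: FragmentCountMatrix) -> pd.DataFrame:
    """Counts per million: ``counts / library_size * 1e6`` per sample."""
    lib = matrix.library_sizes.reindex(matrix.counts.columns)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero or negative library size for samples: {bad}")
    return matrix.counts / lib * 1e6


def estimate_dispersion(
    matrix: FragmentCountMatrix, groups: Sequence[Sequence[str]]
) -> DispersionEstimate:
    """Method-of-moments common dispersion from within-group replicates.

    Counts are rescaled to the mean library size; for each fragment and each
    group with >= 2 replicates, ``phi = max(0, (s^2 - m) / m^2)``; the common
    value is the median over fragments with positive mean.
    """
    lib = matrix.library_sizes
    mean_lib = float(lib.mean())
    vals: List[float] = []
    any_reps = False
    for samples in groups:
        samples = list(samples)
        if len(samples) < 2:
            continue
        any_reps = True
        scaled = matrix.counts[samples] * (mean_lib / lib[samples])
        m = scaled.mean(axis=1).to_numpy()
        v = scaled.var(axis=1, ddof=1).to_numpy()
        ok = m > 0
        vals.extend(np.maximum(0.0, (v[ok] - m[ok]) / m[ok] ** 2))
    if not any_reps:
        warnings.warn("no group has replicates; assuming phi = 0", stacklevel=2)
        return DispersionEstimate(0.0)
    if not vals:
        return DispersionEstimate(0.0)
    return DispersionEstimate(float(np.median(vals)))


def _conditional_pmf(t: int, n1: float, n2: float, phi: float) -> np.ndarray:
    """Conditional law of y1 given y1 + y2 = t (support 0..t)."""
    k = np.arange(t + 1)
    if phi <= 1e-12:  # binomial limit (also avoids 1/phi overflow)
        return stats.binom.pmf(k, t, n1 / (n1 + n2))
    size = 1.0 / phi
    mu1 = t * n1 / (n1 + n2)
    mu2 = t * n2 / (n1 + n2)
    if min(mu1, mu2) < 1e-12:
        # one group is effectively impossible under the null; the NB masses
        # underflow and the conditional law degenerates to the binomial one
        return stats.binom.pmf(k, t, n1 / (n1 + n2))
    lp = stats.nbinom.logpmf(k, size, size / (size + mu1)) + stats.nbinom.logpmf(
        t - k, size, size / (size + mu2)
    )
    return np.exp(lp - logsumexp(lp))


def exact_count_test(y1: int, y2: int, n1: float, n2: float, phi: float = 0.0) -> float:
    """Two-sided conditional exact test of equal relative abundance.

    Under the null, the expected split of the pooled total is proportional to
    the library sizes.  The p-value doubles the smaller tail (each including
    the observed outcome) and is capped at 1; ``t == 0`` gives p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be nonnegative")
    t = y1 + y2
    if t == 0:
        return 1.0
    pmf = _conditional_pmf(t, n1, n2, phi)
    lower = float(pmf[: y1 + 1].sum())
    upper = float(pmf[y1:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_count_markers(
    matrix: FragmentCountMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    phi: Optional[float] = None,
    lfc_min: float = 5.0,
    fdr_max: float = 0.01,
    pseudocount: float = 0.5,
    technical_replicates: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Select fragments hypermethylated (over-represented) in group2.

    The log2 fold change compares group-mean CPM with a pseudo-count; the
    exact test runs on raw counts pooled within each group against pooled
    library sizes.  ``technical_replicates`` maps sample id to a technical
    unit; units are averaged on the CPM scale before the group mean.  Markers
    satisfy ``log2fc > lfc_min`` and ``fdr < fdr_max`` (strict).

    Returns the full per-fragment table (one row per fragment, sorted as the
    matrix) with a boolean ``selected`` column.
    """
    group1, group2 = list(group1), list(group2)
    if not group1 or not group2:
        raise ValueError("both groups must contain at least one sample")
    if phi is None:
        phi = estimate_dispersion(matrix, [group1, group2]).phi
    cpm = cpm_normalize(matrix)

    def group_mean(samples: List[str]) -> pd.Series:
        sub = cpm[samples]
        if technical_replicates:
            units = pd.Series({s: technical_replicates.get(s, s) for s in samples})
            sub = sub.T.groupby(units).mean().T
        return sub.mean(axis=1)

    m1 = group_mean(group1)
    m2 = group_mean(group2)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    y1 = matrix.counts[group1].sum(axis=1).to_numpy()
    y2 = matrix.counts[group2].sum(axis=1).to_numpy()
    n1 = float(matrix.library_sizes[group1].sum())
    n2 = float(matrix.library_sizes[group2].sum())
    pvals = np.array(
        [exact_count_test(int(a), int(b), n1, n2, phi) for a, b in zip(y1, y2)]
    )
    fdr = bh_fdr(pvals)
    out = pd.DataFrame(
        {
            "fragment_id": matrix.counts.index,
            "log2fc": log2fc.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
            "mean_cpm_group1": m1.to_numpy(),
            "mean_cpm_group2": m2.to_numpy(),
        }
    )
    out["selected"] = (out["log2fc"] > lfc_min) & (out["fdr"] < fdr_max)
    return out


def select_amf_markers(
    amf_a: Mapping[str, Optional[float]],
    amf_b: Mapping[str, Optional[float]],
    low: float = 0.2,
    high: float = 0.8,
) -> List[str]:
    """Regions hypomethylated in sample a (AMF < low) and hypermethylated in
    sample b (AMF > high); regions with undefined AMF are excluded."""
    out = []
    for rid in amf_a:
        if rid not in amf_b:
            continue
        a, b = amf_a[rid], amf_b[rid]
        if a is None or b is None:
            continue
        if a < low and b > high:
            out.append(rid)
    return out


def hypergeometric_overlap(set_a: Iterable, set_b: Iterable, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two marker sets:
    P(X >= |a & b|) with X ~ Hypergeom(universe, |a|, |b|)."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    k = len(a & b)
    if k > min(len(a), len(b)):
        raise ValueError("overlap exceeds smaller set")
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
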