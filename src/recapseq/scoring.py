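"""Per-sample marker scores and classification metrics.

The detection score is the total CPM over a hypermethylated marker set.  ROC
area uses the Mann-Whitney convention (ties count one half); confidence
intervals come from class-stratified bootstrap resampling; sensitivity is read
off at a fixed specificity with a step-function (no interpolation) threshold
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "SampleScore",
    "RocResult",
    "total_marker_cpm",
    "detected_marker_count",
    "roc_auc",
    "bootstrap_auc_ci",
    "sensitivity_at_specificity",
    "correlate",
    "marker_fraction_screen",
]


@dataclass(frozen=True)
class SampleScore:
    sample_id: str
    total_cpm: float
    detected_markers: int
    label: str


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sens_at_spec: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def _marker_rows(cpm: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    markers = list(markers)
    missing = [m for m in markers if m not in cpm.index]
    if missing:
        raise KeyError(f"unknown marker fragment ids: {missing[:5]}" +
                       ("..." if len(missing) > 5 else ""))
    return cpm.loc[markers]


def total_marker_cpm(cpm: pd.DataFrame, markers: Sequence[str]) -> pd.Series:
    """Per-sample sum of CPM over the marker rows (0 for an empty set)."""
    if len(list(markers)) == 0:
        return pd.Series(0.0, index=cpm.columns, name="total_cpm")
    return _marker_rows(cpm, markers).sum(axis=0).rename("total_cpm")


def detected_marker_count(
    cpm: pd.DataFrame, markers: Sequence[str], cutoff: float = 5.0
) -> pd.Series:
    """Per-sample number of markers with CPM strictly above the cutoff."""
    if len(list(markers)) == 0:
        return pd.Series(0, index=cpm.columns, name="detected_markers")
    return (_marker_rows(cpm, markers) > cutoff).sum(axis=0).rename("detected_markers")


_POSITIVE_NAMES = {"cancer", "tumor", "tumour", "case", "positive", "pos", "1", "true"}


def _as_binary(labels: Sequence, pos_label=None) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {list(uniq)}")
    if pos_label is None:
        if y.dtype.kind in "OUS":
            named = [u for u in uniq if str(u).lower() in _POSITIVE_NAMES]
            pos_label = named[0] if len(named) == 1 else uniq[1]
        else:
            pos_label = uniq.max()
    elif pos_label not in uniq:
        raise ValueError(f"pos_label {pos_label!r} not among labels {list(uniq)}")
    return (y == pos_label).astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence, pos_label=None) -> float:
    """Area under the ROC curve (Mann-Whitney U / (n_pos * n_neg), ties 1/2).

    Without ``pos_label`` the positive class is a recognized case-class name
    (cancer/tumor/case/positive) or, failing that, the larger label.
    """
    y = _as_binary(labels, pos_label)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pos_label=None,
) -> Tuple[float, float]:
    """Percentile bootstrap interval for the AUC, resampling within class."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels, pos_label)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def sensitivity_at_specificity(
    scores: Sequence[float], labels: Sequence, spec: float = 0.95, pos_label=None
) -> float:
    """Sensitivity at the smallest threshold achieving the target specificity.

    The threshold t is the smallest candidate score such that the fraction of
    negatives with score < t reaches ``spec``; sensitivity is the fraction of
    positives with score >= t.  Candidates are the observed scores plus a
    value above the maximum (which always satisfies the constraint).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels, pos_label)
    neg = s[y == 0]
    pos = s[y == 1]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both classes must be present")
    candidates = np.concatenate([np.unique(s), [s.max() + 1.0]])
    for t in candidates:
        if (neg < t).mean() >= spec:
            return float((pos >= t).mean())
    return 0.0  # unreachable: the sentinel candidate always qualifies


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> Optional[float]:
    """Pearson or Spearman (mid-rank ties) correlation; None when either
    vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return None
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method: {method!r}")


def marker_fraction_screen(
    cpm: pd.DataFrame, spikein_fractions: Sequence[float], min_r: float = 0.8
) -> Tuple[List[str], pd.DataFrame]:
    """Fragments whose CPM tracks the spike-in fraction.

    Computes the per-fragment Pearson correlation between CPM (across
    samples, in column order) and the matching spike-in fractions; returns
    the ids with ``r >= min_r`` and the full correlation table.  Fragments
    with zero CPM variance get r = NaN and are never selected.
    """
    f = np.asarray(spikein_fractions, dtype=float)
    if len(f) != cpm.shape[1]:
        raise ValueError("need one spike-in fraction per sample/column")
    x = cpm.to_numpy(dtype=float)
    fc = f - f.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (fc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ fc) / denom
    table = pd.DataFrame({"fragment_id": cpm.index, "pearson_r": r})
    selected = table.loc[table["pearson_r"] >= min_r, "fragment_id"].tolist()
    return selected, table
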