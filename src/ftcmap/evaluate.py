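"""Accuracy assessment with stratified inclusion-probability weights.

Validation samples drawn by stratified random sampling are weighted by the
inverse of their inclusion probability, w_i = K_h / k_h (population over
sample size of the sample's stratum), so MAE, RMSE and ME estimate their
population values:

    MAE  = sum(w |pre - ref|) / sum(w)
    RMSE = sqrt(sum(w (pre - ref)^2) / sum(w))
    ME   = sum(w (pre - ref)) / sum(w)

R^2 (squared Pearson correlation) and the OLS regression of reference on
prediction are reported unweighted. Inter-product consistency uses the
per-pixel mean difference over shared years.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StratumWeights",
    "PairedSamples",
    "AccuracyReport",
    "stratum_weights",
    "weighted_metrics",
    "r_squared",
    "subset_range",
    "mean_difference",
    "assess",
]


@dataclass
class StratumWeights:
    """Per-stratum population (K_h) and sample (k_h) sizes with per-sample weights."""

    K: np.ndarray
    k: np.ndarray
    weights: np.ndarray  # one weight per sample


@dataclass
class PairedSamples:
    """Paired predicted/reference tree cover with weights and stratum ids."""

    pre: np.ndarray
    ref: np.ndarray
    weights: np.ndarray
    strata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.pre.shape == self.ref.shape == self.weights.shape):
            raise ValueError("pre, ref and weights must have equal length")
        if self.weights.size and np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return self.pre.size


@dataclass
class AccuracyReport:
    """Weighted error metrics plus unweighted regression diagnostics."""

    mae: float
    rmse: float
    me: float
    r2: float
    slope: float
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def stratum_weights(K, k, assignment) -> StratumWeights:
    """Per-sample weights w_i = K_h / k_h via each sample's stratum.

    ``K`` and ``k`` are per-stratum population and sample counts (indexed by
    stratum id); ``assignment`` maps each sample to its stratum id.
    """
    K = np.asarray(K, dtype=float)
    k = np.asarray(k, dtype=float)
    if K.shape != k.shape:
        raise ValueError("K and k must be conformable")
    if np.any(k < 1):
        raise ValueError("every stratum sample size k_h must be >= 1")
    if np.any(K < k):
        raise ValueError("population size K_h must be >= sample size k_h")
    assignment = np.asarray(assignment, dtype=int)
    return StratumWeights(K=K, k=k, weights=K[assignment] / k[assignment])


def weighted_metrics(p: PairedSamples) -> tuple[float, float, float]:
    """(MAE, RMSE, ME), inclusion-probability weighted."""
    if len(p) == 0:
        raise ValueError("no samples")
    d = p.pre - p.ref
    wsum = p.weights.sum()
    mae = float(np.sum(p.weights * np.abs(d)) / wsum)
    rmse = float(np.sqrt(np.sum(p.weights * d * d) / wsum))
    me = float(np.sum(p.weights * d) / wsum)
    return mae, rmse, me


def r_squared(p: PairedSamples) -> tuple[float, float, float]:
    """(R^2, slope, intercept) of the OLS fit of reference on prediction."""
    if len(p) < 3:
        raise ValueError("need at least 3 samples for regression")
    if np.std(p.pre) == 0:
        raise ValueError("zero variance in predictions")
    res = stats.linregress(p.pre, p.ref)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def subset_range(p: PairedSamples, lo: float, hi: float) -> PairedSamples:
    """Samples whose *reference* cover lies in [lo, hi] (bounds inclusive)."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    keep = (p.ref >= lo) & (p.ref <= hi)
    if not keep.any():
        import warnings

        warnings.warn("range subset is empty", stacklevel=2)
    return PairedSamples(
        pre=p.pre[keep], ref=p.ref[keep], weights=p.weights[keep],
        strata=None if p.strata is None else np.asarray(p.strata)[keep],
    )


def assess(p: PairedSamples) -> AccuracyReport:
    """Full accuracy report: weighted MAE/RMSE/ME plus unweighted R^2 and fit."""
    mae, rmse, me = weighted_metrics(p)
    r2, slope, intercept = r_squared(p)
    return AccuracyReport(mae=mae, rmse=rmse, me=me, r2=r2,
                          slope=slope, intercept=intercept, n=len(p))


def mean_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel mean of (a - b) over the years where both stacks are valid.

    Stacks have shape (years, rows, cols); nodata is NaN. Pixels with no
    shared valid year come out NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("stacks must cover the same pixels and years")
    if a.ndim == 2:
        a, b = a[None], b[None]
    if a.shape[0] == 0:
        raise ValueError("no shared years")
    both = np.isfinite(a) & np.isfinite(b)
    diff = np.where(both, a - b, 0.0)
    n = both.sum(axis=0)
    with np.errstate(invalid="ignore"):
        md = diff.sum(axis=0) / np.where(n > 0, n, 1)
    return np.where(n > 0, md, np.nan)
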