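"""Mean-dispersion (BCV) and mean-variance characterization.

Per-gene negative-binomial dispersion is estimated by the method of moments
under the parameterization Var = mu + phi * mu^2, clipped at zero for
Poisson-or-underdispersed genes; the biological coefficient of variation is
BCV = sqrt(phi).  A mean-dispersion trend is a running median of phi within
equal-occupancy bins of log mean, linearly interpolated between bin centers
and held constant beyond them.  The same binned-running-median machinery
produces a mean-variance trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix

__all__ = [
    "DispersionEstimates",
    "Trend",
    "cpm",
    "gene_moments",
    "mom_dispersion",
    "dispersion_trend",
    "variance_trend",
    "estimate_dispersions",
]

LOG2_CPM_PRIOR = 0.5


def cpm(cm: CountMatrix, log2: bool = False, prior: float = LOG2_CPM_PRIOR) -> np.ndarray:
    """Counts per million reads.

    Raw mode: count / library_size * 1e6.  Log mode uses a prior count to
    keep zeros finite: log2((count + prior) / (library_size + 2 * prior) * 1e6).
    """
    lib = cm.library_sizes().astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"zero library size for sample(s) {[cm.sample_ids[j] for j in zero[:5]]}"
        )
    if log2:
        return np.log2(
            (cm.counts + prior) / (lib + 2 * prior)[np.newaxis, :] * 1e6
        )
    return cm.counts / lib[np.newaxis, :] * 1e6


def gene_moments(
    cm: CountMatrix, size_factors: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and unbiased (n-1) variance of normalized counts."""
    if cm.n_samples < 2:
        raise ValueError("gene_moments requires at least 2 samples")
    x = cm.counts.astype(float)
    if size_factors is not None:
        size_factors = np.asarray(size_factors, dtype=float)
        if size_factors.shape != (cm.n_samples,) or np.any(size_factors <= 0):
            raise ValueError("size_factors must be positive, one per sample")
        x = x / size_factors[np.newaxis, :]
    return x.mean(axis=1), x.var(axis=1, ddof=1)


def mom_dispersion(mean: np.ndarray, variance: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion: phi = max(0, (var - mu) / mu^2).

    Zero for zero-mean genes and wherever variance <= mean (the Poisson
    boundary of the NB family).
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, (variance - mean) / mean**2, 0.0)
    return np.maximum(phi, 0.0)


@dataclass
class Trend:
    """Piecewise-linear trend through binned running medians.

    Evaluated by linear interpolation between bin centers (on the log-mean
    axis) with constant extrapolation beyond the outermost centers.
    """

    centers: np.ndarray   # log-scale bin centers (log of mean)
    values: np.ndarray    # per-bin median of the response

    def __call__(self, mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        logm = np.log(np.maximum(mean, np.finfo(float).tiny))
        return np.interp(logm, self.centers, self.values)


def _running_median_trend(
    means: np.ndarray, response: np.ndarray, n_bins: int
) -> Trend:
    means = np.asarray(means, dtype=float)
    response = np.asarray(response, dtype=float)
    pos = means > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 features with positive mean")
    m, r = means[pos], response[pos]
    n_bins = min(n_bins, m.size)
    logm = np.log(m)
    # equal-occupancy bins on log mean
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 2:  # all means identical: one flat bin
        return Trend(
            centers=np.array([logm[0]]), values=np.array([np.median(r)])
        )
    idx = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, edges.size - 2)
    centers, values = [], []
    for b in range(edges.size - 1):
        mask = idx == b
        if mask.any():
            centers.append(float(np.median(logm[mask])))
            values.append(float(np.median(r[mask])))
    order = np.argsort(centers)
    return Trend(
        centers=np.asarray(centers)[order], values=np.asarray(values)[order]
    )


def dispersion_trend(
    means: np.ndarray, dispersions: np.ndarray, n_bins: int = 20
) -> Trend:
    """Running-median mean-dispersion trend over equal-occupancy log-mean bins."""
    return _running_median_trend(means, dispersions, n_bins)


def variance_trend(
    means: np.ndarray, variances: np.ndarray, n_bins: int = 20
) -> Trend:
    """Running-median mean-variance trend (same binning as the dispersion trend)."""
    return _running_median_trend(means, variances, n_bins)


@dataclass
class DispersionEstimates:
    """Per-feature dispersion summary of one dataset."""

    feature_ids: list[str]
    mean_log2cpm: np.ndarray
    mean_norm: np.ndarray       # normalized-count mean mu_g
    mom_dispersion: np.ndarray  # phi_g >= 0
    bcv: np.ndarray             # sqrt(phi_g)
    trend: Trend

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_log2cpm": self.mean_log2cpm,
                "mean_norm": self.mean_norm,
                "mom_dispersion": self.mom_dispersion,
                "bcv": self.bcv,
                "trend_value": self.trend(self.mean_norm),
            },
            index=self.feature_ids,
        )


def estimate_dispersions(
    cm: CountMatrix,
    size_factors: np.ndarray | None = None,
    n_bins: int = 20,
) -> DispersionEstimates:
    """Full per-gene dispersion/BCV estimation for one count matrix."""
    mean_norm, var_norm = gene_moments(cm, size_factors)
    phi = mom_dispersion(mean_norm, var_norm)
    trend = dispersion_trend(mean_norm, phi, n_bins=n_bins)
    mean_log2cpm = cpm(cm, log2=True).mean(axis=1)
    return DispersionEstimates(
        feature_ids=list(cm.feature_ids),
        mean_log2cpm=mean_log2cpm,
        mean_norm=mean_norm,
        mom_dispersion=phi,
        bcv=np.sqrt(phi),
        trend=trend,
    )
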