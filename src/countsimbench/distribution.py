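"""Distributional concordance between two count datasets.

The primary diagnostic is the quantile-quantile comparison: matched empirical
quantiles of two value vectors lie on the identity diagonal exactly when the
two empirical distributions agree.  A Q-Q comparison is summarized by the
ordinary-least-squares line through the quantile pairs, the largest absolute
quantile deviation, and the two-sample Kolmogorov-Smirnov statistic of the
underlying vectors.  Descriptive per-sample and per-feature summaries
(library sizes, zero fractions, means, variances) round out the picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .countmatrix import CountMatrix

__all__ = ["QQSummary", "qq_points", "qq_summary", "summary_stats"]


@dataclass
class QQSummary:
    slope: float
    intercept: float
    max_abs_deviation: float
    ks_stat: float
    n_quantiles: int
    degenerate: bool = False  # constant q_x: slope undefined

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "max_abs_deviation": self.max_abs_deviation,
            "ks_stat": self.ks_stat,
            "n_quantiles": self.n_quantiles,
            "degenerate": self.degenerate,
        }


def qq_points(
    x: np.ndarray, y: np.ndarray, n_quantiles: int = 99
) -> np.ndarray:
    """Matched empirical quantile pairs of two value vectors.

    Quantiles are taken at probabilities i/(n_quantiles + 1), i = 1..n_quantiles,
    with linear interpolation of order statistics (numpy's default, the
    "type 7" estimator).  Returns an (n_quantiles, 2) array of (q_x, q_y).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("qq_points requires non-empty vectors")
    probs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    return np.column_stack([np.quantile(x, probs), np.quantile(y, probs)])


def qq_summary(
    points: np.ndarray,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> QQSummary:
    """Summarize a set of Q-Q pairs.

    Slope and intercept come from ordinary least squares of q_y on q_x;
    ``max_abs_deviation`` is max |q_y - q_x| over the pairs.  When the raw
    vectors are supplied the exact two-sample KS statistic is computed from
    them; otherwise it is approximated from the quantile pairs themselves.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 2:
        raise ValueError("qq_summary needs at least two (q_x, q_y) pairs")
    qx, qy = points[:, 0], points[:, 1]
    max_dev = float(np.max(np.abs(qy - qx)))
    # closed-form OLS; a (near-)constant q_x axis leaves the slope undefined
    var_x = float(np.var(qx))
    degenerate = var_x == 0.0 or not np.isfinite(var_x)
    if degenerate:
        slope, intercept = float("nan"), float(np.mean(qy))
    else:
        slope = float(np.cov(qx, qy, bias=True)[0, 1] / var_x)
        intercept = float(np.mean(qy) - slope * np.mean(qx))
    if x is not None and y is not None:
        ks = float(stats.ks_2samp(np.ravel(x), np.ravel(y)).statistic)
    else:
        ks = float(stats.ks_2samp(qx, qy).statistic)
    return QQSummary(
        slope=float(slope),
        intercept=float(intercept),
        max_abs_deviation=max_dev,
        ks_stat=ks,
        n_quantiles=points.shape[0],
        degenerate=degenerate,
    )


def summary_stats(cm: CountMatrix) -> dict:
    """Descriptive statistics of a count matrix.

    Returns per-sample library sizes and zero fractions, per-feature means,
    variances and zero fractions, and the overall zero fraction.
    """
    counts = cm.counts
    per_sample = pd.DataFrame(
        {
            "library_size": counts.sum(axis=0),
            "zero_fraction": (counts == 0).mean(axis=0),
        },
        index=cm.sample_ids,
    )
    ddof = 1 if counts.shape[1] > 1 else 0
    per_feature = pd.DataFrame(
        {
            "mean": counts.mean(axis=1),
            "variance": counts.var(axis=1, ddof=ddof),
            "zero_fraction": (counts == 0).mean(axis=1),
        },
        index=cm.feature_ids,
    )
    return {
        "per_sample": per_sample,
        "per_feature": per_feature,
        "overall_zero_fraction": float((counts == 0).mean()),
    }
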