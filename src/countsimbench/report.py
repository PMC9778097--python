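"""Benchmark orchestration: input-vs-synthetic metric battery and ranking.

``assess_pair`` runs every metric family on an input dataset and one
synthetic dataset generated from it, and condenses each family to a scalar
distance: mean Q-Q deviation over library-size-matched sample pairs,
median absolute log-ratio between binned dispersion (and variance) trends on
a shared mean grid, KS distance between feature-pair correlation
distributions, absolute difference in DEG counts at a common FDR threshold,
and the class-silhouette gap.  A dataset compared with itself yields zero on
every distance.  ``compare_generators`` ranks several synthetic datasets per
criterion (ascending distance, ties broken by name).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix, SampleAnnotation
from .correlation import correlation_distance, correlation_profile
from .de import count_degs, deg_recovery, nb_wald_test, sign_balance
from .dispersion import Trend, estimate_dispersions, gene_moments, variance_trend
from .de import size_factors
from .distribution import qq_points, qq_summary
from .separability import assess_separability
from .simulate import GroundTruth

logger = logging.getLogger("countsimbench")

__all__ = ["MetricReport", "assess_pair", "compare_generators", "CRITERIA"]

TREND_RATIO_DELTA = 1e-3
TREND_GRID_SIZE = 50
QQ_N_QUANTILES = 99

#: ranked criteria and the report field holding each distance
CRITERIA = {
    "qq": "qq_max_abs_deviation",
    "dispersion": "dispersion_distance",
    "mean_variance": "mean_variance_distance",
    "correlation": "correlation_distance",
    "deg": "deg_abs_diff",
    "separability": "silhouette_abs_diff",
}


@dataclass
class MetricReport:
    """Scalar metric battery for one input-vs-synthetic comparison."""

    name: str
    qq_slope: float
    qq_intercept: float
    qq_max_abs_deviation: float
    qq_ks: float
    dispersion_distance: float
    mean_variance_distance: float
    correlation_distance: float
    deg_count: int
    deg_count_input: int
    sign_balance: float
    silhouette_synth: float
    silhouette_input: float
    recovery: dict | None = field(default=None)

    @property
    def deg_abs_diff(self) -> int:
        return abs(self.deg_count - self.deg_count_input)

    @property
    def silhouette_abs_diff(self) -> float:
        return abs(self.silhouette_synth - self.silhouette_input)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "qq_slope": self.qq_slope,
            "qq_intercept": self.qq_intercept,
            "qq_max_abs_deviation": self.qq_max_abs_deviation,
            "qq_ks": self.qq_ks,
            "dispersion_distance": self.dispersion_distance,
            "mean_variance_distance": self.mean_variance_distance,
            "correlation_distance": self.correlation_distance,
            "deg_count": self.deg_count,
            "deg_count_input": self.deg_count_input,
            "deg_abs_diff": self.deg_abs_diff,
            "sign_balance": self.sign_balance,
            "silhouette_synth": self.silhouette_synth,
            "silhouette_input": self.silhouette_input,
            "silhouette_abs_diff": self.silhouette_abs_diff,
        }
        if self.recovery is not None:
            d["recovery"] = self.recovery
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        drop = {"deg_abs_diff", "silhouette_abs_diff"}
        return cls(**{k: v for k, v in d.items() if k not in drop})

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _log2p1_columns(cm: CountMatrix) -> np.ndarray:
    return np.log2(cm.counts.astype(float) + 1.0)


def _qq_aggregate(input_cm: CountMatrix, synth_cm: CountMatrix) -> dict:
    """Mean Q-Q summary over sample pairs matched by library-size rank."""
    order_i = np.argsort(input_cm.library_sizes(), kind="stable")
    order_s = np.argsort(synth_cm.library_sizes(), kind="stable")
    n_pairs = min(order_i.size, order_s.size)
    vals_i = _log2p1_columns(input_cm)
    vals_s = _log2p1_columns(synth_cm)
    slopes, intercepts, maxdevs, kss = [], [], [], []
    for i, s in zip(order_i[:n_pairs], order_s[:n_pairs]):
        x, y = vals_i[:, i], vals_s[:, s]
        summ = qq_summary(qq_points(x, y, QQ_N_QUANTILES), x=x, y=y)
        if not summ.degenerate:
            slopes.append(summ.slope)
            intercepts.append(summ.intercept)
        maxdevs.append(summ.max_abs_deviation)
        kss.append(summ.ks_stat)
    return {
        "slope": float(np.mean(slopes)) if slopes else float("nan"),
        "intercept": float(np.mean(intercepts)) if intercepts else float("nan"),
        "max_abs_deviation": float(np.mean(maxdevs)),
        "ks": float(np.mean(kss)),
    }


def qq_pair_table(
    input_cm: CountMatrix, synth_cm: CountMatrix, n_pairs: int = 5
) -> pd.DataFrame:
    """Plot-ready quantile pairs for the first ``n_pairs`` library-size-matched
    sample pairs: columns (input_sample, synth_sample, prob, q_input, q_synth),
    on the log2(count + 1) scale."""
    order_i = np.argsort(input_cm.library_sizes(), kind="stable")
    order_s = np.argsort(synth_cm.library_sizes(), kind="stable")
    n_pairs = min(n_pairs, order_i.size, order_s.size)
    vals_i = _log2p1_columns(input_cm)
    vals_s = _log2p1_columns(synth_cm)
    probs = np.arange(1, QQ_N_QUANTILES + 1) / (QQ_N_QUANTILES + 1)
    rows = []
    for i, s in zip(order_i[:n_pairs], order_s[:n_pairs]):
        pts = qq_points(vals_i[:, i], vals_s[:, s], QQ_N_QUANTILES)
        for p, (qx, qy) in zip(probs, pts):
            rows.append(
                {
                    "input_sample": input_cm.sample_ids[i],
                    "synth_sample": synth_cm.sample_ids[s],
                    "prob": p,
                    "q_input": qx,
                    "q_synth": qy,
                }
            )
    return pd.DataFrame(rows)


def _trend_distance(trend_a: Trend, trend_b: Trend) -> float:
    """Median |log ratio| of two trends over a shared log-mean grid."""
    lo = max(trend_a.centers.min(), trend_b.centers.min())
    hi = min(trend_a.centers.max(), trend_b.centers.max())
    if hi < lo:  # disjoint mean ranges: compare at each trend's own span
        lo, hi = (
            min(trend_a.centers.min(), trend_b.centers.min()),
            max(trend_a.centers.max(), trend_b.centers.max()),
        )
    grid = np.linspace(lo, hi, TREND_GRID_SIZE)
    means = np.exp(grid)
    va = trend_a(means) + TREND_RATIO_DELTA
    vb = trend_b(means) + TREND_RATIO_DELTA
    return float(np.median(np.abs(np.log(vb / va))))


def _variance_trend_of(cm: CountMatrix) -> Trend:
    sf = size_factors(cm)
    mean, var = gene_moments(cm, sf)
    return variance_trend(mean, var)


def assess_pair(
    input_cm: CountMatrix,
    synth_cm: CountMatrix,
    ann_input: SampleAnnotation,
    ann_synth: SampleAnnotation,
    seed: int = 0,
    name: str = "synthetic",
    truth_synth: GroundTruth | None = None,
    alpha: float = 0.05,
) -> MetricReport:
    """Run the full metric battery on one input/synthetic dataset pair."""
    ann_input.validate_two_class(input_cm.sample_ids)
    ann_synth.validate_two_class(synth_cm.sample_ids)
    logger.info(
        "assess_pair: input %dx%d vs %s %dx%d (seed=%d, alpha=%g, "
        "qq on log2(count+1) paired by library-size rank, correlations on "
        "log2(count+1) within-class pooled)",
        input_cm.n_features, input_cm.n_samples, name,
        synth_cm.n_features, synth_cm.n_samples, seed, alpha,
    )
    qq = _qq_aggregate(input_cm, synth_cm)

    disp_i = estimate_dispersions(input_cm, size_factors(input_cm))
    disp_s = estimate_dispersions(synth_cm, size_factors(synth_cm))
    dispersion_distance = _trend_distance(disp_i.trend, disp_s.trend)
    mv_distance = _trend_distance(
        _variance_trend_of(input_cm), _variance_trend_of(synth_cm)
    )

    # same seeded substream for both profiles so identical datasets select
    # identical feature sets (self-comparison distance is exactly zero)
    prof_i = correlation_profile(input_cm, ann_input, seed=seed)
    prof_s = correlation_profile(synth_cm, ann_synth, seed=seed)
    corr_dist = correlation_distance(prof_i.rho_values, prof_s.rho_values)

    de_i = nb_wald_test(input_cm, ann_input)
    de_s = nb_wald_test(synth_cm, ann_synth)
    recovery = (
        deg_recovery(de_s, truth_synth, alpha) if truth_synth is not None else None
    )

    sep_i = assess_separability(input_cm, ann_input)
    sep_s = assess_separability(synth_cm, ann_synth)

    return MetricReport(
        name=name,
        qq_slope=qq["slope"],
        qq_intercept=qq["intercept"],
        qq_max_abs_deviation=qq["max_abs_deviation"],
        qq_ks=qq["ks"],
        dispersion_distance=dispersion_distance,
        mean_variance_distance=mv_distance,
        correlation_distance=corr_dist,
        deg_count=count_degs(de_s, alpha),
        deg_count_input=count_degs(de_i, alpha),
        sign_balance=sign_balance(de_s, alpha),
        silhouette_synth=sep_s.silhouette,
        silhouette_input=sep_i.silhouette,
        recovery=recovery,
    )


def compare_generators(entries: Sequence[MetricReport]) -> pd.DataFrame:
    """Rank generators per criterion (ascending distance, ties by name).

    Returns a DataFrame indexed by generator name with one rank column per
    criterion plus the underlying distances.
    """
    if not entries:
        raise ValueError("compare_generators needs at least one entry")
    rows = {}
    for e in entries:
        rows[e.name] = {c: float(getattr(e, attr)) for c, attr in CRITERIA.items()}
    dist = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out = dist.add_prefix("distance_")
    for c in CRITERIA:
        order = sorted(dist.index, key=lambda g: (dist.loc[g, c], g))
        out[f"rank_{c}"] = [order.index(g) + 1 for g in dist.index]
    return out
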