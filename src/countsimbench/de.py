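"""Two-class differential expression testing on count data.

A self-contained negative-binomial Wald procedure: samples are normalized by
median-of-ratios size factors; per-gene dispersions come from the
method-of-moments estimator applied to the residual variance around the
class means (pooled across the two classes, so the tested effect does not
inflate its own noise estimate), with a running-median trend; the final
dispersion is the more conservative of gene estimate and trend.  The log2
fold change between normalized class means is then tested with a
delta-method standard error under Var = mu + phi * mu^2.  P-values are
two-sided normal, adjusted by Benjamini-Hochberg.

The procedure is deliberately simple and analytically checkable; it is not a
re-implementation of any published DE package, and absolute discovery counts
are expected to differ from such packages at the margin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .countmatrix import CountMatrix, SampleAnnotation
from .dispersion import (
    DispersionEstimates,
    dispersion_trend as dispersion_trend_fn,
    mom_dispersion as mom_dispersion_fn,
)
from .simulate import GroundTruth

__all__ = [
    "DEResult",
    "VolcanoTable",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "count_degs",
    "volcano_table",
    "sign_balance",
    "deg_recovery",
]

MEAN_PSEUDOCOUNT = 0.5
DEFAULT_ALPHA = 0.05
NEG_LOG10_P_CEILING = 320.0  # cap applied to -log10(p) for p underflowing to 0


@dataclass
class DEResult:
    """Per-feature Wald-test results for a two-class comparison."""

    feature_ids: list[str]
    base_mean: np.ndarray
    lfc: np.ndarray      # log2(class2 / class1)
    se: np.ndarray
    wald: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "base_mean": self.base_mean,
                "lfc": self.lfc,
                "se": self.se,
                "wald": self.wald,
                "pvalue": self.pvalue,
                "qvalue": self.qvalue,
            },
            index=self.feature_ids,
        )


@dataclass
class VolcanoTable:
    feature_ids: list[str]
    lfc: np.ndarray
    neg_log10_p: np.ndarray
    volcano_class: list[str]  # nonsig | sig_small_fc | sig_up | sig_down

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lfc": self.lfc,
                "neg_log10_p": self.neg_log10_p,
                "volcano_class": self.volcano_class,
            },
            index=self.feature_ids,
        )


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    s_j = median over reference features g of count(g, j) / geomean_j'(count(g, j')),
    where the reference set is the features with all-positive counts.  When no
    feature is positive in every sample, the geometric means are computed over
    each feature's positive entries instead (with a warning).
    """
    counts = cm.counts.astype(float)
    all_pos = np.all(counts > 0, axis=1)
    if np.any(all_pos):
        ref = counts[all_pos, :]
        geomean = np.exp(np.mean(np.log(ref), axis=1))
        ratios = ref / geomean[:, np.newaxis]
    else:
        warnings.warn(
            "no feature with all-positive counts; using positive-subset "
            "geometric means",
            stacklevel=2,
        )
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        geomean = np.exp(np.nanmean(logc, axis=1))
        keep = np.isfinite(geomean) & (geomean > 0)
        if not np.any(keep):
            raise ValueError("cannot compute size factors: all-zero matrix")
        with np.errstate(invalid="ignore"):
            ratios = np.where(
                counts[keep, :] > 0,
                counts[keep, :] / geomean[keep, np.newaxis],
                np.nan,
            )
        sf = np.nanmedian(ratios, axis=0)
        if np.any(~np.isfinite(sf) | (sf <= 0)):
            raise ValueError("size factor undefined for some sample")
        return sf
    return np.median(ratios, axis=0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(
    cm: CountMatrix,
    ann: SampleAnnotation,
    dispersions: DispersionEstimates | None = None,
    size_factors_: np.ndarray | None = None,
) -> DEResult:
    """Delta-method NB Wald test of class 2 vs class 1.

    For gene g with normalized class means m1, m2 (n1, n2 samples) and final
    dispersion phi_g = max(gene MoM estimate, trend value at the gene mean):

        lfc  = log2((m2 + eps) / (m1 + eps)),  eps = 0.5
        v_k  = (m_k + phi_g * m_k^2) / n_k
        se   = sqrt(v1 / (m1 + eps)^2 + v2 / (m2 + eps)^2) / ln 2
        wald = lfc / se,  two-sided normal p-value.

    By default the MoM dispersion is computed from the residual variance
    around the two class means (within-class pooled), so a true expression
    difference does not inflate the noise estimate of the very gene carrying
    it.  Passing precomputed ``dispersions`` (e.g. the design-blind estimates
    from the dispersion diagnostics) overrides this.
    """
    labels = ann.labels_for(cm.sample_ids)
    for c in (1, 2):
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c} needs at least 2 samples")
    sf = size_factors(cm) if size_factors_ is None else np.asarray(
        size_factors_, dtype=float
    )
    norm = cm.counts / sf[np.newaxis, :]
    in1, in2 = labels == 1, labels == 2
    n1, n2 = int(in1.sum()), int(in2.sum())
    m1 = norm[:, in1].mean(axis=1)
    m2 = norm[:, in2].mean(axis=1)
    if dispersions is not None:
        phi = np.maximum(
            dispersions.mom_dispersion,
            dispersions.trend(dispersions.mean_norm),
        )
    else:
        v1 = norm[:, in1].var(axis=1, ddof=1)
        v2 = norm[:, in2].var(axis=1, ddof=1)
        resid_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        grand_mean = (n1 * m1 + n2 * m2) / (n1 + n2)
        phi_mom = mom_dispersion_fn(grand_mean, resid_var)
        trend = dispersion_trend_fn(grand_mean, phi_mom)
        phi = np.maximum(phi_mom, trend(grand_mean))
    eps = MEAN_PSEUDOCOUNT
    lfc = np.log2((m2 + eps) / (m1 + eps))
    v1 = (m1 + phi * m1**2) / n1
    v2 = (m2 + phi * m2**2) / n2
    se = np.sqrt(v1 / (m1 + eps) ** 2 + v2 / (m2 + eps) ** 2) / math.log(2.0)
    se = np.maximum(se, np.finfo(float).tiny)
    wald = np.where(lfc == 0.0, 0.0, lfc / se)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    pvalue = np.minimum(pvalue, 1.0)
    return DEResult(
        feature_ids=list(cm.feature_ids),
        base_mean=norm.mean(axis=1),
        lfc=lfc,
        se=se,
        wald=wald,
        pvalue=pvalue,
        qvalue=bh_adjust(pvalue),
    )


def count_degs(res: DEResult, alpha: float = DEFAULT_ALPHA) -> int:
    """Number of features with BH q-value <= alpha."""
    return int(np.sum(res.qvalue <= alpha))


def volcano_table(
    res: DEResult,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    neg_log10_ceiling: float = NEG_LOG10_P_CEILING,
) -> VolcanoTable:
    """Classify features for a volcano plot.

    Significance is p < ``p_thresh``; significant features with
    |lfc| > ``lfc_thresh`` are ``sig_up`` / ``sig_down`` by sign, other
    significant features ``sig_small_fc``, the rest ``nonsig``.
    """
    p = np.maximum(res.pvalue, 0.0)
    with np.errstate(divide="ignore"):
        neg_log10 = np.where(p > 0, -np.log10(p), neg_log10_ceiling)
    neg_log10 = np.minimum(neg_log10, neg_log10_ceiling)
    classes = []
    for pv, fc in zip(res.pvalue, res.lfc):
        if pv >= p_thresh:
            classes.append("nonsig")
        elif fc > lfc_thresh:
            classes.append("sig_up")
        elif fc < -lfc_thresh:
            classes.append("sig_down")
        else:
            classes.append("sig_small_fc")
    return VolcanoTable(
        feature_ids=list(res.feature_ids),
        lfc=res.lfc.copy(),
        neg_log10_p=neg_log10,
        volcano_class=classes,
    )


def sign_balance(res: DEResult, alpha: float = DEFAULT_ALPHA) -> float:
    """Fraction of significant features (q <= alpha) with positive lfc.

    Returns NaN when nothing is significant (undefined).
    """
    sig = res.qvalue <= alpha
    if not np.any(sig):
        return float("nan")
    return float(np.mean(res.lfc[sig] > 0))


def deg_recovery(
    res: DEResult, truth: GroundTruth, alpha: float = DEFAULT_ALPHA
) -> dict:
    """Sensitivity and observed FDR of the caller against designed truth."""
    de_true = np.asarray(truth.de_flags, bool)
    if not np.any(de_true):
        raise ValueError("ground truth has no DE feature")
    called = res.qvalue <= alpha
    tp = int(np.sum(called & de_true))
    fp = int(np.sum(called & ~de_true))
    return {
        "sensitivity": tp / int(de_true.sum()),
        "observed_fdr": fp / max(1, int(called.sum())),
        "n_discoveries": int(called.sum()),
    }
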