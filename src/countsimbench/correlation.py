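"""Feature-feature correlation structure comparison.

Mirrors the standard diagnostic for synthetic count data: take up to 25
randomly chosen non-constant features, compute Spearman correlations for all
pairs, and compare the resulting correlation distributions of two datasets
with a two-sample Kolmogorov-Smirnov distance.  For simulated data with
designed correlation blocks, block recovery contrasts mean within-block
correlation against a matched sample of off-block pairs.

By default correlations are computed on log2(count + 1) within each class
separately and pooled, which prevents between-class mean shifts (DE) from
inflating the correlations; a raw pooled mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from ._rng import substream
from .countmatrix import CountMatrix, SampleAnnotation
from .simulate import GroundTruth

__all__ = [
    "CorrelationSummary",
    "select_nonconstant_features",
    "spearman_pairs",
    "correlation_distance",
    "block_recovery",
    "correlation_profile",
]

MAX_SELECTED_FEATURES = 25
OFF_BLOCK_PAIR_MULTIPLIER = 10


@dataclass
class CorrelationSummary:
    selected_features: list[str]
    rho_values: np.ndarray
    distance_vs_reference: float | None = None


def select_nonconstant_features(
    cm: CountMatrix, max_n: int = MAX_SELECTED_FEATURES, seed: int = 0
) -> list[str]:
    """Feature ids with >= 2 distinct values; seeded subsample of ``max_n``
    when more qualify."""
    nonconst = [
        fid
        for fid, row in zip(cm.feature_ids, cm.counts)
        if row.min() != row.max()
    ]
    if not nonconst:
        warnings.warn("no non-constant features found", stacklevel=2)
        return []
    if len(nonconst) <= max_n:
        return nonconst
    rng = substream(seed, "select_features")
    picked = rng.choice(len(nonconst), size=max_n, replace=False)
    return [nonconst[i] for i in sorted(picked)]


def _pair_rhos(values: np.ndarray) -> np.ndarray:
    """Spearman rho for every unordered row pair, pairs in lexicographic order."""
    if values.shape[0] < 2:
        raise ValueError("need at least 2 features")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for Spearman correlation")
    # average-rank transform per row, then Pearson on ranks
    ranks = np.apply_along_axis(stats.rankdata, 1, values.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-rank rows
        corr = np.corrcoef(ranks)
    iu = np.triu_indices(values.shape[0], k=1)
    rhos = corr[iu]
    return np.nan_to_num(rhos, nan=0.0)


def spearman_pairs(cm: CountMatrix, features: list[str]) -> np.ndarray:
    """All-pairs Spearman correlations (ties averaged) for the given features.

    Pairs are ordered lexicographically by the positions in ``features``:
    (0,1), (0,2), ..., (k-2, k-1).
    """
    sub = cm.subset_features(features)
    return _pair_rhos(sub.counts)


def correlation_distance(rhos_a: np.ndarray, rhos_b: np.ndarray) -> float:
    """Two-sample KS distance between two correlation distributions."""
    rhos_a = np.asarray(rhos_a, float)
    rhos_b = np.asarray(rhos_b, float)
    if rhos_a.size == 0 or rhos_b.size == 0:
        raise ValueError("correlation vectors must be non-empty")
    return float(stats.ks_2samp(rhos_a, rhos_b).statistic)


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(x.astype(float) + 1.0)


def _class_pooled_rhos(
    values: np.ndarray, class_labels: np.ndarray | None
) -> np.ndarray:
    """Pair correlations computed within each class then pooled; pooled
    across all samples when labels are absent."""
    if class_labels is None:
        return _pair_rhos(values)
    rhos = []
    for c in np.unique(class_labels):
        cols = class_labels == c
        if cols.sum() >= 3:
            rhos.append(_pair_rhos(values[:, cols]))
    if not rhos:
        raise ValueError("no class with >= 3 samples")
    return np.concatenate(rhos)


def correlation_profile(
    cm: CountMatrix,
    ann: SampleAnnotation | None = None,
    max_n: int = MAX_SELECTED_FEATURES,
    seed: int = 0,
    transform: str = "log2",
) -> CorrelationSummary:
    """Correlation distribution of a dataset over selected non-constant features.

    ``transform='log2'`` (default) correlates log2(count + 1) within each
    class separately and pools the values; ``transform='raw'`` correlates raw
    counts pooled across all samples.
    """
    features = select_nonconstant_features(cm, max_n=max_n, seed=seed)
    if len(features) < 2:
        return CorrelationSummary(features, np.array([]))
    sub = cm.subset_features(features)
    if transform == "log2":
        values = _log2p1(sub.counts)
        labels = ann.labels_for(cm.sample_ids) if ann is not None else None
    elif transform == "raw":
        values, labels = sub.counts.astype(float), None
    else:
        raise ValueError(f"unknown transform {transform!r}")
    rhos = _class_pooled_rhos(values, labels)
    return CorrelationSummary(features, rhos)


def block_recovery(
    cm: CountMatrix,
    truth: GroundTruth,
    seed: int = 0,
    transform: str = "raw",
) -> dict:
    """Mean within-block vs off-block pairwise Spearman correlation.

    Off-block pairs are a seeded random sample sized ten times the number of
    within-block pairs; constant features are excluded with a warning.
    Returns ``{"within_block_mean", "off_block_mean", "per_block"}``.
    """
    block_ids = np.asarray(truth.block_id)
    if not np.any(block_ids >= 0):
        raise ValueError("ground truth contains no correlation block")
    values = (
        _log2p1(cm.counts) if transform == "log2" else cm.counts.astype(float)
    )
    nonconst = cm.counts.min(axis=1) != cm.counts.max(axis=1)
    per_block: dict[int, float] = {}
    n_within_pairs = 0
    within_all: list[float] = []
    for b in np.unique(block_ids[block_ids >= 0]):
        idx = np.flatnonzero((block_ids == b) & nonconst)
        dropped = int(((block_ids == b) & ~nonconst).sum())
        if dropped:
            warnings.warn(
                f"block {b}: {dropped} constant feature(s) excluded",
                stacklevel=2,
            )
        if idx.size < 2:
            continue
        rhos = _pair_rhos(values[idx, :])
        per_block[int(b)] = float(rhos.mean())
        within_all.extend(rhos.tolist())
        n_within_pairs += rhos.size
    if n_within_pairs == 0:
        raise ValueError("no block with >= 2 non-constant features")
    off_idx = np.flatnonzero((block_ids < 0) & nonconst)
    rng = substream(seed, "off_block_pairs")
    n_off = OFF_BLOCK_PAIR_MULTIPLIER * n_within_pairs
    off_rhos: list[float] = []
    if off_idx.size >= 2:
        for _ in range(n_off):
            i, j = rng.choice(off_idx.size, size=2, replace=False)
            r = stats.spearmanr(values[off_idx[i]], values[off_idx[j]]).statistic
            off_rhos.append(0.0 if np.isnan(r) else float(r))
    return {
        "within_block_mean": float(np.mean(within_all)),
        "off_block_mean": float(np.mean(off_rhos)) if off_rhos else float("nan"),
        "per_block": per_block,
    }
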