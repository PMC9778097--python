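"""Two-class separability via principal-component embedding.

Samples are embedded in the plane of the first two principal components of
the per-feature-centered log2-CPM matrix; class separability is the mean
silhouette coefficient of the class labels in that plane.  The silhouette is
near 1 for two tight, distant classes, near 0 for fully mixed classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .countmatrix import CountMatrix, SampleAnnotation
from .dispersion import cpm

__all__ = ["SeparabilityResult", "pca_embed", "separability_score", "assess_separability"]


@dataclass
class SeparabilityResult:
    sample_ids: list[str]
    scores: np.ndarray              # samples x 2
    variance_explained: tuple[float, float]
    silhouette: float

    def to_frame(self, ann: SampleAnnotation | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, index=self.sample_ids, columns=["PC1", "PC2"]
        )
        if ann is not None:
            df.insert(0, "class", ann.labels_for(self.sample_ids))
        return df


def pca_embed(
    cm: CountMatrix, n_components: int = 2, top_k_features: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of samples on log2-CPM values.

    Features are centered but not scaled.  Component signs are fixed by
    making the largest-magnitude loading of each component positive, so the
    embedding is fully deterministic.  ``top_k_features`` optionally
    restricts to the most variable features first.
    """
    if cm.n_samples < 3 or cm.n_features < 2:
        raise ValueError("pca_embed needs >= 3 samples and >= 2 features")
    x = cpm(cm, log2=True).T  # samples x features
    if top_k_features is not None and top_k_features < x.shape[1]:
        var = x.var(axis=0)
        keep = np.argsort(var)[::-1][:top_k_features]
        x = x[:, np.sort(keep)]
    if np.allclose(x, x[0, :]):
        raise ValueError("constant matrix: PCA undefined")
    n_components = min(n_components, cm.n_samples - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] *= -1
    return scores, pca.explained_variance_ratio_


def separability_score(scores: np.ndarray, ann: SampleAnnotation, sample_ids: list[str]) -> float:
    """Mean silhouette of the class labels on the first two embedding axes."""
    labels = ann.labels_for(sample_ids)
    for c in (1, 2):
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c} needs at least 2 samples for silhouette")
    return float(silhouette_score(scores[:, :2], labels, metric="euclidean"))


def assess_separability(
    cm: CountMatrix, ann: SampleAnnotation, top_k_features: int | None = None
) -> SeparabilityResult:
    """PCA embedding plus class silhouette for one dataset."""
    scores, varexp = pca_embed(cm, n_components=2, top_k_features=top_k_features)
    sil = separability_score(scores, ann, cm.sample_ids)
    ve = tuple(float(v) for v in varexp[:2]) if len(varexp) >= 2 else (
        float(varexp[0]),
        0.0,
    )
    return SeparabilityResult(
        sample_ids=list(cm.sample_ids),
        scores=scores[:, :2],
        variance_explained=ve,
        silhouette=sil,
    )
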