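"""Deterministic tiny datasets for tests and documentation examples.

Every fixture is generated in code from (name, seed); nothing is shipped on
disk and nothing is downloaded.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .countmatrix import CountMatrix, SampleAnnotation
from .simulate import GroundTruth, preset_config, simulate_dataset

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "tiny_counts",
    "null_nb",
    "two_blob",
    "ngsspg1_small",
    "ngsspg2_small",
)

#: truncation ceiling paired with tiny_counts (one entry lies above it)
TINY_TRUNCATION_CEILING = 100


def _tiny_counts() -> tuple[CountMatrix, SampleAnnotation]:
    # 6 features x 4 samples: row "g_zeromed" has median 0, row "g_big"
    # carries one value above TINY_TRUNCATION_CEILING
    counts = np.array(
        [
            [5, 8, 6, 7],
            [0, 0, 0, 9],      # zero-median feature
            [1, 1, 1, 1],
            [12, 250, 11, 13], # 250 > TINY_TRUNCATION_CEILING
            [3, 0, 4, 2],
            [20, 22, 19, 21],
        ],
        dtype=np.int64,
    )
    feature_ids = ["g_a", "g_zeromed", "g_const1", "g_big", "g_c", "g_d"]
    sample_ids = ["s1", "s2", "s3", "s4"]
    ann = SampleAnnotation({"s1": 1, "s2": 1, "s3": 2, "s4": 2})
    return CountMatrix(counts, feature_ids, sample_ids), ann


def _null_nb(
    seed: int, n_features: int = 2000, n_per_class: int = 25,
    mu: float = 300.0, phi: float = 0.1,
) -> tuple[CountMatrix, SampleAnnotation]:
    """NB counts with no class effect (gamma-Poisson mixture)."""
    rng = substream(seed, "null_nb")
    n = 2 * n_per_class
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi, size=(n_features, n))
    counts = rng.poisson(lam).astype(np.int64)
    cm = CountMatrix(
        counts,
        [f"g{i}" for i in range(n_features)],
        [f"s{j}" for j in range(n)],
    )
    ann = SampleAnnotation(
        {f"s{j}": (1 if j < n_per_class else 2) for j in range(n)}
    )
    return cm, ann


def _two_blob(
    seed: int, n_features: int = 200, n_per_class: int = 10
) -> tuple[CountMatrix, SampleAnnotation]:
    """Two well-separated classes: strong mean shift on half the features."""
    rng = substream(seed, "two_blob")
    n = 2 * n_per_class
    base = rng.uniform(50, 500, size=n_features)
    rates = np.tile(base[:, np.newaxis], (1, n))
    shifted = np.arange(n_features) < n_features // 2
    rates[np.ix_(shifted, np.arange(n_per_class, n))] *= 8.0
    counts = rng.poisson(rates).astype(np.int64)
    cm = CountMatrix(
        counts,
        [f"g{i}" for i in range(n_features)],
        [f"s{j}" for j in range(n)],
    )
    ann = SampleAnnotation(
        {f"s{j}": (1 if j < n_per_class else 2) for j in range(n)}
    )
    return cm, ann


def make_fixture(name: str, seed: int = 0):
    """Build a named fixture.

    Returns ``(CountMatrix, SampleAnnotation)`` for data-only fixtures and
    ``(CountMatrix, SampleAnnotation, GroundTruth)`` for the simulator-backed
    ones (``ngsspg1_small``, ``ngsspg2_small``: the full presets with only
    the dimensions shrunk to 500 features x 20 samples).
    """
    if name == "tiny_counts":
        return _tiny_counts()
    if name == "null_nb":
        return _null_nb(seed)
    if name == "two_blob":
        return _two_blob(seed)
    if name in ("ngsspg1_small", "ngsspg2_small"):
        preset = name.replace("_", "-")
        cm, truth = simulate_dataset(preset_config(preset), seed=seed)
        ann = truth.annotation(cm.sample_ids)
        return cm, ann, truth
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
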