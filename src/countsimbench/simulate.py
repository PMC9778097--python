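"""Ground-truth two-class RNA-seq count simulator.

The generative model has two stages:

1. Latent log-concentrations are multivariate Gaussian per sample: column
   ``s`` is drawn from N(mu(class(s)), sigma^2 * R), where R is a block
   compound-symmetry correlation matrix (designed feature-feature blocks at
   correlation ``block_rho``, identity elsewhere).  Differentially expressed
   (DE) features receive an additive shift of ``lfc_de * ln(2)`` in class 2;
   heterogeneous markers shift only in a designated subset of class-1
   subgroups.
2. Reads are Poisson: ``count(g, s) ~ Poisson(scale * d_s * exp(latent))``
   with an optional per-sample depth jitter ``d_s``.  The rate multiplier
   ``scale`` is calibrated empirically so the grand mean count hits a target
   (default 300 reads per feature).

Because the latent log scale is Gaussian, concentrations are log-normal and
Poisson rates are automatically positive; marginally the counts are
overdispersed (Poisson-log-normal), with the latent standard deviation
``sigma`` controlling the biological noise level.  Two presets are provided:
``ngsspg1`` (sigma = 0.4, easily separable classes) and ``ngsspg2``
(sigma = 0.7, strongly mixed classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._rng import substream
from .countmatrix import CountMatrix, SampleAnnotation

__all__ = [
    "SimConfig",
    "GroundTruth",
    "BlockCovariance",
    "SimulationError",
    "build_covariance",
    "simulate_log_concentrations",
    "calibrate_depth",
    "simulate_counts",
    "simulate_dataset",
    "preset_config",
    "PRESETS",
]

#: Poisson rates above this raise instead of silently overflowing
RATE_CEILING = 1e12

#: depth-calibration contract: relative tolerance and iteration cap
CALIBRATION_RTOL = 0.01
CALIBRATION_MAX_ITER = 20


class SimulationError(ValueError):
    """Invalid simulator configuration or failed calibration."""


def _round_half_even(x: float) -> int:
    # banker's rounding, so 0.05*10000 -> 500 and 0.05*34616 -> 1731
    return int(round(x))


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated dataset.

    Attributes
    ----------
    n_features, n_per_class
        Matrix dimensions; ``n_per_class`` is (class 1, class 2).
    n_subgroups_class1
        Number of latent subgroups within class 1 (heterogeneous markers
        shift only in some of them).
    de_fraction / n_global_markers
        Fraction (or absolute number) of globally DE features.
    n_hetero_markers
        Features shifted only in a subset of class-1 subgroups.
    baseline_log_mean
        Natural-log latent concentration baseline (shared by all features;
        absolute scale is set by depth calibration, not by this value).
    lfc_de
        log2 fold change of DE features (class 2 over class 1).
    sigma
        Latent log-scale standard deviation (biological noise).
    block_size, block_rho, n_blocks
        Designed feature-feature correlation blocks.
    target_mean_count
        Grand-mean reads per matrix entry after depth calibration.
    depth_jitter
        (low, high) bounds of the uniform per-sample depth factor;
        (1.0, 1.0) disables depth variation.
    """

    n_features: int = 10_000
    n_per_class: tuple[int, int] = (50, 50)
    n_subgroups_class1: int = 1
    de_fraction: float = 0.05
    n_global_markers: Optional[int] = None
    n_hetero_markers: int = 0
    baseline_log_mean: float = 0.0
    lfc_de: float = 1.0
    sigma: float = 0.4
    block_size: int = 5
    block_rho: float = 0.4
    n_blocks: int = 1
    target_mean_count: float = 300.0
    depth_jitter: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(self.n_per_class[0] + self.n_per_class[1])

    @property
    def n_de(self) -> int:
        """Number of globally DE (marker) features."""
        if self.n_global_markers is not None:
            return int(self.n_global_markers)
        return _round_half_even(self.de_fraction * self.n_features)

    def validate(self) -> None:
        if self.n_features <= 0:
            raise SimulationError("n_features must be positive")
        if min(self.n_per_class) <= 0:
            raise SimulationError("n_per_class entries must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise SimulationError("de_fraction must lie in [0, 1]")
        if self.n_hetero_markers < 0:
            raise SimulationError("n_hetero_markers must be >= 0")
        if self.sigma < 0:
            raise SimulationError("sigma must be non-negative")
        if self.n_subgroups_class1 <= 0:
            raise SimulationError("n_subgroups_class1 must be positive")
        if self.target_mean_count <= 0:
            raise SimulationError("target_mean_count must be positive")
        lo, hi = self.depth_jitter
        if not (0 < lo <= hi):
            raise SimulationError("depth_jitter must satisfy 0 < low <= high")
        if self.n_blocks > 0 and self.block_size > 1:
            lower = -1.0 / (self.block_size - 1)
            if not (lower < self.block_rho < 1.0):
                raise SimulationError(
                    f"block_rho={self.block_rho} outside positive-definite "
                    f"range ({lower:.4f}, 1) for block_size={self.block_size}"
                )
        if self.n_blocks * self.block_size > self.n_features:
            raise SimulationError(
                "n_blocks * block_size exceeds n_features"
            )
        needed = self.n_de + self.n_hetero_markers + self.n_blocks * self.block_size
        if needed > self.n_features:
            raise SimulationError(
                f"marker/block layout needs {needed} features, "
                f"have {self.n_features}"
            )


PRESETS: dict[str, SimConfig] = {
    # "simple" two-class preset: low latent noise, well separable
    "ngsspg1": SimConfig(sigma=0.4),
    # "difficult" preset: high latent noise, strongly mixed classes
    "ngsspg2": SimConfig(sigma=0.7),
    # scaled-down variants for examples and fast checks: only the
    # dimensions shrink, every statistical parameter is identical
    "ngsspg1-small": SimConfig(sigma=0.4, n_features=500, n_per_class=(10, 10)),
    "ngsspg2-small": SimConfig(sigma=0.7, n_features=500, n_per_class=(10, 10)),
}


def preset_config(name: str, **overrides) -> SimConfig:
    """Look up a preset by name, optionally overriding fields."""
    key = name.lower()
    if key not in PRESETS:
        raise SimulationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    cfg = PRESETS[key]
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """Per-feature and per-sample truth emitted alongside a simulation."""

    de_flags: np.ndarray          # bool, per feature
    true_lfc: np.ndarray          # log2, per feature (0 where not DE)
    block_id: np.ndarray          # int per feature, -1 = not in a block
    class_label: np.ndarray       # {1, 2} per sample
    subgroup_label: np.ndarray    # int per sample (-1 for class-2 samples)
    hetero_flags: np.ndarray = field(default=None)  # bool, per feature
    hetero_subgroups: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.hetero_flags is None:
            self.hetero_flags = np.zeros(len(self.de_flags), dtype=bool)
        if np.any(self.true_lfc[~self.de_flags] != 0.0):
            raise SimulationError("true_lfc must be 0 where de_flags is false")

    def annotation(self, sample_ids: list[str]) -> SampleAnnotation:
        class_of = dict(zip(sample_ids, (int(c) for c in self.class_label)))
        subgroup_of = {
            s: int(g)
            for s, g in zip(sample_ids, self.subgroup_label)
            if g >= 0
        }
        return SampleAnnotation(class_of, subgroup_of)


# ---------------------------------------------------------------------------
# Covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockCovariance:
    """Block compound-symmetry correlation structure.

    ``blocks`` maps block id -> feature indices; all within-block
    off-diagonals equal ``rho``, everything else is independent.  The full
    matrix is materialized only on demand (it is identity outside the
    blocks), so simulations with tens of thousands of features never build
    an n x n matrix.
    """

    n_features: int
    blocks: tuple[tuple[int, ...], ...]
    rho: float

    def block_matrix(self, k: int) -> np.ndarray:
        size = len(self.blocks[k])
        return np.full((size, size), self.rho) + (1 - self.rho) * np.eye(size)

    def full(self) -> np.ndarray:
        """Dense correlation matrix (use only for modest n_features)."""
        R = np.eye(self.n_features)
        for block in self.blocks:
            idx = np.array(block)
            R[np.ix_(idx, idx)] = self.block_matrix(0)[: len(idx), : len(idx)]
        return R

    def block_of(self) -> np.ndarray:
        """Per-feature block id (-1 outside all blocks)."""
        out = np.full(self.n_features, -1, dtype=int)
        for k, block in enumerate(self.blocks):
            out[list(block)] = k
        return out


def _feature_layout(config: SimConfig) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Deterministic feature layout: DE markers first, then heterogeneous
    markers, then the correlation blocks."""
    n_de = config.n_de
    de_idx = np.arange(n_de)
    het_idx = np.arange(n_de, n_de + config.n_hetero_markers)
    start = n_de + config.n_hetero_markers
    blocks = [
        list(range(start + k * config.block_size,
                   start + (k + 1) * config.block_size))
        for k in range(config.n_blocks)
    ]
    return de_idx, het_idx, blocks


def build_covariance(config: SimConfig) -> BlockCovariance:
    """Construct the designed feature-feature correlation structure.

    Within each block all off-diagonals equal ``block_rho``; all other
    correlations are zero.  Compound symmetry of size k is positive definite
    iff rho is in (-1/(k-1), 1); violations are rejected at validation.
    """
    config.validate()
    _, _, blocks = _feature_layout(config)
    return BlockCovariance(
        n_features=config.n_features,
        blocks=tuple(tuple(b) for b in blocks),
        rho=config.block_rho if config.n_blocks > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# Latent Gaussian stage
# ---------------------------------------------------------------------------

def _class_assignment(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = config.n_per_class
    class_label = np.concatenate([np.ones(n1, int), np.full(n2, 2, int)])
    subgroup = np.full(n1 + n2, -1, dtype=int)
    subgroup[:n1] = np.arange(n1) % config.n_subgroups_class1
    return class_label, subgroup


def _mean_matrix(config: SimConfig, truth: GroundTruth) -> np.ndarray:
    """Per-sample latent mean vectors (n_features x n_samples)."""
    mu = np.full(
        (config.n_features, config.n_samples), config.baseline_log_mean
    )
    shift = config.lfc_de * math.log(2.0)
    in_class2 = truth.class_label == 2
    mu[np.ix_(truth.de_flags, in_class2)] += shift
    if truth.hetero_flags.any() and truth.hetero_subgroups:
        in_hetero = np.isin(truth.subgroup_label, truth.hetero_subgroups) & (
            truth.class_label == 1
        )
        mu[np.ix_(truth.hetero_flags, in_hetero)] += shift
    return mu


def make_ground_truth(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Lay out DE flags, heterogeneous markers and blocks for a config."""
    config.validate()
    if seed is None:
        seed = config.seed
    de_idx, het_idx, blocks = _feature_layout(config)
    de_flags = np.zeros(config.n_features, dtype=bool)
    de_flags[de_idx] = True
    true_lfc = np.where(de_flags, config.lfc_de, 0.0)
    hetero_flags = np.zeros(config.n_features, dtype=bool)
    hetero_flags[het_idx] = True
    block_id = np.full(config.n_features, -1, dtype=int)
    for k, b in enumerate(blocks):
        block_id[b] = k
    class_label, subgroup = _class_assignment(config)
    hetero_subgroups: tuple[int, ...] = ()
    if config.n_hetero_markers > 0:
        n_shift = math.ceil(config.n_subgroups_class1 / 2)
        rng = substream(seed, "hetero_subgroups")
        hetero_subgroups = tuple(
            sorted(
                rng.choice(
                    config.n_subgroups_class1, size=n_shift, replace=False
                ).tolist()
            )
        )
    return GroundTruth(
        de_flags=de_flags,
        true_lfc=true_lfc,
        block_id=block_id,
        class_label=class_label,
        subgroup_label=subgroup,
        hetero_flags=hetero_flags,
        hetero_subgroups=hetero_subgroups,
    )


def simulate_log_concentrations(
    config: SimConfig,
    seed: int | None = None,
    truth: GroundTruth | None = None,
) -> np.ndarray:
    """Draw the latent Gaussian log-concentration matrix.

    Column ``s`` is one draw from N(mu(class(s)), sigma^2 R).  Independent
    features are drawn i.i.d.; block features are drawn jointly via the
    Cholesky factor of their compound-symmetry block, so the full n x n
    covariance is never materialized.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if truth is None:
        truth = make_ground_truth(config, seed)
    cov = build_covariance(config)
    rng = substream(seed, "latent")
    z = rng.standard_normal((config.n_features, config.n_samples))
    for k in range(len(cov.blocks)):
        idx = np.array(cov.blocks[k])
        L = np.linalg.cholesky(cov.block_matrix(k))
        z[idx, :] = L @ z[idx, :]
    return _mean_matrix(config, truth) + config.sigma * z


# ---------------------------------------------------------------------------
# Poisson read stage and depth calibration
# ---------------------------------------------------------------------------

def _depth_factors(config: SimConfig, seed: int) -> np.ndarray:
    lo, hi = config.depth_jitter
    if lo == hi:
        return np.full(config.n_samples, float(lo))
    rng = substream(seed, "depth_jitter")
    return rng.uniform(lo, hi, size=config.n_samples)


def simulate_counts(
    latent: np.ndarray,
    scale: float,
    config: SimConfig,
    seed: int | None = None,
) -> CountMatrix:
    """Sample Poisson reads from exponentiated latent concentrations.

    ``count(g, s) ~ Poisson(scale * d_s * exp(latent(g, s)))`` with per-sample
    depth factors ``d_s`` drawn uniformly from ``depth_jitter``.
    """
    if scale < 0:
        raise SimulationError("scale must be non-negative")
    if seed is None:
        seed = config.seed
    d = _depth_factors(config, seed)
    rates = scale * d[np.newaxis, :] * np.exp(latent)
    if np.any(rates > RATE_CEILING):
        raise SimulationError(
            f"Poisson rate exceeds ceiling {RATE_CEILING:g} "
            f"(max {rates.max():g}); check scale and baseline_log_mean"
        )
    rng = substream(seed, "poisson")
    counts = rng.poisson(rates).astype(np.int64)
    n_feat, n_samp = counts.shape
    width_f = len(str(n_feat))
    width_s = len(str(n_samp))
    feature_ids = [f"gene_{i + 1:0{width_f}d}" for i in range(n_feat)]
    sample_ids = [f"sample_{j + 1:0{width_s}d}" for j in range(n_samp)]
    return CountMatrix(counts, feature_ids, sample_ids)


def calibrate_depth(
    config: SimConfig,
    pilot_seed: int | None = None,
    latent: np.ndarray | None = None,
) -> float:
    """Find the rate multiplier whose pilot grand-mean count hits the target.

    Fixed-point iteration ``a <- a * target / empirical_mean`` on a pilot
    simulation (same dimensions as the target dataset), stopping when the
    pilot mean is within 1% of ``target_mean_count``; at most 20 iterations.
    The pilot latent matrix is drawn once and re-used across iterations so
    only the Poisson stage is repeated.
    """
    config.validate()
    if pilot_seed is None:
        pilot_seed = config.seed
    if latent is None:
        latent = simulate_log_concentrations(config, seed=pilot_seed)
    target = config.target_mean_count
    scale = 1.0
    last_mean = float("nan")
    for it in range(CALIBRATION_MAX_ITER):
        pilot = simulate_counts(
            latent, scale, config, seed=pilot_seed + 1000 + it
        )
        last_mean = float(pilot.counts.mean())
        if last_mean > 0 and abs(last_mean - target) / target <= CALIBRATION_RTOL:
            return scale
        if last_mean <= 0:
            # all-zero pilot: jump the rate up using the analytic mean
            scale *= target / max(float(np.exp(latent).mean() * scale), 1e-12)
        else:
            scale *= target / last_mean
    raise SimulationError(
        f"depth calibration did not converge in {CALIBRATION_MAX_ITER} "
        f"iterations; last pilot mean {last_mean:.3f} vs target {target}"
    )


def simulate_dataset(
    preset_or_config: str | SimConfig,
    seed: int | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """End-to-end simulation: covariance -> latent Gaussian -> depth
    calibration -> Poisson reads.

    Returns the count matrix plus the fully populated ground truth (DE flags,
    true log2 fold changes, block membership, class and subgroup labels).
    """
    config = (
        preset_config(preset_or_config)
        if isinstance(preset_or_config, str)
        else preset_or_config
    )
    if seed is not None:
        config = replace(config, seed=int(seed))
    config.validate()
    truth = make_ground_truth(config)
    latent = simulate_log_concentrations(config, truth=truth)
    scale = calibrate_depth(config, latent=latent)
    cm = simulate_counts(latent, scale, config)
    return cm, truth
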