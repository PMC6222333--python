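"""Mean-force and metric-tensor estimators from restrained-trajectory statistics.

The free-energy gradient at an anchored image is the restraint force constant times
the time-averaged deviation of each CV from its anchor, dG/dz_i = k_i ⟨z_i − θ_i⟩
(the stiff-spring estimator); the metric tensor is the time-averaged Gram matrix of
the CV gradients, M_ij = ⟨Σ_k (∂θ_i/∂x_k)(∂θ_j/∂x_k)⟩, which accounts for the
curvilinear map from Cartesian coordinates to CVs. Standard errors come from
non-overlapping block averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampler import RestraintSpec, TrajectoryStats

__all__ = ["MeanForceEstimate", "estimate_gradient", "estimate_metric", "estimate_mean_force"]


@dataclass
class MeanForceEstimate:
    """Per-image free-energy gradient, metric tensor, and gradient standard errors."""

    gradient: np.ndarray
    metric: np.ndarray
    standard_error: np.ndarray
    image_index: int = 0

    def __post_init__(self):
        m = np.asarray(self.metric, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("metric tensor must be symmetric")
        if np.linalg.eigvalsh(0.5 * (m + m.T)).min() < -1e-10:
            raise ValueError("metric tensor must be positive semidefinite")


def estimate_gradient(
    stats: TrajectoryStats,
    spec: RestraintSpec,
    convention: str = "force-constant",
):
    """Per-CV free-energy gradient estimate and its block-averaged standard error.

    ``convention="force-constant"`` (default) returns k_i × ⟨z_i − θ_i⟩, the
    dimensionally consistent stiff-spring estimator. ``"literal-kT"`` exposes, for
    comparison only, the thermal-energy-times-time-integral reading
    kT × ∫(z_i − θ_i)dt; its units are not an energy per CV-unit.
    """
    if stats.n_samples < 2:
        raise ValueError("need at least two samples to estimate a gradient")
    if convention == "force-constant":
        scale = spec.k
        grad = scale * stats.mean_deviation
        blocks = scale * stats.block_deviation_means
    elif convention == "literal-kT":
        # kT here is unknown to the stats object; the caller multiplies by kT.
        # We return the raw time integral of the deviation.
        scale = stats.sample_time
        grad = scale * stats.mean_deviation
        blocks = scale * stats.block_deviation_means
    else:
        raise ValueError(f"unknown convention '{convention}'")
    nb = blocks.shape[0]
    stderr = blocks.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full_like(grad, np.nan)
    return grad, stderr


def estimate_metric(stats: TrajectoryStats) -> np.ndarray:
    """Symmetrized time-averaged Gram matrix of the CV gradients."""
    if stats.n_samples < 1:
        raise ValueError("no samples")
    m = np.asarray(stats.gradient_products, dtype=float)
    return 0.5 * (m + m.T)


def estimate_mean_force(
    stats: TrajectoryStats, spec: RestraintSpec, image_index: int = 0
) -> MeanForceEstimate:
    grad, stderr = estimate_gradient(stats, spec)
    return MeanForceEstimate(
        gradient=grad,
        metric=estimate_metric(stats),
        standard_error=stderr,
        image_index=image_index,
    )
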