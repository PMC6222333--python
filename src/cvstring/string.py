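"""String-of-images path optimization toward the minimum free energy path.

A string is R images of N CV values on a uniform arc-length parametrization
α ∈ [0, 1]. Each cycle: restrained sampling at every image → mean-force and metric
estimates → metric-scaled steepest-descent update with the component along the path
tangent projected out → nearest-neighbour smoothing → equal-arc-length
reparametrization. Convergence is monitored both prospectively (RMSD between
consecutive cycles) and retrospectively (RMSD of every cycle against the final
path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geom import resample_polyline, weighted_norm
from .cvs import CVSet
from .meanforce import MeanForceEstimate, estimate_mean_force
from .sampler import SamplerConfig, run_restrained_batch
from .surfaces import PotentialSurface

__all__ = [
    "StringPath",
    "OptimizationSchedule",
    "ConvergenceRecord",
    "StringResult",
    "linear_initial_path",
    "path_tangent",
    "evolve_image",
    "smooth_path",
    "reparametrize",
    "path_rmsd",
    "optimize_string",
    "image_seed",
    "total_sampling_time",
]


@dataclass
class StringPath:
    """R images of N CV values at strictly increasing α from 0 to 1."""

    images: np.ndarray
    alphas: np.ndarray | None = None
    cycle: int = 0

    def __post_init__(self):
        self.images = np.atleast_2d(np.asarray(self.images, dtype=float))
        if self.alphas is None:
            self.alphas = np.linspace(0.0, 1.0, self.images.shape[0])
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.shape != (self.images.shape[0],):
            raise ValueError("alphas must have one value per image")
        if self.images.shape[0] >= 2:
            if not (
                np.all(np.diff(self.alphas) > 0)
                and abs(self.alphas[0]) < 1e-12
                and abs(self.alphas[-1] - 1.0) < 1e-12
            ):
                raise ValueError("alphas must increase strictly from 0 to 1")

    @property
    def R(self) -> int:
        return self.images.shape[0]

    @property
    def N(self) -> int:
        return self.images.shape[1]

    @property
    def delta_alpha(self) -> float:
        return 1.0 / (self.R - 1)

    def copy(self, cycle: int | None = None) -> "StringPath":
        return StringPath(
            self.images.copy(),
            self.alphas.copy(),
            self.cycle if cycle is None else cycle,
        )


def linear_initial_path(start, end, R: int) -> StringPath:
    """Straight-line string between two CV endpoints with R images."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0.0, 1.0, R)[:, None]
    return StringPath((1 - t) * start + t * end)


def path_tangent(path: StringPath, image_index: int, weights=None) -> np.ndarray:
    """Unit tangent at one image: central differences over α in the interior,
    one-sided at the endpoints, normalized in the weighted CV metric."""
    if path.R < 3:
        raise ValueError("tangents need at least three images")
    z = path.images
    i = image_index
    if i == 0:
        d = z[1] - z[0]
    elif i == path.R - 1:
        d = z[-1] - z[-2]
    else:
        d = z[i + 1] - z[i - 1]
    n = weighted_norm(d, weights)
    if n < 1e-14:
        raise ValueError(f"degenerate (zero) tangent at image {i}")
    return d / n


def evolve_image(
    z: np.ndarray,
    estimate: MeanForceEstimate,
    tangent: np.ndarray | None,
    descent_step: float,
    weights=None,
) -> np.ndarray:
    """One steepest-descent update z′ = z + Δt · P[M(−∇G)].

    The projector P = I − t̂t̂ᵀ removes the component of the metric-scaled driving
    force along the path tangent; with ``tangent=None`` (free endpoints) the update
    is applied unprojected.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(estimate.gradient, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite free-energy gradient")
    disp = estimate.metric @ (-g)
    if tangent is not None:
        t = np.asarray(tangent, dtype=float)
        w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
        t = t / weighted_norm(t, w)
        disp = disp - t * np.sum(w * t * disp)
    return z + descent_step * disp


def smooth_path(path: StringPath, s: float) -> StringPath:
    """Nearest-neighbour smoothing z′_r = (1−s) z_r + (s/2)(z_{r−1} + z_{r+1});
    endpoints unchanged."""
    if not 0 <= s < 0.5:
        raise ValueError("smoothing parameter must satisfy 0 <= s < 0.5")
    z = path.images.copy()
    if path.R > 2:
        z[1:-1] = (1 - s) * path.images[1:-1] + 0.5 * s * (
            path.images[:-2] + path.images[2:]
        )
    return StringPath(z, path.alphas.copy(), path.cycle)


def reparametrize(path: StringPath, weights=None) -> StringPath:
    """Redistribute images along the piecewise-linear path so consecutive weighted
    arc lengths are equal (Δα = 1/(R−1)); endpoints are preserved exactly."""
    z = resample_polyline(path.images, path.R, weights)
    return StringPath(z, np.linspace(0.0, 1.0, path.R), path.cycle)


def path_rmsd(a: StringPath, b: StringPath) -> float:
    """Root mean squared per-CV, per-image difference between two strings."""
    if a.images.shape != b.images.shape:
        raise ValueError("paths must have identical shape")
    return float(np.sqrt(np.mean((a.images - b.images) ** 2)))


@dataclass
class OptimizationSchedule:
    """Per-run knobs: cycle count, descent step Δt, smoothing s, convergence
    tolerance, the per-cycle sampler settings, and endpoint handling."""

    per_cycle_sampler: SamplerConfig
    n_cycles: int = 100
    descent_step: float = 0.001
    smoothing: float = 0.01
    rmsd_tolerance: float = 0.01
    endpoint_mode: str = "free"
    early_stop: bool = False
    convergence_window: int = 5

    def __post_init__(self):
        if not 0 <= self.smoothing < 0.5:
            raise ValueError("smoothing must satisfy 0 <= s < 0.5")
        if self.descent_step <= 0:
            raise ValueError("descent_step must be positive")
        if self.endpoint_mode not in ("free", "fixed"):
            raise ValueError("endpoint_mode must be 'free' or 'fixed'")


@dataclass
class ConvergenceRecord:
    """Retrospective and prospective convergence diagnostics."""

    per_cycle_rmsd_vs_final: np.ndarray
    per_cv_deviation_maps: np.ndarray  # (cycles, R, N) deviations from the final path
    per_cycle_rmsd_consecutive: np.ndarray
    converged_cycle: int | None = None


@dataclass
class StringResult:
    final_path: StringPath
    paths: list[StringPath]
    estimates: list[list[MeanForceEstimate]]
    convergence: ConvergenceRecord
    stats: list = field(default_factory=list)  # per-image TrajectoryStats, last cycle


def image_seed(master_seed: int, cycle: int, image: int) -> np.random.SeedSequence:
    """Deterministic counter-based seed for one (cycle, image) trajectory, so any
    single image run is reproducible in isolation."""
    return np.random.SeedSequence((int(master_seed), int(cycle), int(image)))


def total_sampling_time(per_image_time: float, n_images: int, n_cycles: int) -> float:
    """Aggregate sampling effort of a full string optimization (protocol arithmetic)."""
    return per_image_time * n_images * n_cycles


def optimize_string(
    initial: StringPath,
    surface: PotentialSurface,
    cvset: CVSet,
    k,
    schedule: OptimizationSchedule,
    master_seed: int = 0,
    x0: np.ndarray | None = None,
    monitored: dict | None = None,
    keep_stats_every: int | None = None,
) -> StringResult:
    """Run the full per-cycle loop: sample → estimate → evolve → smooth → reparametrize.

    ``k`` is the (scalar or per-CV) restraint force constant. ``x0`` supplies the
    initial configuration of each image walker; for purely identity CV sets it is
    derived from the initial path spine. Walkers warm-start each cycle from the final
    configuration of the previous one. The sampler noise of image r in cycle c is
    seeded by ``image_seed(master_seed, c, r)``.
    """
    path = reparametrize(initial.copy(cycle=0), cvset.weights)
    R, N = path.R, path.N
    if x0 is None:
        if not cvset.all_identity:
            raise ValueError(
                "x0 is required unless every CV is an identity map onto a coordinate"
            )
        x0 = np.zeros((R, surface.dimension))
        x0[:, cvset.identity_indices()] = path.images
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()

    weights = cvset.weights
    paths: list[StringPath] = []
    estimates: list[list[MeanForceEstimate]] = []
    consec = []
    last_stats = []
    stagnant = 0
    monitored_stats: list = []

    for cycle in range(schedule.n_cycles):
        seeds = [image_seed(master_seed, cycle, r) for r in range(R)]
        stats = run_restrained_batch(
            surface, cvset, path.images, k, schedule.per_cycle_sampler, x, seeds,
            monitored=monitored,
        )
        x = np.array([st.final_configuration for st in stats])
        from .sampler import RestraintSpec  # local to avoid cycle at import time

        ests = [
            estimate_mean_force(st, RestraintSpec(path.images[r], k), r)
            for r, st in enumerate(stats)
        ]

        new = path.images.copy()
        for r in range(R):
            if r in (0, R - 1):
                if schedule.endpoint_mode == "fixed":
                    continue
                tangent = None  # unprojected downhill relaxation toward the basin
            else:
                tangent = path_tangent(path, r, weights)
            new[r] = evolve_image(
                path.images[r], ests[r], tangent, schedule.descent_step, weights
            )
        evolved = StringPath(new, path.alphas.copy(), cycle)
        smoothed = smooth_path(evolved, schedule.smoothing)
        new_path = reparametrize(smoothed, weights)
        new_path.cycle = cycle

        consec.append(path_rmsd(new_path, path))
        path = new_path
        paths.append(path.copy())
        estimates.append(ests)
        last_stats = stats
        if keep_stats_every and cycle % keep_stats_every == 0:
            monitored_stats.append((cycle, stats))

        if len(consec) > 20 and consec[-1] >= consec[-21]:
            stagnant += 1
            if stagnant == 10:
                warnings.warn(
                    f"string RMSD not decreasing around cycle {cycle}", RuntimeWarning
                )
        if (
            schedule.early_stop
            and len(consec) >= schedule.convergence_window
            and max(consec[-schedule.convergence_window :]) < schedule.rmsd_tolerance
        ):
            break

    final = paths[-1]
    dev_maps = np.array([p.images - final.images for p in paths])
    rmsd_final = np.sqrt(np.mean(dev_maps**2, axis=(1, 2)))
    converged = None
    for c in range(len(paths)):
        if np.all(rmsd_final[c:] < schedule.rmsd_tolerance):
            converged = c
            break
    record = ConvergenceRecord(
        per_cycle_rmsd_vs_final=rmsd_final,
        per_cv_deviation_maps=dev_maps,
        per_cycle_rmsd_consecutive=np.array(consec),
        converged_cycle=converged,
    )
    return StringResult(final, paths, estimates, record, list(last_stats))
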