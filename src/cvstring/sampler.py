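"""Restrained overdamped Langevin sampling of a surface plus harmonic CV anchors.

The dynamics are Euler–Maruyama on dx = −∇[V(x) + U_restraint(θ[x])] dt/γ +
sqrt(2 kBT dt/γ) dW, whose stationary distribution is the Boltzmann weight of the
restrained potential. Each image of the string is one such walker; the per-image
time averages of the CV deviations (z − θ) and of the CV-gradient Gram products are
accumulated over the post-burn-in portion of the trajectory, which is everything the
mean-force and metric estimators need.

The engine is deliberately diffusive: the path-optimization formalism it feeds is
derived for Brownian dynamics of the CVs, and a sampler with a provable stationary
distribution keeps the estimator contracts checkable. Identical seeds and inputs
reproduce identical trajectories bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cvs import CVSet, evaluate_cvs, cv_gradients
from .surfaces import PotentialSurface

__all__ = [
    "SamplerConfig",
    "RestraintSpec",
    "TrajectoryStats",
    "SamplerError",
    "harmonic_restraint",
    "run_restrained",
    "run_restrained_batch",
]

_CHUNK = 8192


class SamplerError(RuntimeError):
    """Trajectory failure (left the domain, or non-finite forces), with step context."""


@dataclass
class SamplerConfig:
    """Thermostat and integration settings.

    kT is the thermal energy in the surface's energy units (kT = 0 gives plain
    gradient descent); burn-in defaults to the first quarter of the trajectory,
    mirroring a discard-the-first-5-of-20 equilibration convention.
    """

    kT: float
    timestep: float
    n_steps_total: int
    n_steps_burnin: int | None = None
    friction: float = 1.0
    sample_stride: int = 1
    store_stride: int | None = None
    n_blocks: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.n_steps_burnin is None:
            self.n_steps_burnin = self.n_steps_total // 4
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if not 0 <= self.n_steps_burnin < self.n_steps_total:
            raise ValueError("need 0 <= n_steps_burnin < n_steps_total")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(range(self.n_steps_burnin, self.n_steps_total, self.sample_stride))

    def to_dict(self) -> dict:
        return {
            "kT": self.kT,
            "timestep": self.timestep,
            "n_steps_total": self.n_steps_total,
            "n_steps_burnin": self.n_steps_burnin,
            "friction": self.friction,
            "sample_stride": self.sample_stride,
            "store_stride": self.store_stride,
            "n_blocks": self.n_blocks,
            "seed": self.seed,
        }


@dataclass
class RestraintSpec:
    """Harmonic anchors: per-CV reference values z_ref and force constants k
    (energy per CV-unit squared); a scalar k is broadcast over the CVs."""

    z_ref: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        self.z_ref = np.atleast_1d(np.asarray(self.z_ref, dtype=float))
        self.k = np.broadcast_to(
            np.asarray(self.k, dtype=float), self.z_ref.shape
        ).copy()
        if np.any(self.k <= 0):
            raise ValueError("restraint force constants must be positive")


@dataclass
class TrajectoryStats:
    """Post-burn-in accumulators of one restrained trajectory.

    ``mean_deviation`` is the time average of (z_ref − θ); ``gradient_products`` the
    time-averaged Gram matrix Σ_k (∂θ_i/∂x_k)(∂θ_j/∂x_k); ``block_deviation_means``
    holds per-block averages of (z_ref − θ) for block-averaged standard errors.
    """

    mean_deviation: np.ndarray
    gradient_products: np.ndarray
    n_samples: int
    block_deviation_means: np.ndarray
    sample_time: float
    timestep: float
    final_configuration: np.ndarray
    monitored_samples: dict[str, np.ndarray] = field(default_factory=dict)
    stored_configurations: np.ndarray | None = None


def harmonic_restraint(theta: np.ndarray, spec: RestraintSpec):
    """Energy Σ k_i (θ_i − z_i)^2 / 2 and the generalized force −k_i (θ_i − z_i)."""
    theta = np.asarray(theta, dtype=float)
    dev = theta - spec.z_ref
    energy = 0.5 * np.sum(spec.k * dev * dev, axis=-1)
    force = -spec.k * dev
    return energy, force


def _resolve_rngs(seeds, R):
    rngs = []
    for s in seeds:
        if isinstance(s, np.random.Generator):
            rngs.append(s)
        else:
            rngs.append(np.random.default_rng(s))
    if len(rngs) != R:
        raise ValueError("need one seed per walker")
    return rngs


def run_restrained_batch(
    surface: PotentialSurface,
    cvset: CVSet,
    z_ref: np.ndarray,
    k,
    config: SamplerConfig,
    x0: np.ndarray,
    seeds,
    monitored: dict | None = None,
) -> list[TrajectoryStats]:
    """Evolve R walkers simultaneously, one per row of ``z_ref`` / ``x0``.

    Noise for walker r comes exclusively from ``seeds[r]``, so a batch run is
    bit-identical to R independent single-walker runs with the same seeds.
    """
    z_ref = np.atleast_2d(np.asarray(z_ref, dtype=float))
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    R, N = z_ref.shape
    dim = x.shape[1]
    if x.shape[0] != R:
        raise ValueError("x0 and z_ref must agree on the number of walkers")
    kvec = np.broadcast_to(np.asarray(k, dtype=float), (N,)).copy()
    if np.any(kvec <= 0):
        raise ValueError("restraint force constants must be positive")
    if not np.all(surface.in_domain(x)):
        raise SamplerError("initial configuration outside the surface domain")
    rngs = _resolve_rngs(seeds, R)
    monitored = monitored or {}

    dt_over_g = config.timestep / config.friction
    noise_amp = np.sqrt(2.0 * config.kT * dt_over_g)
    lo, hi = surface.domain[:, 0], surface.domain[:, 1]

    identity = cvset.all_identity
    if identity:
        idx = cvset.identity_indices()
        gram_const = np.zeros((N, N))
        J_const = np.zeros((N, dim))
        J_const[np.arange(N), idx] = 1.0
        gram_const = J_const @ J_const.T  # identity matrix for distinct indices

    n_samples = config.n_samples
    n_blocks = min(config.n_blocks, n_samples)
    dev_block = np.zeros((n_blocks, R, N))
    block_counts = np.zeros(n_blocks, dtype=int)
    gram_sum = np.zeros((R, N, N))
    mon_out = {lbl: np.empty((R, n_samples)) for lbl in monitored}
    store = []
    sample_i = 0

    t = 0
    total = config.n_steps_total
    while t < total:
        span = min(_CHUNK, total - t)
        if config.kT > 0:
            noise = np.stack(
                [rng.standard_normal((span, dim)) for rng in rngs], axis=1
            )
        else:
            noise = None
        for s in range(span):
            step = t + s
            if identity:
                theta = x[:, idx]
            else:
                theta = evaluate_cvs(cvset, x)
                J = cv_gradients(cvset, x)
            devzt = z_ref - theta  # z - theta
            force = -surface.gradient(x)
            if identity:
                force[:, idx] += kvec * devzt
            else:
                force += np.einsum("rn,rnd->rd", kvec * devzt, J)
            if not np.all(np.isfinite(force)):
                bad = int(np.argwhere(~np.isfinite(force).all(axis=1))[0, 0])
                raise SamplerError(f"non-finite force at step {step} (walker {bad})")

            if step >= config.n_steps_burnin and (
                (step - config.n_steps_burnin) % config.sample_stride == 0
            ):
                b = sample_i * n_blocks // n_samples
                dev_block[b] += devzt
                block_counts[b] += 1
                if identity:
                    gram_sum += gram_const
                else:
                    gram_sum += np.einsum("rnd,rmd->rnm", J, J)
                for lbl, cvdef in monitored.items():
                    mon_out[lbl][:, sample_i] = evaluate_cvs(
                        CVSet((cvdef,)), x
                    )[:, 0]
                if config.store_stride and sample_i % config.store_stride == 0:
                    store.append(x.copy())
                sample_i += 1

            x = x + dt_over_g * force
            if noise is not None:
                x = x + noise_amp * noise[s]
            inside = np.all((x >= lo) & (x <= hi), axis=-1)
            if not np.all(inside):
                bad = int(np.argwhere(~inside)[0, 0])
                raise SamplerError(
                    f"trajectory left the surface domain at step {step} (walker {bad})"
                )
        t += span

    dev_mean = dev_block.sum(axis=0) / n_samples
    block_means = dev_block / block_counts[:, None, None]
    gram_mean = gram_sum / n_samples
    gram_mean = 0.5 * (gram_mean + np.swapaxes(gram_mean, -1, -2))
    stored = np.stack(store, axis=1) if store else None  # (R, S, dim)

    out = []
    for r in range(R):
        out.append(
            TrajectoryStats(
                mean_deviation=dev_mean[r],
                gradient_products=gram_mean[r],
                n_samples=n_samples,
                block_deviation_means=block_means[:, r, :],
                sample_time=n_samples * config.sample_stride * config.timestep,
                timestep=config.timestep,
                final_configuration=x[r].copy(),
                monitored_samples={lbl: mon_out[lbl][r].copy() for lbl in mon_out},
                stored_configurations=None if stored is None else stored[r],
            )
        )
    return out


def run_restrained(
    surface: PotentialSurface,
    cvset: CVSet,
    spec: RestraintSpec,
    config: SamplerConfig,
    x0: np.ndarray,
    seed=None,
    monitored: dict | None = None,
) -> TrajectoryStats:
    """Single restrained trajectory; see :func:`run_restrained_batch`."""
    if seed is None:
        seed = config.seed
    return run_restrained_batch(
        surface,
        cvset,
        spec.z_ref[None, :],
        spec.k,
        config,
        np.asarray(x0, dtype=float)[None, :],
        [seed],
        monitored=monitored,
    )[0]
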