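"""Committor-probability validation of candidate transition states.

A configuration's committor pB is the probability that an unbiased trajectory
started from it reaches the product basin before the reactant basin; pB ≈ 0.5
defines a transition state. Configurations are harvested from a restrained run
anchored at the candidate state's CV values (the transition-state ensemble), then
each is shot ``n_shots`` times with fresh noise and no restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cvs import CVSet, evaluate_cvs
from .sampler import RestraintSpec, SamplerConfig, SamplerError, run_restrained
from .surfaces import PotentialSurface

__all__ = [
    "BasinDefinition",
    "CommittorResult",
    "default_basins",
    "sample_ts_ensemble",
    "estimate_committor",
]


@dataclass
class BasinDefinition:
    """Reactant and product regions as per-CV interval boxes.

    Each region is a list of ``(lo, hi)`` bounds per CV; ``None`` in place of a
    bound (or of a whole interval) leaves that side/CV unconstrained. The two boxes
    must be disjoint.
    """

    reactant_region: list
    product_region: list
    max_steps: int = 100000

    def __post_init__(self):
        self.reactant_region = [self._norm(iv) for iv in self.reactant_region]
        self.product_region = [self._norm(iv) for iv in self.product_region]
        if len(self.reactant_region) != len(self.product_region):
            raise ValueError("regions must cover the same number of CVs")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        overlap = True
        for (alo, ahi), (blo, bhi) in zip(self.reactant_region, self.product_region):
            if alo > bhi or blo > ahi:
                overlap = False
        if overlap:
            raise ValueError("reactant and product regions must be disjoint")

    @staticmethod
    def _norm(iv):
        if iv is None:
            return (-np.inf, np.inf)
        lo, hi = iv
        lo = -np.inf if lo is None else float(lo)
        hi = np.inf if hi is None else float(hi)
        if not lo < hi:
            raise ValueError("interval bounds must satisfy lo < hi")
        return (lo, hi)

    def _inside(self, theta, region):
        theta = np.asarray(theta, dtype=float)
        ok = np.ones(theta.shape[:-1], dtype=bool)
        for i, (lo, hi) in enumerate(region):
            ok &= (theta[..., i] >= lo) & (theta[..., i] <= hi)
        return ok

    def in_reactant(self, theta):
        return self._inside(theta, self.reactant_region)

    def in_product(self, theta):
        return self._inside(theta, self.product_region)


def default_basins(
    rc_values, pc_values, kT: float, k, max_steps: int = 100000
) -> BasinDefinition:
    """Boxes of per-CV half-width 3·sqrt(kT/k) around the reactant and product CV
    values — the equilibrium width of a harmonic anchor at stiffness k."""
    rc = np.atleast_1d(np.asarray(rc_values, dtype=float))
    pc = np.atleast_1d(np.asarray(pc_values, dtype=float))
    kvec = np.broadcast_to(np.asarray(k, dtype=float), rc.shape)
    half = 3.0 * np.sqrt(max(kT, 1e-12) / kvec)
    return BasinDefinition(
        [(lo, hi) for lo, hi in zip(rc - half, rc + half)],
        [(lo, hi) for lo, hi in zip(pc - half, pc + half)],
        max_steps,
    )


@dataclass
class CommittorResult:
    """Per-configuration committed-to-product fractions and their distribution."""

    pB_samples: np.ndarray
    n_shots: int
    histogram: tuple[np.ndarray, np.ndarray]
    unresolved_fraction: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.pB_samples))


def sample_ts_ensemble(
    surface: PotentialSurface,
    cvset: CVSet,
    ts_values,
    k,
    config: SamplerConfig,
    n_configs: int,
    x0,
    seed=None,
) -> np.ndarray:
    """Thinned configurations from a restrained run anchored at the candidate
    transition state's CV values.

    The thinning interval is at least ten relaxation times of the stiffest-safe
    anchor estimate, γ/(k·Δt) steps, so successive configurations are effectively
    decorrelated.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be positive")
    ts_values = np.atleast_1d(np.asarray(ts_values, dtype=float))
    kvec = np.broadcast_to(np.asarray(k, dtype=float), ts_values.shape)
    relax_steps = config.friction / (float(np.min(kvec)) * config.timestep)
    stride = max(1, int(np.ceil(10.0 * relax_steps)))
    needed = config.n_steps_burnin + n_configs * stride
    cfg = SamplerConfig(
        kT=config.kT,
        timestep=config.timestep,
        n_steps_total=max(config.n_steps_total, needed),
        n_steps_burnin=config.n_steps_burnin,
        friction=config.friction,
        sample_stride=1,
        store_stride=stride,
        n_blocks=config.n_blocks,
        seed=config.seed,
    )
    stats = run_restrained(
        surface, cvset, RestraintSpec(ts_values, kvec), cfg, x0, seed=seed
    )
    configs = stats.stored_configurations
    if configs is None or len(configs) < n_configs:
        raise SamplerError("restrained run produced too few stored configurations")
    return configs[-n_configs:]


def estimate_committor(
    surface: PotentialSurface,
    cvset: CVSet,
    configs,
    basins: BasinDefinition,
    n_shots: int,
    config: SamplerConfig,
    seed=None,
    n_bins: int = 10,
) -> CommittorResult:
    """Shoot ``n_shots`` unbiased trajectories from every configuration and count
    the fraction committing to the product basin first.

    Shots exceeding ``basins.max_steps`` are unresolved: excluded from pB and
    reported through ``unresolved_fraction``.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be positive")
    configs = np.atleast_2d(np.asarray(configs, dtype=float))
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    dt_over_g = config.timestep / config.friction
    amp = np.sqrt(2.0 * config.kT * dt_over_g)
    lo, hi = surface.domain[:, 0], surface.domain[:, 1]

    pBs = []
    unresolved_total = 0
    for x0 in configs:
        x = np.repeat(x0[None, :], n_shots, axis=0)
        outcome = np.zeros(n_shots, dtype=int)  # 0 running, 1 product, -1 reactant
        active = np.ones(n_shots, dtype=bool)
        for _ in range(basins.max_steps):
            theta = evaluate_cvs(cvset, x[active])
            prod = basins.in_product(theta)
            reac = basins.in_reactant(theta)
            ia = np.flatnonzero(active)
            outcome[ia[prod]] = 1
            outcome[ia[reac & ~prod]] = -1
            active[ia[prod | reac]] = False
            if not np.any(active):
                break
            xa = x[active]
            xa = xa - dt_over_g * surface.gradient(xa)
            if config.kT > 0:
                xa = xa + amp * rng.standard_normal(xa.shape)
            xa = np.clip(xa, lo, hi)
            x[active] = xa
        resolved = outcome != 0
        unresolved_total += int(np.sum(~resolved))
        if not np.any(resolved):
            raise SamplerError(
                "all trajectories unresolved for a configuration; raise max_steps"
            )
        pBs.append(np.mean(outcome[resolved] == 1))
    pBs = np.asarray(pBs)
    hist = np.histogram(pBs, bins=n_bins, range=(0.0, 1.0))
    return CommittorResult(
        pB_samples=pBs,
        n_shots=n_shots,
        histogram=hist,
        unresolved_fraction=unresolved_total / (len(configs) * n_shots),
    )
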