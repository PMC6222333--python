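"""Free-energy integration along a converged string, stationary-state location,
profile uncertainties, and rate↔barrier kinetic conversions.

The profile is G(α) = ∫0^α Σ_i (dz_i/dα′)(dG/dz_i) dα′ with both factors
interpolated over α by natural cubic splines and the integral taken with the
trapezoidal rule on a dense grid (75 points by default, endpoints inclusive).
Stationary states are the endpoints (reactant and product complexes) plus interior
extrema classified as transition states (maxima) and intermediates (minima), with
extrema of prominence below twice the local statistical uncertainty suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from ._constants import (
    KB_KCAL_PER_MOL_K,
    KB_OVER_H_PER_S_K,
    ROOM_TEMPERATURE_K,
    SECONDS_PER_DAY,
)
from .meanforce import MeanForceEstimate
from .string import StringPath

__all__ = [
    "FreeEnergyProfile",
    "StationaryState",
    "integrate_profile",
    "locate_stationary_states",
    "profile_uncertainty",
    "eyring_barrier",
    "eyring_rate",
    "first_order_half_life",
    "SECONDS_PER_DAY",
]


@dataclass
class FreeEnergyProfile:
    """G(α) on a dense inclusive grid over [0, 1], zeroed at α = 0, with per-point
    uncertainty (standard deviation across trailing optimization cycles)."""

    alpha_grid: np.ndarray
    G: np.ndarray
    stderr: np.ndarray | None = None
    source_cycles: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.stderr is None:
            self.stderr = np.zeros_like(self.G)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if abs(self.G[0]) > 1e-12:
            raise ValueError("profile must be zeroed at alpha = 0")
        if abs(self.alpha_grid[0]) > 1e-12 or abs(self.alpha_grid[-1] - 1.0) > 1e-12:
            raise ValueError("alpha grid must cover [0, 1] inclusive")

    @property
    def barrier(self) -> float:
        """Highest point of the profile relative to the α = 0 reactant."""
        return float(np.max(self.G))


@dataclass
class StationaryState:
    """A labelled stationary state on the profile: RC/PC at the endpoints, TSn for
    interior maxima, IMn for interior minima, with interpolated CV values."""

    label: str
    alpha: float
    G: float
    cv_values: np.ndarray | None = None


def integrate_profile(
    path: StringPath,
    estimates: list[MeanForceEstimate],
    n_grid: int = 75,
) -> FreeEnergyProfile:
    """Integrate the mean-force line integral along the string.

    dz_i/dα comes from a natural cubic spline of the image CV values, dG/dz_i from a
    natural cubic spline of the per-image gradient estimates; their dot product is
    integrated by the trapezoidal rule on ``n_grid`` points (endpoints counted).
    """
    if path.R < 4:
        raise ValueError("cubic-spline integration needs at least four images")
    if len(estimates) != path.R:
        raise ValueError("need one mean-force estimate per image")
    grads = np.array([e.gradient for e in estimates])
    z_spline = CubicSpline(path.alphas, path.images, bc_type="natural", axis=0)
    g_spline = CubicSpline(path.alphas, grads, bc_type="natural", axis=0)
    grid = np.linspace(0.0, 1.0, n_grid)
    integrand = np.sum(z_spline(grid, 1) * g_spline(grid), axis=1)
    G = cumulative_trapezoid(integrand, grid, initial=0.0)
    return FreeEnergyProfile(grid, G, source_cycles=[path.cycle])


def profile_uncertainty(profiles: list[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Mean profile over trailing cycles with pointwise sample standard deviation."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    grid = profiles[0].alpha_grid
    for p in profiles[1:]:
        if p.alpha_grid.shape != grid.shape or not np.allclose(p.alpha_grid, grid):
            raise ValueError("profiles must share a common alpha grid")
    stack = np.array([p.G for p in profiles])
    cycles = sorted({c for p in profiles for c in p.source_cycles})
    return FreeEnergyProfile(
        grid,
        stack.mean(axis=0),
        stack.std(axis=0, ddof=1),
        source_cycles=cycles,
    )


def _prune_extrema(G, idx, threshold):
    """Drop interior extrema whose height difference to an adjacent extremum falls
    below the local threshold, least prominent first. Endpoints (first/last entries)
    are never removed."""
    idx = list(idx)
    while len(idx) > 2:
        best = None
        for i in range(len(idx) - 1):
            a, b = idx[i], idx[i + 1]
            d = abs(G[b] - G[a])
            thr = max(threshold[a], threshold[b])
            interior = [j for j in (i, i + 1) if j not in (0, len(idx) - 1)]
            if interior and d < thr and (best is None or d < best[0]):
                best = (d, interior)
        if best is None:
            break
        for j in sorted(best[1], reverse=True):
            del idx[j]
    return idx


def locate_stationary_states(
    profile: FreeEnergyProfile,
    path: StringPath | None = None,
    min_prominence: float = 0.0,
) -> list[StationaryState]:
    """Classify the profile's stationary states in order of α.

    Interior local maxima become TS1, TS2, ..., interior minima IM1, IM2, ...; the
    endpoints are always reported as RC and PC. Wiggles whose height difference to a
    neighbouring extremum is below 2× the local uncertainty (or ``min_prominence``,
    whichever is larger) are suppressed.
    """
    G = profile.G
    n = len(G)
    ext = [0]
    kinds = {}  # grid index -> True for maximum
    for i in range(1, n - 1):
        if (G[i] - G[i - 1]) * (G[i + 1] - G[i]) < 0:
            ext.append(i)
            kinds[i] = G[i] > G[i - 1]
    ext.append(n - 1)
    thr = np.maximum(2.0 * profile.stderr, min_prominence)
    ext = _prune_extrema(G, ext, thr)

    # pruning can leave two like extrema adjacent: keep the more extreme of each run
    cleaned = [ext[0]]
    for i in ext[1:-1]:
        if cleaned[-1] != ext[0] and kinds[i] == kinds[cleaned[-1]]:
            better = (G[i] > G[cleaned[-1]]) == kinds[i]
            if better:
                cleaned[-1] = i
        else:
            cleaned.append(i)
    cleaned.append(ext[-1])

    cv_spline = None
    if path is not None:
        cv_spline = CubicSpline(path.alphas, path.images, bc_type="natural", axis=0)

    states = []
    n_ts = n_im = 0
    for j, i in enumerate(cleaned):
        a = float(profile.alpha_grid[i])
        if j == 0:
            label = "RC"
        elif j == len(cleaned) - 1:
            label = "PC"
        elif kinds[i]:
            n_ts += 1
            label = f"TS{n_ts}"
        else:
            n_im += 1
            label = f"IM{n_im}"
        states.append(
            StationaryState(
                label,
                a,
                float(G[i]),
                None if cv_spline is None else cv_spline(a),
            )
        )
    return states


def eyring_barrier(rate: float, temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Activation free energy (kcal/mol) from a first-order rate constant (s^-1):
    ΔG‡ = RT ln(kB·T / (h·k))."""
    if rate <= 0 or temperature <= 0:
        raise ValueError("rate and temperature must be positive")
    return KB_KCAL_PER_MOL_K * temperature * np.log(
        KB_OVER_H_PER_S_K * temperature / rate
    )


def eyring_rate(barrier: float, temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Inverse of :func:`eyring_barrier`: k = (kB·T/h) exp(−ΔG‡/RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_OVER_H_PER_S_K * temperature * np.exp(
        -barrier / (KB_KCAL_PER_MOL_K * temperature)
    )


def first_order_half_life(rate: float) -> float:
    """Half-life t½ = ln 2 / k in seconds (divide by SECONDS_PER_DAY for days)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return float(np.log(2.0) / rate)
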