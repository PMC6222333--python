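"""Analytic benchmark landscapes with exact gradients, plus an independent MEP oracle.

These surfaces stand in for an expensive molecular potential-energy surface when the
path-optimization machinery is exercised at desk scale: a canonical two-dimensional
four-Gaussian landscape, a symmetric double well with a closed-form barrier, a
quadratic well for estimator closed forms, and a multi-basin "proton relay" chain of
coupled double wells whose one-dimensional spine profile is prescribed exactly.

The oracle (`brute_force_mep`) computes minimum-energy paths by machinery that shares
nothing with the string optimizer: an edge-maximum (minimax) Dijkstra search on a dense
grid to bracket the saddles, Newton refinement of each saddle, and steepest-descent
streamlines stitched through the basins.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._geom import arc_lengths, resample_polyline

__all__ = [
    "PotentialSurface",
    "ReferencePath",
    "muller_brown",
    "double_well",
    "quadratic_well",
    "proton_relay_surface",
    "gac_like_profile",
    "sac_like_profile",
    "brute_force_mep",
    "refine_minimum",
    "refine_saddle",
    "finite_difference_hessian",
    "surface_from_dict",
]


class PotentialSurface:
    """An analytic energy landscape V(x) with exact gradients.

    Subclasses implement :meth:`energy` and :meth:`gradient` accepting arrays whose
    trailing axis has length :attr:`dimension`; both are vectorized over any leading
    axes. ``domain`` gives per-coordinate bounds inside which the energy is finite.
    """

    name: str = "base"

    def __init__(self, dimension: int, parameters: dict, domain: np.ndarray):
        self.dimension = int(dimension)
        self.parameters = dict(parameters)
        self.domain = np.asarray(domain, dtype=float).reshape(self.dimension, 2)

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def in_domain(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain[:, 0], self.domain[:, 1]
        return np.all((x >= lo) & (x <= hi), axis=-1)

    def to_dict(self) -> dict:
        return {"name": self.name, "parameters": dict(self.parameters)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(dim={self.dimension}, parameters={self.parameters})"


class _MullerBrown(PotentialSurface):
    name = "muller_brown"

    #: standard literature parameter set of the four-Gaussian benchmark
    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def __init__(self):
        params = {
            "A": self.A.tolist(),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "x0": self.x0.tolist(),
            "y0": self.y0.tolist(),
        }
        super().__init__(2, params, [[-2.0, 1.5], [-0.8, 2.5]])

    def _terms(self, x):
        x = np.asarray(x, dtype=float)
        dx = x[..., 0, None] - self.x0
        dy = x[..., 1, None] - self.y0
        e = np.exp(self.a * dx**2 + self.b * dx * dy + self.c * dy**2)
        return dx, dy, self.A * e

    def energy(self, x):
        _, _, t = self._terms(x)
        return np.sum(t, axis=-1)

    def gradient(self, x):
        dx, dy, t = self._terms(x)
        gx = np.sum(t * (2 * self.a * dx + self.b * dy), axis=-1)
        gy = np.sum(t * (self.b * dx + 2 * self.c * dy), axis=-1)
        return np.stack([gx, gy], axis=-1)


class _DoubleWell(PotentialSurface):
    """V(x, y) = h (x^2 - 1)^2 + c y^2 / 2: minima at (±1, 0), saddle at the origin."""

    name = "double_well"

    def __init__(self, h: float, c: float):
        if h <= 0 or c <= 0:
            raise ValueError("double_well requires h > 0 and c > 0")
        super().__init__(2, {"h": float(h), "c": float(c)}, [[-4.0, 4.0], [-4.0, 4.0]])
        self.h = float(h)
        self.c = float(c)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.h * (x[..., 0] ** 2 - 1.0) ** 2 + 0.5 * self.c * x[..., 1] ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        gx = 4.0 * self.h * x[..., 0] * (x[..., 0] ** 2 - 1.0)
        gy = self.c * x[..., 1]
        return np.stack([gx, gy], axis=-1)


class _QuadraticWell(PotentialSurface):
    """Isotropic harmonic well V = a |x|^2 / 2 (a = 0 gives a flat landscape)."""

    name = "quadratic_well"

    def __init__(self, a: float, dimension: int):
        if a < 0:
            raise ValueError("quadratic_well requires a >= 0")
        bounds = [[-1e6, 1e6]] * int(dimension)
        super().__init__(dimension, {"a": float(a), "dimension": int(dimension)}, bounds)
        self.a = float(a)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.a * np.sum(x * x, axis=-1)

    def gradient(self, x):
        return self.a * np.asarray(x, dtype=float)


def _smoothstep(u):
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


def _smoothstep_d(u):
    return 30.0 * u * u * (1.0 - u) ** 2


class _ProtonRelay(PotentialSurface):
    """Chain of coupled double wells along a straight spine in ``n_cv`` coordinates.

    The spine runs along the first coordinate with stationary points at integer
    multiples of ``node_spacing`` taking exactly the prescribed alternating values
    (quintic smoothstep segments: C2-continuous, monotone between nodes, zero slope
    and curvature at each node). Transverse coordinates are harmonic with stiffness
    ``transverse``; beyond the spine ends quadratic walls confine the walker.
    """

    name = "proton_relay"

    def __init__(self, n_cv, values, transverse, node_spacing, wall):
        values = np.asarray(values, dtype=float)
        if not (2 <= int(n_cv) <= 6):
            raise ValueError("n_cv must be between 2 and 6")
        if values.size < 2 or not np.all(np.isfinite(values)):
            raise ValueError("barrier_spec must list at least two finite values")
        d = np.diff(values)
        flat = np.all(d == 0)
        if not flat:
            if np.any(d == 0) or np.any(d[:-1] * d[1:] >= 0):
                raise ValueError(
                    "barrier_spec must strictly alternate between maxima and minima"
                )
        length = (values.size - 1) * float(node_spacing)
        bounds = [[-2.0 * node_spacing, length + 2.0 * node_spacing]] + [
            [-1e3, 1e3]
        ] * (int(n_cv) - 1)
        super().__init__(
            int(n_cv),
            {
                "n_cv": int(n_cv),
                "barrier_spec": values.tolist(),
                "transverse": float(transverse),
                "node_spacing": float(node_spacing),
                "wall": float(wall),
            },
            bounds,
        )
        self.values = values
        self.transverse = float(transverse)
        self.node_spacing = float(node_spacing)
        self.wall = float(wall)
        self.spine_length = length

    # -- exact 1-D spine profile -------------------------------------------------
    def spine_profile(self, t):
        t = np.asarray(t, dtype=float)
        h = self.node_spacing
        m = self.values.size - 1
        seg = np.clip(np.floor(t / h).astype(int), 0, m - 1)
        u = np.clip(t / h - seg, 0.0, 1.0)
        v0 = self.values[seg]
        dv = self.values[seg + 1] - v0
        s = v0 + dv * _smoothstep(u)
        s = np.where(t < 0, self.values[0] + self.wall * t**2, s)
        over = t - m * h
        s = np.where(over > 0, self.values[-1] + self.wall * over**2, s)
        return s

    def _spine_slope(self, t):
        t = np.asarray(t, dtype=float)
        h = self.node_spacing
        m = self.values.size - 1
        seg = np.clip(np.floor(t / h).astype(int), 0, m - 1)
        u = np.clip(t / h - seg, 0.0, 1.0)
        dv = self.values[seg + 1] - self.values[seg]
        g = dv * _smoothstep_d(u) / h
        g = np.where(t < 0, 2.0 * self.wall * t, g)
        over = t - m * h
        g = np.where(over > 0, 2.0 * self.wall * over, g)
        return g

    def spine_points(self, n: int) -> np.ndarray:
        pts = np.zeros((n, self.dimension))
        pts[:, 0] = np.linspace(0.0, self.spine_length, n)
        return pts

    def spine_nodes(self) -> np.ndarray:
        return np.arange(self.values.size) * self.node_spacing

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.spine_profile(x[..., 0]) + 0.5 * self.transverse * np.sum(
            x[..., 1:] ** 2, axis=-1
        )

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = self.transverse * x.copy()
        g[..., 0] = self._spine_slope(x[..., 0])
        return g


# -- factories -------------------------------------------------------------------


def muller_brown() -> PotentialSurface:
    """The canonical four-Gaussian two-dimensional benchmark landscape."""
    return _MullerBrown()


def double_well(h: float, c: float) -> PotentialSurface:
    """Symmetric double well with exact barrier ``h`` and transverse stiffness ``c``."""
    return _DoubleWell(h, c)


def quadratic_well(a: float, dimension: int = 1) -> PotentialSurface:
    """Isotropic quadratic well V = a|x|^2/2 (estimator closed-form test bed)."""
    return _QuadraticWell(a, dimension)


def proton_relay_surface(
    n_cv: int,
    barrier_spec,
    transverse: float = 20.0,
    node_spacing: float = 1.0,
    wall: float = 10.0,
) -> PotentialSurface:
    """Multi-basin chain of coupled double wells embedded in ``n_cv`` coordinates.

    ``barrier_spec`` lists the exact energies of the stationary states along the
    spine in order (reactant, first barrier, first intermediate, ..., product); it
    must strictly alternate between maxima and minima, or be entirely flat.
    """
    return _ProtonRelay(n_cv, barrier_spec, transverse, node_spacing, wall)


def gac_like_profile() -> list[float]:
    """Default spine energies emulating a proton-relay mechanism with four barriers
    and three metastable intermediates (units: kcal/mol-like)."""
    return [0.0, 8.0, 2.0, 14.0, 4.0, 12.0, -6.0, 2.0, -1.7]


def sac_like_profile() -> list[float]:
    """Default spine energies for the simpler direct mechanism: two barriers, the
    second rate-limiting, one intermediate, strongly exergonic overall."""
    return [0.0, 9.1, 2.0, 25.0, -12.2]


_REGISTRY = {
    "muller_brown": lambda p: muller_brown(),
    "double_well": lambda p: double_well(p["h"], p["c"]),
    "quadratic_well": lambda p: quadratic_well(p["a"], p.get("dimension", 1)),
    "proton_relay": lambda p: proton_relay_surface(
        p["n_cv"],
        p["barrier_spec"],
        p.get("transverse", 20.0),
        p.get("node_spacing", 1.0),
        p.get("wall", 10.0),
    ),
}


def surface_from_dict(spec: dict) -> PotentialSurface:
    """Rebuild a surface from its serialized ``{"name": ..., "parameters": ...}``."""
    name = spec["name"]
    if name not in _REGISTRY:
        raise ValueError(f"unknown surface '{name}'; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name](spec.get("parameters", {}))


# -- oracle machinery --------------------------------------------------------------


@dataclass
class ReferencePath:
    """Ground-truth minimum-energy path from the grid oracle.

    ``points`` are uniformly spaced along the polyline; ``saddle_points`` holds the
    Newton-refined first-order saddles the path crosses, in order, and
    ``saddle_indices`` the nearest indices into ``points``.
    """

    points: np.ndarray
    energies: np.ndarray
    saddle_indices: list[int] = field(default_factory=list)
    saddle_points: np.ndarray | None = None

    @property
    def length(self) -> float:
        return float(arc_lengths(self.points)[-1]) if len(self.points) > 1 else 0.0


def finite_difference_hessian(surface: PotentialSurface, x, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian from the exact gradient."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        H[:, j] = (surface.gradient(x + e) - surface.gradient(x - e)) / (2 * h)
    return 0.5 * (H + H.T)


def _newton_stationary(surface, x0, max_iter=100, tol=1e-12):
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        g = surface.gradient(x)
        if np.linalg.norm(g) < tol:
            return x, True
        H = finite_difference_hessian(surface, x)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return x, False
        if np.linalg.norm(step) > 1.0:  # keep Newton local
            step *= 1.0 / np.linalg.norm(step)
        x = x - step
    return x, np.linalg.norm(surface.gradient(x)) < 1e-8


def refine_minimum(surface: PotentialSurface, x0) -> np.ndarray:
    """Polish a nearby local minimum to machine precision (gradient descent + Newton)."""
    x = np.asarray(x0, dtype=float).copy()
    res = optimize.minimize(
        lambda p: float(surface.energy(p)),
        x,
        jac=lambda p: np.asarray(surface.gradient(p), dtype=float),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    x, ok = _newton_stationary(surface, res.x)
    if not ok:
        raise RuntimeError("minimum refinement did not converge")
    return x


def refine_saddle(surface: PotentialSurface, x0) -> np.ndarray:
    """Newton-refine a first-order saddle from a nearby guess; validates the index."""
    x, ok = _newton_stationary(surface, x0)
    if not ok:
        raise RuntimeError("saddle refinement did not converge")
    eig = np.linalg.eigvalsh(finite_difference_hessian(surface, x))
    if np.sum(eig < 0) != 1:
        raise RuntimeError(f"refined stationary point is not a first-order saddle: {eig}")
    return x


def _grid_minimax_path(surface, a, b, resolution, box):
    xs = np.arange(box[0, 0], box[0, 1] + resolution / 2, resolution)
    ys = np.arange(box[1, 0], box[1, 1] + resolution / 2, resolution)
    nx, ny = len(xs), len(ys)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    E = surface.energy(np.stack([XX, YY], axis=-1))

    def node(p):
        i = int(round((p[0] - xs[0]) / resolution))
        j = int(round((p[1] - ys[0]) / resolution))
        return min(max(i, 0), nx - 1), min(max(j, 0), ny - 1)

    start, goal = node(a), node(b)
    INF = np.inf
    best = np.full((nx, ny), INF)
    prev = np.full((nx, ny, 2), -1, dtype=np.int32)
    best[start] = E[start]
    heap = [(E[start], start)]
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while heap:
        cost, (i, j) = heapq.heappop(heap)
        if cost > best[i, j]:
            continue
        if (i, j) == goal:
            break
        for di, dj in nbrs:
            ii, jj = i + di, j + dj
            if 0 <= ii < nx and 0 <= jj < ny:
                c = max(cost, E[ii, jj])
                if c < best[ii, jj]:
                    best[ii, jj] = c
                    prev[ii, jj] = (i, j)
                    heapq.heappush(heap, (c, (ii, jj)))
    if not np.isfinite(best[goal]):
        raise RuntimeError("grid too coarse to connect endpoints")
    path = [goal]
    while path[-1] != start:
        i, j = path[-1]
        pi, pj = prev[i, j]
        if pi < 0:
            raise RuntimeError("grid too coarse to connect endpoints")
        path.append((int(pi), int(pj)))
    path.reverse()
    return np.array([(xs[i], ys[j]) for i, j in path])


def _streamline(surface, x0, step, max_steps=200000, g_stop=0.5):
    """Normalized steepest-descent streamline from x0 down into a basin.

    Fixed-arc steps cannot settle onto the minimum itself, so the walk stops once
    the gradient norm falls below ``g_stop`` (well inside the basin for any surface
    with curvature ≳ 1) and the exact minimum is appended by Newton polish.
    """
    x = np.asarray(x0, dtype=float).copy()
    pts = [x.copy()]
    e = float(surface.energy(x))
    h = step
    for _ in range(max_steps):
        g = surface.gradient(x)
        gn = np.linalg.norm(g)
        if gn < g_stop or h < 1e-3 * step:
            break
        xn = x - h * g / gn
        en = float(surface.energy(xn))
        if en >= e:  # overshot the basin floor: shrink the arc step
            h *= 0.5
            continue
        x, e = xn, en
        pts.append(x.copy())
    m = refine_minimum(surface, x)
    pts.append(m)
    return np.array(pts), m


def brute_force_mep(
    surface: PotentialSurface,
    a,
    b,
    resolution: float = 0.01,
    n_points: int = 200,
) -> ReferencePath:
    """Minimum-energy path between ``a`` and ``b`` by grid search plus relaxation.

    Independent of the string machinery: a minimax (edge-maximum energy) Dijkstra
    search on a dense 8-connected grid brackets the saddle corridor; each energy
    maximum along the grid path is Newton-refined to a first-order saddle; exact
    steepest-descent streamlines from the saddles are stitched through the basins.
    Implemented for two-dimensional surfaces, which is where a dense grid is
    tractable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if surface.dimension != 2:
        raise ValueError("brute_force_mep requires a two-dimensional surface")
    if not (surface.in_domain(a) and surface.in_domain(b)):
        raise ValueError("endpoints must lie inside the surface domain")
    if np.allclose(a, b):
        pt = a[None, :]
        return ReferencePath(pt, np.atleast_1d(surface.energy(a)), [], None)

    lo = np.minimum(a, b) - 1.0
    hi = np.maximum(a, b) + 1.0
    box = np.stack(
        [np.maximum(lo, surface.domain[:, 0]), np.minimum(hi, surface.domain[:, 1])],
        axis=1,
    )
    grid_path = _grid_minimax_path(surface, a, b, resolution, box)
    E = surface.energy(grid_path)

    # candidate saddles: windowed local maxima of energy along the grid path
    w = max(3, int(0.05 / resolution))
    cand = [
        i
        for i in range(w, len(E) - w)
        if E[i] >= np.max(E[max(0, i - w) : i + w + 1]) and E[i] > min(E[i - w], E[i + w])
    ]
    saddles = []
    for i in cand:
        try:
            s = refine_saddle(surface, grid_path[i])
        except RuntimeError:
            continue
        if not any(np.linalg.norm(s - t) < 10 * resolution for t in saddles):
            saddles.append(s)

    if not saddles:
        pts = resample_polyline(grid_path, n_points) if len(grid_path) > 1 else grid_path
        return ReferencePath(pts, surface.energy(pts), [], None)

    # order saddles by position along the corridor
    sidx = [int(np.argmin(np.linalg.norm(grid_path - s, axis=1))) for s in saddles]
    order = np.argsort(sidx)
    saddles = [saddles[k] for k in order]

    step = resolution / 2
    pieces = []
    prev_min = None
    for s in saddles:
        eig, vec = np.linalg.eigh(finite_difference_hessian(surface, s))
        v = vec[:, 0]  # unstable direction
        downA, mA = _streamline(surface, s + 5 * resolution * v, step)
        downB, mB = _streamline(surface, s - 5 * resolution * v, step)
        # orient so the A side continues from the previous basin
        ref = a if prev_min is None else prev_min
        if np.linalg.norm(mB - ref) < np.linalg.norm(mA - ref):
            downA, downB = downB, downA
            mA, mB = mB, mA
        pieces.append(np.vstack([downA[::-1], s, downB]))
        prev_min = mB
    full = np.vstack(pieces)
    dense = resample_polyline(full, max(n_points, 4 * len(saddles) + 2))
    energies = surface.energy(dense)
    sad_idx = [int(np.argmin(np.linalg.norm(dense - s, axis=1))) for s in saddles]
    return ReferencePath(dense, energies, sad_idx, np.array(saddles))
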