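"""Polyline geometry helpers shared by the string optimizer and the path oracles."""

from __future__ import annotations

import numpy as np


def weighted_norm(v: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Euclidean norm in CV space, optionally scaled per-CV by sqrt(weights)."""
    v = np.asarray(v, dtype=float)
    if weights is None:
        return np.linalg.norm(v, axis=-1)
    w = np.asarray(weights, dtype=float)
    return np.sqrt(np.sum(w * v * v, axis=-1))


def arc_lengths(points: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Cumulative (weighted) arc length along a polyline, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = weighted_norm(np.diff(points, axis=0), weights)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _interp_along(points: np.ndarray, s: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of polyline `points` (cum. arc `s`) at `targets`."""
    out = np.empty((len(targets), points.shape[1]))
    for j in range(points.shape[1]):
        out[:, j] = np.interp(targets, s, points[:, j])
    return out


def resample_polyline(
    points: np.ndarray,
    n: int,
    weights: np.ndarray | None = None,
    tol: float = 1e-13,
    max_iter: int = 100,
) -> np.ndarray:
    """Place `n` points at equal (weighted) arc length along a polyline.

    Linear interpolation along the current polyline is iterated to a fixed point so
    that the returned vertices are equally spaced along *their own* polyline; this
    makes the operation idempotent to round-off and the spacing uniform to well below
    1e-8 relative.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array (n_points, n_dims)")
    if n < 2:
        raise ValueError("need at least two output points")
    s = arc_lengths(points, weights)
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-length path cannot be resampled")
    current = _interp_along(points, s, np.linspace(0.0, total, n))
    scale = max(total, 1.0)
    for _ in range(max_iter):
        s = arc_lengths(current, weights)
        if s[-1] <= 0:
            break
        new = _interp_along(current, s, np.linspace(0.0, s[-1], n))
        move = np.max(np.abs(new - current))
        current = new
        if move < tol * scale:
            break
    # endpoints are preserved exactly
    current[0] = points[0]
    current[-1] = points[-1]
    return current
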