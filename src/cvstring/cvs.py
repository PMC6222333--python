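"""Collective variables θ[x] and their exact Cartesian partial derivatives.

Three kinds are supported: interatomic ``distance`` (configuration interpreted as
flat xyz triplets, atom ``i`` at coordinates ``x[3i:3i+3]``), ``dihedral`` over four
atoms (degrees, IUPAC sign convention, range (−180°, 180°]), and ``identity`` (a raw
configuration coordinate, for analytic landscapes where the CVs *are* the
coordinates). All evaluations are vectorized over leading axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CVDefinition",
    "CVSet",
    "DegenerateGeometryError",
    "evaluate_cvs",
    "cv_gradients",
]

_KINDS = {"distance": 2, "dihedral": 4, "identity": 1}


class DegenerateGeometryError(ValueError):
    """Raised for geometries where a CV or its gradient is undefined
    (coincident atoms in a distance, collinear atoms in a dihedral)."""


@dataclass(frozen=True)
class CVDefinition:
    """One collective variable: kind, the indices it reads, a metric weight, a label.

    For ``distance``/``dihedral`` the indices are atom indices; for ``identity`` a
    single raw coordinate index. ``weight`` scales this CV in the arc-length metric
    (all distances in commensurate units keep the default 1).
    """

    kind: str
    indices: tuple[int, ...]
    weight: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown CV kind '{self.kind}'")
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) != _KINDS[self.kind]:
            raise ValueError(f"{self.kind} CV needs {_KINDS[self.kind]} indices")
        if len(set(idx)) != len(idx):
            raise ValueError("CV indices must be distinct")
        if min(idx) < 0:
            raise ValueError("CV indices must be non-negative")
        if not self.weight > 0:
            raise ValueError("CV weight must be positive")
        if not self.label:
            object.__setattr__(self, "label", f"{self.kind}{idx}")

    def min_dimension(self) -> int:
        """Smallest configuration dimension this CV can read."""
        if self.kind == "identity":
            return max(self.indices) + 1
        return 3 * (max(self.indices) + 1)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "indices": list(self.indices),
            "weight": self.weight,
            "label": self.label,
        }


@dataclass(frozen=True)
class CVSet:
    """Ordered collection of collective variables with unique labels."""

    cvs: tuple[CVDefinition, ...]
    _all_identity: bool = field(init=False, repr=False, default=False)

    def __post_init__(self):
        cvs = tuple(self.cvs)
        object.__setattr__(self, "cvs", cvs)
        if not cvs:
            raise ValueError("CVSet needs at least one CV")
        labels = [c.label for c in cvs]
        if len(set(labels)) != len(labels):
            raise ValueError("CV labels must be unique")
        object.__setattr__(self, "_all_identity", all(c.kind == "identity" for c in cvs))

    @property
    def N(self) -> int:
        return len(self.cvs)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.cvs]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.cvs])

    @property
    def all_identity(self) -> bool:
        return self._all_identity

    def identity_indices(self) -> np.ndarray:
        if not self._all_identity:
            raise ValueError("CV set is not purely identity")
        return np.array([c.indices[0] for c in self.cvs])

    def min_dimension(self) -> int:
        return max(c.min_dimension() for c in self.cvs)

    def to_list(self) -> list[dict]:
        return [c.to_dict() for c in self.cvs]


def identity_cvset(n: int, labels=None) -> CVSet:
    labels = labels or [f"z{i+1}" for i in range(n)]
    return CVSet(tuple(CVDefinition("identity", (i,), label=labels[i]) for i in range(n)))


def cvset_from_list(specs: list[dict]) -> CVSet:
    return CVSet(
        tuple(
            CVDefinition(
                s["kind"], tuple(s["indices"]), s.get("weight", 1.0), s.get("label", "")
            )
            for s in specs
        )
    )


def cvset_from_atom_names(specs: list[dict], atom_names: list[str]) -> CVSet:
    """Build a CV set declaring distance/dihedral CVs by atom *name*.

    Each spec is ``{"kind": ..., "atoms": [name, ...], "weight": ..., "label": ...}``;
    names are resolved against ``atom_names`` (e.g. from an XYZ file) and must be
    unique there."""
    cvs = []
    for s in specs:
        idx = []
        for name in s["atoms"]:
            hits = [i for i, a in enumerate(atom_names) if a == name]
            if len(hits) != 1:
                raise ValueError(
                    f"atom name '{name}' resolves to {len(hits)} atoms; need exactly 1"
                )
            idx.append(hits[0])
        cvs.append(
            CVDefinition(
                s["kind"], tuple(idx), s.get("weight", 1.0),
                s.get("label", "-".join(s["atoms"])),
            )
        )
    return CVSet(tuple(cvs))


def _atoms(x: np.ndarray, idx: tuple[int, ...]) -> list[np.ndarray]:
    return [x[..., 3 * i : 3 * i + 3] for i in idx]


def _distance(x, idx, grad: bool, dim: int):
    ra, rb = _atoms(x, idx)
    d = ra - rb
    r = np.linalg.norm(d, axis=-1)
    if np.any(r < 1e-10):
        raise DegenerateGeometryError(
            f"coincident points for distance CV over atoms {idx}"
        )
    if not grad:
        return r
    u = d / r[..., None]
    g = np.zeros(x.shape[:-1] + (dim,))
    ia, ib = idx
    g[..., 3 * ia : 3 * ia + 3] = u
    g[..., 3 * ib : 3 * ib + 3] = -u
    return r, g


def _dihedral(x, idx, grad: bool, dim: int):
    ra, rb, rc, rd = _atoms(x, idx)
    b1 = rb - ra
    b2 = rc - rb
    b3 = rd - rc
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.sum(n1 * n1, axis=-1)
    n2sq = np.sum(n2 * n2, axis=-1)
    if np.any(n1sq < 1e-20) or np.any(n2sq < 1e-20):
        raise DegenerateGeometryError(f"collinear geometry for dihedral CV over atoms {idx}")
    b2n = np.linalg.norm(b2, axis=-1)
    # IUPAC convention: cis (eclipsed) = 0, sign from the b2-handedness of n1 x n2
    phi = np.arctan2(np.sum(np.cross(n1, n2) * b2, axis=-1) / b2n, np.sum(n1 * n2, axis=-1))
    deg = np.degrees(phi)
    # map -180 to +180 so the range is (-180, 180]
    deg = np.where(deg <= -180.0, deg + 360.0, deg)
    if not grad:
        return deg
    # standard analytic dihedral gradient (radians), converted to degrees at the end
    dA = -(b2n / n1sq)[..., None] * n1
    dD = (b2n / n2sq)[..., None] * n2
    f = (np.sum(b1 * b2, axis=-1) / b2n**2)[..., None]
    h = (np.sum(b3 * b2, axis=-1) / b2n**2)[..., None]
    dB = -(1.0 + f) * dA + h * dD
    dC = f * dA - (1.0 + h) * dD
    g = np.zeros(x.shape[:-1] + (dim,))
    for i, gi in zip(idx, (dA, dB, dC, dD)):
        g[..., 3 * i : 3 * i + 3] = np.degrees(gi)
    return deg, g


def evaluate_cvs(cvset: CVSet, x: np.ndarray) -> np.ndarray:
    """Return θ[x], shape ``x.shape[:-1] + (N,)``; distances in configuration length
    units, dihedrals in degrees on (−180°, 180°]."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < cvset.min_dimension():
        raise ValueError(
            f"configuration dimension {x.shape[-1]} too small for CV set "
            f"(needs >= {cvset.min_dimension()})"
        )
    if cvset.all_identity:
        return x[..., cvset.identity_indices()]
    vals = []
    for cv in cvset.cvs:
        if cv.kind == "identity":
            vals.append(x[..., cv.indices[0]])
        elif cv.kind == "distance":
            vals.append(_distance(x, cv.indices, False, x.shape[-1]))
        else:
            vals.append(_dihedral(x, cv.indices, False, x.shape[-1]))
    return np.stack(vals, axis=-1)


def cv_gradients(cvset: CVSet, x: np.ndarray) -> np.ndarray:
    """Exact partials ∂θ_i/∂x_k, shape ``x.shape[:-1] + (N, dim)``; rows are CVs,
    columns Cartesian coordinates, zero where a coordinate is not referenced."""
    x = np.asarray(x, dtype=float)
    dim = x.shape[-1]
    if dim < cvset.min_dimension():
        raise ValueError(
            f"configuration dimension {dim} too small for CV set "
            f"(needs >= {cvset.min_dimension()})"
        )
    rows = []
    for cv in cvset.cvs:
        if cv.kind == "identity":
            g = np.zeros(x.shape[:-1] + (dim,))
            g[..., cv.indices[0]] = 1.0
        elif cv.kind == "distance":
            _, g = _distance(x, cv.indices, True, dim)
        else:
            _, g = _dihedral(x, cv.indices, True, dim)
        rows.append(g)
    return np.stack(rows, axis=-2)
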