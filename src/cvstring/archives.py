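"""Delimited-text archives for paths, mean-force estimates, profiles and states.

All scientific outputs are diff-able text: CSV bodies at full decimal precision
(round-trips are bit-for-bit) preceded by '#' header lines recording the tool
version, the configuration hash, the master seed, and a content hash of the data
rows."""

from __future__ import annotations

import hashlib
import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .meanforce import MeanForceEstimate
from .profile import FreeEnergyProfile, StationaryState
from .string import StringPath

__all__ = [
    "read_xyz",
    "write_path_archive",
    "read_path_archive",
    "write_estimates_archive",
    "read_estimates_archive",
    "write_profile_table",
    "read_profile_table",
    "write_states_table",
    "write_xyz_snapshots",
]

_FMT = "%.17g"


def read_xyz(src):
    """First frame of an XYZ file: (atom names, coordinates of shape (n, 3)).

    The names let distance/dihedral CVs on molecular toy systems be declared by
    atom label instead of raw index (see ``cvs.cvset_from_atom_names``)."""
    lines = Path(src).read_text().splitlines()
    if not lines:
        raise ValueError("empty XYZ file")
    n = int(lines[0].split()[0])
    names, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        names.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    if len(names) != n:
        raise ValueError("XYZ frame shorter than its declared atom count")
    return names, np.asarray(coords)


def _header(master_seed=None, config_hash=None, content: str = "") -> str:
    from . import __version__

    lines = [f"# cvstring {__version__}"]
    if config_hash is not None:
        lines.append(f"# config_hash={config_hash}")
    if master_seed is not None:
        lines.append(f"# master_seed={master_seed}")
    digest = hashlib.sha256(content.encode()).hexdigest()[:16]
    lines.append(f"# content_hash={digest}")
    return "\n".join(lines) + "\n"


def _fmt(x: float) -> str:
    return _FMT % x


def write_path_archive(
    paths, dest, cv_labels=None, master_seed=None, config_hash=None
) -> None:
    """One row per (cycle, image): cycle, image, alpha, cv_1...cv_N in declaration
    order. Accepts a single path or a per-cycle list."""
    if isinstance(paths, StringPath):
        paths = [paths]
    if not paths:
        raise ValueError("no paths to write")
    N = paths[0].N
    cv_labels = cv_labels or [f"cv_{i+1}" for i in range(N)]
    buf = io.StringIO()
    buf.write("cycle,image,alpha," + ",".join(cv_labels) + "\n")
    for p in paths:
        for r in range(p.R):
            row = [str(p.cycle), str(r), _fmt(p.alphas[r])]
            row += [_fmt(v) for v in p.images[r]]
            buf.write(",".join(row) + "\n")
    body = buf.getvalue()
    Path(dest).write_text(_header(master_seed, config_hash, body) + body)


def read_path_archive(src) -> list[StringPath]:
    """Inverse of :func:`write_path_archive`, grouped by cycle in file order."""
    df = pd.read_csv(src, comment="#", float_precision="round_trip")
    cv_cols = [c for c in df.columns if c not in ("cycle", "image", "alpha")]
    out = []
    for cyc, grp in df.groupby("cycle", sort=True):
        grp = grp.sort_values("image")
        out.append(
            StringPath(grp[cv_cols].to_numpy(), grp["alpha"].to_numpy(), int(cyc))
        )
    return out


def write_estimates_archive(
    estimates_per_cycle, dest, cv_labels=None, master_seed=None, config_hash=None
) -> None:
    """One row per (cycle, image, cv): gradient, stderr, metric row flattened."""
    first = estimates_per_cycle[0][0]
    N = len(first.gradient)
    cv_labels = cv_labels or [f"cv_{i+1}" for i in range(N)]
    mcols = ",".join(f"M_{j+1}" for j in range(N))
    buf = io.StringIO()
    buf.write(f"cycle,image,cv_label,gradient,stderr,{mcols}\n")
    for cyc, ests in enumerate(estimates_per_cycle):
        for est in ests:
            for i in range(N):
                row = [
                    str(cyc),
                    str(est.image_index),
                    cv_labels[i],
                    _fmt(est.gradient[i]),
                    _fmt(est.standard_error[i]),
                ] + [_fmt(v) for v in est.metric[i]]
                buf.write(",".join(row) + "\n")
    body = buf.getvalue()
    Path(dest).write_text(_header(master_seed, config_hash, body) + body)


def read_estimates_archive(src) -> list[list[MeanForceEstimate]]:
    df = pd.read_csv(src, comment="#", float_precision="round_trip")
    mcols = sorted([c for c in df.columns if c.startswith("M_")], key=lambda c: int(c[2:]))
    out = []
    for cyc in sorted(df["cycle"].unique()):
        dcyc = df[df["cycle"] == cyc]
        ests = []
        for img in sorted(dcyc["image"].unique()):
            d = dcyc[dcyc["image"] == img]
            ests.append(
                MeanForceEstimate(
                    gradient=d["gradient"].to_numpy(),
                    metric=d[mcols].to_numpy(),
                    standard_error=d["stderr"].to_numpy(),
                    image_index=int(img),
                )
            )
        out.append(ests)
    return out


def write_profile_table(profile: FreeEnergyProfile, dest, master_seed=None, config_hash=None):
    buf = io.StringIO()
    buf.write("alpha,G,stderr\n")
    for a, g, s in zip(profile.alpha_grid, profile.G, profile.stderr):
        buf.write(f"{_fmt(a)},{_fmt(g)},{_fmt(s)}\n")
    body = buf.getvalue()
    Path(dest).write_text(_header(master_seed, config_hash, body) + body)


def read_profile_table(src) -> FreeEnergyProfile:
    df = pd.read_csv(src, comment="#", float_precision="round_trip")
    return FreeEnergyProfile(df["alpha"].to_numpy(), df["G"].to_numpy(), df["stderr"].to_numpy())


def write_states_table(
    states: list[StationaryState], dest, cv_labels=None, master_seed=None, config_hash=None
):
    """Stationary-state table: label, alpha, G, one column per CV value."""
    ncv = 0
    for s in states:
        if s.cv_values is not None:
            ncv = len(s.cv_values)
            break
    cv_labels = cv_labels or [f"cv_{i+1}" for i in range(ncv)]
    buf = io.StringIO()
    buf.write("label,alpha,G" + ("," + ",".join(cv_labels) if ncv else "") + "\n")
    for s in states:
        row = [s.label, _fmt(s.alpha), _fmt(s.G)]
        if ncv:
            vals = s.cv_values if s.cv_values is not None else [np.nan] * ncv
            row += [_fmt(v) for v in vals]
        buf.write(",".join(row) + "\n")
    body = buf.getvalue()
    Path(dest).write_text(_header(master_seed, config_hash, body) + body)


def write_xyz_snapshots(configs, labels, dest) -> None:
    """Multi-frame XYZ; configurations with fewer than three coordinates are padded
    with zeros and written as a single pseudo-atom (flagged in the comment line)."""
    configs = [np.asarray(c, dtype=float).ravel() for c in configs]
    if not configs:
        warnings.warn("writing empty XYZ snapshot file", RuntimeWarning)
        Path(dest).write_text("")
        return
    labels = list(labels)
    if len(labels) != len(configs):
        raise ValueError("need one label per configuration")
    lines = []
    for c, lab in zip(configs, labels):
        dim = c.size
        if dim < 3:
            padded = np.zeros(3)
            padded[:dim] = c
            atoms = padded[None, :]
            note = f"{lab} (padded pseudo-atom; original dimension {dim})"
        elif dim % 3 == 0:
            atoms = c.reshape(-1, 3)
            note = str(lab)
        else:
            raise ValueError(f"configuration dimension {dim} is not divisible by 3")
        lines.append(str(len(atoms)))
        lines.append(note)
        for i, (x, y, z) in enumerate(atoms):
            lines.append(f"X{i+1} {x:.10f} {y:.10f} {z:.10f}")
    Path(dest).write_text("\n".join(lines) + "\n")
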