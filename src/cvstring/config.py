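"""Structured-text run configuration: parsing, validation, defaults, round-trips.

A run is described by a YAML document with sections ``surface``, ``cvs``,
``restraints``, ``sampler``, ``schedule``, ``string``, plus ``output_dir`` and
``master_seed``. Unknown keys anywhere are rejected (fail-closed); defaults mirror
the reference protocol (25 images, 100 cycles, descent step 0.001, smoothing 0.01,
20000-step per-image sampling with the first quarter discarded, 298 K).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._constants import thermal_energy
from .cvs import CVSet, cvset_from_list, identity_cvset
from .sampler import SamplerConfig
from .string import OptimizationSchedule, StringPath, linear_initial_path
from .surfaces import PotentialSurface, surface_from_dict

__all__ = ["RunConfig", "read_config", "write_config", "config_hash"]

_SAMPLER_DEFAULTS = {
    "kT": thermal_energy(298.0),
    "timestep": 0.001,
    "n_steps_total": 20000,
    "n_steps_burnin": None,
    "friction": 1.0,
    "sample_stride": 1,
    "store_stride": None,
    "n_blocks": 10,
    "seed": None,
}
_SCHEDULE_DEFAULTS = {
    "n_cycles": 100,
    "descent_step": 0.001,
    "smoothing": 0.01,
    "rmsd_tolerance": 0.01,
    "endpoint_mode": "free",
    "early_stop": False,
    "convergence_window": 5,
}
_STRING_DEFAULTS = {"n_images": 25, "start": None, "end": None, "initial_path": None}
_CV_KEYS = {"kind", "indices", "weight", "label"}


def _merge(section: str, raw: dict | None, defaults: dict) -> dict:
    raw = dict(raw or {})
    unknown = set(raw) - set(defaults)
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    out = dict(defaults)
    out.update(raw)
    return out


@dataclass
class RunConfig:
    """Validated, defaults-resolved description of one string-optimization run."""

    surface: dict
    cvs: list | None
    restraint_k: float | list
    sampler: dict
    schedule: dict
    string: dict
    output_dir: str = "cvstring_out"
    master_seed: int = 0

    def build_surface(self) -> PotentialSurface:
        return surface_from_dict(self.surface)

    def build_cvset(self) -> CVSet:
        if self.cvs is None:
            return identity_cvset(self.build_surface().dimension)
        return cvset_from_list(self.cvs)

    def build_sampler(self) -> SamplerConfig:
        return SamplerConfig(**self.sampler)

    def build_schedule(self) -> OptimizationSchedule:
        return OptimizationSchedule(per_cycle_sampler=self.build_sampler(), **self.schedule)

    def build_initial_path(self) -> StringPath:
        from .archives import read_path_archive

        if self.string["initial_path"]:
            return read_path_archive(self.string["initial_path"])[-1]
        if self.string["start"] is None or self.string["end"] is None:
            raise ValueError("config needs string.start and string.end, or an initial_path")
        return linear_initial_path(
            np.asarray(self.string["start"], dtype=float),
            np.asarray(self.string["end"], dtype=float),
            int(self.string["n_images"]),
        )

    def to_dict(self) -> dict:
        return {
            "surface": self.surface,
            "cvs": self.cvs,
            "restraints": {"k": self.restraint_k},
            "sampler": dict(self.sampler),
            "schedule": dict(self.schedule),
            "string": dict(self.string),
            "output_dir": self.output_dir,
            "master_seed": self.master_seed,
        }


def _parse(doc: dict) -> RunConfig:
    top_keys = {
        "surface",
        "cvs",
        "restraints",
        "sampler",
        "schedule",
        "string",
        "output_dir",
        "master_seed",
    }
    unknown = set(doc) - top_keys
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    if "surface" not in doc:
        raise ValueError("config must define a surface")
    surf = dict(doc["surface"])
    if set(surf) - {"name", "parameters"}:
        raise ValueError(f"unknown keys in 'surface': {sorted(set(surf) - {'name', 'parameters'})}")

    cvs = doc.get("cvs")
    if cvs is not None:
        for i, cv in enumerate(cvs):
            bad = set(cv) - _CV_KEYS
            if bad:
                raise ValueError(f"unknown keys in cvs[{i}]: {sorted(bad)}")

    restraints = _merge("restraints", doc.get("restraints"), {"k": 100.0})
    sampler = _merge("sampler", doc.get("sampler"), _SAMPLER_DEFAULTS)
    schedule = _merge("schedule", doc.get("schedule"), _SCHEDULE_DEFAULTS)
    string = _merge("string", doc.get("string"), _STRING_DEFAULTS)

    cfg = RunConfig(
        surface=surf,
        cvs=cvs,
        restraint_k=restraints["k"],
        sampler=sampler,
        schedule=schedule,
        string=string,
        output_dir=str(doc.get("output_dir", "cvstring_out")),
        master_seed=int(doc.get("master_seed", 0)),
    )
    # building validates invariants (force constants, smoothing range, ...)
    cfg.build_surface()
    cfg.build_cvset()
    cfg.build_schedule()
    k = np.asarray(cfg.restraint_k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("restraints.k must be positive")
    return cfg


def read_config(path) -> RunConfig:
    """Load, validate and default-resolve a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("config file must contain a mapping")
    return _parse(doc)


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a resolved configuration; read(write(cfg)) reproduces it."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the resolved configuration, recorded in output headers.

    The output directory is excluded: the hash identifies the scientific run, not
    where its files land."""
    doc = cfg.to_dict()
    doc.pop("output_dir", None)
    blob = yaml.safe_dump(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
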