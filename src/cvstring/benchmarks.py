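"""End-to-end benchmark runs on the analytic landscapes.

Each function performs one self-contained validation study at desk scale and
returns the measured quantities: kinetic conversions and protocol arithmetic,
oracle equivalence of the zero-temperature string on the two-dimensional
four-Gaussian benchmark, barrier recovery under sampling noise on the double well,
stationary-state topology recovery on the proton-relay chain, committor
validation at a saddle, estimator closed forms, and conformer-center recovery.
The problem sizes are chosen so the full battery runs in minutes on one core;
docs/methods.md discusses what they do and do not demonstrate.
"""

from __future__ import annotations

import numpy as np

from ._constants import SECONDS_PER_DAY, thermal_energy
from .committor import BasinDefinition, estimate_committor, sample_ts_ensemble
from .conformers import cluster_dihedral_populations
from .cvs import CVDefinition, CVSet, identity_cvset
from .meanforce import estimate_gradient, estimate_metric
from .profile import (
    eyring_barrier,
    first_order_half_life,
    integrate_profile,
    locate_stationary_states,
    profile_uncertainty,
)
from .sampler import RestraintSpec, SamplerConfig, run_restrained
from .string import OptimizationSchedule, StringPath, linear_initial_path, optimize_string
from .surfaces import (
    brute_force_mep,
    double_well,
    gac_like_profile,
    muller_brown,
    proton_relay_surface,
    quadratic_well,
    refine_minimum,
)

__all__ = [
    "kinetic_conversions",
    "protocol_arithmetic",
    "muller_brown_zero_temperature_string",
    "double_well_barrier_recovery",
    "proton_relay_topology_recovery",
    "double_well_saddle_committor",
    "estimator_closed_forms",
    "conformer_center_recovery",
]

_ROOM_T = 300.0  # K; "room temperature" for the kinetic conversions


def kinetic_conversions(temperature: float = _ROOM_T) -> dict:
    """Activation free energies and half-lives for the catalyzed (k_cat = 0.2/s)
    and non-catalyzed aqueous (k = 8e-8/s) ATP-hydrolysis rate constants."""
    k_cat, k_sol = 0.2, 8e-8
    return {
        "barrier_catalyzed_kcal_per_mol": eyring_barrier(k_cat, temperature),
        "barrier_solution_kcal_per_mol": eyring_barrier(k_sol, temperature),
        "half_life_catalyzed_s": first_order_half_life(k_cat),
        "half_life_solution_days": first_order_half_life(k_sol) / SECONDS_PER_DAY,
    }


def protocol_arithmetic() -> dict:
    """Aggregate sampling (20 ps/image x 25 images x 100 cycles) and image spacing."""
    total_s = 20e-12 * 25 * 100
    path = linear_initial_path([0.0], [1.0], 25)
    return {
        "total_sampling_ns": total_s * 1e9,
        "delta_alpha": path.delta_alpha,
        "n_image_cycles": 25 * 100,
    }


def muller_brown_zero_temperature_string(oracle_resolution: float = 0.01) -> dict:
    """Zero-temperature string (25 images, descent step 0.001, smoothing 0.01,
    100 cycles) between the two lowest basins, judged against the grid oracle.

    The anchors use k = 4000: the restraint must dominate both the steepest
    transverse wall curvature (~4e3) and the saddles' negative curvature (~750),
    and the post-burn-in time average over the walker relaxation low-passes the
    measured force, which keeps the outer update stable at the fixed descent step.
    Deterministic: the zero-temperature engine draws no noise.
    """
    from scipy.spatial.distance import cdist

    mb = muller_brown()
    a = refine_minimum(mb, [-0.55, 1.44])
    b = refine_minimum(mb, [0.62, 0.03])
    oracle = brute_force_mep(mb, a, b, resolution=oracle_resolution)

    sampler = SamplerConfig(kT=0.0, timestep=2e-5, n_steps_total=400, n_steps_burnin=100)
    schedule = OptimizationSchedule(
        per_cycle_sampler=sampler,
        n_cycles=100,
        descent_step=0.001,
        smoothing=0.01,
        rmsd_tolerance=0.01,
    )
    result = optimize_string(
        linear_initial_path(a, b, 25), mb, identity_cvset(2), 4000.0, schedule
    )
    rmsd = result.convergence.per_cycle_rmsd_vs_final
    dist = cdist(result.final_path.images, oracle.points).min(axis=1)
    saddle_miss = cdist(oracle.saddle_points, result.final_path.images).min(axis=1)
    return {
        "trailing_rmsd_to_final": float(rmsd[-11:-1].max()),
        "max_deviation_from_oracle": float(dist.max()),
        "max_saddle_miss": float(saddle_miss.max()),
        "converged_cycle": result.convergence.converged_cycle,
        "n_images": 25,
        "n_cycles": 100,
    }


def double_well_barrier_recovery(seed: int = 1) -> dict:
    """Finite-temperature string + restrained sampling + mean-force integration on
    the h = 5 double well; the recovered barrier carries the last-10-cycle
    standard deviation as its uncertainty."""
    surf = double_well(5.0, 1.0)
    kT = thermal_energy(298.0)
    sampler = SamplerConfig(kT=kT, timestep=1e-3, n_steps_total=4000)
    schedule = OptimizationSchedule(
        per_cycle_sampler=sampler, n_cycles=50, descent_step=0.001, smoothing=0.01
    )
    result = optimize_string(
        linear_initial_path([-1.0, 0.0], [1.0, 0.0], 25),
        surf,
        identity_cvset(2),
        200.0,
        schedule,
        master_seed=seed,
    )
    profiles = [
        integrate_profile(p, e)
        for p, e in zip(result.paths[-10:], result.estimates[-10:])
    ]
    prof = profile_uncertainty(profiles)
    top = int(np.argmax(prof.G))
    return {
        "barrier": float(prof.barrier),
        "barrier_sd": float(prof.stderr[top]),
        "exact_barrier": 5.0,
        "n_samples_per_image": sampler.n_samples,
        "n_cycles": 50,
    }


def proton_relay_topology_recovery(seed: int = 2) -> dict:
    """Four-barrier / three-intermediate chain in six CVs: does the integrated
    profile recover the stationary-state topology in order?"""
    surf = proton_relay_surface(6, gac_like_profile())
    kT = thermal_energy(298.0)
    sampler = SamplerConfig(kT=kT, timestep=1e-3, n_steps_total=2000)
    schedule = OptimizationSchedule(
        per_cycle_sampler=sampler, n_cycles=40, descent_step=0.001, smoothing=0.01
    )
    start = np.zeros(6)
    end = np.zeros(6)
    end[0] = surf.spine_length
    result = optimize_string(
        linear_initial_path(start, end, 25), surf, identity_cvset(6), 200.0,
        schedule, master_seed=seed,
    )
    profiles = [
        integrate_profile(p, e)
        for p, e in zip(result.paths[-10:], result.estimates[-10:])
    ]
    prof = profile_uncertainty(profiles)
    states = locate_stationary_states(prof, result.final_path)
    labels = [s.label for s in states]
    return {
        "labels": labels,
        "n_transition_states": sum(l.startswith("TS") for l in labels),
        "n_intermediates": sum(l.startswith("IM") for l in labels),
        "barrier_profile": [round(s.G, 3) for s in states],
        "spine_spec": gac_like_profile(),
        "n_images": 25,
    }


def double_well_saddle_committor(seed: int = 3, n_configs: int = 20, n_shots: int = 10) -> dict:
    """Committor distribution from a restrained ensemble at the double-well saddle;
    the mean commitment probability should sit at one half by symmetry.

    The ensemble anchor uses k = 2000 so the configurational spread (width
    sqrt(kT/k) ~ 0.017) contributes negligible committor variance next to the
    shot noise, keeping the statistics of the pooled estimate binomial."""
    surf = double_well(5.0, 1.0)
    cvset = identity_cvset(2)
    kT = thermal_energy(298.0)
    cfg = SamplerConfig(kT=kT, timestep=2e-3, n_steps_total=4000)
    ens_cfg = SamplerConfig(kT=kT, timestep=2e-4, n_steps_total=4000)  # k*dt << 2
    ens = sample_ts_ensemble(
        surf, cvset, [0.0, 0.0], 2000.0, ens_cfg, n_configs, np.zeros(2), seed=seed
    )
    basins = BasinDefinition(
        [(-1.3, -0.7), None], [(0.7, 1.3), None], max_steps=50000
    )
    res = estimate_committor(surf, cvset, ens, basins, n_shots, cfg, seed=seed + 1)
    return {
        "mean_pB": res.mean,
        "unresolved_fraction": res.unresolved_fraction,
        "n_total_shots": n_configs * n_shots,
    }


def estimator_closed_forms(seed: int = 4) -> dict:
    """Mean-force estimator on a one-dimensional quadratic against the Gaussian
    closed form, and the metric tensor for a lone distance CV / identity CVs."""
    a, k, z = 1.0, 100.0, 0.5
    surf = quadratic_well(a, 1)
    spec = RestraintSpec([z], k)
    cfg = SamplerConfig(kT=thermal_energy(298.0), timestep=1e-3, n_steps_total=100000)
    stats = run_restrained(surf, identity_cvset(1), spec, cfg, np.array([z]), seed=seed)
    grad, se = estimate_gradient(stats, spec)

    dist_cv = CVSet((CVDefinition("distance", (0, 1), label="d"),))
    dstats = run_restrained(
        quadratic_well(0.0, 6),
        dist_cv,
        RestraintSpec([1.5], 100.0),
        SamplerConfig(kT=0.0, timestep=1e-3, n_steps_total=100),
        np.array([0.0, 0, 0, 1.5, 0, 0]),
    )
    istats = run_restrained(
        quadratic_well(1.0, 2),
        identity_cvset(2),
        RestraintSpec([0.0, 0.0], 10.0),
        SamplerConfig(kT=0.5, timestep=1e-3, n_steps_total=200),
        np.zeros(2),
        seed=seed + 1,
    )
    return {
        "quadratic_gradient_estimate": float(grad[0]),
        "quadratic_gradient_closed_form": k * a * z / (a + k),
        "quadratic_gradient_se": float(se[0]),
        "distance_cv_metric": float(estimate_metric(dstats)[0, 0]),
        "identity_metric_max_offdiag": float(
            np.abs(estimate_metric(istats) - np.eye(2)).max()
        ),
        "n_steps": 100000,
    }


def conformer_center_recovery(seed: int = 5, sigma: float = 10.0) -> dict:
    """Circular clustering of synthetic rotamer samples around the three reference
    dihedral categories (-52, +82, -172 degrees)."""
    centers = np.array([-52.0, 82.0, -172.0])
    rng = np.random.default_rng(seed)
    samples = []
    for r in range(10):
        w = np.array([max(0.05, 1 - r / 4), max(0.05, 1 - abs(r - 5) / 4), max(0.05, (r - 4) / 5)])
        w = w / w.sum()
        ns = rng.multinomial(200, w)
        s = np.concatenate([rng.normal(c, sigma, size=n) for c, n in zip(centers, ns)])
        samples.append((s + 180.0) % 360.0 - 180.0)
    pops = cluster_dihedral_populations(samples, n_clusters=3, random_state=seed)
    target = np.sort(centers)
    err = np.abs(
        (pops.cluster_centers - target + 180.0) % 360.0 - 180.0
    )
    return {
        "recovered_centers_deg": pops.cluster_centers.tolist(),
        "generating_centers_deg": target.tolist(),
        "max_center_error_deg": float(err.max()),
        "n_samples": int(sum(len(s) for s in samples)),
    }
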