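# cvstring

String method in collective variables: minimum free energy paths (MFEPs) on
analytic benchmark landscapes.

Enzymatic reactions such as ATP hydrolysis in ABC-transporter motor domains
proceed through sequences of proton transfers and phosphoryl-transfer steps. The
standard way to map such multi-step mechanisms quantitatively is to describe the
reaction by a small set of collective variables (CVs) — typically the forming
and breaking bond distances — and to find the *minimum free energy path*: the
curve **z**[α] in CV space along which the mean force has no component
perpendicular to the path. This package implements that machinery end to end
for users who want to study, validate, or teach the method on landscapes where
the right answer is known exactly, rather than behind an expensive QM/MM
potential.

## The method

The free-energy gradient at a point **z** in CV space is estimated from a
restrained ("umbrella-anchored") trajectory in which each CV θᵢ[x] is tethered
at zᵢ with a stiff harmonic spring of force constant k:

    dG/dzᵢ ≈ kᵢ ⟨zᵢ − θᵢ[x(t)]⟩

Because the CVs are curvilinear functions of the underlying coordinates, path
evolution uses the metric tensor (time-averaged Gram matrix of the CV
gradients)

    Mᵢⱼ ≈ ⟨Σₖ (∂θᵢ/∂xₖ)(∂θⱼ/∂xₖ)⟩

and the MFEP condition reads [**M f**]^⊥ = 0 with **f** = −∇₂G. A string of R
images discretizes the path; each optimization cycle runs restrained sampling
at every image, takes a projected steepest-descent step Δt·P[**M**(−∇G)],
smooths neighbouring images, and reparametrizes to equal arc length
(Δα = 1/(R−1)). The free-energy profile follows by integrating

    G(α) = ∫₀^α Σᵢ (dzᵢ/dα′)(dG/dzᵢ) dα′

with cubic-spline interpolation and the trapezoidal rule on a dense grid.
Candidate transition states are validated by committor analysis (pB ≈ 0.5 from
unbiased shots), and non-CV "monitored" coordinates — e.g. a side-chain
dihedral that responds to the reaction — are analyzed by circular clustering.

Sampling uses an overdamped Langevin engine whose stationary distribution is
exactly the Boltzmann weight of surface-plus-restraint, so every estimator has
a checkable closed form. Benchmark surfaces include the classic
two-dimensional four-Gaussian landscape, a double well with an exact barrier,
and a configurable multi-basin "proton relay" chain (e.g. four barriers and
three intermediates across six CVs) emulating multi-step mechanism topologies.
A brute-force oracle — minimax grid search plus saddle refinement and
steepest-descent streamlines — provides ground-truth minimum-energy paths that
share no code with the string optimizer.

## Worked example

```sh
$ cvstring benchmark --seed 0
barrier_catalyzed_kcal_per_mol=18.52
barrier_solution_kcal_per_mol=27.31
half_life_catalyzed_s=3.466
half_life_solution_days=100.3
double_well_barrier=4.880+-0.178 (exact 5.0)
```

The first four lines are transition-state-theory conversions at 300 K: a
first-order rate of 0.2 s⁻¹ (an efficient ATPase) corresponds to an activation
free energy of ≈18.5 kcal/mol and a substrate half-life of ≈3.5 s, while the
non-catalyzed aqueous rate 8×10⁻⁸ s⁻¹ corresponds to ≈27.3 kcal/mol and a
half-life of ≈100 days. The last line is a full finite-temperature string
optimization (25 images, 50 cycles, restrained Langevin sampling at 298 K) on
a double well whose exact barrier is 5: the integrated profile recovers
4.88 ± 0.18, where the error bar is the standard deviation of the profiles
over the last ten optimization cycles.

The same pipeline is scriptable:

```python
import numpy as np, cvstring as cs

surf = cs.double_well(5.0, 1.0)
sampler = cs.SamplerConfig(kT=cs.thermal_energy(298.0), timestep=1e-3,
                           n_steps_total=4000)
schedule = cs.OptimizationSchedule(per_cycle_sampler=sampler, n_cycles=50)
result = cs.optimize_string(cs.linear_initial_path([-1, 0], [1, 0], 25),
                            surf, cs.identity_cvset(2), 200.0, schedule,
                            master_seed=1)
profiles = [cs.integrate_profile(p, e)
            for p, e in zip(result.paths[-10:], result.estimates[-10:])]
profile = cs.profile_uncertainty(profiles)
for s in cs.locate_stationary_states(profile, result.final_path):
    print(s.label, round(s.alpha, 2), round(s.G, 2))
```

which prints the classified stationary states (`RC 0.0 0.0`, `TS1 0.5 4.93`,
`PC 1.0 0.05` for seed 1): reactant, the transition state at the barrier top,
and the product.

Full runs are driven from a YAML configuration through the CLI
(`cvstring init-string / optimize / profile / committor / analyze-conformers`);
all outputs are plain-text archives with headers recording the tool version,
configuration hash and master seed, and identical seeds reproduce results
byte for byte.

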