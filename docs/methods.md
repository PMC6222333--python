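# Methods

## Model and scope

`cvstring` implements the string method in collective variables for locating
minimum free energy paths (MFEPs). A path is R discrete images of N CV values
**z**[α], α ∈ [0, 1]. Each optimization cycle (i) runs a restrained trajectory
at every image, (ii) converts the trajectory statistics into a mean-force
estimate dG/dzᵢ = kᵢ⟨zᵢ − θᵢ⟩ and a metric tensor Mᵢⱼ = ⟨Σₖ ∂θᵢ/∂xₖ ∂θⱼ/∂xₖ⟩,
(iii) moves each interior image by Δt·P[**M**(−∇G)] with P = I − t̂t̂ᵀ the
projector orthogonal to the discrete path tangent, (iv) smooths neighbouring
images, z′ᵣ = (1−s)zᵣ + (s/2)(zᵣ₋₁+zᵣ₊₁), and (v) reparametrizes the string to
equal arc length. The order evolve → smooth → reparametrize is fixed. The
profile G(α) is the line integral of the mean force along the converged path,
taken with natural cubic splines for dz/dα and dG/dz and the trapezoidal rule
on a dense inclusive grid (default 75 points).

The package deliberately replaces a molecular potential with analytic
landscapes carrying exact gradients, so every stage has an independent check:
Gaussian closed forms for the estimators, a brute-force path oracle for the
optimizer, and prescribed spine profiles for the multi-basin generator.

## Sampling engine

Dynamics are overdamped Langevin integrated by Euler–Maruyama:
dx = −∇V dt/γ + sqrt(2 kBT dt/γ) dW, with the restraint energy
Σᵢ kᵢ(θᵢ−zᵢ)²/2 added to V through the chain rule (restraint forces act on
every coordinate a CV reads). The stationary distribution is the Boltzmann
weight of V + restraint, which makes the stiff-spring estimator contract
exactly checkable; on a 1-D quadratic of curvature a restrained at z the mean
force is k·a·z/(a+k) and the position variance kBT/(a+k). Two discretization
facts matter at the step sizes used here:

- stability requires (a_max + k)·Δt_inner/γ < 2, where a_max is the largest
  local curvature of the landscape; all built-in studies choose Δt_inner
  accordingly;
- Euler–Maruyama inflates the stationary variance of a mode of curvature κ by
  1/(1 − κΔt/2). Mean-force estimates depend only on means, which are unbiased
  for the linearized dynamics, so this bias is second order in the estimators;
  the sampler test asserts the variance against the discretization-corrected
  value.

Burn-in defaults to the first quarter of each per-cycle trajectory (the
discard-5-of-20 convention of per-image equilibration); accumulators use every
post-burn-in step unless a stride is set. At kBT = 0 no noise is drawn and the
engine reduces to gradient descent, so zero-temperature studies are
deterministic regardless of seed.

Reproducibility: the noise of image r in cycle c derives from
`SeedSequence((master_seed, c, r))`, so any single image trajectory can be
regenerated in isolation, and a batched run is bit-identical to R independent
runs.

## Mean force and uncertainty

The printed form of the gradient estimator in parts of the literature fuses
the restraint constant and the 1/T time-average into a "kT" prefactor; that
reading is dimensionally inconsistent (an energy per CV-unit cannot scale with
temperature times a bare time integral), so the implementation uses force
constant × time-averaged deviation, which is the stiff-spring estimator of the
underlying formulation. The literal reading remains available through
`estimate_gradient(..., convention="literal-kT")` for comparison only.

Standard errors come from 10 non-overlapping block averages of the deviation
time series. Profile uncertainties follow the trailing-cycle recipe: the
pointwise sample standard deviation of the profiles integrated from the last
10 optimization cycles, attached to their mean.

## Choice of restraint stiffness

k (default 100 energy/CV-unit²) must be chosen against the landscape:

- it must exceed the magnitude of the most negative curvature along the path,
  otherwise walkers anchored at barrier tops slide off and the measured force
  is no longer a local mean force;
- at zero temperature the measured force is the gradient of the Moreau
  envelope of V at scale 1/k, whose curvature approaches k where the landscape
  is much stiffer than the spring; the outer descent step must then satisfy
  k_eff·Δt ≲ 2. The finite per-cycle sampling window helps here: averaging the
  deviation while the walker relaxes low-passes the measured force, which
  damps the outer iteration beyond what the instantaneous envelope gradient
  would allow.

For the four-Gaussian benchmark (wall curvatures up to ≈4×10³, saddle
curvature ≈ −750) the built-in study uses k = 4000 with an inner step of
2×10⁻⁵; for the double well and proton-relay chain (curvatures ≤ ~10²),
k = 200 with an inner step of 10⁻³.

## Benchmark landscapes (synthetic-data module)

The generator emulates the *structure* of reaction free-energy landscapes —
multiple basins separated by saddles, sequential barriers and intermediates,
Boltzmann-distributed fluctuations — not any molecular system:

- `muller_brown()`: the standard four-Gaussian 2-D landscape with its
  published parameter set recorded in `parameters`; the community benchmark
  for path methods.
- `double_well(h, c)`: V = h(x²−1)² + cy²/2, exact barrier h, used for
  closed-form barrier recovery.
- `proton_relay_surface(n_cv, barrier_spec)`: a 1-D chain of quintic
  smoothstep segments through prescribed alternating stationary energies,
  embedded as the first coordinate of an n_cv-dimensional space with harmonic
  transverse confinement and quadratic end walls. Stationary nodes are spaced
  1.0 CV-unit apart: with paper-scale barriers (≈14 units) compressed into a
  unit interval the spine curvature would reach ~4×10³ and exceed any sane
  restraint stiffness, whereas unit spacing keeps it ≲10², commensurate with
  k ≈ 200. `gac_like_profile()` supplies a four-barrier/three-intermediate
  default (proton-relay-like topology), `sac_like_profile()` a
  two-barrier/one-intermediate, strongly exergonic default.
- `quadratic_well(a, dim)`: estimator closed forms.

What these surfaces do **not** model: rugged high-dimensional landscapes,
multiple competing reaction tubes, CV sets with strongly varying metric along
the path, inertial (underdamped) dynamics, or sampling error structure of real
molecular force fields. Passing the battery therefore demonstrates
correctness of the machinery, not transferability of any particular parameter
choice to molecular systems.

The path oracle `brute_force_mep` is independent of the string machinery:
minimax (edge-maximum energy) Dijkstra on a dense 8-connected grid brackets
the saddle corridor; windowed energy maxima along the grid path are
Newton-refined and accepted only with exactly one negative Hessian eigenvalue;
exact steepest-descent streamlines from each saddle are stitched through the
basins and resampled to uniform spacing. It is implemented for 2-D surfaces,
where dense grids are tractable; the proton-relay surfaces carry their own
exact spine profile as oracle.

## Protocol defaults

| parameter | default | origin |
|---|---|---|
| images R | 25 | reference protocol; Δα = 1/24 |
| cycles | 100 | reference protocol |
| descent step Δt | 0.001 | reference protocol |
| smoothing s | 0.01 | reference protocol |
| convergence RMSD | 0.01 CV units | reference protocol |
| per-image sampling | 20 000 steps, first 25% discarded | 20 ps at 1 fs with 5 ps equilibration |
| profile grid | 75 points, endpoints inclusive | reference protocol (read as inclusive; configurable) |
| restraint k | 100 energy/CV² | not stated by the protocol; see stiffness discussion |
| temperature | kBT(298 K) = 0.592 kcal/mol | reference protocol |

Endpoints default to *free*: they receive unprojected downhill updates and
relax into the adjacent basins, consistent with reporting reactant and product
states as free-energy minima; `endpoint_mode="fixed"` pins them.

Convergence is tracked two ways: prospectively (RMSD between consecutive
cycles, used for optional early stopping over a trailing window) and
retrospectively (RMSD of every cycle against the final path, the view used for
convergence maps). The built-in studies run the full cycle budget and report
the retrospective measure.

## Committor validation

Candidate transition states are checked by launching unbiased (restraint-free)
overdamped trajectories from configurations harvested out of a stiffly
restrained run anchored at the candidate's CV values (thinning ≥ 10 anchor
relaxation times). pB is the fraction reaching the product box before the
reactant box; shots hitting the step cap are excluded and reported as an
unresolved fraction. Basin boxes default to per-CV intervals of half-width
3·sqrt(kBT/k) around the endpoint CV values — the equilibrium width of the
anchored distribution — with `None` leaving a CV unconstrained. Because the
engine is diffusive there are no momenta to resample; shooting with
Maxwell-distributed velocities has no analogue here, and committor values are
those of the overdamped dynamics. In the validation study the ensemble anchor
is deliberately stiff (k = 2000) so the configurational spread contributes
negligible committor variance and the pooled 200-shot estimate carries plain
binomial statistics.

## Conformer analysis

Monitored coordinates are declared alongside the CV set and recorded during
restrained sampling without entering the dynamics. Dihedral populations are
clustered by k-means on unit-circle embeddings (wraparound-safe), 10 seeded
restarts, centers reported as circular means in degrees on (−180°, 180°];
`CircularKMeans` follows the sklearn estimator idiom. With `n_clusters="auto"`
k ∈ 1..5 is chosen by silhouette score on the embedding; splitting a unimodal
angular blob scores ≈0.55–0.6 while separated rotamer modes score ≳0.8, so a
best silhouette below 0.7 is read as a single population.

## Validation battery and problem sizes

`scripts/acceptance.py` (and the mirror tests in `tests/test_acceptance.py`)
recompute: the Eyring conversions at 300 K and the half-life conversions; the
protocol arithmetic; the zero-temperature string (25 images, Δt = 0.001,
s = 0.01, 100 cycles, k = 4000) against the 0.01-resolution oracle on the
four-Gaussian landscape; barrier recovery on the double well (25 images, 50
cycles, 4000 steps/image/cycle at 298 K, k = 200, error bar from the last 10
cycles); topology recovery on the six-CV proton-relay chain (40 cycles, 2000
steps/image/cycle); the 200-shot saddle committor; the estimator closed forms
(10⁵-step quadratic run; exact metric identities); and recovery of three
dihedral cluster centers from σ = 10° synthetic rotamer samples. These sizes
keep the whole battery in the minutes range on a single core while leaving
each statistical check several standard errors of headroom.

## Known limitations

- First-order (Euler–Maruyama) integration: step sizes trade bias for speed;
  no underdamped/velocity-Verlet engine is provided, though the sampler
  contract is written so one can be added.
- The zero-temperature string inherits the Moreau-envelope bias of order
  |∇V|/k along the path; with the stiffness guidance above this is well below
  the image spacing.
- `brute_force_mep` is 2-D only, and its minimax stage can wander within
  energy plateaus below the highest saddle; the streamline stitching removes
  this for landscapes with genuine saddles, and saddle-free paths are returned
  at grid resolution.
- Committor machinery assumes box-shaped basins in CV space.
- No Voronoi-tessellation free-energy definition, no climbing-image or
  finite-temperature-string variants, no weighted-histogram estimators, and no
  molecular force fields or structure-file topology parsing: CV sets are
  declared by explicit indices, optionally resolved against a small XYZ file.
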