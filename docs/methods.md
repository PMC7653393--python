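# Methods

## Models and coupling

`blendsim` couples three single-species reaction–diffusion
representations on a blended domain [a, b] with interfaces
a < I₁ < I₂ < b:

* **Macroscopic** — ∂c/∂t = ∂ₓ(D(x)∂ₓc) + R(c) with prescribed
  diffusive boundary fluxes J_a = D∂ₓc|_a and J_b = D∂ₓc|_b, so
  d(mass)/dt = J_b − J_a plus net reaction. The divergence form is a
  modelling choice: the spatial dependence of D exists only as a
  coupling device, so the operator is chosen so that a uniform profile
  is a steady state and the three descriptions agree in their common
  limit.
* **Mesoscopic (RDME)** — well-mixed compartments of width h (volume
  h·h_y·h_z in 3D); diffusion as nearest-neighbour jumps at
  per-particle rate D(face)/h² across each shared face; mass-action
  reaction propensities per compartment (order 0: κ₂V, order 1: μC,
  order 2: κ₁C(C−1)/(2V) removing two). Simulated with the Gillespie
  direct method.
* **Microscopic** — off-lattice positions updated by the
  drift-corrected Euler–Maruyama rule
  y ← y + Δt_b·dD/dx|_y + √(2D(y)Δt_b)·ξ; reflecting boundaries;
  bimolecular reactions by the λ–ρ rule (pairs closer than ρ react
  with per-step probability P_λ); first-order decay with the exact
  probability 1 − exp(−μΔt_b); zeroth-order production as Poisson
  placements.

The face-evaluated jump rate and the Euler–Maruyama drift term are the
two conventions that make all three models limits of the same
divergence-form equation; both are verified by uniform-equilibrium
tests that would fail for the common mis-specifications
(Fickian hopping, missing drift).

Each coupler splits D = D₁ + D₂ with the linear blend
β₁(x) = (I₂−x)/(I₂−I₁) on [I₁, I₂] (β₁ ≡ 1 left of I₁, 0 right of I₂),
assigns D₁ to the coarse engine on [a, I₂] and D₂ to the fine engine
on [I₁, b], and advances the two flow maps sequentially over each
synchronization window (coarse first). Because D₁(I₂) = D₂(I₁) = 0,
neither engine transports mass across its far interface, and the
splitting error is first order in the window length (verified
deterministically by composing two PDE operators).

Synchronization per window:

* PDE→compartment: blending counts := voxel integrals (Eq-level
  identity; counts become fractional). Compartment→PDE: the net
  integer count change δC of each blending compartment is spread
  uniformly over its γ = h/Δx voxels (δC/(γΔx) concentration each).
  Per-window accumulation and per-event mirroring are algebraically
  identical because the update is linear; the window form is the
  default, the per-event form is available through the SSA event hook.
* Compartment→Brownian: mirroring is *immediate* (inside the SSA event
  loop), so a later event in the same window selects particles from
  the post-move configuration; jumps displace a uniformly chosen
  resident by ±h, interface crossings delete a uniformly chosen
  resident or create one uniformly in [I₁, I₁+h). Brownian→compartment:
  blending counts := half-open histogram of positions, recomputed once
  per window rather than tracking each crossing.

Reactions in the blending region always follow the compartment
paradigm (the mean-field reaction term of the PDE is masked to the
pure-PDE voxels; Brownian scalar/pair channels act only beyond I₂).
A λ–ρ pair straddling I₂ reacts only if **both** partners are beyond
I₂; otherwise the pair is governed by the blending compartment's
mesoscopic channel. This prevents double counting at the interface
but is an interpretation — the handling of straddling pairs is
genuinely open — and is the one place the two reaction paradigms meet.

## Parameters

| symbol | meaning | unit | default (1D problems) |
|---|---|---|---|
| D | macroscopic diffusivity | length²/time | 1 |
| I₁, I₂ | interface positions | length | 1/3, 2/3 |
| h | compartment width | length | 1/30 (1/3 in 3D) |
| Δx | PDE voxel width | length | 1/300 |
| Δt_p, Δt_b | window/step lengths | time | 10⁻⁴ |
| N | initial particle number | – | 1000 (465 in 3D) |
| J | boundary influx parameter (influx = D·J) | 1/(length·time) | 10⁴ |
| μ | decay rate | 1/time | 10 |
| κ₁ | pair-annihilation rate | volume/(particle·time) | 0.1 |
| κ₂ | production rate | particle/(volume·time) | 89.7 |
| ρ, P_λ | interaction radius, per-step reaction probability | length, – | 0.06, 2.5×10⁻⁵ |
| M | ensemble size | – | 500/1000 |

The mesoscopic κ₁ and the microscopic (ρ, P_λ) parameterizations of
the order-2 channel are configured independently; no small-h
mesoscopic rate correction is applied. Compartment counts are always
derived from region lengths and h (the 3D compartment–Brownian chain
on [0, 20/3] at h = 1/3 has 20 compartments; the full-domain
ground-truth lattice has 30).

## Built-in problems (what they emulate and what they do not)

The four generators define the study conditions: (1) uniform diffusion
— the null test that the interfaces are invisible at steady state;
(2) redistribution of all mass from [a, I₁] — maximal interface flux;
(3) morphogen-gradient formation — first-order reactions plus a
boundary source, with initial mass DJ/μ equal to the steady-state mass
so the expected total stays at 1000 for all t; (4) 3D bimolecular
production–degradation from the linear profile c(x) = (183 − 18x)/2
(465 particles) — second-order reactions, where the mean-field PDE is
*not* the mean of the stochastic models and the discrepancy itself is
the quantity of interest.

Initialization is by expected value: each stochastic region receives
its largest-remainder share of N (positions sampled from the profile);
in blending regions the finer representation is sampled first and the
coarser matched to it. Real morphogen systems have geometry, multiple
species and non-mass-action kinetics; passing these tests shows the
couplers are unbiased for single-species mass-action systems on boxes,
nothing more.

## Numerical choices

* PDE: cell-centred finite volume, face diffusivity evaluated
  analytically at the face, θ = 1/2 (Crank–Nicolson) via banded
  Cholesky; unconditionally stable, discretely conservative
  (conservation tested to 10⁻¹⁰ relative). Reactions are integrated
  explicitly within the step. In 3D the grid is meshed along x only
  (one cell across the cross-section), exact for the y,z-invariant
  built-in data.
* SSA: real-valued counts are allowed in blending compartments
  (fractional mass synced from the PDE); waiting times use the
  real-valued propensities, events change counts by integers, and
  propensities floor at zero so transiently negative counts (possible
  when an event removes a particle from fractional mass) cannot run
  away — the next sync restores consistency. The propensity total and
  the event-selection scan accumulate in the identical floating-point
  order so selection cannot fall through.
* Half-open voxel/bin convention [left, right): a position exactly on
  an internal boundary belongs to the right cell.
* dD₂/dx at the kinks I₁, I₂ is taken one-sided from inside the
  blending region (particles governed by D₂ live in [I₁, b]); any
  convention on this measure-zero set is equivalent in the limit but
  must be fixed for reproducibility.
* Erroneous Brownian crossings of I₁ (a finite-time-step artefact,
  possible because D₂ is small but nonzero near I₁) are reflected and
  tallied; the tally is written to the run log.
* Pair search: cKDTree radius query in the Python engine, all-pairs
  scan in the compiled kernel; pairs are processed in randomized order
  and consumed particles leave the pool within a step.
* RNG: one stream per repeat (seed = base_seed + repeat index); the
  compiled kernels are seeded from that stream, so runs are bit
  reproducible from (config, seed).
* Consistency faults (a blending event addressed to a compartment with
  no resident twin) raise immediately; they cannot occur while the
  window invariant holds and are asserted in debug mode after every
  window.

## Problem sizes in the tests and the acceptance script

The test suite runs reduced ensembles chosen so each check is decided
by its Monte-Carlo error budget: M = 100 repeats with horizons 0.25–0.3
for the RME tests (|RME| < 0.05 with standard errors ≈ 0.5–2%),
M = 100 for the morphogen mean-recovery check (3-standard-error
criterion), and M = 1000 for the bimolecular mean-field-vs-RDME
comparison, where the larger ensemble keeps the Monte-Carlo inflation
of the max-over-compartments statistic small relative to the
systematic moment-closure bias it measures. Statistical assertions use
4–5σ bands on seeded streams.

## Limitations

* Single species; planar interfaces at fixed positions; the blending
  function ships only as the linear ramp (a tabulated β₁ is accepted
  but untested science: whether smoother blends reduce interface error
  is open).
* The mesoscopic (κ₁) and microscopic (ρ, P_λ) order-2
  parameterizations are configured independently and no
  mesoscopic–microscopic rate matching is applied. With the default 3D
  parameters read literally, the λ–ρ channel is far weaker than the
  mesoscopic channel (effective pair rate ≈ λ·(4/3)πρ³ ≈ 2×10⁻⁴
  versus κ₁ = 0.1), so a pure-Brownian ensemble of the bimolecular
  problem equilibrates at a much higher mass than the RDME, and the
  compartment-side regions of the compartment–Brownian hybrid cannot
  track a pure-Brownian reference for that problem (its pure-Brownian
  region does). Users who need consistent bimolecular dynamics across
  scales must supply a matched (ρ, P_λ).
* The PDE–Brownian direct coupling is not implemented; couple via the
  compartment scale.
* Fractional blending counts make low-copy-number blending regions
  fragile by construction — if that regime matters, the interface is
  in the wrong place.
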