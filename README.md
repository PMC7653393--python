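# blendsim

Hybrid multiscale simulation of stochastic reaction–diffusion processes
via a *blending region*.

## The problem

Reaction–diffusion systems in cell biology are genuinely multiscale:
where copy numbers are high a deterministic PDE for the concentration
c(x, t) is accurate and cheap, but where they are low the discreteness
and stochasticity of individual molecules matter and a finer model is
needed — either a mesoscopic compartment model (the reaction–diffusion
master equation, RDME, simulated with the spatial Gillespie algorithm)
or microscopic off-lattice Brownian dynamics. Running the fine model
everywhere is prohibitively expensive; running the coarse model
everywhere is wrong where it matters. `blendsim` couples a coarse and
a fine representation across space so each is used where it is valid.

## The method

The domain Ω = [a, b] is split by interfaces I₁ < I₂. The coarse model
owns [a, I₂], the fine model owns [I₁, b], and on the overlap [I₁, I₂]
(the blending region) **both** representations coexist as equivalent
descriptions of the same mass. The macroscopic diffusivity D is split
as D = D₁(x) + D₂(x) with complementary blending functions

    D₁(x) = D on [a, I₁),  D·(I₂−x)/(I₂−I₁) on [I₁, I₂],  0 on (I₂, b]
    D₂(x) = D − D₁(x)

so each model's contribution to diffusion ramps down linearly across
the overlap and vanishes at the far interface: the coarse model cannot
transport mass into the pure fine region and vice versa. One window of
length Δt advances the coarse flow map and then the fine flow map
(operator splitting, first-order in the window), after which the two
representations are re-synchronized in the blending region:

* **PDE–compartment coupler** — compartment counts are overwritten
  with the voxel integrals of the PDE solution (counts may be
  fractional); every subsequent SSA event in a blending compartment is
  mirrored back into its γ = h/Δx PDE voxels uniformly.
* **Compartment–Brownian coupler** — every blending SSA jump displaces
  a uniformly chosen resident Brownian particle by ±h (creating or
  deleting a particle at interface crossings); after the
  Euler–Maruyama update the blending counts are reset to the half-open
  position histogram.

Reactions in the blending region always follow the compartment
paradigm. The engines are: a conservative cell-centred finite-volume
Crank–Nicolson solver with flux boundary conditions; a Gillespie
direct-method RDME engine with face-evaluated jump rates
D(face)/h² (whose diffusive limit is the divergence-form equation
∂c/∂t = ∂ₓ(D(x)∂ₓc)); and drift-corrected Euler–Maruyama Brownian
dynamics y ← y + Δt D′(y) + √(2D(y)Δt)·ξ with λ–ρ bimolecular
reactions. Four built-in problems validate the couplers: uniform
diffusion, particle redistribution, morphogen-gradient formation
(influx DJ at x=0, decay μ), and a 3D bimolecular
production–degradation system (2A → ∅ at κ₁, ∅ → A at κ₂). Accuracy is
quantified by the region-wise relative mass error
RME = (hybrid − reference)/reference against the analytic mean-field
solution or, for the bimolecular system, the ensemble mean of the
finest-scale model.

## Worked example

Morphogen-gradient formation with the compartment–Brownian coupler
(J = 10⁴, μ = 10, D = 1, h = 1/30, Δt = 10⁻⁴), 20 repeats:

```python
import blendsim as bs

cfg = bs.default_config("morphogen", "compartment-brownian",
                        repeats=20, seed=1, output_times=[0.01, 0.1, 1.0])
res = bs.run_experiment(cfg)
print(res.rme_frame().to_string(index=False))
print("mean region masses at t=1:", res.region_masses[-1].round(2))
```

prints

```
 time      region       rme  mc_stderr
 0.01 compartment  0.010286   0.004728
 0.10 compartment  0.003439   0.010075
 1.00 compartment -0.010467   0.005476
 0.01    blending -0.002865   0.011403
 0.10    blending  0.017963   0.013076
 1.00    blending  0.025366   0.013484
 0.01    brownian -0.003025   0.010909
 0.10    brownian -0.012086   0.018608
 1.00    brownian  0.014990   0.021348
mean region masses at t=1: [649.15 243.1  108.5 ]
```

Every region tracks the analytic solution to within a few percent (the
Monte-Carlo standard errors at M = 20 are of the same size, i.e. no
detectable bias), and the region masses reproduce the exponential-like
morphogen profile: most mass near the source at x = 0, least in the
purely Brownian third. The same study is available from the shell:

```bash
blendsim run --problem morphogen --coupling compartment-brownian \
             --repeats 20 --seed 1 --out out/
blendsim reference --problem morphogen --times 0.01,1.0
```

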