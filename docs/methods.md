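# Methods

This note records the mathematical model implemented by `actidiff`, the
numerical choices, the calibration of the presets, and the known
limitations. Everything here can be re-derived from the source; the point
is to make the choices explicit.

## Model

A spherical particle of radius `R` carries a thin interfacial layer of
thickness ε. A catalytic cap `|ϕ| ≤ ϕ0` (azimuthal angle ϕ measured from
the cap pole, domain `[−π, π]` periodic) converts substrate M to product N
at rate `k_r C_M`. Steady dimensionless fields on the interface obey

```
Ĉ_M'' − α² Θ_cap Ĉ_M − β² (Ĉ_M − 1)      = 0
Ĉ_N'' + α² Θ_cap Ĉ_M − β² Ĉ_N            = 0
T̂''   + λ² Θ_cap Ĉ_M − ω² (T̂ − T̂_b)     = 0
ψ̂''   + ξ² (z_M Ĉ_M + z_N Ĉ_N)           = 0
```

with `Ĉ = C/C0`, `T̂ = T/T0`, `ψ̂ = q0ψ/k_BT0`, primes `d/dϕ`, and groups

```
α² = k_r R²/D_s         β² = U R²/D_s          ω² = U_q R/κ
λ² = R²|ΔH_r| k_r C0/(κ T0)
ξ² = s · R² C0 N_A q0² / (k_B T0 ε0 ε_r)
```

`s` is a per-preset electrostatic coupling scale (`xi2_prefactor`)
calibrated so that the swept ξ² covers each system's reported operating
range (see Calibration). Adding the two concentration equations shows
`Ĉ_N = 1 − Ĉ_M` exactly; the solver exploits and the tests verify this.

### Surface excess energy

Two meridian brackets evaluate all energies ("half-meridian" reading, the
profiles being even in ϕ):

```
I[X] = (X(π) − X(0)) / π          J[g] = (1/π) ∫₀^π g dϕ
```

Nondissipative pentad (signed, in J):

```
e_reaction  = −A ε C0 (ΔH_r + Δμ_r0) I[Ĉ_N]
e_entropic  = +A ε C0 R_g T0 J[ T̂ (ln x_M · Ĉ_M' + ln x_N · Ĉ_N') ]     x_i = w0 Ĉ_i
e_electro   = +A ε C0 N_A k_B T0 J[ ψ̂ (z_M Ĉ_M' + z_N Ĉ_N') ]
e_diffusio  = −A C0 (γ_CM I[Ĉ_M] + γ_CN I[Ĉ_N])
e_thermo    = −A γ_T T0 I[T̂]
```

Dissipative pentad: τ × (mixing entropy flow + entropy production by mass
diffusion, heat conduction, reaction affinity, and a viscous Marangoni
closure). Each viscous bracket entry is a squared interfacial-tension
variation `(∂γ/∂X · ΔX)²`; for the electrostatic entry the tension scale
is the osmotic pressure integrated across the layer, `ε C0 R_g T0 ξ²`.
τ defaults to `1/k_r` or `1/(k_r β²)` per preset (`tau_mode`).

The diffusivity of the chosen route is `D = D0 (1 + |E_s|/k_B T_b)` and the
activity variable is the **cap-restricted mean reaction rate**

```
ṙ = k_r C0 ⟨Ĉ_M Θ_cap⟩ = k_r C0 (β²/α²)(1 − ⟨Ĉ_M⟩),
```

the second equality being the exact steady-state balance between cap
consumption and surface adsorption; at ϕ0 = π it reduces to
`k_r C0 β²/(α²+β²)`.

## Numerics

- **Discretization.** Uniform periodic grid on `[−π, π)` (even `n`, node at
  ϕ = 0), second-order central differences, sparse direct solves. The cap
  indicator uses cell-averaged weights (edge cells get their covered
  fraction; the wrap cell at ±π counts its two half-sides), which keeps the
  discrete reaction–adsorption balance exact and the scheme second order.
- **Temperature in deviation form.** θ = T̂ − T̂_b is split into its exact
  mean `λ²⟨Θ_cap Ĉ_M⟩/ω²` and a zero-mean remainder solved with a
  mean-constrained (bordered Lagrange) Helmholtz system. Storing the two
  parts separately preserves the fluctuation to full precision even when
  `θ ~ 1e-19` — adding it to T̂_b = 1 first would erase it entirely. All
  brackets and gradients use the fluctuating part, to which constants are
  blind.
- **Potential gauge.** The periodic Poisson problem fixes ψ̂ to zero mean;
  the source is compatible up to a recorded offset.
- **Analytic cross-check.** The substrate has an exact piecewise-cosh
  solution; temperature and potential follow as cosine series with
  closed-form coefficients (`θ_k = λ² S_k/(k²+ω²)`, `ψ_k = ξ² Δz c_k/k²`,
  truncation k ≤ 1024). The `energy` CLI always logs the term-by-term
  discrepancy between this analytic route and the quadrature route; both
  presets agree to ≲ 1e-4 relative at small α², β² and at native groups.
  The quadrature route is the source of truth.
- **Langevin.** Exact joint (x, v) Ornstein–Uhlenbeck update per step (no
  Euler discretization error), a scalar phoretic noise of strength
  `√(6 ξ_t B)` along the particle axis, rotational diffusion by
  Ornstein–Uhlenbeck angular velocity plus Rodrigues rotation. Diffusivity
  estimation uses non-overlapping displacement windows with the exact OU
  finite-window correction `⟨|Δx|²⟩ = 6D(t_w − τ(1 − e^{−t_w/τ}))`, which
  beats MSD slope fitting at equal sample count.
- **Fitting.** Multi-start bounded least squares (scipy), 1/σ² weighting,
  invariant to data ordering. Synthetic curves (model × multiplicative
  Gaussian noise) are the test bed standing in for experimental data.

## Calibration of the presets

Physical constants are tabled experimental values for the two systems.
The only fitted scale is `xi2_prefactor`, set a priori so that the ξ²
interval swept over each system's activity window (ṙ = 1–100 nM/s)
matches that system's reported electrostatic operating range:
`5.9e3` for the nano Janus case (reproducing both ends of its range) and
`1.64e2` for the vesicle case (geometric-mean match; the reported end
points for that system are mutually inconsistent by ~2×). The preset
default `C0 = 0.5 mol/m³` (0.5 mM) is the tabled bulk concentration;
note it lies far above the activity windows, so sweeps always override it.

## Limitations

- **No interior minimum of the vesicle activity curve.** Within the
  calibrated ξ² window the electrophoretic term is bounded by
  `e_electro/(A ε C0 R_g T0) ≈ 7.5e-4 · ξ²`, while the (negative)
  reaction + entropic contribution is ≈ −2.4 in the same units. The signed
  total would change sign only near ξ² ≈ 3e3 — three orders of magnitude
  beyond the window top (ξ² ≈ 3). Consequently `E_nd` keeps its sign,
  `|E_nd|` grows monotonically with C0, and `D(ṙ)` is monotone increasing:
  the advertised maximum-then-minimum shape and the minimum near 8.1 nM/s
  are not reproduced by the model as specified. No magnitude of a
  deviation-product surface average can close this gap (it is bounded by
  the product of the ψ̂ and Ĉ deviation amplitudes), so we have left the
  principled gauge-invariant quadrature in place rather than rescale terms
  toward the desired shape. The corresponding acceptance tests fail by
  design.
- **No quadratic convexity of the nano Janus curve.** For that preset the
  electro/reaction magnitude ratio is ~1e-16 at the window top; the only
  term quadratic in C0 is numerically invisible and `D(ṙ)` is linear to
  machine precision.
- The Marangoni viscous dissipation is an order-of-magnitude closure (no
  surface flow field is solved).
- Entropic brackets drop nodes where a concentration vanishes (measure-zero
  on the grid; guarded by `x ln x → 0`).
- The azimuthal (1-D) reduction ignores polar curvature factors; brackets
  treat ϕ as arc length on the equatorial meridian.
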