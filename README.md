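# actidiff

Interfacial thermodynamics of active diffusion.

Chemically active colloids — catalytic Janus nanoparticles, enzyme-coated
vesicles — diffuse faster than their passive twins. `actidiff` models this
enhancement from a single thermodynamic quantity: the **surface excess
energy** stored by the reaction-induced deviations of concentration,
temperature, and electrostatic potential from uniformity across the
particle's interfacial layer. That energy, `E_s`, feeds the random phoretic
force acting on the particle, and the long-time diffusivity follows as

```
D = D0 · (1 + |E_s| / k_B T)
```

## What the package computes

1. **Surface fields.** Steady azimuthal reaction–diffusion, heat, and
   electrostatic boundary-value problems on the spherical interface, driven
   by a catalytic cap `|ϕ| ≤ ϕ0`. Five dimensionless groups control the
   solution: α² (reaction/diffusion), β² (adsorption/diffusion),
   λ² (heat generation/conduction), ω² (cooling/conduction), and
   ξ² (electrostatic coupling). λ² and ξ² are proportional to the bulk
   substrate concentration `C0`, which is how experiments sweep activity.
2. **Excess energy.** Two routes:
   - *nondissipative* — a pentad of terms (reaction, entropic, electrophoretic,
     diffusiophoretic, thermophoretic) evaluated by quadrature of the solved
     profiles; an exact analytic route (piecewise-cosh substrate solution plus
     Fourier series for temperature and potential) cross-checks every term.
   - *dissipative* — mixing entropy plus the interfacial entropy production
     (diffusion, heat conduction, reaction affinity, viscous stresses),
     multiplied by the process time scale τ.
3. **Activity curves.** Sweeps of `C0` reported against the mean reaction
   rate `ṙ = k_r C0 ⟨Ĉ_M Θ_cap⟩` (in nM/s), with automatic location of
   interior extrema of `D(ṙ)` and sign changes of the signed energy total.
4. **Langevin verification.** An inertial Langevin simulator with an extra
   phoretic noise channel of energy scale `B` verifies the two fluctuation
   relations behind the diffusivity formula: per-axis kinetic energy
   `(k_B T + B)/2` and long-time diffusivity `D = (k_B T + B)/ξ_t`.
5. **Fitting.** Bounded least-squares recovery of the interfacial thickness
   ε (and optionally surface-tension derivatives) from noisy `D(ṙ)` curves.

Two bundled presets describe the studied systems: `case1_janus_nano`
(nanometric catalytic Janus particle, charged substrate) and
`case2_vesicle` (micron-scale phospholipid vesicle with membrane enzymes
hydrolyzing ATP).

## Worked example

Evaluate the vesicle system at 100 nM ATP (inside its activity window):

```python
from actidiff import load_preset, evaluate_point
from actidiff.constants import K_B

p = load_preset("case2_vesicle")
pt = evaluate_point(p, C0=1e-7)          # 100 nM ATP
kT = K_B * p.T0
print(f"mean reaction rate : {pt['rdot']:.3f} nM/s")
print(f"E_nd (signed total): {pt['E_nd'] / kT:.4f} kT")
print(f"D0 -> D            : {p.D0 * 1e12:.4f} -> {pt['D_nd'] * 1e12:.4f} um^2/s")
```

prints

```
mean reaction rate : 0.864 nM/s
E_nd (signed total): -0.1191 kT
D0 -> D            : 0.0650 -> 0.0727 um^2/s
```

The same sweep from the command line:

```bash
actidiff sweep --preset case2_vesicle --rdot-min 1 --rdot-max 100 --n 5 --out sweep.csv
```

```
 rdot_nMps    E_nd_kT  D_nd_um2ps
  1.000000  -0.137944    0.073966
  3.162278  -0.436079    0.093345
 10.000000  -1.377631    0.154546
 31.622777  -4.342742    0.347278
100.000000 -13.595850    0.948730
```

Every run writes a `*.manifest.yaml` next to its outputs with the resolved
parameters, the derived dimensionless groups, the seeds used, and SHA-256
hashes of the output files; deterministic runs reproduce bit-for-bit from
the manifest. All CLI randomness derives from one root `--seed`, split per
stage as SHA-256(`"<root>:<stage>"`).

Other subcommands: `actidiff fields` (surface profiles), `actidiff energy`
(energy breakdown plus the analytic-vs-quadrature discrepancy report),
`actidiff simulate` (Langevin verification), `actidiff fit` (synthetic
parameter recovery). See `actidiff <cmd> --help`.

## Layout

- `src/actidiff/` — library modules (`params`, `surface_fields`,
  `excess_energy`, `diffusivity`, `langevin`, `fitting`, `cli`).
- `src/actidiff/presets/` — the two bundled parameter sets (YAML).
- `tests/` — unit, property (hypothesis), and acceptance tests.
- `scripts/acceptance.py` — standalone recomputation of the headline target.
- `docs/methods.md` — mathematical and numerical methods note.
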