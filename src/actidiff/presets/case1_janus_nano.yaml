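# Nanometric catalytic Janus particles with a charged salt substrate.
# SI units throughout; gamma_CM/gamma_CN in J m/mol (1 mJ/(m^2 M) = 1e-6),
# gamma_T in J/(m^2 K).  xi2_prefactor is the fitted electrostatic-coupling
# scale placing the swept xi^2 in this system's reported operating range.
params:
  C0: 0.5            # 0.5 mM = 0.5 mol/m^3
  T0: 298.15
  k_r: 21.4
  D_s: 650.0e-12     # 650 um^2/s
  eta_s: 0.891e-3
  U: 10.0
  dH_r: -91.0e+3
  dmu_r0: 30.0e+3
  kappa: 0.6
  U_q: 0.01
  eps_thick: 5.0e-9  # main fitting parameter, 5 nm
  z_M: -3
  z_N: -4
  gamma_CM: 1.5e-6   # 1.5 mJ/(m^2 M)
  gamma_CN: 0.2e-6
  gamma_T: -0.2e-3
  D0: 7.75e-12       # 7.75 um^2/s
  R: 9.0e-9
  w0: 0.5
  phi0: 1.5707963267948966
  eps_r: 78.5
  xi2_prefactor: 5.9e+3
  tau_mode: kr_beta2
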