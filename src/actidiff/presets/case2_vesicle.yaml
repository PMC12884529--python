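# Phospholipid vesicles with membrane-embedded enzymes hydrolyzing ATP.
# SI units; see case1_janus_nano.yaml for unit conventions.
params:
  C0: 0.5            # 0.5 mM = 0.5 mol/m^3
  T0: 294.15
  k_r: 250.0
  D_s: 360.0e-12
  eta_s: 1.0e-3
  U: 10.0
  dH_r: -30.0e+3
  dmu_r0: -60.0e+3
  kappa: 0.59
  U_q: 0.01
  eps_thick: 15.0e-9 # main fitting parameter, 15 nm
  z_M: 0
  z_N: -1
  gamma_CM: -0.01e-6
  gamma_CN: 0.02e-6
  gamma_T: -0.01e-3
  D0: 0.065e-12
  R: 2.1e-6
  w0: 0.5
  phi0: 1.5707963267948966
  eps_r: 78.5
  xi2_prefactor: 1.64e+2
  tau_mode: kr
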