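# Het-1A (non-tumorous esophageal epithelium) set: the KYSE-150
# calibration with k_f divided by 5 and alpha1 divided by 3,
# reflecting weaker ER release and SOCE in non-tumorous cells.
model:
  delta: 1.5
  K_tau: 0.1
  K_c: 0.2
  k_f: 0.78
  V_serca: 0.9
  gamma: 5.5
  V_pm: 0.11
  alpha0: 0.0027
  K_p: 0.2
  tau_max: 1420.0
  beta_p: 0.027
  K_h: 0.08
  K_bar: 1.9e-05
  K_e: 8.0
  K_pm: 0.3
  alpha1: 0.1283333333
  p_s: 0.1004
  k_beta: 0.4
  k_serca_half: 0.2
drug:
  c1: 0.51
  c2: 1.0
  c3: 0.76
  k1: 0.34
  k2: 0.6
  k3: 0.8
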