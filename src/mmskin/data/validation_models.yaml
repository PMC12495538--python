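# Gel-phantom validation models: a tissue-simulating gel half-space
# (Cole-Cole) optionally covered with thin PTFE films.  tau in ps,
# thicknesses in micrometers, 'inf' marks the terminal half-space.
materials:
  - {name: gel, d_um: inf, eps_inf: 4.62, eps_s: 42.5, sigma_S_per_m: 1.02, tau_ps: 11.8, alpha: 0.075}
  - {name: ptfe, eps_inf: 2.1, eps_s: 2.1, sigma_S_per_m: 0, tau_ps: 0, alpha: 0}
  # rigid low-permittivity foam spacer (eps_r 1.09, tan d 2.68e-3 near 30 GHz);
  # included in probe calibration, so NOT part of any default stack
  - {name: foam, eps_inf: 1.09, eps_s: 1.09, sigma_S_per_m: 4.876e-3, tau_ps: 0, alpha: 0}

stacks:
  - name: gel_bare
    layers:
      - {material: gel}
  - name: gel_ptfe50
    layers:
      - {material: ptfe, d_um: 50}
      - {material: gel}
  - name: gel_ptfe100
    layers:
      - {material: ptfe, d_um: 100}
      - {material: gel}
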