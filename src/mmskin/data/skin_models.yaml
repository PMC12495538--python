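# Two-layer skin models: a stratum-corneum (SC) surface layer over an
# effective inner-skin half-space ("Layer D"), all Debye (alpha = 0).
# layer_d_mean fits the cohort mean reflection; layer_d_p68 / layer_d_p95
# fit mean minus one / two standard deviations (conventional 68% / 95%
# population-coverage labels).  sc_thick1..3 are the thick-SC models at the
# mean / 68% / 95% points of the thick-site distribution; their thicknesses
# came out of the fit.  tau in ps, d in micrometers.
materials:
  - {name: layer_d_mean, d_um: inf, eps_inf: 7.88, eps_s: 47.0, sigma_S_per_m: 5.19, tau_ps: 8.35}
  - {name: layer_d_p68,  d_um: inf, eps_inf: 5.06, eps_s: 37.0, sigma_S_per_m: 7.62, tau_ps: 8.19}
  - {name: layer_d_p95,  d_um: inf, eps_inf: 2.98, eps_s: 32.8, sigma_S_per_m: 6.94, tau_ps: 8.76}
  - {name: sc_thin,   d_um: 20,  eps_inf: 2.96, eps_s: 4.46, sigma_S_per_m: 0, tau_ps: 6.9}
  - {name: sc_thick1, d_um: 227, eps_inf: 4.01, eps_s: 9.11, sigma_S_per_m: 0, tau_ps: 1.63}
  - {name: sc_thick2, d_um: 262, eps_inf: 3.27, eps_s: 8.22, sigma_S_per_m: 0, tau_ps: 2.04}
  - {name: sc_thick3, d_um: 295, eps_inf: 2.49, eps_s: 7.29, sigma_S_per_m: 0, tau_ps: 2.22}

stacks:
  - name: skin_thin_mean
    layers:
      - {material: sc_thin}
      - {material: layer_d_mean}
  - name: skin_thin_p68
    layers:
      - {material: sc_thin}
      - {material: layer_d_p68}
  - name: skin_thin_p95
    layers:
      - {material: sc_thin}
      - {material: layer_d_p95}
  - name: skin_thick1
    layers:
      - {material: sc_thick1}
      - {material: layer_d_mean}
  - name: skin_thick2
    layers:
      - {material: sc_thick2}
      - {material: layer_d_mean}
  - name: skin_thick3
    layers:
      - {material: sc_thick3}
      - {material: layer_d_mean}
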