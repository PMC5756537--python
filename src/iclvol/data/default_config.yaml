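# Default end-to-end run configuration.
# Every stochastic stage carries an explicit seed; group parameter sets are the
# published cohort-level estimates (see iclvol.reference).

seeds:
  ephys: 101
  swell: 202
  caspase: 303

recipes:
  pipette: pipette
  bath: bath_iso

temperature_K: 310.15

analysis:
  window_ms: [180.0, 200.0]      # steady-state window within the 200 ms step
  exclusion_half_width_mV: 10.0  # near-reversal exclusion for the conductance transform
  ci_method: bootstrap
  n_boot: 1000
  junction_potential_mV: 0.0     # subtracted from command voltages when nonzero
  alpha: 0.05

ephys:
  erev_mV: -19.0
  capacitance_pF: 10.0
  noise_sd_pA: 5.0
  groups:
    control:
      iso:  {gmax_pS_per_pF: 364.0,  vh_mV: 40.0, k_mV: 62.0}
      hypo: {gmax_pS_per_pF: 1350.0, vh_mV: -2.0, k_mV: 31.0}
    aclt4w:
      iso:  {gmax_pS_per_pF: 762.0,  vh_mV: 23.0, k_mV: 42.0}
      hypo: {gmax_pS_per_pF: 2290.0, vh_mV: 10.0, k_mV: 25.0}

swell:
  t_eval_s: 300.0
  rise_tau_s: 90.0
  groups:
    control: {initial_area_um2: 875.0, plateau_relative_area: 1.06, n_cells: 15}
    aclt2w:  {initial_area_um2: 726.0, plateau_relative_area: 1.08, n_cells: 21}
    aclt4w:  {initial_area_um2: 935.0, plateau_relative_area: 1.11, n_cells: 11}

caspase:
  n_per_group: 20
  cv: 0.06
  folds:
    control: 1.0
    aclt2w: 1.24
    aclt4w: 1.52
    tnfa: 2.15
    dcpib: 1.0
    tnfa_dcpib: 1.05
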