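# voltmatrix pipeline configuration template.
#
# Load with:  voltmatrix run-all --config examples/pipeline.yaml --out out/
# Field names mirror SimulationConfig / DetectionParams exactly.

simulation:
  # Either start from a named scenario and override fields...
  scenario: two_marker          # two_marker | aptamer_shift | baseline_overfit_demo
                                # | equimolar_mixture | serum_shift
  duration_s: 20.0              # seconds per run
  runs_per_condition: 3
  sampling_rate: 100000.0       # Hz
  voltage_grid: [-50, -100, -150, -200, -250, -300]   # mV, negative, distinct
  pore_conductance: 10.0        # nS -> open-pore current = G * V (pA)
  noise_rms: 12.0               # pA, white Gaussian
  noise_rms_jitter: 0.05        # fractional run-to-run spread (log-normal)
  drift_rate: 0.5               # pA/s
  drift_rate_jitter: 0.2        # fractional run-to-run spread
  run_offset_sigma: 25.0        # pA, per-run baseline offset
  seed: 0
  # ...or drop `scenario` and specify molecules/samples explicitly:
  # molecules:
  #   - name: cea_like
  #     capture_prefactor_alpha: 0.046    # events/s/mV
  #     capture_barrier_vstar: 61.6       # mV
  #     blockage_frac_mean: 0.18
  #     blockage_frac_sd: 0.02
  #     dwell_median_ref_ms: 0.5          # at |V| = 100 mV
  #     dwell_log_sd: 0.4
  #     dwell_voltage_exponent_gamma: 1.0
  #     blockage_voltage_slope: 0.0       # per 250 mV beyond 100 mV
  #     edge_tau_us: 20.0
  # samples:                             # molar fractions over `molecules`
  #   cea_like: [1.0, 0.0]
  #   mixture:  [0.5, 0.5]

detection:
  baseline_window_ms: 50.0
  threshold_k: 5.0              # event entry, multiples of baseline RMS
  exit_k: 2.0                   # event exit
  min_dwell_samples: 5
  refractory_samples: 5

feature_set: A                  # A = event-intrinsic, B = + baseline-dependent
algo: random_forest             # random_forest | svm
seed: 0
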