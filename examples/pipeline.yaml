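# Full-pipeline demo: three synthetic regimes, reduced trace count for a
# quick desk-scale run.  Conditions may instead list `files:` of recorded
# traces (CSV with `# sampling_rate_hz:` metadata, or .f32 + JSON sidecar).
seed: 1
control: {que_um: 0, ca_um: 0}
conditions:
  - {regime: control, que_um: 0, ca_um: 0, n_traces: 2, duration: 20.0}
  - {regime: que_low, que_um: 10, ca_um: 0, n_traces: 2, duration: 20.0}
  - {regime: ca_high, que_um: 0, ca_um: 100, n_traces: 2, duration: 20.0}
params:
  segment_length: 16384     # periodogram segment (samples)
  spectral_window_s: 0.0128 # short-time Hamming window width
  k_bins: 1000              # peak-entropy histogram bins
  emd_window: 100000        # samples per EMD window
  sampen_window: 4000       # dwells per SampEn window
  sampen_m: 2
  sampen_r_factor: 0.2
  k_clusters: 6
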