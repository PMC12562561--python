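# singlechan

Entropy, spectral and EMD analysis of single-channel patch-clamp
recordings, with a semi-Markov gating simulator for synthetic ground truth.

## The problem

A single-channel patch-clamp recording is a noisy two-level current time
series produced by one ion channel stochastically switching between
conducting (open) and non-conducting (closed) conformations.  Summary
numbers like the open-state probability

```
p_open = (# samples assigned open) / (# samples)
```

are easy to compute but cumulative: very different switching dynamics can
share one p_open.  This package implements a set of complementary measures
that resolve *how* a channel gates, designed for studies of channel
activators (the motivating system is the large-conductance Ca²⁺- and
voltage-activated potassium (BK) channel under calcium and quercetin
stimulation):

* **Idealization** — half-amplitude thresholding at
  `(I_closed + I_open)/2`, giving the binary state sequence, p_open, and
  the dwell-time series (durations of successive open/closed episodes).
* **Shannon entropy** of the normalized dwell-time histogram,
  `H = −Σ p_k log₂ p_k` (bits): how many timescales participate in gating.
* **Sample entropy** of the dwell-time series (m = 2, r = 0.2 σ, Chebyshev
  distance, windows of 4000 dwells):
  `SampEn = −ln(C^{m+1}/C^m)`, the negative log conditional probability
  that dwell patterns matching for m steps still match at step m+1 — a
  regularity measure of the *succession* of dwells.
* **Power spectra** — averaged periodograms per recording, per-condition
  medians, and the relative spectrum `P̂(f) = P(f)/P_control(f)` showing by
  what factor each band responds to stimulation.
* **Spectral peak entropy** — short-time spectra over a sliding Hamming
  window (a₀ = 25/46, width 12.8 ms), then per frequency bin the Shannon
  entropy of the window-to-window power distribution, histogrammed over
  (0, 10 σ_P] in 1000 bins with σ_P pooled over all conditions.
* **EMD features** — each 100,000-sample window is min–max normalized and
  decomposed into intrinsic mode functions, `X(t) = Σ C_i(t) + r_n(t)`;
  every IMF contributes one (frequency, energy) point with energy
  `(I/I_max)² = mean(C_i²)`.  The per-condition feature population is
  binned on a shared log–log grid and split into six clusters by weighted
  K-means; each cluster is summarised by centroid, occupancy and Shannon
  entropy.
* **Gating simulator** — a semi-Markov scheme (2 open states O₁,O₂ and
  3 closed states C₁,C₂,C₃ by default) with exponential or Pareto
  (power-law) dwell distributions, two-level rendering, Gaussian noise and
  a 4-pole Bessel low-pass (1 kHz at 10 kHz sampling, the standard
  acquisition chain).  The stationary open probability
  `Σ_open π_i E[dwell_i] / Σ_all π_j E[dwell_j]` is available analytically,
  so every estimator can be checked against exact ground truth.

## Worked example

```python
import singlechan as sc

model = sc.make_regime("control")            # 2 open + 3 closed states
print(round(sc.stationary_open_probability(model), 4))
# 0.234

events = sc.simulate_event_sequence(model, duration=20.0, seed=1)
trace = sc.render_current_trace(events, model, seed=1)
ideal, dwells, p_open = sc.idealize_trace(trace, 0.0, 10.0)
print(len(trace), round(p_open, 4), len(dwells))
# 200000 0.2477 2553

h = sc.dwell_histogram(dwells)
print(round(h.entropy_bits(), 3))
# 4.34
```

The analytic open probability of the control regime is 0.234; the
half-amplitude estimate on a 20 s rendered trace (200,000 samples at
10 kHz) is 0.2477, and the pooled dwell-time histogram of its 2553 dwells
carries 4.34 bits of Shannon entropy.

The same flows from the shell:

```bash
singlechan simulate --regime ca_high --duration 20 --seed 1 --out trace.csv
singlechan idealize trace.csv --closed-level 0 --open-level 10 --out dwells.csv
singlechan run --config examples/pipeline.yaml --out results/
```

## Layout

```
src/singlechan/
  gating.py      semi-Markov simulator, regimes, analytic p_open
  idealize.py    level estimation, half-amplitude idealization, dwells
  entropy.py     dwell histograms, Shannon entropy, SampEn
  spectral.py    periodograms, median/relative PSD, peak entropy
  emd.py         sifting, IMFs, (frequency, energy) features
  clustering.py  2-D feature histograms, weighted K-means, summaries
  pipeline.py    per-condition orchestration, CSV/JSON outputs
  io.py          trace/event/dwell file formats
  cli.py         `singlechan` command-line interface
docs/methods.md  model assumptions, parameter choices, limitations
```
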