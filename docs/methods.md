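# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `singlechan`, including every place where the design was
genuinely open and a choice had to be made.

## 1. Gating model and synthetic recordings

A channel is modelled as a semi-Markov process over a small set of
conformational states, each labelled open (conducting) or closed.  The dwell
in a state is drawn from a state-specific distribution; on leaving, the next
state is drawn from a transition row supported only on the *opposite*
conducting class — a two-level idealization cannot resolve within-class
transitions, so the model only contains what the data can identify.

Two dwell families are supported:

* **Exponential(τ)** — a state with a characteristic lifetime; mixtures of
  exponentials across same-class states produce the multi-exponential dwell
  histograms typical of channel recordings.
* **Pareto(α, t_min, t_max)** — density f(t) ∝ t^(−α) above t_min, i.e.
  survival S(t) = (t_min/t)^(α−1), a straight line of slope −(α−1) in
  log–log.  Scale-free closed-dwell statistics of this kind are reported
  for strongly Ca²⁺-activated BK channels.  For α ≤ 2 the uncapped mean
  diverges, so a truncation cap `t_max` is provided (and used by the
  shipped regimes) to keep simulated event counts finite.

The analytic stationary open probability is
`p_open = Σ_open π_i E[dwell_i] / Σ_all π_j E[dwell_j]`, with π the
stationary distribution of the embedded jump chain; it is the ground truth
against which the half-amplitude estimator is tested.

**Rendering.** Events are quantized to the sample grid by midpoint
occupancy: sample *i* carries the conductance level of whichever state
occupies time (i + ½)·Δt.  Gaussian noise (per-sample, SD `noise_sigma`)
is added *before* the low-pass filter so the filter shapes signal and
noise together, as in hardware.  The filter is a 4-pole Bessel-type
low-pass applied forward only (matching common patch-clamp amplifiers);
defaults are 1 kHz cutoff and 10 kHz sampling.  One master seed is split
into named (events, noise) streams, so the noise can be redrawn with the
gating path fixed.

**Packaged regimes.**  Rates are not identifiable from published summary
statistics, so the three named regimes are package choices tuned *a priori*
to the qualitative structure they must emulate:

| regime    | open dwells            | closed dwells                          | analytic p_open |
|-----------|------------------------|----------------------------------------|-----------------|
| `control` | Exp(1.5 ms), Exp(6 ms) | Exp(0.8 ms), Exp(8 ms), Exp(40 ms)     | 0.234           |
| `que_low` | Exp(1 ms), Exp(8 ms)   | Exp(1.5 ms), Exp(12 ms), Exp(30 ms)    | 0.283           |
| `ca_high` | Exp(25 ms), Exp(50 ms) | Pareto(α=4.5, t_min 0.10–0.20 ms, caps 5–10 ms) | 0.995 |

`control` reproduces a partially active channel (p_open ≈ 0.23) with
several overlapping dwell timescales.  `que_low` keeps p_open near control
but broadens the intermediate dwells.  `ca_high` stabilises long openings
and makes closings a sharp short-duration peak with power-law scaling.
The steep closed-dwell exponent deserves a comment: with log-spaced dwell
bins (8/decade) any exponential component intrinsically carries ~4 bits,
and the disjoint open/closed timescales of a fully activated channel add a
further mixture bit, so the documented *decrease* of pooled dwell entropy
under full activation is only reproduced when the closed dwells concentrate
hard — a steep, truncated power law.  A mild exponent (α ≈ 1.5 survival
slope −0.5) with long caps yields power-law closings whose log-bin entropy
*exceeds* control; that variant is expressible with the same classes but is
not shipped as the default because it contradicts the entropy phenomenology
the regime exists to emulate.

## 2. Idealization

Half-amplitude thresholding: threshold = (closed + open)/2, a sample is
open iff strictly on the open side (a tie is closed — conservative and
deterministic); level ordering, not sign, decides the open side, so
negative-going openings work unchanged.  No missed-event (filter dead-time)
correction is applied and 1-sample events are retained: the output is the
literal half-amplitude idealization.  Consequently, at 1 kHz filtering,
events shorter than ≈0.2 ms are attenuated below threshold and merge into
their neighbours; the p_open estimator tolerates this (tested at ±0.03
with SNR 10 and filtering) but dwell histograms of heavily filtered traces
under-represent the shortest bin or two.

Level estimation, when levels are not supplied, takes the two dominant
modes of a Gaussian-KDE-smoothed all-points histogram and requires them to
be ≥ 4 estimated noise SD apart; anything less bimodal is rejected with an
instruction to pass levels explicitly, rather than guessed at.

## 3. Entropies

**Dwell-time Shannon entropy** is computed on the *pooled* (open + closed)
dwell histogram over shared log₁₀-spaced bins, 8 per decade, from one
sampling interval (0.1 ms) to 100 s.  Pooling and the shared grid make the
numbers comparable across conditions; out-of-range dwells are counted in
the nearest end bin and logged.  Open-only/closed-only histograms are
available by passing `dwells.open_durations` / `.closed_durations`.

**Sample entropy.**  The default estimator counts matches per template:
templates
u_m(i), i = 1…N−m+1; n_i^m = #{j ≠ i : Chebyshev distance ≤ r};
C_i^m = n_i^m/(N−m); C^m = mean over templates; SampEn = −ln(C^{m+1}/C^m).
This differs from the canonical Richman–Moorman estimator (both orders
restricted to the same N−m templates, pair counting) by boundary terms of
order 1/N; the canonical form is available via
`variant="richman-moorman"`.  A worked consequence: for the alternating
series (1,2,1,2,…) of length 50 the pair-counting form is exactly 0 while
the per-template form retains a residue of 8.87×10⁻⁴ from the 25-vs-24
split of template parities.  When no (m+1)-matches exist the result is
flagged undefined (NaN + reason), never ±inf.

Windowing: the dwell series (interleaved durations, no transform) is cut
into non-overlapping windows of 4000 values; each window uses its own
r = 0.2 × (window SD, population convention); the mean ± SE over windows
is reported.  Series shorter than one window fall back to a single
whole-series window with a logged warning.

## 4. Spectra

`periodogram_psd` is an averaged periodogram (boxcar window,
non-overlapping segments of 2¹⁴ samples by default, density scaling), so
Σ P·Δf equals the signal mean square and all recordings of a condition
share one frequency grid — a prerequisite for the per-frequency median
across recordings.  The relative spectrum is the plain ratio to the
control median; bins with zero control power are masked NaN and logged.

Short-time spectra use the Hamming taper w_i = a₀ − (1−a₀)cos(2πi/W) with
a₀ = 25/46 and W = 12.8 ms × sampling rate (128 samples at 10 kHz).  Two
deliberate deviations from the most literal formulation, both switchable:
windows do not span recording boundaries (default processes each trace
separately and pools windows; `literal_concat=True` concatenates first),
and the default stride is W/2 rather than 1 (`stride=1` restores the
exhaustive advance; the spectra populations differ only in sample count).

Peak entropy: the histogram intervals are fixed *once for all samples* —
the mean P̄ and SD σ_P are pooled over every condition, window and
frequency bin (a per-frequency pooling variant exists behind
`pooling="per-frequency"`, since the printed statistics can be read either
way).  Per condition and frequency, window powers are histogrammed over
(0, 10σ_P] in K = 1000 equal bins; values beyond the range are dropped
(not clipped) and their fraction recorded; probabilities are normalized
within each histogram and H_i = −Σ p log₂ p ∈ [0, log₂ K].  No spectral
rescaling is applied to the windowed spectra: any constant factor cancels
because the bin width is σ_P-relative.

## 5. EMD

Sifting uses cubic-spline envelopes through local maxima/minima.  Numerical
conventions the literature leaves open:

* extrema are strict sign changes of the first difference, plateaus
  contribute their midpoint; endpoints are never extrema;
* envelopes mirror-extend two extrema about each window end before spline
  fitting, so the splines bracket the full window;
* "local mean approximately zero" is max |envelope mean| ≤ 0.05 × RMS
  envelope amplitude;
* caps: 50 sifting iterations per IMF for the mean condition, 12 IMFs per
  window.  The zero-crossing/extrema condition is *insisted* on beyond the
  mean-condition cap (with a separate iteration budget and a
  last-good-candidate fallback): near-two-level signals can hold a
  crossing deficit of 2 for hundreds of sifts, and every returned IMF must
  satisfy the counting rule;
* decomposition stops when the residual has ≤ 1 extremum, is
  monotonic/constant, or no longer has two maxima *and* two minima to
  build envelopes from (the unavoidable terminal state of spline-envelope
  sifting);
* reconstruction Σ IMFs + residual = input is exact by construction and
  asserted to 10⁻⁹ × input range.

Feature extraction: traces are cut into non-overlapping windows of 100,000
samples (10 s at 10 kHz; trailing remainder dropped and logged), each
window min–max normalized to [0,1] before decomposition so baseline
position does not leak into amplitudes.  Energy is the mean square of the
IMF of the *normalized* window — the (I/I_max)² convention — and the
residual (the trend) is excluded from the feature population.  The IMF
frequency estimator is not canonical; the default is the zero-crossing
rate (#crossings of the demeaned IMF / 2 × duration): cheap, deterministic
and exact for narrowband modes.  A Hilbert mean-instantaneous-frequency
estimator is available via `estimator="hilbert"`.

## 6. IMF clustering

Both feature axes span decades, so clustering runs in
(log₁₀ f, log₁₀ E).  The population is first binned on a fixed shared grid
(60 × 60 cells over 1 Hz–5 kHz × 10⁻⁸–1); K-means (k = 6, k-means++, best
of 20 restarts, seeded) runs on the non-empty cell centers weighted by
counts — clustering the histogram, with a point-level run expressible by
passing one feature per cell.  "Weighted average" centroids are
count-weighted means of member cell centers in log space, reported in
linear units (i.e. geometric means).  Occupancy is the member-count
fraction; cluster entropy is the Shannon entropy of the within-cluster
normalized count distribution.  Labels are canonicalized by centroid
frequency band (log₁₀ f rounded to 0.1 decade) then energy, so cluster 0
is always the low-frequency/low-energy group and cluster 1 its
high-energy partner, independent of K-means' arbitrary labelling.

## 7. Pipeline and determinism

`run_pipeline` executes idealize → entropies → spectra → EMD → clustering
per condition, then the cross-condition stages (relative PSD against the
control median; peak entropy with globally pooled σ_P; dwell entropy
rescaled to control as a ratio).  One master seed derives per-condition
and per-trace 31-bit seeds through seed-sequence hashing; a rerun from the
same config is byte-identical across all CSV outputs.  A failing stage is
recorded per condition and does not abort the rest.

## 8. What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses consume:
two-level conductance, Gaussian instrument noise shaped by a 1 kHz filter,
alternating semi-Markov gating with multi-exponential or power-law dwell
families, and trace lengths ≥ 2×10⁵ samples.  It deliberately omits
subconductance levels, baseline drift and seal/capacitive artifacts,
multi-channel patches, and voltage-dependent kinetics.  Tests passing on
these signals therefore validate the *estimators* — recovery of known
dwell means, survival slopes, stationary p_open, exact oracle equivalence
for SampEn and the spectral entropy recount, planted-cluster recovery —
and the qualitative orderings of the packaged regimes; they do not certify
conclusions about any particular experimental dataset.

## 9. Problem sizes

Defaults target the acquisition scale of the motivating experiments
(10 kHz, 1 kHz low-pass, ≥ 2×10⁵-sample traces).  The packaged
demonstration and the acceptance script use 3 traces × 20 s per condition —
enough for ~1,600–7,000 dwells and six occupied IMF clusters per condition —
and the test suite exercises the estimators at the sizes where their
statistical tolerances (3-SE bands, ±0.05 slope, ±0.01/±0.03 p_open) are
meaningful.
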