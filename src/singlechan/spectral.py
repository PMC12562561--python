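"""Spectral analysis of single-channel currents.

Three layers:

* :func:`periodogram_psd` — averaged periodogram of one trace on a fixed
  frequency grid (non-overlapping segments, density scaling, so the PSD
  integrates to the signal's mean square power);
* :func:`median_psd` / :func:`relative_psd` — the per-condition median
  spectrum across recordings and its ratio to the unstimulated control,
  P̂(f) = P(f) / P_control(f), which shows by what factor each spectral
  band grows or shrinks under stimulation;
* :func:`windowed_spectra` / :func:`peak_entropy` — short-time spectra over
  a sliding Hamming window (width 12.8 ms by default), followed by the
  per-frequency Shannon entropy of the distribution of spectral peak
  values across windows.  For each frequency bin the window-to-window power
  values are histogrammed over (0, 10·σ_P] in K equal bins (σ_P pooled over
  all conditions, windows and frequencies so the intervals characterise
  every sample), and H_i = −Σ_k p log₂ p is reported in bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .containers import Condition, CurrentTrace

__all__ = [
    "PowerSpectrum",
    "RelativePowerSpectrum",
    "WindowedSpectra",
    "PeakEntropyResult",
    "HAMMING_A0",
    "periodogram_psd",
    "median_psd",
    "relative_psd",
    "hamming_taper",
    "windowed_spectra",
    "peak_entropy",
]

log = logging.getLogger(__name__)

#: Hamming coefficient: w_i = a0 - (1 - a0) cos(2πi/W)
HAMMING_A0 = 25.0 / 46.0


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray   # Hz, strictly increasing, >= 0
    power: np.ndarray         # density, >= 0
    segment_length: int
    estimator: str = "per-recording"
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must be non-negative and increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def total_power(self) -> float:
        """Σ P(f)·Δf — equals the signal mean square for density scaling."""
        df = self.frequencies[1] - self.frequencies[0]
        return float(self.power.sum() * df)


@dataclass
class RelativePowerSpectrum:
    frequencies: np.ndarray
    ratio: np.ndarray         # NaN where the control power is zero (masked)
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)


@dataclass
class WindowedSpectra:
    """Matrix of short-time power spectra: rows = windows, cols = frequency."""

    frequencies: np.ndarray
    power: np.ndarray         # shape (n_windows, n_freq)
    window_length: int
    stride: int
    a0: float = HAMMING_A0
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("windowed power must be 2-D (windows x freq)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.power.shape[0]


@dataclass
class PeakEntropyResult:
    frequencies: np.ndarray
    entropy_bits: np.ndarray          # H_i per frequency
    pooled_mean: float                # P̄ used to set the bin range
    pooled_sd: float                  # σ_P
    k_bins: int
    dropped_fraction: float = 0.0     # values beyond 10 σ_P, excluded
    condition: Condition = field(default_factory=Condition)


# ---------------------------------------------------------------------------
# full-trace PSDs
# ---------------------------------------------------------------------------

def periodogram_psd(
    trace: CurrentTrace, segment_length: int = 2**14
) -> PowerSpectrum:
    """One-sided averaged periodogram over non-overlapping segments.

    Density scaling (power per Hz): the spectrum integrates to the signal's
    mean square (Parseval-consistent).  A fixed ``segment_length`` puts all
    recordings of a condition on one frequency grid so their median is
    well-defined.
    """
    if len(trace) < segment_length:
        raise ValueError(
            f"trace has {len(trace)} samples < segment_length {segment_length}"
        )
    f, p = _signal.welch(
        trace.samples,
        fs=trace.sampling_rate,
        window="boxcar",
        nperseg=segment_length,
        noverlap=0,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )
    return PowerSpectrum(f, p, segment_length=segment_length,
                         condition=trace.condition)


def median_psd(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Per-frequency median across recordings of one condition."""
    if not spectra:
        raise ValueError("no spectra to aggregate")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != f0.shape or not np.allclose(s.frequencies, f0):
            raise ValueError("spectra must share one frequency grid")
    stack = np.vstack([s.power for s in spectra])
    return PowerSpectrum(f0, np.median(stack, axis=0),
                         segment_length=spectra[0].segment_length,
                         estimator="median-across-recordings",
                         condition=spectra[0].condition)


def relative_psd(
    condition: PowerSpectrum, control: PowerSpectrum
) -> RelativePowerSpectrum:
    """Ratio spectrum P̂(f) = P(f)/P_control(f); zero-power control bins are
    masked to NaN and logged."""
    if condition.frequencies.shape != control.frequencies.shape or not np.allclose(
        condition.frequencies, control.frequencies
    ):
        raise ValueError("condition and control spectra must share one grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(control.power > 0, condition.power / control.power, np.nan)
    n_masked = int(np.count_nonzero(~(control.power > 0)))
    if n_masked:
        log.info("relative_psd: %d bins masked (zero control power)", n_masked)
    return RelativePowerSpectrum(condition.frequencies, ratio,
                                 condition=condition.condition)


# ---------------------------------------------------------------------------
# windowed spectra and per-frequency peak entropy
# ---------------------------------------------------------------------------

def hamming_taper(W: int, a0: float = HAMMING_A0) -> np.ndarray:
    """w_i = a0 − (1 − a0)·cos(2πi/W), i = 0…W−1."""
    i = np.arange(W)
    return a0 - (1.0 - a0) * np.cos(2.0 * np.pi * i / W)


def windowed_spectra(
    traces: list[CurrentTrace] | CurrentTrace,
    W: int | None = None,
    stride: int | None = None,
    window_seconds: float = 0.0128,
    a0: float = HAMMING_A0,
    literal_concat: bool = False,
) -> WindowedSpectra:
    """Short-time power spectra of one condition's recordings.

    Each length-``W`` window (default 12.8 ms worth of samples) is tapered
    with the Hamming window and its one-sided magnitude-squared FFT becomes
    one row.  By default windows never span recording boundaries (each
    trace is processed separately and the rows pooled); ``literal_concat``
    concatenates the traces first instead.  Default stride is W//2; pass
    ``stride=1`` for the exhaustive single-sample advance.
    """
    if isinstance(traces, CurrentTrace):
        traces = [traces]
    if not traces:
        raise ValueError("no traces")
    fs = traces[0].sampling_rate
    if any(t.sampling_rate != fs for t in traces):
        raise ValueError("traces must share one sampling rate")
    if W is None:
        W = int(round(window_seconds * fs))
    if W < 4:
        raise ValueError("window shorter than 4 samples")
    if stride is None:
        stride = max(1, W // 2)
    if any(len(t) < W for t in traces):
        raise ValueError("window W exceeds the shortest trace")

    taper = hamming_taper(W, a0)
    sources = ([np.concatenate([t.samples for t in traces])] if literal_concat
               else [t.samples for t in traces])
    rows = []
    for x in sources:
        n_win = (x.size - W) // stride + 1
        starts = np.arange(n_win) * stride
        seg = np.lib.stride_tricks.sliding_window_view(x, W)[starts]
        spec = np.abs(np.fft.rfft(seg * taper, axis=1)) ** 2
        rows.append(spec)
    power = np.vstack(rows)
    freqs = np.fft.rfftfreq(W, d=1.0 / fs)
    return WindowedSpectra(freqs, power, window_length=W, stride=stride,
                           a0=a0, condition=traces[0].condition)


def peak_entropy(
    all_conditions: dict[Condition, WindowedSpectra],
    k_bins: int = 1000,
    pooling: str = "global",
) -> dict[Condition, PeakEntropyResult]:
    """Per-frequency Shannon entropy of spectral peak values across windows.

    The histogram intervals are established once for all samples: the mean
    P̄ and SD σ_P of the windowed spectral values are pooled over every
    condition, window and frequency (``pooling="global"``, default), or per
    frequency bin over all conditions (``pooling="per-frequency"``).  For
    each condition and frequency ``i`` the values P_i(n) are histogrammed
    over (0, 10·σ_P] into ``k_bins`` equal bins; values beyond the range
    are dropped (their fraction recorded).  Probabilities are normalized
    within each histogram and H_i = −Σ p log₂ p.
    """
    if not all_conditions:
        raise ValueError("no conditions")
    for cond, ws in all_conditions.items():
        if ws.n_windows < 2:
            raise ValueError(f"condition {cond.label}: need >= 2 windows")
    pooled = np.concatenate([ws.power.ravel() for ws in all_conditions.values()])
    if pooling == "global":
        p_bar = float(pooled.mean())
        sigma = float(pooled.std())
        sigma_i = None
    elif pooling == "per-frequency":
        stack = np.vstack([ws.power for ws in all_conditions.values()])
        p_bar_i = stack.mean(axis=0)
        sigma_i = stack.std(axis=0)
        p_bar = float(p_bar_i.mean())
        sigma = float(sigma_i.mean())
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if sigma == 0 or (sigma_i is not None and np.any(sigma_i == 0)):
        raise ValueError("degenerate spectra: sigma_P is zero")

    out: dict[Condition, PeakEntropyResult] = {}
    for cond, ws in all_conditions.items():
        n_freq = ws.power.shape[1]
        H = np.empty(n_freq)
        dropped = 0
        total = 0
        for i in range(n_freq):
            vals = ws.power[:, i]
            hi = 10.0 * (sigma if sigma_i is None else sigma_i[i])
            in_range = vals[(vals > 0) & (vals <= hi)]
            dropped += vals.size - in_range.size
            total += vals.size
            if in_range.size == 0:
                H[i] = 0.0
                continue
            counts, _ = np.histogram(in_range, bins=k_bins, range=(0.0, hi))
            p = counts / counts.sum()
            nz = p[p > 0]
            H[i] = float(-(nz * np.log2(nz)).sum())
        frac = dropped / total if total else 0.0
        if frac:
            log.info("peak_entropy %s: %.3g of values outside (0, 10 sigma_P]",
                     cond.label, frac)
        out[cond] = PeakEntropyResult(ws.frequencies, H, pooled_mean=p_bar,
                                      pooled_sd=sigma, k_bins=k_bins,
                                      dropped_fraction=frac, condition=cond)
    return out
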