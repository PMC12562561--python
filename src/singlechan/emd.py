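"""Empirical mode decomposition of signal windows and IMF features.

EMD splits a signal X(t) into intrinsic mode functions (IMFs) C_i(t) plus a
residual trend r_n(t), X(t) = Σ C_i(t) + r_n(t), by iterated "sifting":
cubic-spline envelopes are drawn through the local maxima and minima, the
envelope mean is subtracted, and the result is accepted as an IMF once
(a) its numbers of zero crossings and extrema differ by at most one and
(b) its local envelope mean is approximately zero everywhere.  The
decomposition stops when the residual has at most one extremum or is
monotonic/constant.

For population-level analysis, recordings are cut into non-overlapping
windows (100,000 samples by default, i.e. 10 s at 10 kHz), each window is
min–max normalized to [0, 1] so the baseline position does not leak into
IMF amplitudes, and each IMF is summarised by two numbers: its energy
(I/I_max)² — the mean square of the normalized-signal IMF, i.e. its
relative contribution to signal power per sampling interval — and a
characteristic frequency.  The default frequency estimator is the
zero-crossing rate, #crossings / (2 · window duration); a mean
instantaneous-frequency (Hilbert) estimator is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .containers import Condition, CurrentTrace

__all__ = [
    "IMF",
    "Decomposition",
    "IMFFeature",
    "minmax_normalize",
    "emd_decompose",
    "imf_energy",
    "imf_frequency",
    "decompose_trace_windows",
    "local_extrema",
    "zero_crossings",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima.

    Extrema are strict sign changes of the first difference; equal-value
    plateaus contribute their midpoint.  Endpoints are never extrema.
    """
    d = np.sign(np.diff(x))
    idx = np.flatnonzero(d != 0)
    if idx.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    s = d[idx]
    change = np.flatnonzero(s[:-1] != s[1:])
    a = idx[change]
    b = idx[change + 1]
    pos = (a + 1 + b) // 2  # plateau midpoint
    kind = s[change]
    return pos[kind > 0], pos[kind < 0]


def zero_crossings(x: np.ndarray) -> int:
    """Number of sign changes, with exact zeros compressed out."""
    s = np.sign(x)
    nz = s[s != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(nz[:-1] != nz[1:]))


def _envelope(x: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema ``ext``, mirror-extending
    two extrema about each end of the window before fitting."""
    n = x.size
    t = ext.astype(float)
    v = x[ext]
    # mirror two extrema about each boundary so the spline brackets [0, n-1]
    tl = -t[1::-1]
    vl = v[1::-1]
    tr = 2.0 * (n - 1) - t[:-3:-1]
    vr = v[:-3:-1]
    tt = np.concatenate([tl, t, tr])
    vv = np.concatenate([vl, v, vr])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    cs = CubicSpline(tt[keep], vv[keep])
    return cs(np.arange(n))


def _envelopes(x: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    maxima, minima = local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    return _envelope(x, maxima), _envelope(x, minima)


def _is_imf(h: np.ndarray, mean_env: np.ndarray, amp_env: np.ndarray,
            tol: float) -> tuple[bool, bool]:
    """(zero-crossing/extrema condition, small-local-mean condition)."""
    maxima, minima = local_extrema(h)
    n_ext = maxima.size + minima.size
    zc_ok = abs(n_ext - zero_crossings(h)) <= 1
    rms_amp = float(np.sqrt(np.mean(amp_env**2)))
    mean_ok = rms_amp > 0 and float(np.max(np.abs(mean_env))) <= tol * rms_amp
    return zc_ok, mean_ok


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass
class IMF:
    samples: np.ndarray
    n_sift: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class Decomposition:
    """Ordered IMFs (highest frequency first) plus the residual trend.

    ``Σ imfs + residual`` reconstructs the input exactly (floating point)."""

    imfs: list[IMF]
    residual: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.residual = np.asarray(self.residual, dtype=float)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf.samples
        return out

    def __len__(self) -> int:
        return len(self.imfs)


def _sift(x: np.ndarray, max_sift: int, tol: float,
          zc_extra: int = 400) -> IMF | None:
    """Extract one IMF from ``x`` by iterated envelope-mean subtraction.

    The mean-smallness condition is enforced up to ``max_sift`` iterations;
    past that the zero-crossing/extrema condition alone is still insisted
    on (with an extra iteration budget, entered only for the rare stubborn
    windows — near-two-level signals can hold a crossing deficit of 2 for
    hundreds of sifts before it clears) so every returned IMF satisfies it.
    """
    h = x.astype(float, copy=True)
    best: IMF | None = None  # last candidate satisfying the crossing rule
    for it in range(max_sift + zc_extra + 1):
        env = _envelopes(h)
        if env is None:
            return None if it == 0 else (best or IMF(h, it))
        upper, lower = env
        mean_env = 0.5 * (upper + lower)
        amp_env = 0.5 * (upper - lower)
        zc_ok, mean_ok = _is_imf(h, mean_env, amp_env, tol)
        if zc_ok:
            if mean_ok or it >= max_sift:
                return IMF(h, it)
            best = IMF(h.copy(), it)
        h = h - mean_env
    return best or IMF(h, max_sift + zc_extra)


def _residual_done(r: np.ndarray) -> bool:
    maxima, minima = local_extrema(r)
    return maxima.size + minima.size <= 1


def emd_decompose(
    window: np.ndarray,
    max_imfs: int = 12,
    max_sift: int = 50,
    mean_tol: float = 0.05,
    source_id: str = "",
) -> Decomposition:
    """Full EMD of one signal window.

    Parameters
    ----------
    window
        Input samples (length >= 8 for a meaningful decomposition).
    max_imfs, max_sift
        Caps on the number of modes and sifting iterations per mode.
    mean_tol
        "Approximately zero" local mean: max |envelope mean| must not
        exceed ``mean_tol`` × RMS envelope amplitude.

    A window with fewer than two interior extrema is returned whole as the
    residual with zero IMFs.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("window must be 1-D with at least 8 samples")
    imfs: list[IMF] = []
    residual = x.copy()
    while len(imfs) < max_imfs and not _residual_done(residual):
        imf = _sift(residual, max_sift, mean_tol)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf.samples
    return Decomposition(imfs, residual, source_id=source_id)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def minmax_normalize(window: np.ndarray) -> np.ndarray:
    """(x − min) / (max − min); rejects constant windows."""
    x = np.asarray(window, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant window cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def imf_energy(imf: IMF | np.ndarray, n: int | None = None) -> float:
    """(I/I_max)² energy: mean square of the (normalized-signal) IMF."""
    c = imf.samples if isinstance(imf, IMF) else np.asarray(imf, dtype=float)
    if n is None:
        n = c.size
    return float((c**2).sum() / n)


def imf_frequency(
    imf: IMF | np.ndarray, sampling_rate: float, estimator: str = "zero-crossing"
) -> float:
    """Characteristic frequency of an IMF in Hz.

    ``"zero-crossing"`` (default): crossings / (2 × duration) — each full
    oscillation crosses zero twice.  ``"hilbert"``: amplitude²-weighted
    mean instantaneous frequency from the analytic signal.
    """
    c = imf.samples if isinstance(imf, IMF) else np.asarray(imf, dtype=float)
    if c.size < 2:
        raise ValueError("IMF must have at least 2 samples")
    if estimator == "zero-crossing":
        duration = c.size / sampling_rate
        return zero_crossings(c - c.mean()) / (2.0 * duration)
    if estimator == "hilbert":
        analytic = hilbert(c)
        phase = np.unwrap(np.angle(analytic))
        inst = np.diff(phase) * sampling_rate / (2.0 * np.pi)
        w = np.abs(analytic[:-1]) ** 2
        if w.sum() == 0:
            return 0.0
        return float(np.clip((inst * w).sum() / w.sum(), 0.0, None))
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class IMFFeature:
    """One (frequency, energy) point of the IMF population."""

    frequency: float
    energy: float
    condition: Condition = field(default_factory=Condition)
    trace_id: str = ""
    window_idx: int = 0
    imf_idx: int = 0


def decompose_trace_windows(
    trace: CurrentTrace,
    window: int = 100_000,
    max_imfs: int = 12,
    max_sift: int = 50,
    mean_tol: float = 0.05,
    frequency_estimator: str = "zero-crossing",
) -> list[IMFFeature]:
    """EMD features of a whole trace.

    The trace is cut into non-overlapping windows of ``window`` samples
    (the trailing partial window is dropped and logged), each window is
    min–max normalized and decomposed, and one (frequency, energy) feature
    is emitted per IMF.  The residual trend is excluded.
    """
    n_win = len(trace) // window
    if n_win == 0:
        raise ValueError(
            f"trace has {len(trace)} samples < one window of {window}"
        )
    rem = len(trace) - n_win * window
    if rem:
        log.info("decompose_trace_windows %s: dropping trailing %d samples",
                 trace.trace_id, rem)
    features: list[IMFFeature] = []
    for w in range(n_win):
        seg = trace.samples[w * window:(w + 1) * window]
        norm = minmax_normalize(seg)
        dec = emd_decompose(norm, max_imfs=max_imfs, max_sift=max_sift,
                            mean_tol=mean_tol,
                            source_id=f"{trace.trace_id}/w{w}")
        for k, imf in enumerate(dec.imfs):
            features.append(IMFFeature(
                frequency=imf_frequency(imf, trace.sampling_rate,
                                        estimator=frequency_estimator),
                energy=imf_energy(imf, norm.size),
                condition=trace.condition,
                trace_id=trace.trace_id,
                window_idx=w,
                imf_idx=k,
            ))
    return features
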