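"""Half-amplitude idealization of single-channel current traces.

A two-level recording is reduced to a binary open/closed sequence by
thresholding midway between the closed and open conductance levels (the
standard half-amplitude method).  From the idealized sequence the module
derives the open-state probability p_open — the fraction of samples assigned
to the open state — and the dwell-time series, i.e. the run-length encoding
of successive state episodes.

Levels can be supplied by the caller or estimated from the all-points
amplitude histogram (:func:`estimate_levels`); estimation requires a clearly
bimodal histogram and refuses to guess otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal
from scipy.stats import gaussian_kde

from .containers import CurrentTrace, DwellTimeSeries, IdealizedTrace

__all__ = [
    "estimate_levels",
    "half_amplitude_idealize",
    "extract_dwell_times",
    "open_probability",
    "idealize_trace",
]


def estimate_levels(trace: CurrentTrace, grid_points: int = 512) -> tuple[float, float]:
    """Estimate the closed and open conductance levels (pA).

    The two dominant modes of a kernel-smoothed all-points amplitude
    histogram are taken as the levels; they must be separated by at least
    four times the estimated within-level noise SD, otherwise the histogram
    is considered unimodal and the caller must supply levels explicitly.

    Returns ``(closed_level, open_level)`` ordered so that the open level is
    the one farther from zero (openings may be positive- or negative-going).
    """
    x = trace.samples
    if np.ptp(x) == 0:
        raise ValueError(
            "constant trace: amplitude histogram is degenerate; "
            "supply closed/open levels explicitly"
        )
    # subsample for the KDE; mode locations are stable under thinning
    step = max(1, x.size // 50_000)
    xs = x[::step]
    kde = gaussian_kde(xs)
    pad = 0.05 * np.ptp(x)  # keep modes at the data extremes interior to the grid
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_points)
    dens = kde(grid)
    peaks, props = _signal.find_peaks(dens, height=dens.max() * 1e-3)
    if peaks.size < 2:
        raise ValueError(
            "amplitude histogram is unimodal; supply closed/open levels explicitly"
        )
    top = peaks[np.argsort(props["peak_heights"])[-2:]]
    levels = np.sort(grid[top])
    # within-level noise: robust SD of samples near the lower mode
    lower = levels[0]
    near = x[np.abs(x - lower) < 0.25 * (levels[1] - levels[0])]
    noise_sd = 1.4826 * np.median(np.abs(near - np.median(near))) if near.size else 0.0
    if levels[1] - levels[0] < 4 * noise_sd:
        raise ValueError(
            "amplitude modes are not separated by >= 4 noise SD; "
            "supply closed/open levels explicitly"
        )
    lo, hi = float(levels[0]), float(levels[1])
    if abs(hi) >= abs(lo):
        return lo, hi
    return hi, lo


def half_amplitude_idealize(
    trace: CurrentTrace, closed_level: float, open_level: float
) -> IdealizedTrace:
    """Threshold a trace at the midpoint of the two conductance levels.

    A sample is open iff its value lies strictly on the open side of
    ``(closed_level + open_level) / 2``; a sample exactly at threshold is
    assigned closed.
    """
    if closed_level == open_level:
        raise ValueError("closed and open levels must differ")
    threshold = 0.5 * (closed_level + open_level)
    if open_level > closed_level:
        states = trace.samples > threshold
    else:
        states = trace.samples < threshold
    return IdealizedTrace(
        states=states,
        sampling_rate=trace.sampling_rate,
        threshold=threshold,
        closed_level=closed_level,
        open_level=open_level,
        condition=trace.condition,
        trace_id=trace.trace_id,
    )


def extract_dwell_times(ideal: IdealizedTrace, sampling_rate: float | None = None) -> DwellTimeSeries:
    """Run-length encode an idealized trace into dwell times (seconds)."""
    fs = sampling_rate if sampling_rate is not None else ideal.sampling_rate
    s = ideal.states
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [s.size]])
    return DwellTimeSeries(
        states=s[starts],
        durations=(ends - starts) / fs,
        condition=ideal.condition,
        trace_id=ideal.trace_id,
    )


def open_probability(ideal: IdealizedTrace) -> float:
    """Fraction of samples assigned to the open state."""
    return float(np.count_nonzero(ideal.states) / ideal.states.size)


def idealize_trace(
    trace: CurrentTrace,
    closed_level: float | None = None,
    open_level: float | None = None,
) -> tuple[IdealizedTrace, DwellTimeSeries, float]:
    """Convenience wrapper: estimate levels if needed, idealize, extract.

    Returns ``(idealized, dwells, p_open)``.
    """
    if closed_level is None or open_level is None:
        closed_level, open_level = estimate_levels(trace)
    ideal = half_amplitude_idealize(trace, closed_level, open_level)
    return ideal, extract_dwell_times(ideal), open_probability(ideal)
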