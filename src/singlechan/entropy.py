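"""Entropy measures for dwell-time data.

Two complementary measures are provided.  The Shannon entropy of the
normalized dwell-time histogram quantifies how broadly the episode
durations are distributed over timescales — a channel parked in one stable
conformation yields a nearly degenerate histogram and low entropy, while
gating that mixes many timescales yields high entropy.  Sample entropy
(SampEn) of the dwell-time *series* quantifies the temporal regularity of
the succession of dwells: it is the negative natural logarithm of the
conditional probability that two subsequences that match for ``m``
consecutive dwells (within a Chebyshev tolerance ``r``) still match at the
(m+1)-th.

The default SampEn estimator uses per-template counting: with ``N``
points and templates ``u_m(i)``,
``i = 1 … N−m+1``, the per-template match probability is
``C_i^m = n_i^m / (N−m)`` with ``n_i^m`` the number of other templates
within ``r``; ``C^m`` is the mean over all templates, and
``SampEn = −ln(C^{m+1}/C^m)``.  The canonical Richman–Moorman variant
(templates truncated to ``N−m`` so that the m- and (m+1)-counts run over
the same pairs) is available via ``variant="richman-moorman"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import DwellTimeSeries

__all__ = [
    "DwellHistogram",
    "SampEnResult",
    "default_dwell_edges",
    "dwell_histogram",
    "shannon_entropy",
    "sample_entropy",
    "windowed_sample_entropy",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Shannon entropy of dwell-time histograms
# ---------------------------------------------------------------------------

@dataclass
class DwellHistogram:
    """Normalized dwell-time histogram over (typically log-spaced) bins."""

    bin_edges: np.ndarray       # seconds, strictly increasing
    probabilities: np.ndarray   # one per bin, sums to 1
    n_dwells: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.probabilities.size != self.bin_edges.size - 1:
            raise ValueError("need one probability per bin")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def entropy_bits(self) -> float:
        return shannon_entropy(self.probabilities)


def default_dwell_edges(
    dt: float = 1e-4, t_max: float = 100.0, bins_per_decade: int = 8
) -> np.ndarray:
    """Shared log10-spaced dwell bins from one sampling interval up to
    ``t_max`` seconds.  A common grid across conditions keeps the entropies
    comparable."""
    n_dec = math.log10(t_max / dt)
    n_bins = int(math.ceil(n_dec * bins_per_decade))
    return dt * 10 ** (np.arange(n_bins + 1) / bins_per_decade)


def dwell_histogram(
    dwells: DwellTimeSeries | np.ndarray, edges: np.ndarray | None = None
) -> DwellHistogram:
    """Normalized histogram of dwell durations (open and closed pooled).

    Durations outside the edge range are counted in the nearest end bin and
    logged rather than silently dropped.
    """
    if isinstance(dwells, DwellTimeSeries):
        durations = dwells.durations
    else:
        durations = np.asarray(dwells, dtype=float)
    if durations.size == 0:
        raise ValueError("need at least one dwell")
    if edges is None:
        edges = default_dwell_edges()
    edges = np.asarray(edges, dtype=float)
    n_out = int(np.count_nonzero((durations < edges[0]) | (durations > edges[-1])))
    if n_out:
        log.info("dwell_histogram: %d of %d dwells outside bin range, "
                 "counted in end bins", n_out, durations.size)
    lo, hi = edges[0], edges[-1]
    clipped = np.clip(durations, lo + 0.0, hi)
    counts, _ = np.histogram(clipped, bins=edges)
    # np.histogram drops values exactly below the first edge after clip only
    # if lo > min; clip guarantees inclusion
    return DwellHistogram(edges, counts / counts.sum(), n_dwells=durations.size)


def shannon_entropy(probabilities: np.ndarray, tol: float = 1e-6) -> float:
    """Shannon entropy −Σ p log₂ p in bits, with 0·log 0 ≡ 0."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"probabilities sum to {p.sum():g}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

@dataclass
class SampEnResult:
    """Sample entropy value with the parameters that produced it.

    ``value`` is in natural-log units; ``defined`` is False when no
    (m+1)-matches (or no m-matches) exist, in which case ``value`` is NaN
    and ``reason`` explains why.
    """

    value: float
    m: int
    r: float
    n: int
    defined: bool = True
    reason: str | None = None
    variant: str = "printed"
    # windowed statistics (populated by windowed_sample_entropy)
    window_length: int | None = None
    window_values: np.ndarray | None = None
    se: float | None = None

    def __repr__(self) -> str:  # keep NaN prints readable
        v = f"{self.value:.4f}" if self.defined else f"undefined ({self.reason})"
        return f"SampEnResult({v}, m={self.m}, r={self.r:g}, n={self.n})"


def _template_match_counts(x: np.ndarray, m: int, r: float,
                           n_templates: int | None = None) -> np.ndarray:
    """For each m-template, count *other* templates within Chebyshev
    distance r.  O(N²) but blocked and vectorized."""
    X = np.lib.stride_tricks.sliding_window_view(x, m)
    if n_templates is not None:
        X = X[:n_templates]
    nt = X.shape[0]
    counts = np.empty(nt, dtype=np.int64)
    block = max(1, int(4e6 // max(nt * m, 1)))
    for s in range(0, nt, block):
        B = X[s:s + block]
        d = np.abs(B[:, None, :] - X[None, :, :]).max(axis=2)
        counts[s:s + block] = (d <= r).sum(axis=1) - 1  # exclude self-match
    return counts


def sample_entropy(
    series: np.ndarray,
    m: int = 2,
    r: float | None = None,
    r_factor: float = 0.2,
    variant: str = "printed",
) -> SampEnResult:
    """Sample entropy of a series with Chebyshev-distance template matching.

    Parameters
    ----------
    series
        The data series (e.g. interleaved dwell durations).
    m
        Embedding dimension (default 2).
    r
        Absolute similarity threshold.  If None, ``r = r_factor · σ`` with
        σ the population SD of ``series``.
    variant
        ``"printed"`` (default): templates ``i = 1…N−m+1`` for order m,
        per-template denominator ``N−m``.  ``"richman-moorman"``: both
        orders restricted to the same ``N−m`` templates (pair counting).
    """
    x = np.asarray(series, dtype=float)
    N = x.size
    if N <= m + 1:
        raise ValueError(f"series length {N} too short for m={m}")
    if r is None:
        sigma = float(np.std(x))
        if sigma == 0:
            raise ValueError("zero-variance series: r = r_factor*sigma is 0")
        r = r_factor * sigma
    if not r > 0:
        raise ValueError("similarity threshold r must be positive")
    if variant not in ("printed", "richman-moorman"):
        raise ValueError(f"unknown variant {variant!r}")

    if variant == "printed":
        cm = _template_match_counts(x, m, r) / (N - m)
        cm1 = _template_match_counts(x, m + 1, r) / (N - m - 1)
        Cm = float(cm.mean())
        Cm1 = float(cm1.mean())
    else:
        # pair counts over the common N-m templates
        bm = _template_match_counts(x, m, r, n_templates=N - m).sum() / 2
        am = _template_match_counts(x, m + 1, r).sum() / 2
        Cm, Cm1 = float(bm), float(am)

    base = dict(m=m, r=float(r), n=N, variant=variant)
    if Cm == 0:
        return SampEnResult(math.nan, defined=False,
                            reason="no m-template matches", **base)
    if Cm1 == 0:
        return SampEnResult(math.nan, defined=False,
                            reason="no (m+1)-template matches", **base)
    return SampEnResult(-math.log(Cm1 / Cm), **base)


def windowed_sample_entropy(
    dwells: DwellTimeSeries | np.ndarray,
    window: int = 4000,
    m: int = 2,
    r_factor: float = 0.2,
    variant: str = "printed",
) -> SampEnResult:
    """SampEn of a dwell-time series over non-overlapping windows.

    The series is the interleaved sequence of dwell durations.  Each window
    of ``window`` values gets its own threshold ``r = r_factor · σ(window)``;
    the mean ± standard error over windows is reported.  If the series is
    shorter than one window, the whole series is used as a single window
    (logged as a fallback).
    """
    x = (dwells.durations if isinstance(dwells, DwellTimeSeries)
         else np.asarray(dwells, dtype=float))
    if x.size < window:
        log.warning(
            "windowed_sample_entropy: %d dwells < window %d; "
            "falling back to a single whole-series window", x.size, window,
        )
        windows = [x]
        eff_window = x.size
    else:
        n_w = x.size // window
        windows = [x[i * window:(i + 1) * window] for i in range(n_w)]
        eff_window = window

    values = []
    n_undef = 0
    for w in windows:
        sigma = float(np.std(w))
        if sigma == 0:
            n_undef += 1
            continue
        res = sample_entropy(w, m=m, r=r_factor * sigma, variant=variant)
        if res.defined:
            values.append(res.value)
        else:
            n_undef += 1
    if n_undef:
        log.info("windowed_sample_entropy: %d window(s) undefined", n_undef)
    vals = np.array(values)
    base = dict(m=m, r=math.nan, n=int(x.size), variant=variant,
                window_length=eff_window, window_values=vals)
    if vals.size == 0:
        return SampEnResult(math.nan, defined=False,
                            reason="all windows undefined", se=math.nan, **base)
    se = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
    return SampEnResult(float(vals.mean()), se=se, **base)
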