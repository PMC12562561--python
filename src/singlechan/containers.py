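"""Shared in-memory containers for single-channel recordings.

The pipeline passes three core objects between stages: a sampled current
trace (:class:`CurrentTrace`), its binary open/closed idealization
(:class:`IdealizedTrace`) and the run-length-encoded dwell-time series
(:class:`DwellTimeSeries`).  All carry the experimental condition — the
quercetin and calcium concentrations in the bath, in micromolar — so that
every downstream table can be labelled without side channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True, order=True)
class Condition:
    """Experimental condition: activator concentrations in the bath (μM)."""

    que_um: float = 0.0
    ca_um: float = 0.0

    @property
    def label(self) -> str:
        return f"que{self.que_um:g}_ca{self.ca_um:g}"


CONTROL = Condition(0.0, 0.0)


@dataclass
class CurrentTrace:
    """Sampled single-channel current.

    Parameters
    ----------
    samples
        Current values in pA.
    sampling_rate
        Sampling rate in Hz (the acquisition default is 10 kHz, i.e. one
        sample every 100 μs).
    condition
        Bath condition the trace was recorded/simulated under.
    trace_id
        Free-form identifier used in output tables.
    amplifier_error
        Amplifier current resolution ΔI in pA, metadata only.
    """

    samples: np.ndarray
    sampling_rate: float
    condition: Condition = field(default_factory=Condition)
    trace_id: str = ""
    amplifier_error: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a current trace needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.trace_id!r} contains non-finite samples")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class IdealizedTrace:
    """Per-sample open/closed assignment produced by thresholding.

    ``states`` is a boolean array, True = open.  The threshold and the two
    conductance levels used to derive it are retained for provenance.
    """

    states: np.ndarray
    sampling_rate: float
    threshold: float
    closed_level: float
    open_level: float
    condition: Condition = field(default_factory=Condition)
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("idealized trace must be a non-empty 1-D state array")

    def __len__(self) -> int:
        return self.states.size


@dataclass
class DwellTimeSeries:
    """Alternating open/closed episode durations from an idealized trace.

    ``states`` (bool, True = open) and ``durations`` (seconds) have equal
    length and strictly alternate conducting class.  Durations are integer
    multiples of the sampling interval when extracted from a sampled trace.
    """

    states: np.ndarray
    durations: np.ndarray
    condition: Condition = field(default_factory=Condition)
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.states.shape != self.durations.shape:
            raise ValueError("states and durations must have equal length")
        if self.durations.size and not np.all(self.durations > 0):
            raise ValueError("dwell durations must be positive")
        if self.states.size > 1 and np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("dwell states must alternate open/closed")

    def __len__(self) -> int:
        return self.states.size

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def open_durations(self) -> np.ndarray:
        return self.durations[self.states]

    @property
    def closed_durations(self) -> np.ndarray:
        return self.durations[~self.states]

    @staticmethod
    def concat(parts: list["DwellTimeSeries"]) -> "DwellTimeSeries":
        """Pool several series into one (alternation is not enforced across
        the seams; used for population-level histograms)."""
        if not parts:
            raise ValueError("nothing to concatenate")
        states = np.concatenate([p.states for p in parts])
        durations = np.concatenate([p.durations for p in parts])
        out = DwellTimeSeries.__new__(DwellTimeSeries)
        out.states = states
        out.durations = durations
        out.condition = parts[0].condition
        out.trace_id = "+".join(p.trace_id for p in parts if p.trace_id)
        return out
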