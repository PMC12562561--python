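"""Reading and writing traces, event sequences and result tables.

Two trace formats are supported:

* CSV — ``time_s,current_pA`` columns preceded by ``# key: value`` metadata
  lines (``sampling_rate_hz`` is mandatory; ``que_um``, ``ca_um``,
  ``trace_id``, ``seed`` optional);
* raw — little-endian 32-bit floats in ``<name>.f32`` with a JSON sidecar
  ``<name>.json`` holding the same metadata.

Event sequences and dwell-time series are exported as ``state,duration_s``
CSV; idealized traces as ``time_s,state``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import Condition, CurrentTrace, DwellTimeSeries, IdealizedTrace
from .gating import EventSequence

__all__ = [
    "read_trace",
    "write_trace",
    "write_events",
    "write_dwells",
    "write_idealized",
]


def _metadata(trace: CurrentTrace) -> dict:
    md = {
        "sampling_rate_hz": trace.sampling_rate,
        "units": "pA",
        "que_um": trace.condition.que_um,
        "ca_um": trace.condition.ca_um,
        "trace_id": trace.trace_id,
    }
    if trace.seed is not None:
        md["seed"] = trace.seed
    return md


def write_trace(trace: CurrentTrace, path: str | Path, fmt: str = "csv") -> Path:
    """Write a trace; returns the path written (the CSV file or the ``.f32``
    payload whose JSON sidecar sits alongside)."""
    path = Path(path)
    if fmt == "csv":
        md = _metadata(trace)
        t = np.arange(len(trace)) / trace.sampling_rate
        with open(path, "w") as fh:
            for k, v in md.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("time_s,current_pA\n")
            for ti, ci in zip(t.tolist(), trace.samples.tolist()):
                fh.write(f"{ti!r},{ci!r}\n")
        return path
    if fmt == "float32":
        payload = path if path.suffix == ".f32" else path.with_suffix(".f32")
        trace.samples.astype("<f4").tofile(payload)
        payload.with_suffix(".json").write_text(
            json.dumps(_metadata(trace), indent=2))
        return payload
    raise ValueError(f"unknown trace format {fmt!r}")


def read_trace(
    path: str | Path,
    fmt: str | None = None,
    sampling_rate: float | None = None,
) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`.

    ``fmt`` is inferred from the suffix when omitted.  A CSV without a
    ``sampling_rate_hz`` metadata line is rejected unless ``sampling_rate``
    is supplied explicitly.
    """
    path = Path(path)
    if fmt is None:
        fmt = "float32" if path.suffix in (".f32", ".json") else "csv"
    if fmt == "csv":
        md: dict[str, str] = {}
        data_lines = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition(":")
                    md[key.strip()] = val.strip()
                elif line[0].isdigit() or line[0] in "+-.":
                    data_lines.append(line)
        rate = float(md["sampling_rate_hz"]) if "sampling_rate_hz" in md else sampling_rate
        if rate is None:
            raise ValueError(
                f"{path}: no sampling_rate_hz metadata; pass sampling_rate="
            )
        samples = np.array([float(l.split(",")[1]) for l in data_lines])
    elif fmt == "float32":
        payload = path if path.suffix == ".f32" else path.with_suffix(".f32")
        sidecar = payload.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
        md = json.loads(sidecar.read_text())
        if "sampling_rate_hz" not in md and sampling_rate is None:
            raise ValueError(f"{sidecar}: no sampling_rate_hz")
        rate = float(md.get("sampling_rate_hz", sampling_rate))
        samples = np.fromfile(payload, dtype="<f4").astype(float)
        if samples.size == 0:
            raise ValueError(f"{payload}: empty or truncated binary payload")
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    if np.any(~np.isfinite(samples)):
        raise ValueError(f"{path}: trace contains NaN/inf samples")
    cond = Condition(float(md.get("que_um", 0.0)), float(md.get("ca_um", 0.0)))
    seed = md.get("seed")
    return CurrentTrace(
        samples=samples,
        sampling_rate=rate,
        condition=cond,
        trace_id=str(md.get("trace_id", path.stem)),
        seed=int(seed) if seed not in (None, "", "None") else None,
    )


def write_events(events: EventSequence, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("state,duration_s\n")
        for lbl, dur in zip(events.state_labels, events.durations.tolist()):
            fh.write(f"{lbl},{dur!r}\n")
    return path


def write_dwells(dwells: DwellTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("state,duration_s\n")
        for open_, dur in zip(dwells.states, dwells.durations.tolist()):
            fh.write(f"{'O' if open_ else 'C'},{dur!r}\n")
    return path


def write_idealized(ideal: IdealizedTrace, path: str | Path) -> Path:
    path = Path(path)
    dt = 1.0 / ideal.sampling_rate
    with open(path, "w") as fh:
        fh.write("time_s,state\n")
        for i, s in enumerate(ideal.states):
            fh.write(f"{i * dt!r},{'O' if s else 'C'}\n")
    return path
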