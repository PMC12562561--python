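"""End-to-end pipeline: traces → idealization → entropies → spectra → EMD
clusters, per experimental condition.

The pipeline takes a :class:`PipelineConfig` describing, per condition,
either a list of trace files or a named synthetic regime to simulate, plus
all analysis parameters.  Exactly one condition is the unstimulated control;
the relative PSD and the control-rescaled dwell entropy are computed against
it.  One master seed fixes every stochastic stage (simulation noise and the
K-means restarts), so a rerun from the same config is byte-identical.

Outputs per run: a CSV table per result family (entropies, p_open, PSDs,
relative PSDs, peak entropies, IMF features, cluster summaries), plus a JSON
run manifest recording the config, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import Condition, CurrentTrace, DwellTimeSeries
from .clustering import ClusterSummary, HistogramGrid, cluster_condition
from .emd import IMFFeature, decompose_trace_windows
from .entropy import (SampEnResult, default_dwell_edges, dwell_histogram,
                      windowed_sample_entropy)
from .gating import (GatingModel, make_regime, render_current_trace,
                     simulate_event_sequence, stationary_open_probability)
from .idealize import idealize_trace
from .io import read_trace
from .spectral import (PeakEntropyResult, PowerSpectrum, RelativePowerSpectrum,
                       median_psd, peak_entropy, periodogram_psd,
                       relative_psd, windowed_spectra)

__all__ = ["ConditionSpec", "PipelineParams", "PipelineConfig",
           "ConditionSummary", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class ConditionSpec:
    """One experimental condition: either trace files or a synthetic regime."""

    condition: Condition
    files: list[str] = field(default_factory=list)
    regime: str | None = None
    n_traces: int = 3
    duration: float = 20.0       # seconds per synthetic trace

    def __post_init__(self) -> None:
        if bool(self.files) == (self.regime is not None):
            raise ValueError("give either trace files or a synthetic regime")


@dataclass
class PipelineParams:
    """All analysis parameters, with the acquisition-scale defaults."""

    segment_length: int = 2**14        # periodogram segment (samples)
    spectral_window_s: float = 0.0128  # short-time window width (12.8 ms)
    spectral_stride: int | None = None  # default W//2
    k_bins: int = 1000                 # peak-entropy histogram bins
    emd_window: int = 100_000          # samples per EMD window
    emd_max_imfs: int = 12
    sampen_window: int = 4000          # dwells per SampEn window
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    k_clusters: int = 6
    dwell_bins_per_decade: int = 8
    grid: HistogramGrid = field(default_factory=HistogramGrid)

    def validate(self) -> None:
        checks = [self.segment_length >= 8, self.spectral_window_s > 0,
                  self.k_bins >= 2, self.emd_window >= 8,
                  self.sampen_window > self.sampen_m + 1,
                  self.sampen_r_factor > 0, self.k_clusters >= 1]
        if not all(checks):
            raise ValueError("pipeline parameters out of range")


@dataclass
class PipelineConfig:
    conditions: list[ConditionSpec]
    control: Condition = field(default_factory=Condition)
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("manifest is empty")
        matches = [c for c in self.conditions if c.condition == self.control]
        if len(matches) != 1:
            raise ValueError("exactly one condition must be the control")
        self.params.validate()


@dataclass
class ConditionSummary:
    """Per-condition pipeline outputs."""

    condition: Condition
    n_traces: int = 0
    n_dwells: int = 0
    p_open_mean: float = float("nan")
    p_open_se: float = float("nan")
    p_open_analytic: float | None = None   # synthetic conditions only
    dwell_entropy_bits: float = float("nan")
    dwell_entropy_vs_control: float = float("nan")  # ratio to control
    sampen: SampEnResult | None = None
    median_spectrum: PowerSpectrum | None = None
    relative_spectrum: RelativePowerSpectrum | None = None
    peak_entropy: PeakEntropyResult | None = None
    clusters: list[ClusterSummary] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    conditions = []
    for entry in raw.get("conditions", []):
        cond = Condition(float(entry.get("que_um", 0.0)),
                         float(entry.get("ca_um", 0.0)))
        conditions.append(ConditionSpec(
            condition=cond,
            files=entry.get("files", []),
            regime=entry.get("regime"),
            n_traces=int(entry.get("n_traces", 3)),
            duration=float(entry.get("duration", 20.0)),
        ))
    ctrl = raw.get("control", {})
    control = Condition(float(ctrl.get("que_um", 0.0)),
                        float(ctrl.get("ca_um", 0.0)))
    params = PipelineParams(**raw.get("params", {}))
    return PipelineConfig(conditions=conditions, control=control,
                          params=params, seed=int(raw.get("seed", 0)))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _condition_seed(master: int, index: int) -> int:
    """Derive a per-condition 31-bit seed from the master seed."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0]
               % (2**31))


def _gather_traces(spec: ConditionSpec, seed: int
                   ) -> tuple[list[CurrentTrace], GatingModel | None]:
    if spec.files:
        return [read_trace(f) for f in spec.files], None
    model = make_regime(spec.regime, condition=spec.condition)
    traces = []
    for t in range(spec.n_traces):
        trace_seed = int(np.random.SeedSequence([seed, t]).generate_state(1)[0]
                         % (2**31))
        events = simulate_event_sequence(model, spec.duration, trace_seed)
        traces.append(render_current_trace(
            events, model, trace_seed,
            trace_id=f"{spec.condition.label}_t{t}"))
    return traces, model


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None
                 ) -> dict[Condition, ConditionSummary]:
    """Run every stage for every condition; optionally write all outputs.

    A failing stage is recorded in the condition's ``errors`` and the
    remaining stages still run where their inputs exist.
    """
    t0 = time.time()
    p = config.params
    summaries: dict[Condition, ConditionSummary] = {}
    dwells_by_cond: dict[Condition, DwellTimeSeries] = {}
    traces_by_cond: dict[Condition, list[CurrentTrace]] = {}
    features_by_cond: dict[Condition, list[IMFFeature]] = {}
    edges = default_dwell_edges(bins_per_decade=p.dwell_bins_per_decade)

    for idx, spec in enumerate(config.conditions):
        cond = spec.condition
        s = ConditionSummary(condition=cond)
        summaries[cond] = s
        cseed = _condition_seed(config.seed, idx)
        try:
            traces, model = _gather_traces(spec, cseed)
        except Exception as exc:  # noqa: BLE001 - per-condition isolation
            s.errors["input"] = str(exc)
            continue
        traces_by_cond[cond] = traces
        s.n_traces = len(traces)
        if model is not None:
            s.p_open_analytic = stationary_open_probability(model)

        # --- idealization, p_open, dwell series
        try:
            p_opens, dwell_parts = [], []
            for tr in traces:
                if model is not None:
                    _, dw, po = idealize_trace(
                        tr, model.closed_level, model.open_level)
                else:
                    _, dw, po = idealize_trace(tr)
                p_opens.append(po)
                dwell_parts.append(dw)
            pooled = DwellTimeSeries.concat(dwell_parts)
            dwells_by_cond[cond] = pooled
            s.n_dwells = len(pooled)
            s.p_open_mean = float(np.mean(p_opens))
            s.p_open_se = (float(np.std(p_opens, ddof=1)
                                 / np.sqrt(len(p_opens)))
                           if len(p_opens) > 1 else float("nan"))
        except Exception as exc:  # noqa: BLE001
            s.errors["idealize"] = str(exc)
            continue

        # --- entropies of dwell times
        try:
            s.dwell_entropy_bits = dwell_histogram(pooled, edges).entropy_bits()
            s.sampen = windowed_sample_entropy(
                pooled, window=p.sampen_window, m=p.sampen_m,
                r_factor=p.sampen_r_factor)
        except Exception as exc:  # noqa: BLE001
            s.errors["entropy"] = str(exc)

        # --- PSDs
        try:
            spectra = [periodogram_psd(tr, p.segment_length) for tr in traces]
            s.median_spectrum = median_psd(spectra)
        except Exception as exc:  # noqa: BLE001
            s.errors["psd"] = str(exc)

        # --- EMD features and clusters
        try:
            feats: list[IMFFeature] = []
            for tr in traces:
                feats.extend(decompose_trace_windows(
                    tr, window=p.emd_window, max_imfs=p.emd_max_imfs))
            features_by_cond[cond] = feats
            _, _, s.clusters = cluster_condition(
                feats, grid=p.grid, k=p.k_clusters, seed=cseed)
        except Exception as exc:  # noqa: BLE001
            s.errors["emd"] = str(exc)

    # --- cross-condition stages: relative PSD, dwell-entropy rescale
    ctrl = summaries.get(config.control)
    if ctrl is not None and ctrl.median_spectrum is not None:
        for cond, s in summaries.items():
            if s.median_spectrum is not None:
                s.relative_spectrum = relative_psd(s.median_spectrum,
                                                   ctrl.median_spectrum)
    if ctrl is not None and np.isfinite(ctrl.dwell_entropy_bits) \
            and ctrl.dwell_entropy_bits > 0:
        for s in summaries.values():
            s.dwell_entropy_vs_control = (s.dwell_entropy_bits
                                          / ctrl.dwell_entropy_bits)

    # --- windowed spectra + peak entropy pooled across all conditions
    try:
        ws = {}
        for cond, traces in traces_by_cond.items():
            fs = traces[0].sampling_rate
            W = int(round(p.spectral_window_s * fs))
            ws[cond] = windowed_spectra(traces, W=W, stride=p.spectral_stride)
        if ws:
            for cond, res in peak_entropy(ws, k_bins=p.k_bins).items():
                summaries[cond].peak_entropy = res
    except Exception as exc:  # noqa: BLE001
        for s in summaries.values():
            s.errors.setdefault("peak_entropy", str(exc))

    if outdir is not None:
        _write_outputs(Path(outdir), config, summaries, features_by_cond,
                       elapsed=time.time() - t0)
    return summaries


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def _cond_cols(cond: Condition) -> dict:
    return {"condition": cond.label, "que_um": cond.que_um, "ca_um": cond.ca_um}


def _write_outputs(outdir: Path, config: PipelineConfig,
                   summaries: dict[Condition, ConditionSummary],
                   features: dict[Condition, list[IMFFeature]],
                   elapsed: float) -> None:
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for cond, s in summaries.items():
        base = _cond_cols(cond)
        rows.append({**base, "metric": "p_open", "value": s.p_open_mean,
                     "se": s.p_open_se, "n_windows": s.n_traces})
        if s.p_open_analytic is not None:
            rows.append({**base, "metric": "p_open_analytic",
                         "value": s.p_open_analytic, "se": np.nan,
                         "n_windows": np.nan})
        rows.append({**base, "metric": "dwell_shannon_bits",
                     "value": s.dwell_entropy_bits, "se": np.nan,
                     "n_windows": s.n_dwells})
        rows.append({**base, "metric": "dwell_shannon_vs_control",
                     "value": s.dwell_entropy_vs_control, "se": np.nan,
                     "n_windows": np.nan})
        if s.sampen is not None:
            nw = (s.sampen.window_values.size
                  if s.sampen.window_values is not None else 0)
            rows.append({**base, "metric": "sampen", "value": s.sampen.value,
                         "se": s.sampen.se, "n_windows": nw})
    pd.DataFrame(rows).to_csv(outdir / "entropy_results.csv", index=False)

    for cond, s in summaries.items():
        if s.median_spectrum is not None:
            pd.DataFrame({
                "frequency_hz": s.median_spectrum.frequencies,
                "power": s.median_spectrum.power,
            }).to_csv(outdir / f"psd_{cond.label}.csv", index=False)
        if s.relative_spectrum is not None:
            pd.DataFrame({
                "frequency_hz": s.relative_spectrum.frequencies,
                "ratio": s.relative_spectrum.ratio,
            }).to_csv(outdir / f"relative_psd_{cond.label}.csv", index=False)
        if s.peak_entropy is not None:
            pd.DataFrame({
                "frequency_hz": s.peak_entropy.frequencies,
                "entropy_bits": s.peak_entropy.entropy_bits,
            }).to_csv(outdir / f"peak_entropy_{cond.label}.csv", index=False)

    feat_rows = [{**_cond_cols(c), "trace_id": f.trace_id,
                  "window_idx": f.window_idx, "imf_idx": f.imf_idx,
                  "frequency_hz": f.frequency, "energy": f.energy}
                 for c, fl in features.items() for f in fl]
    if feat_rows:
        pd.DataFrame(feat_rows).to_csv(outdir / "imf_features.csv", index=False)

    cl_rows = [{**_cond_cols(c), "cluster": cl.cluster,
                "centroid_freq_hz": cl.centroid_frequency,
                "centroid_energy": cl.centroid_energy,
                "occupancy": cl.occupancy, "entropy_bits": cl.entropy_bits}
               for c, s in summaries.items() for cl in s.clusters]
    if cl_rows:
        pd.DataFrame(cl_rows).to_csv(outdir / "cluster_summaries.csv",
                                     index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "control": _cond_cols(config.control),
        "params": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                       else v)
                   for k, v in dataclasses.asdict(config.params).items()},
        "conditions": [
            {**_cond_cols(c.condition), "regime": c.regime,
             "files": c.files, "n_traces": c.n_traces,
             "duration_s": c.duration}
            for c in config.conditions
        ],
        "errors": {c.label: s.errors for c, s in summaries.items() if s.errors},
        "elapsed_s": round(elapsed, 3),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
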