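"""Full-run orchestration: metrics → fits → phases → kinetics → MCR.

One configuration drives the whole multimodal analysis of a sample and
writes a fixed set of CSV outputs plus a machine-readable JSON report.
Stages whose inputs are absent are skipped (a SANS-only run is valid);
the methanol pathway stops at the network-stage fits, since no
correlation peak exists to cluster.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import synthetic
from .clustering import cluster_phases
from .kinetics import fit_sigmoid, landmarks, tht_trace, turbidity_trace
from .mcr import build_joint_matrix, correlation_map, envelopes, select_rank
from .metrics import DEFAULT_PEAK_WINDOW, metric_traces
from .model import CLUSTER_PARAMS, fit_series

__all__ = ["RunConfig", "RunReport", "run_full"]

log = logging.getLogger("silkgel")


@dataclass
class RunConfig:
    """Configuration of one full run.

    Either ``manifest`` points at a frame-series manifest on disk, or
    ``simulate`` is true and the packaged synthetic reference (driven by
    ``seed``) is analysed.  Optional trace/spectra paths add the optical
    and FTIR stages.
    """

    outdir: Path
    manifest: Path | None = None
    simulate: bool = False
    seed: int = 1
    mode: str = "gdl"
    tht_path: Path | None = None
    emission_path: Path | None = None
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW
    eps: float = 1.0
    min_samples: int = 5
    mcr_k: int = 3
    mcr_restarts: int = 4
    noise: float = 0.02

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outdir", "manifest", "tht_path", "emission_path"):
            if raw.get(key) is not None:
                raw[key] = Path(path).parent / raw[key]
        if "peak_window" in raw:
            raw["peak_window"] = tuple(raw["peak_window"])
        if "outdir" not in raw:
            raise ValueError("config must set outdir")
        cfg = cls(**raw)
        if cfg.manifest is not None and not Path(cfg.manifest).exists():
            raise FileNotFoundError(cfg.manifest)
        if not cfg.simulate and cfg.manifest is None:
            raise ValueError("config needs either a manifest or simulate: true")
        return cfg


@dataclass
class RunReport:
    """Stage status, landmark table, phase summary and file inventory."""

    stages: dict[str, str] = field(default_factory=dict)
    landmarks: dict[str, float | None] = field(default_factory=dict)
    phase_summary: list[dict] = field(default_factory=list)
    mcr_lack_of_fit: float | None = None
    mcr_rank_suggestion: int | None = None
    files: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(o)

        return json.dumps(self.__dict__, indent=2, default=default)


def _register(report: RunReport, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    report.files[path.name] = digest


def run_full(config: RunConfig) -> RunReport:
    """Execute all stages in order and write outputs under config.outdir.

    Deterministic given the config seed: re-running reproduces
    byte-identical CSVs.  A hard error in any stage aborts with a partial
    report naming the stage (written to disk before re-raising).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    stage = "load"
    try:
        tht = turb = ph = emission = None
        if config.simulate:
            if config.mode == "methanol":
                series = synthetic.simulate_methanol_series(
                    noise=config.noise, seed=config.seed + 1
                )
                tht = synthetic.simulate_tht(noise=0.02, seed=config.seed + 2)
            else:
                data = synthetic.reference_dataset(
                    seed=config.seed, noise=config.noise
                )
                series = data["sans"]
                tht, turb, ph, emission = (
                    data["tht"], data["turbidity"], data["ph"], data["emission"]
                )
        else:
            series = sio.read_series(config.manifest)
            if config.tht_path is not None:
                tht = sio.read_trace(config.tht_path, "tht")
            if config.emission_path is not None:
                emission = sio.read_spectra(config.emission_path,
                                            "fluorescence_emission")
                tht = tht or tht_trace(emission)
                turb = turbidity_trace(emission)
        report.stages[stage] = "ok"

        stage = "metrics"
        t0 = _time.perf_counter()
        mt = metric_traces(series, peak_window=config.peak_window)
        mt.to_frame().to_csv(outdir / "metrics.csv", index=False)
        _register(report, outdir / "metrics.csv")
        report.landmarks["t_q_plus"] = mt.t_q_plus
        report.landmarks["t_q_on"] = mt.t_q_on
        report.stages[stage] = f"ok ({_time.perf_counter() - t0:.1f}s)"

        stage = "fit"
        t0 = _time.perf_counter()
        mode = config.mode if config.mode else series.trigger
        traj = fit_series(series, mode=mode)
        traj.to_frame().to_csv(outdir / "fits.csv", index=False)
        _register(report, outdir / "fits.csv")
        report.stages[stage] = f"ok ({_time.perf_counter() - t0:.1f}s)"

        if mode == "gdl":
            stage = "phases"
            t0 = _time.perf_counter()
            assignment = cluster_phases(
                traj, eps=config.eps, min_samples=config.min_samples
            )
            assignment.to_frame().to_csv(outdir / "phases.csv", index=False)
            assignment.summary().to_csv(outdir / "phase_summary.csv", index=False)
            _register(report, outdir / "phases.csv")
            _register(report, outdir / "phase_summary.csv")
            report.phase_summary = assignment.summary().to_dict("records")
            report.stages[stage] = f"ok ({_time.perf_counter() - t0:.1f}s)"
        else:
            report.stages["phases"] = "skipped (methanol mode: no peak stage)"

        if tht is not None:
            stage = "kinetics"
            fit = fit_sigmoid(tht)
            lm = landmarks(fit, tht)
            table = pd.DataFrame(
                [{
                    "sample": series.sample_label,
                    "tht_on": lm.tht_on, "tht_m": lm.tht_m, "tht_p": lm.tht_p,
                    "A": fit.A, "tau": fit.tau, "baseline": fit.baseline,
                }]
            )
            table.to_csv(outdir / "landmarks.csv", index=False)
            _register(report, outdir / "landmarks.csv")
            report.landmarks.update(
                tht_on=lm.tht_on, tht_m=lm.tht_m, tht_p=lm.tht_p
            )
            report.stages[stage] = "ok"
        else:
            report.stages["kinetics"] = "skipped (no ThT trace)"

        if emission is not None and mode == "gdl":
            stage = "mcr"
            t0 = _time.perf_counter()
            joint = build_joint_matrix(series, emission)
            report.mcr_rank_suggestion = select_rank(joint)[0]
            result = envelopes(
                joint, k=config.mcr_k, n_restarts=config.mcr_restarts,
                seed=config.seed,
            )
            result.profiles_frame().to_csv(outdir / "mcr_C.csv", index=False)
            pd.DataFrame(result.S_sans,
                         columns=[f"C{i+1}" for i in range(result.k)]).assign(
                q=joint.sans_q
            ).to_csv(outdir / "mcr_S_sans.csv", index=False)
            pd.DataFrame(result.S_fluor,
                         columns=[f"C{i+1}" for i in range(result.k)]).assign(
                wavelength=joint.fluor_axis
            ).to_csv(outdir / "mcr_S_fluor.csv", index=False)
            for name in ("mcr_C.csv", "mcr_S_sans.csv", "mcr_S_fluor.csv"):
                _register(report, outdir / name)
            report.mcr_lack_of_fit = result.lack_of_fit

            # correlation bubble matrix: 8 parameters + ThT + turbidity
            fit_df = traj.to_frame().dropna(subset=["a"])
            signals: dict = {
                p: (fit_df["time_min"].to_numpy(), fit_df[p].to_numpy())
                for p in CLUSTER_PARAMS
            }
            signals["tht"] = tht
            if turb is not None:
                signals["turbidity"] = turb
            cm = correlation_map(result, signals)
            cm.to_csv(outdir / "correlations.csv")
            _register(report, outdir / "correlations.csv")
            report.stages[stage] = f"ok ({_time.perf_counter() - t0:.1f}s)"
        else:
            report.stages["mcr"] = "skipped (no emission series or methanol mode)"

        if ph is not None:
            sio.write_trace(outdir / "ph.csv", ph)
            _register(report, outdir / "ph.csv")
    except Exception as exc:
        report.stages[stage] = f"error: {exc}"
        (outdir / "report.json").write_text(report.to_json())
        raise
    (outdir / "report.json").write_text(report.to_json())
    return report
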