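"""Domain containers and CSV interchange for the multimodal gelation data.

The pipeline consumes four kinds of measured series:

* reduced 1-D small-angle scattering frames (``ScatteringCurve`` /
  ``CurveSeries``), one CSV per frame plus a manifest carrying frame times
  and sample metadata;
* scalar kinetic traces (``KineticTrace``) — ThT fluorescence, the 450 nm
  turbidity proxy, off-line pH, FTIR band intensities — as two-column CSV;
* spectral series (``SpectrumSeries``) — fluorescence emission or FTIR
  amide-I spectra — as wide CSV, first column the axis, one column per
  time point.

All times are minutes since the gelation trigger (GdL or methanol) was
added; frames keep absolute times and are never re-zeroed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScatteringCurve",
    "CurveSeries",
    "KineticTrace",
    "SpectrumSeries",
    "CurveParseError",
    "CurveValidationError",
    "read_curve",
    "write_curve",
    "read_series",
    "write_series",
    "read_trace",
    "write_trace",
    "read_spectra",
    "write_spectra",
    "align_to_frames",
    "resample_trace",
]

#: relative tolerance for deciding two q grids are "the same grid"
Q_GRID_RTOL = 1e-6

TRACE_KINDS = ("tht", "turbidity", "ph", "ftir_band")
SPECTRUM_KINDS = ("fluorescence_emission", "ftir")


class CurveParseError(ValueError):
    """A curve file could not be parsed."""


class CurveValidationError(ValueError):
    """Parsed data violate a container invariant."""


@dataclass(frozen=True)
class ScatteringCurve:
    """One reduced 1-D scattering frame.

    Parameters
    ----------
    q
        Scattering vector grid, Å⁻¹; strictly increasing and positive.
    intensity
        Absolute intensity I(q), cm⁻¹.  Non-finite or non-positive rows are
        retained but marked in :attr:`flagged`; the fit layer decides what
        to exclude (the log transform is undefined there).
    uncertainty
        Optional per-point dI, cm⁻¹.
    time_min
        Acquisition time since trigger addition, minutes.
    """

    q: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None
    time_min: float = 0.0
    flagged: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.shape != q.shape:
            raise CurveValidationError("q and intensity must be 1-D and equal length")
        if self.uncertainty is not None:
            u = np.asarray(self.uncertainty, dtype=float)
            if u.shape != q.shape:
                raise CurveValidationError("uncertainty length mismatch")
            object.__setattr__(self, "uncertainty", u)
        if q.size and (not np.all(np.isfinite(q)) or np.any(q <= 0)):
            raise CurveValidationError("q must be finite and positive")
        if q.size > 1 and np.any(np.diff(q) <= 0):
            raise CurveValidationError("q must be strictly increasing")
        flagged = ~np.isfinite(i) | (i <= 0)
        object.__setattr__(self, "flagged", flagged)

    def __len__(self) -> int:
        return self.q.size

    @property
    def usable(self) -> np.ndarray:
        """Mask of points safe for log-space fitting (finite, I > 0)."""
        return ~self.flagged

    def with_intensity(self, intensity: np.ndarray) -> "ScatteringCurve":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass(frozen=True)
class CurveSeries:
    """Time-ordered scattering frames of one sample on a common q grid."""

    frames: tuple[ScatteringCurve, ...]
    sample_label: str = ""
    trigger: str = "gdl"  # "gdl" | "methanol"
    gdl_percent: float | None = None
    methanol_percent: float | None = None
    rsf_mg_ml: float | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if self.trigger not in ("gdl", "methanol"):
            raise CurveValidationError(f"unknown trigger {self.trigger!r}")
        times = np.array([f.time_min for f in frames])
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise CurveValidationError("frame times must be strictly increasing")
        if frames:
            q0 = frames[0].q
            for f in frames[1:]:
                if f.q.shape != q0.shape or not np.allclose(
                    f.q, q0, rtol=Q_GRID_RTOL, atol=0.0
                ):
                    raise CurveValidationError(
                        "frames do not share a q grid (beyond tolerance); "
                        "re-reduce or harmonise before constructing a series"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_min for f in self.frames])

    @property
    def q(self) -> np.ndarray:
        if not self.frames:
            raise CurveValidationError("empty series has no q grid")
        return self.frames[0].q

    def intensity_matrix(self) -> np.ndarray:
        """Frames stacked as a (n_frames, n_q) matrix."""
        return np.vstack([f.intensity for f in self.frames])


@dataclass(frozen=True)
class KineticTrace:
    """A scalar signal versus time (ThT, turbidity proxy, pH, FTIR band)."""

    time_min: np.ndarray
    value: np.ndarray
    kind: str = "tht"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "value", v)
        if t.shape != v.shape or t.ndim != 1:
            raise CurveValidationError("time and value must be 1-D, equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise CurveValidationError("trace times must be strictly increasing")
        if self.kind not in TRACE_KINDS:
            raise CurveValidationError(f"unknown trace kind {self.kind!r}")

    def __len__(self) -> int:
        return self.time_min.size


@dataclass(frozen=True)
class SpectrumSeries:
    """Spectra sharing one axis, one spectrum per time point.

    ``axis`` is wavelength (nm) for fluorescence emission or wavenumber
    (cm⁻¹) for FTIR; ``spectra`` has shape (n_times, n_axis).
    """

    axis: np.ndarray
    spectra: np.ndarray
    time_min: np.ndarray
    kind: str = "fluorescence_emission"

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        sp = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        t = np.asarray(self.time_min, dtype=float)
        object.__setattr__(self, "axis", ax)
        object.__setattr__(self, "spectra", sp)
        object.__setattr__(self, "time_min", t)
        if sp.shape != (t.size, ax.size):
            raise CurveValidationError(
                f"spectra shape {sp.shape} != (n_times={t.size}, n_axis={ax.size})"
            )
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise CurveValidationError("spectra times must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise CurveValidationError(f"unknown spectrum kind {self.kind!r}")

    def __len__(self) -> int:
        return self.time_min.size


# ---------------------------------------------------------------------------
# readers / writers

DEFAULT_DIALECT = {"q": "q", "intensity": "I", "uncertainty": "dI"}


def read_curve(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    time_min: float = 0.0,
) -> ScatteringCurve:
    """Read one reduced curve from CSV.

    ``dialect`` maps the logical names ``q``, ``intensity``, ``uncertainty``
    to the file's column headers (deposited data sets vary); files without a
    recognisable header are read positionally as (q, I[, dI]).
    Rows with non-finite or non-positive intensity are kept and flagged,
    never dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = {**DEFAULT_DIALECT, **(dialect or {})}
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise CurveParseError(f"{path}: {exc}") from exc
    if cols["q"] in df.columns:
        q = df[cols["q"]]
        i = df[cols["intensity"]]
        u = df[cols["uncertainty"]] if cols["uncertainty"] in df.columns else None
    else:
        # no header match: re-read headerless, positional columns
        try:
            df = pd.read_csv(path, comment="#", header=None,
                             float_precision="round_trip")
            df = df.apply(pd.to_numeric, errors="raise")
        except Exception as exc:
            raise CurveParseError(f"{path}: not numeric and no known header") from exc
        if df.shape[1] < 2:
            raise CurveParseError(f"{path}: need at least 2 numeric columns")
        q, i = df.iloc[:, 0], df.iloc[:, 1]
        u = df.iloc[:, 2] if df.shape[1] >= 3 else None
    q = pd.to_numeric(q, errors="coerce").to_numpy()
    if np.any(~np.isfinite(q)):
        bad = int(np.flatnonzero(~np.isfinite(q))[0]) + 2  # 1-based + header
        raise CurveParseError(f"{path}: non-numeric q at line {bad}")
    return ScatteringCurve(
        q=q,
        intensity=pd.to_numeric(i, errors="coerce").to_numpy(),
        uncertainty=None if u is None else pd.to_numeric(u, errors="coerce").to_numpy(),
        time_min=time_min,
    )


def write_curve(path: str | Path, curve: ScatteringCurve) -> None:
    data = {"q": curve.q, "I": curve.intensity}
    if curve.uncertainty is not None:
        data["dI"] = curve.uncertainty
    # %.17g round-trips float64 exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def _load_manifest(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def read_series(manifest: str | Path, dialect: Mapping[str, str] | None = None) -> CurveSeries:
    """Read a frame series from a manifest (YAML or JSON).

    The manifest lists per-frame files and acquisition times::

        sample_label: RSF 10 mg/ml, 1% GdL
        trigger: gdl
        gdl_percent: 1.0
        rsf_mg_ml: 10.0
        frames:
          - {path: frames/frame_0001.csv, time_min: 5}
          - {path: frames/frame_0002.csv, time_min: 10}

    Frames are returned sorted by time; duplicate timestamps and q grids
    differing beyond a relative 1e-6 are errors.
    """
    mpath = Path(manifest)
    meta = _load_manifest(mpath)
    entries = meta.get("frames", [])
    if not entries:
        raise CurveValidationError(f"{mpath}: manifest lists no frames")
    times = [float(e["time_min"]) for e in entries]
    if len(set(times)) != len(times):
        raise CurveValidationError(f"{mpath}: duplicate frame timestamps")
    order = np.argsort(times)
    frames = []
    for k in order:
        e = entries[int(k)]
        fpath = mpath.parent / e["path"]
        frames.append(read_curve(fpath, dialect=dialect, time_min=float(e["time_min"])))
    return CurveSeries(
        frames=tuple(frames),
        sample_label=str(meta.get("sample_label", "")),
        trigger=str(meta.get("trigger", "gdl")),
        gdl_percent=meta.get("gdl_percent"),
        methanol_percent=meta.get("methanol_percent"),
        rsf_mg_ml=meta.get("rsf_mg_ml"),
    )


def write_series(directory: str | Path, series: CurveSeries) -> Path:
    """Write frames + manifest under ``directory``; returns the manifest path."""
    directory = Path(directory)
    (directory / "frames").mkdir(parents=True, exist_ok=True)
    entries = []
    for k, f in enumerate(series.frames):
        rel = f"frames/frame_{k:04d}.csv"
        write_curve(directory / rel, f)
        entries.append({"path": rel, "time_min": float(f.time_min)})
    meta = {
        "sample_label": series.sample_label,
        "trigger": series.trigger,
        "gdl_percent": series.gdl_percent,
        "methanol_percent": series.methanol_percent,
        "rsf_mg_ml": series.rsf_mg_ml,
        "frames": entries,
    }
    mpath = directory / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(meta, sort_keys=False))
    return mpath


def read_trace(path: str | Path, kind: str) -> KineticTrace:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return KineticTrace(
        time_min=df.iloc[:, 0].to_numpy(float),
        value=df.iloc[:, 1].to_numpy(float),
        kind=kind,
    )


def write_trace(path: str | Path, trace: KineticTrace) -> None:
    pd.DataFrame({"time_min": trace.time_min, "value": trace.value}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_spectra(path: str | Path, kind: str) -> SpectrumSeries:
    """Read a wide-CSV spectral series: first column axis, one column per time.

    Column headers after the first are the times in minutes.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    axis = df.iloc[:, 0].to_numpy(float)
    times = np.array([float(c) for c in df.columns[1:]])
    spectra = df.iloc[:, 1:].to_numpy(float).T
    return SpectrumSeries(axis=axis, spectra=spectra, time_min=times, kind=kind)


def write_spectra(path: str | Path, series: SpectrumSeries) -> None:
    df = pd.DataFrame(series.spectra.T, columns=[f"{t:g}" for t in series.time_min])
    df.insert(0, "axis", series.axis)
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# time alignment


def resample_trace(trace: KineticTrace, times: np.ndarray) -> KineticTrace:
    """Linearly interpolate a trace onto ``times``, truncated to the overlap."""
    times = np.asarray(times, dtype=float)
    lo, hi = trace.time_min[0], trace.time_min[-1]
    keep = (times >= lo) & (times <= hi)
    if not np.any(keep):
        raise CurveValidationError("trace and target times do not overlap")
    t = times[keep]
    return KineticTrace(
        time_min=t,
        value=np.interp(t, trace.time_min, trace.value),
        kind=trace.kind,
    )


def align_to_frames(trace: KineticTrace, series: CurveSeries) -> KineticTrace:
    """Resample a kinetic trace onto the SANS frame times.

    Linear interpolation, truncated to the interval where the trace and the
    frame grid overlap, so downstream correlation analysis sees matched time
    points.
    """
    return resample_trace(trace, series.times)
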