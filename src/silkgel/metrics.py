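"""Model-free per-frame scattering metrics and their time traces.

Three quantities are tracked without any model fitting: the apparent
scattering invariant Q* (the integral of I(q)·q² over the measured
q-range, a proxy for the total contrast from nanoscale density
fluctuations), the mid-q correlation-peak position q⁺ and its intensity
I(q⁺), and the mean low-q intensity.  Two landmark times are derived from
the I(q⁺) trace: the time of its maximum, t(q⁺), and the onset of its
second rise, t(q_on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .io import CurveSeries, ScatteringCurve

__all__ = [
    "FrameMetrics",
    "MetricTraces",
    "DEFAULT_PEAK_WINDOW",
    "DEFAULT_LOW_Q_MAX",
    "apparent_invariant",
    "find_correlation_peak",
    "low_q_intensity",
    "metric_traces",
]

#: mid-q window searched for the correlation peak, Å⁻¹
DEFAULT_PEAK_WINDOW = (0.013, 0.025)
#: upper edge of the low-q averaging window, Å⁻¹ (well below the peak window)
DEFAULT_LOW_Q_MAX = 0.003


@dataclass(frozen=True)
class FrameMetrics:
    """Model-free metrics of one frame.

    ``q_plus``/``i_q_plus`` are NaN when the frame shows no detectable
    peak; ``i_mid`` is the intensity at the series' reference peak
    position (the median detected q⁺), defined for every frame of a
    series that shows a peak at all — it is the trace the landmark times
    are read from.
    """

    time_min: float
    q_star: float
    i_low_q: float
    q_plus: float = float("nan")
    i_q_plus: float = float("nan")
    i_mid: float = float("nan")

    @property
    def has_peak(self) -> bool:
        return np.isfinite(self.q_plus)


@dataclass(frozen=True)
class MetricTraces:
    """Per-frame metrics plus the landmark times of the I(q⁺) trace."""

    frames: tuple[FrameMetrics, ...]
    t_q_plus: float | None
    t_q_on: float | None

    def __len__(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": [f.time_min for f in self.frames],
                "q_plus": [f.q_plus for f in self.frames],
                "i_q_plus": [f.i_q_plus for f in self.frames],
                "i_mid": [f.i_mid for f in self.frames],
                "i_low_q": [f.i_low_q for f in self.frames],
                "q_star": [f.q_star for f in self.frames],
            }
        )


def apparent_invariant(curve: ScatteringCurve) -> float:
    """Trapezoidal integral of I(q)·q² over the measured grid only.

    No Porod or Guinier extrapolation is applied — this is the *apparent*
    invariant on the accessible q-window, so it shows apparent temporal
    evolution.  Non-finite intensities are excluded; negative intensities
    contribute negatively (they are flagged upstream).
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 points to integrate")
    ok = np.isfinite(curve.intensity)
    q, i = curve.q[ok], curve.intensity[ok]
    if q.size < 2:
        raise ValueError("fewer than 2 finite intensities")
    return float(np.trapezoid(i * q**2, q))


def find_correlation_peak(
    curve: ScatteringCurve,
    window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    smooth: bool = False,
    min_prominence: float = 0.0,
    min_rel_prominence: float = 0.0,
) -> tuple[float, float] | None:
    """Most prominent strict local maximum of I(q) inside the mid-q window.

    Returns ``(q_plus, i_q_plus)`` or ``None`` when the window holds no
    local maximum (e.g. a monotone power law).  Prominence is computed on
    the raw intensity by default; ``smooth`` applies a 3-point moving
    average first for noisy data.  ``min_prominence`` is an absolute
    threshold; ``min_rel_prominence`` demands prominence be at least that
    fraction of the intensity at the candidate, which rejects noise bumps
    uniformly when the noise scales with intensity.  Equal prominences
    break toward the smaller q.  The reported intensity is always read
    from the raw curve.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("empty window")
    if lo < curve.q[0] or hi > curve.q[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] not inside measured range "
            f"[{curve.q[0]}, {curve.q[-1]}]"
        )
    y = curve.intensity.astype(float)
    if smooth:
        y = np.convolve(y, np.ones(3), mode="same") / np.convolve(
            np.ones_like(y), np.ones(3), mode="same"
        )
    peaks, _ = find_peaks(y)
    if peaks.size == 0:
        return None
    in_win = peaks[(curve.q[peaks] >= lo) & (curve.q[peaks] <= hi)]
    if in_win.size == 0:
        return None
    prom = peak_prominences(y, in_win)[0]
    keep = (prom >= min_prominence) & (
        prom >= min_rel_prominence * np.abs(y[in_win])
    )
    if not np.any(keep):
        return None
    in_win, prom = in_win[keep], prom[keep]
    best = in_win[int(np.argmax(prom))]  # argmax ties -> first = smallest q
    return float(curve.q[best]), float(curve.intensity[best])


def low_q_intensity(
    curve: ScatteringCurve, window: tuple[float, float] | None = None
) -> float:
    """Mean intensity over the low-q window (default [q_min, 0.003 Å⁻¹])."""
    if window is None:
        window = (curve.q[0], DEFAULT_LOW_Q_MAX)
    lo, hi = window
    mask = (curve.q >= lo) & (curve.q <= hi) & np.isfinite(curve.intensity)
    if not np.any(mask):
        raise ValueError(f"no points in low-q window [{lo}, {hi}]")
    return float(np.mean(curve.intensity[mask]))


def _second_rise_onset(
    times: np.ndarray, y: np.ndarray, rise_fraction: float
) -> float | None:
    """Onset of the second rise of the mid-q intensity trace.

    The trace's first regime culminates in its (early) global maximum;
    after the minimum that follows it, the onset is the first time at
    which the trace exceeds that minimum by ``rise_fraction`` of the
    trace's total range.  Returns None when the maximum sits at the end
    of the run (no second regime).
    """
    ok = np.isfinite(y)
    if np.count_nonzero(ok) < 3:
        return None
    t, v = times[ok], y[ok]
    p = int(np.argmax(v))
    if p >= v.size - 2:
        return None
    rel_min = p + int(np.argmin(v[p:]))
    if rel_min >= v.size - 1:
        return None
    threshold = v[rel_min] + rise_fraction * (np.max(v) - np.min(v))
    after = np.flatnonzero(v[rel_min + 1:] >= threshold)
    if after.size == 0:
        return None
    return float(t[rel_min + 1 + int(after[0])])


def metric_traces(
    series: CurveSeries,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    low_q_window: tuple[float, float] | None = None,
    smooth: bool = True,
    min_prominence: float = 0.0,
    min_rel_prominence: float = 0.02,
    rise_fraction: float = 0.10,
) -> MetricTraces:
    """Per-frame metrics in time order, plus t(q⁺) and t(q_on).

    Peak detection defaults to 3-point smoothing with a 2% relative
    prominence floor — on measured (noisy) series an unfiltered strict
    local maximum would fire on noise in almost every frame.  For frames
    without a detectable peak the mid-q trace ``i_mid`` reads the
    intensity at the series' reference peak position (the median
    detected q⁺), so the two-regime trace is defined through the whole
    run; the landmarks derive from it.  t(q⁺) is the time of its maximum
    (plateaus break toward the earliest time); t(q_on) marks the onset of
    the second intensity rise, defined as the first time after the
    post-peak minimum at which the trace exceeds that minimum by
    ``rise_fraction`` (default 10%) of its total range.
    """
    peaks = [
        find_correlation_peak(
            f, window=peak_window, smooth=smooth, min_prominence=min_prominence,
            min_rel_prominence=min_rel_prominence,
        )
        for f in series.frames
    ]
    detected_q = [p[0] for p in peaks if p is not None]
    q_ref = float(np.median(detected_q)) if detected_q else float("nan")
    frames = []
    for f, peak in zip(series.frames, peaks):
        if np.isfinite(q_ref):
            k = int(np.argmin(np.abs(f.q - q_ref)))
            i_mid = float(f.intensity[k])
        else:
            i_mid = float("nan")
        frames.append(
            FrameMetrics(
                time_min=f.time_min,
                q_star=apparent_invariant(f),
                i_low_q=low_q_intensity(f, low_q_window),
                q_plus=peak[0] if peak else float("nan"),
                i_q_plus=peak[1] if peak else float("nan"),
                i_mid=i_mid,
            )
        )
    i_trace = np.array(
        [f.i_q_plus if np.isfinite(f.i_q_plus) else f.i_mid for f in frames]
    )
    times = series.times
    t_q_plus: float | None = None
    if np.any(np.isfinite(i_trace)):
        # earliest time attaining the maximum (plateau tie rule)
        imax = np.nanmax(i_trace)
        t_q_plus = float(times[int(np.flatnonzero(i_trace >= imax)[0])])
    t_q_on = _second_rise_onset(times, i_trace, rise_fraction)
    return MetricTraces(frames=tuple(frames), t_q_plus=t_q_plus, t_q_on=t_q_on)
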