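"""Hierarchical composite scattering model and its sequential two-stage fit.

The gel network is described by a composite intensity model built from a
power law (large-scale gel-like fractal network), a Lorentzian
(correlated domains of size η) and, in the second stage, an exponential
cut-off on the power law plus a Gaussian correlation peak:

stage "network" (fitted first)::

    I(q) = a / q**n + c / (1 + (eta*q)**m) + b

stage "peak" (seeded from the network-stage parameters)::

    I(q) = a/q**n * exp(-(eta*q)**m) + c/(1 + (eta*q)**m)
           + d * exp(-(q - q0)**2 / (2*sigma**2)) + b

η and m are shared between the cut-off and the Lorentzian; there is no
second correlation length.  The inter-domain spacing d* = 2π/q0 is derived,
never fitted.  Fitting minimises unweighted squared residuals of log10 I
over points with I > 0 (the log–log transform balances the decades spanned
between low and high q); an uncertainty-weighted loss is available behind
a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import CurveSeries, ScatteringCurve
from .metrics import DEFAULT_PEAK_WINDOW, find_correlation_peak

__all__ = [
    "HierParams",
    "FitResult",
    "ParamTrajectory",
    "FitBounds",
    "PARAM_NAMES",
    "CLUSTER_PARAMS",
    "eval_network_model",
    "eval_peak_model",
    "fit_network_model",
    "fit_peak_model",
    "fit_series",
]

PARAM_NAMES = ("a", "n", "c", "eta", "m", "d", "q0", "sigma", "b")
#: the eight parameters used for phase clustering (background excluded)
CLUSTER_PARAMS = ("a", "n", "c", "eta", "m", "d", "q0", "sigma")

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class HierParams:
    """The nine model parameters.

    a : power-law amplitude; n : gel fractal exponent; c : Lorentzian
    amplitude; eta : correlation length, Å; m : internal fractal exponent;
    d : Gaussian amplitude; q0 : Gaussian centre, Å⁻¹; sigma : Gaussian
    width, Å⁻¹; b : constant (incoherent) background.  ``stage`` is
    "network" or "peak"; the Gaussian fields are NaN at the network stage.
    """

    a: float
    n: float
    c: float
    eta: float
    m: float
    b: float
    d: float = float("nan")
    q0: float = float("nan")
    sigma: float = float("nan")
    stage: str = "network"

    def __post_init__(self) -> None:
        if self.stage not in ("network", "peak"):
            raise ValueError(f"unknown stage {self.stage!r}")
        for name in ("a", "c", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.stage == "peak":
            if not (self.d >= 0):
                raise ValueError("d must be >= 0 at the peak stage")
            if not (self.sigma > 0):
                raise ValueError("sigma must be > 0 at the peak stage")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}


@dataclass(frozen=True)
class FitResult:
    """One frame's fit: parameters, loss, and the derived spacing d* = 2π/q0."""

    params: HierParams | None
    residual_norm: float
    n_points_used: int
    converged: bool
    d_star: float | None = None
    message: str = ""

    @property
    def failed(self) -> bool:
        return self.params is None


@dataclass
class ParamTrajectory:
    """Time-ordered fit results for one sample."""

    times: np.ndarray
    results: list[FitResult]
    mode: str = "gdl"  # "gdl" (peak stage) or "methanol" (network only)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.results):
            raise ValueError("times and results length mismatch")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        """Tidy fit table: one row per frame (failed frames hold NaN)."""
        rows = []
        for t, r in zip(self.times, self.results):
            row = {"time_min": t, "residual_norm": r.residual_norm,
                   "converged": r.converged}
            if r.params is not None:
                row.update(r.params.as_dict())
                row["d_star"] = r.d_star
            rows.append(row)
        cols = ["time_min", *PARAM_NAMES, "d_star", "residual_norm", "converged"]
        return pd.DataFrame(rows).reindex(columns=cols)


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the fit (amplitude-like parameters are fitted in log10).

    Exponents cover the physically observed range (network exponent near 4
    early, both exponents plateauing near 2.5); the q0 box contains all
    observed inter-domain spacings (d* ≈ 230–400 Å).
    """

    a: tuple[float, float] = (1e-12, 1e3)
    n: tuple[float, float] = (0.0, 6.0)
    c: tuple[float, float] = (1e-9, 1e4)
    eta: tuple[float, float] = (1.0, 1e3)
    m: tuple[float, float] = (0.0, 6.0)
    d: tuple[float, float] = (1e-9, 1e3)
    q0: tuple[float, float] = (0.012, 0.028)
    sigma: tuple[float, float] = (5e-4, 0.02)
    b: tuple[float, float] = (1e-9, 1e3)


DEFAULT_BOUNDS = FitBounds()
#: parameters optimised on a log10 scale (span decades, positivity enforced)
_LOG_PARAMS = frozenset({"a", "c", "d", "b", "eta", "sigma"})


def _lorentzian_denominator(eta: float, m: float, q: np.ndarray) -> np.ndarray:
    return 1.0 + (eta * q) ** m


def eval_network_model(params: HierParams, q: np.ndarray) -> np.ndarray:
    """Power law + Lorentzian + background (first fitting stage)."""
    q = np.asarray(q, dtype=float)
    return (
        params.a * q ** (-params.n)
        + params.c / _lorentzian_denominator(params.eta, params.m, q)
        + params.b
    )


def eval_peak_model(params: HierParams, q: np.ndarray) -> np.ndarray:
    """Cut-off power law + Lorentzian + Gaussian peak + background."""
    q = np.asarray(q, dtype=float)
    u = (params.eta * q) ** params.m
    with np.errstate(over="ignore", under="ignore"):
        cutoff = np.exp(-u)
        gauss = params.d * np.exp(
            -((q - params.q0) ** 2) / (2.0 * params.sigma**2)
        )
    return params.a * q ** (-params.n) * cutoff + params.c / (1.0 + u) + gauss + params.b


def _evaluate(params: HierParams, q: np.ndarray) -> np.ndarray:
    return (eval_peak_model if params.stage == "peak" else eval_network_model)(params, q)


# ---------------------------------------------------------------------------
# fitting machinery


def _pack(params: HierParams, names: Sequence[str]) -> np.ndarray:
    x = []
    for k in names:
        v = getattr(params, k)
        x.append(np.log10(v) if k in _LOG_PARAMS else v)
    return np.array(x, dtype=float)


def _unpack(x: np.ndarray, names: Sequence[str], stage: str) -> HierParams:
    vals = {}
    for k, v in zip(names, x):
        vals[k] = 10.0**v if k in _LOG_PARAMS else float(v)
    return HierParams(stage=stage, **vals)


def _bound_arrays(bounds: FitBounds, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for k in names:
        b = getattr(bounds, k)
        if k in _LOG_PARAMS:
            lo.append(np.log10(b[0]))
            hi.append(np.log10(b[1]))
        else:
            lo.append(b[0])
            hi.append(b[1])
    return np.array(lo), np.array(hi)


def _log_residuals(
    params: HierParams,
    q: np.ndarray,
    log_i: np.ndarray,
    weights: np.ndarray | None,
) -> np.ndarray:
    model = _evaluate(params, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log10(np.maximum(model, 1e-300)) - log_i
    if weights is not None:
        r = r * weights
    return r


def residual_norm(params: HierParams, curve: ScatteringCurve) -> float:
    """Sum of squared log10 residuals over the curve's usable points."""
    mask = curve.usable
    r = _log_residuals(params, curve.q[mask], np.log10(curve.intensity[mask]), None)
    return float(np.sum(r**2))


def _clip_to_bounds(value: float, bound: tuple[float, float]) -> float:
    eps = 1e-12
    return float(min(max(value, bound[0] * (1 + eps) if bound[0] > 0 else bound[0]),
                     bound[1]))


#: characteristic one-frame evolution scale of each packed parameter
#: (log10 for amplitude-like parameters, native units otherwise); used to
#: scale the temporal-continuity penalty in refinement passes
_STEP_SCALES = {
    "a": 0.05, "n": 0.10, "c": 0.05, "eta": 0.05, "m": 0.10,
    "d": 0.10, "q0": 5e-4, "sigma": 0.10, "b": 0.05,
}


def _run_least_squares(
    x0: np.ndarray,
    names: Sequence[str],
    stage: str,
    q: np.ndarray,
    log_i: np.ndarray,
    bounds: FitBounds,
    weights: np.ndarray | None,
    max_iter: int,
    anchor: np.ndarray | None = None,
    anchor_weight: float = 0.0,
) -> tuple[HierParams, float, bool, str]:
    """Bounded least squares in packed space; returns the *data-only* SSE.

    With ``anchor`` set, penalty residuals anchor_weight·(x − anchor)/scale
    are appended — a mild Tikhonov pull toward the anchored parameters in
    the directions the data leave flat.
    """
    lo, hi = _bound_arrays(bounds, names)
    x0 = np.clip(x0, lo, hi)
    scales = np.array([_STEP_SCALES[k] for k in names])

    def fun(x: np.ndarray) -> np.ndarray:
        r = _log_residuals(_unpack(x, names, stage), q, log_i, weights)
        if anchor is not None and anchor_weight > 0.0:
            r = np.concatenate([r, anchor_weight * (x - anchor) / scales])
        return r

    sol = least_squares(
        fun, x0, bounds=(lo, hi), method="trf",
        ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=max_iter * len(x0),
    )
    p = _unpack(sol.x, names, stage)
    data_sse = float(
        np.sum(_log_residuals(p, q, log_i, weights) ** 2)
    )
    return p, data_sse, bool(sol.success), str(sol.message)


def _usable_log_data(
    curve: ScatteringCurve, weighted: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    mask = curve.usable
    q = curve.q[mask]
    i = curve.intensity[mask]
    w = None
    if weighted and curve.uncertainty is not None:
        # propagate dI into log space: sigma_log = dI / (I ln 10)
        sig = curve.uncertainty[mask] / (i * np.log(10.0))
        w = 1.0 / np.maximum(sig, 1e-12)
        w = w / np.mean(w)
    return q, np.log10(i), w


def _network_init(q: np.ndarray, log_i: np.ndarray, bounds: FitBounds) -> HierParams:
    """Heuristic starting point from the data itself.

    The low-q decade estimates the power law by log–log regression, the
    high-q tail estimates the flat background, and the mid-q level above
    background seeds the Lorentzian amplitude.
    """
    i = 10.0**log_i
    n_lo = max(5, q.size // 10)
    slope, intercept = np.polyfit(np.log10(q[:n_lo]), log_i[:n_lo], 1)
    n0 = _clip_to_bounds(-slope, (max(bounds.n[0], 0.3), min(bounds.n[1], 5.5)))
    a0 = _clip_to_bounds(10.0**intercept, bounds.a)
    b0 = _clip_to_bounds(0.8 * float(np.median(i[-max(5, q.size // 10):])), bounds.b)
    eta0 = _clip_to_bounds(50.0, bounds.eta)
    mid = np.searchsorted(q, 1.0 / eta0)
    mid = min(max(mid, 0), q.size - 1)
    c0 = _clip_to_bounds(max(2.0 * (i[mid] - b0), 10 * bounds.c[0]), bounds.c)
    return HierParams(a=a0, n=n0, c=c0, eta=eta0, m=2.5, b=b0, stage="network")


def fit_network_model(
    curve: ScatteringCurve,
    bounds: FitBounds = DEFAULT_BOUNDS,
    init: HierParams | None = None,
    weighted: bool = False,
    max_iter: int = 500,
) -> FitResult:
    """Stage-one fit: power law + Lorentzian + background in log10 space.

    Only points with finite, positive intensity enter the loss.  Requires at
    least 10 such points.  Deterministic given ``init``.
    """
    q, log_i, w = _usable_log_data(curve, weighted)
    if q.size < 10:
        raise ValueError(f"need >= 10 usable points with I > 0, got {q.size}")
    names = ("a", "n", "c", "eta", "m", "b")
    starts = [_network_init(q, log_i, bounds)]
    if init is not None:
        starts.insert(0, replace(init, stage="network"))
    best: tuple[HierParams, float, bool, str] | None = None
    for s in starts:
        cand = _run_least_squares(
            _pack(s, names), names, "network", q, log_i, bounds, w, max_iter
        )
        if best is None or cand[1] < best[1]:
            best = cand
    p, cost, ok, msg = best  # type: ignore[misc]
    return FitResult(params=p, residual_norm=cost, n_points_used=int(q.size),
                     converged=ok, message=msg)


def _peak_inits(
    curve: ScatteringCurve,
    seed: HierParams,
    bounds: FitBounds,
    detect_window: tuple[float, float],
    warm: HierParams | None,
) -> list[HierParams]:
    """Multi-start grid for the peak stage.

    q0 starts at the detected correlation peak plus the window edges
    (local minima in the Gaussian term make single-start fits fragile);
    two σ starts bracket narrow and broad peaks.  A warm start from the
    previous frame is prepended when available.
    """
    q0_candidates: list[float] = []
    lo = max(detect_window[0], curve.q[0])
    hi = min(detect_window[1], curve.q[-1])
    peak = find_correlation_peak(curve, window=(lo, hi))
    if peak is not None:
        q0_candidates.append(peak[0])
    q0_candidates += [lo * 1.05, hi * 0.95]
    sigma_candidates = [0.002, 0.006]

    base = replace(seed, stage="network")
    model1 = eval_network_model(base, curve.q)
    inits: list[HierParams] = []
    if warm is not None and warm.stage == "peak":
        inits.append(warm)
    for q0 in q0_candidates:
        q0 = _clip_to_bounds(q0, bounds.q0)
        k = int(np.argmin(np.abs(curve.q - q0)))
        excess = float(curve.intensity[k] - model1[k])
        d0 = _clip_to_bounds(max(excess, 1e-3), bounds.d)
        for sig in sigma_candidates:
            inits.append(
                replace(
                    base,
                    stage="peak",
                    d=d0,
                    q0=q0,
                    sigma=_clip_to_bounds(sig, bounds.sigma),
                )
            )
    return inits


def fit_peak_model(
    curve: ScatteringCurve,
    seed_fit: FitResult,
    bounds: FitBounds = DEFAULT_BOUNDS,
    detect_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    warm: HierParams | None = None,
    weighted: bool = False,
    max_iter: int = 500,
    basin_margin: float = 0.02,
) -> FitResult:
    """Stage-two fit seeded from the network-stage parameters.

    Multi-start over a small q0 × σ grid with the warm start (previous
    frame) tried first; a later start displaces the incumbent only when
    its residual is lower by more than ``basin_margin`` (relative), so
    ties and near-ties keep the earliest — and warmest — solution.
    d* = 2π/q0 is attached to the result.
    """
    if seed_fit.params is None:
        raise ValueError("seed fit failed; cannot seed the peak stage")
    q, log_i, w = _usable_log_data(curve, weighted)
    if q.size < 10:
        raise ValueError(f"need >= 10 usable points with I > 0, got {q.size}")
    names = ("a", "n", "c", "eta", "m", "d", "q0", "sigma", "b")
    best: tuple[HierParams, float, bool, str] | None = None
    for s in _peak_inits(curve, seed_fit.params, bounds, detect_window, warm):
        cand = _run_least_squares(
            _pack(s, names), names, "peak", q, log_i, bounds, w, max_iter
        )
        # hysteresis: near-degenerate basins are common (the Gaussian can
        # partly absorb the Lorentzian); a later start only displaces the
        # incumbent when clearly better, which keeps warm-started series
        # on a continuous branch instead of hopping between equivalent fits
        if best is None or cand[1] < (1.0 - basin_margin) * best[1]:
            best = cand
    p, cost, ok, msg = best  # type: ignore[misc]
    return FitResult(
        params=p, residual_norm=cost, n_points_used=int(q.size),
        converged=ok, d_star=TWO_PI / p.q0, message=msg,
    )


def _refine_pass(
    series: CurveSeries,
    results: list[FitResult],
    order: Sequence[int],
    bounds: FitBounds,
    detect_window: tuple[float, float],
    weighted: bool,
    continuity_margin: float,
    anchor_weight: float,
) -> None:
    """Temporal-continuity refinement sweep.

    The composite model leaves flat valleys at low peak amplitude — a
    broad Gaussian can partly stand in for the Lorentzian, and η, σ and c
    trade off — so the per-frame minimiser wanders along them with the
    noise.  The structural evolution is smooth on the acquisition
    cadence; each frame is therefore refit with a mild quadratic penalty
    anchoring the packed parameters to the neighbouring frame's solution,
    and the anchored solution is adopted when its data residual is within
    ``continuity_margin`` (relative) of the incumbent's.  Well-determined
    directions are unaffected (the data term dominates); only the flat
    directions are pulled onto a continuous branch.
    """
    prev: HierParams | None = None
    for i in order:
        inc = results[i]
        if inc.params is None:
            continue
        if prev is not None:
            q, log_i, w = _usable_log_data(series.frames[i], weighted)
            names = ("a", "n", "c", "eta", "m", "d", "q0", "sigma", "b")
            p, cost, ok, msg = _run_least_squares(
                _pack(prev, names), names, "peak", q, log_i, bounds, w, 500,
                anchor=_pack(prev, names), anchor_weight=anchor_weight,
            )
            if cost <= inc.residual_norm * (1.0 + continuity_margin):
                results[i] = FitResult(
                    params=p, residual_norm=cost, n_points_used=int(q.size),
                    converged=ok, d_star=TWO_PI / p.q0, message=msg,
                )
        prev = results[i].params


def fit_series(
    series: CurveSeries,
    mode: str | None = None,
    bounds: FitBounds = DEFAULT_BOUNDS,
    detect_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    warm_start: bool = True,
    weighted: bool = False,
    refine_passes: int = 2,
    continuity_margin: float = 0.10,
    anchor_weight: float = 0.02,
) -> ParamTrajectory:
    """Fit every frame of a series.

    ``mode="gdl"`` runs the sequential two-stage fit per frame (network
    stage seeding the peak stage); ``mode="methanol"`` stops at the network
    stage (no correlation peak forms on that pathway).  With ``warm_start``
    each frame's fit additionally starts from the previous frame's
    parameters, reflecting the smooth structural evolution; the forward
    sweep is followed by alternating backward/forward refinement passes
    (see :func:`_refine_pass`).  A cold-start independence check is
    available via ``warm_start=False, refine_passes=0``.  Individual frame
    failures are recorded and the remaining frames are still fitted.
    """
    if mode is None:
        mode = series.trigger
    if mode not in ("gdl", "methanol"):
        raise ValueError(f"unknown mode {mode!r}")
    results: list[FitResult] = []
    prev_net: HierParams | None = None
    prev_peak: HierParams | None = None
    for frame in series.frames:
        try:
            net = fit_network_model(
                frame, bounds=bounds,
                init=prev_net if warm_start else None, weighted=weighted,
            )
            if mode == "gdl":
                res = fit_peak_model(
                    frame, net, bounds=bounds, detect_window=detect_window,
                    warm=prev_peak if warm_start else None, weighted=weighted,
                )
                prev_peak = res.params
            else:
                res = net
            prev_net = net.params
        except ValueError as exc:
            warnings.warn(
                f"frame at t={frame.time_min:g} min failed: {exc}", stacklevel=2
            )
            res = FitResult(params=None, residual_norm=np.inf, n_points_used=0,
                            converged=False, message=str(exc))
        results.append(res)
    if mode == "gdl":
        n = len(results)
        for sweep in range(refine_passes):
            order = range(n - 1, -1, -1) if sweep % 2 == 0 else range(n)
            _refine_pass(
                series, results, order, bounds, detect_window, weighted,
                continuity_margin, anchor_weight,
            )
    return ParamTrajectory(times=series.times, results=results, mode=mode)
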