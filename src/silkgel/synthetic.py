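"""Seeded generators for every input the pipeline consumes.

The generators emulate the beamline study conditions: reduced scattering
curves on q ∈ 0.002–0.5 Å⁻¹ acquired every 5 minutes from t = 5 min, a
GdL-driven pH decay from 7.5 toward ≈3.6, a mid-q correlation peak near
q0 ≈ 0.015 Å⁻¹ that rises and falls, sigmoidal ThT fluorescence, a
slower turbidity rise, and two-band amide-I FTIR spectra.

Parameter truth trajectories follow a scripted sequence of four gelation
phases (Initiation → Pre-assembly → Network Assembly → Maturation) as
sums of logistic steps between per-phase anchor values, plus smooth
seeded within-phase wander whose amplitude is largest during
Pre-assembly — that phase is structurally the most plastic, which is what
makes its convex-hull envelope dominate the phase map.  Anchors track the
observed evolution: the correlation length η shrinking from ≈100 Å to
≈60 Å, the inter-domain spacing d* moving 365 → 380 → 295 → 235 Å, the
Gaussian amplitude peaking near 0.35 during Pre-assembly, the network
exponent n peaking near 4, and m near 2.7 before both settle near 2.5.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CurveSeries, KineticTrace, ScatteringCurve, SpectrumSeries
from .model import (
    TWO_PI,
    FitResult,
    HierParams,
    ParamTrajectory,
    eval_network_model,
    eval_peak_model,
)

__all__ = [
    "PhaseScript",
    "default_phase_script",
    "default_q_grid",
    "default_time_grid",
    "simulate_ph",
    "simulate_param_trajectory",
    "simulate_sans_series",
    "simulate_methanol_series",
    "simulate_tht",
    "simulate_turbidity",
    "simulate_emission_series",
    "simulate_ftir_series",
    "simulate_joint_truth",
    "reference_dataset",
]

#: instrument q range, Å⁻¹
Q_RANGE = (0.002, 0.5)
#: acquisition cadence, minutes
FRAME_INTERVAL = 5.0
#: pH anchors of the GdL pathway
PH_START, PH_END = 7.5, 3.6
#: ThT landmark defaults (midpoint 128 min, onset = t_m - 2 tau = 87 min)
THT_TM, THT_TAU = 128.0, 20.5


def default_q_grid(n_points: int = 120) -> np.ndarray:
    return np.geomspace(Q_RANGE[0], Q_RANGE[1], n_points)


def default_time_grid(t_end: float = 420.0) -> np.ndarray:
    return np.arange(FRAME_INTERVAL, t_end + 0.5 * FRAME_INTERVAL, FRAME_INTERVAL)


@dataclass(frozen=True)
class PhaseScript:
    """Scripted truth for the four-phase parameter evolution.

    ``anchors`` holds one value per phase for each scripted quantity:
    the model parameters except ``a``, with the Gaussian centre stated as
    an inter-domain spacing ``d_star`` (q0 = 2π/d*) and the power-law
    amplitude stated as the low-q intensity ``i_lowq`` at the low edge of
    the q-range (``a`` itself is derived — scripting the amplitude
    directly would let the n evolution swing the low-q intensity over
    decades).  ``wander`` gives the per-phase standard deviation of the
    smooth within-phase fluctuation of each quantity, in its own units.
    ``boundaries`` are the phase-transition times in minutes and
    ``transition_width`` the logistic width of each step;
    ``param_boundaries``/``param_widths`` override them per quantity
    (the Gaussian amplitude d peaks at the Initiation→Pre-assembly
    boundary and then declines gradually, not at the phase boundary).
    """

    boundaries: tuple[float, float, float] = (35.0, 180.0, 300.0)
    transition_width: float = 2.0
    noise: float = 0.02
    seed: int = 0
    anchors: dict = field(default_factory=dict)
    wander: dict = field(default_factory=dict)
    param_boundaries: dict = field(default_factory=dict)
    param_widths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(b2 > b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("phase boundaries must be strictly increasing")
        if not 0.0 <= self.noise <= 0.2:
            raise ValueError("noise fraction must be in [0, 0.2]")


#: anchor values per phase: Initiation, Pre-assembly, Network Assembly, Maturation
DEFAULT_ANCHORS = {
    "i_lowq": (40.0, 20.0, 60.0, 75.0),  # I at q_min, cm^-1 (a is derived)
    "n": (3.2, 4.0, 3.0, 2.5),
    "c": (1.2, 0.7, 1.0, 0.6),
    "eta": (100.0, 50.0, 70.0, 62.0),
    "m": (2.0, 2.7, 2.6, 2.5),
    "d": (0.05, 0.35, 0.15, 0.08),
    "d_star": (365.0, 380.0, 295.0, 235.0),  # q0 = 2*pi/d_star
    "sigma": (0.0025, 0.0030, 0.0035, 0.0030),
    "b": (0.03, 0.03, 0.03, 0.03),
}

#: within-phase wander sd; Pre-assembly is deliberately the most plastic
DEFAULT_WANDER = {
    "i_lowq": (3.0, 2.0, 4.0, 3.0),
    "n": (0.04, 0.30, 0.08, 0.03),
    "c": (0.05, 0.05, 0.08, 0.05),
    "eta": (3.0, 6.0, 3.0, 2.0),
    "m": (0.03, 0.12, 0.05, 0.02),
    "d": (0.004, 0.035, 0.015, 0.005),
    "d_star": (6.0, 12.0, 8.0, 4.0),
    "sigma": (5e-5, 2e-4, 1e-4, 5e-5),
    "b": (0.0, 0.0, 0.0, 0.0),
}

#: the Gaussian amplitude rises at the first phase boundary but then
#: declines gradually through Pre-assembly (broad second step), so the
#: correlation-peak intensity has its maximum early, as observed
DEFAULT_PARAM_BOUNDARIES = {"d": (35.0, 95.0, 300.0)}
DEFAULT_PARAM_WIDTHS = {"d": (2.0, 25.0, 2.0)}

#: reference q at which i_lowq anchors are stated
_Q_REF = Q_RANGE[0]


def default_phase_script(seed: int = 0, noise: float = 0.02) -> PhaseScript:
    return PhaseScript(
        anchors=dict(DEFAULT_ANCHORS), wander=dict(DEFAULT_WANDER),
        param_boundaries=dict(DEFAULT_PARAM_BOUNDARIES),
        param_widths=dict(DEFAULT_PARAM_WIDTHS),
        seed=seed, noise=noise,
    )


def simulate_ph(
    gdl_percent: float,
    t_grid: np.ndarray,
    ph_start: float = PH_START,
    ph_end: float = PH_END,
    rate_per_percent: float = 0.0419,
    noise: float = 0.01,
    seed: int = 0,
) -> KineticTrace:
    """Phenomenological pH decay pH(t) = pH_∞ + (pH₀ − pH_∞)·exp(−k t).

    GdL hydrolysis gives a slow reproducible acidification; the rate k is
    proportional to the GdL load (doubling GdL halves the time to any
    given pH).  The default rate for 1% (w/v) GdL brings pH from 7.5 to
    ≈4.5 by 35 min and toward ≈3.6 at long times.
    """
    t = np.asarray(t_grid, dtype=float)
    k = rate_per_percent * gdl_percent
    ph = ph_end + (ph_start - ph_end) * np.exp(-k * t)
    rng = np.random.default_rng(seed)
    ph = ph + rng.normal(0.0, noise, size=t.size)
    return KineticTrace(time_min=t, value=ph, kind="ph")


def _logistic_steps(
    t: np.ndarray, anchors: tuple, boundaries: tuple, widths: tuple
) -> np.ndarray:
    y = np.full_like(t, float(anchors[0]))
    for v0, v1, tb, w in zip(anchors, anchors[1:], boundaries, widths):
        y = y + (float(v1) - float(v0)) / (1.0 + np.exp(-(t - tb) / w))
    return y


def _phase_index(t: np.ndarray, boundaries: tuple) -> np.ndarray:
    return np.searchsorted(np.asarray(boundaries), t)


def _smooth_wander(
    rng: np.random.Generator, t: np.ndarray, sd_per_phase: tuple, phases: np.ndarray
) -> np.ndarray:
    """Smooth seeded drift: white noise blurred with a Gaussian kernel a
    few frames wide, then scaled to each phase's target standard
    deviation.  The long correlation length matters: it yields a large
    within-phase spread (structural plasticity) while keeping
    consecutive-frame steps small, as slow parameter drift does."""
    white = rng.normal(0.0, 1.0, size=t.size)
    half = min(8, max(1, (t.size - 1) // 2))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-(x**2) / (2.0 * 2.5**2))
    kernel /= kernel.sum()
    smooth = np.convolve(white, kernel, mode="same")
    smooth = smooth / max(np.std(smooth), 1e-12)
    return smooth * np.asarray([sd_per_phase[p] for p in phases])


def simulate_param_trajectory(
    script: PhaseScript, t_grid: np.ndarray
) -> pd.DataFrame:
    """Truth table of the nine model parameters along the phase script.

    Each scripted quantity is a sum of logistic steps between its phase
    anchors plus smooth seeded wander; q0 is derived from the scripted d*
    so the identity q0·d* = 2π holds exactly in the truth, and the
    power-law amplitude a is derived from the scripted low-q intensity
    (a = I_lowq · q_ref^n / exp(−(η q_ref)^m), q_ref the low edge of the
    q-range) so the low-q level stays physical while n evolves.  Returns
    a DataFrame with columns time_min, a…b, d_star and phase.
    """
    t = np.asarray(t_grid, dtype=float)
    anchors = {**DEFAULT_ANCHORS, **script.anchors}
    wander = {**DEFAULT_WANDER, **script.wander}
    phases = _phase_index(t, script.boundaries)
    out = {"time_min": t}
    for j, name in enumerate(
        ("i_lowq", "n", "c", "eta", "m", "d", "d_star", "sigma", "b")
    ):
        rng = np.random.default_rng([script.seed, 101 + j])
        bounds = script.param_boundaries.get(name, script.boundaries)
        widths = script.param_widths.get(
            name, (script.transition_width,) * len(bounds)
        )
        base = _logistic_steps(t, anchors[name], bounds, widths)
        w = _smooth_wander(rng, t, wander[name], phases)
        vals = base + w
        # keep physically required positivity after wander
        floor = 1e-12 if name in ("c", "d", "b") else None
        if name in ("eta", "sigma", "d_star", "i_lowq"):
            floor = 0.1 * float(min(anchors[name]))
        if floor is not None:
            vals = np.maximum(vals, floor)
        out[name] = vals
    out["q0"] = TWO_PI / out.pop("d_star")
    i_lowq = out.pop("i_lowq")
    with np.errstate(over="ignore"):
        cutoff = np.exp(-((out["eta"] * _Q_REF) ** out["m"]))
    out["a"] = i_lowq * _Q_REF ** out["n"] / np.maximum(cutoff, 1e-6)
    df = pd.DataFrame(out)
    df["d_star"] = TWO_PI / df["q0"]
    df["phase"] = phases
    return df[["time_min", "a", "n", "c", "eta", "m", "d", "q0", "sigma", "b",
               "d_star", "phase"]]


def _truth_params(row: pd.Series, stage: str) -> HierParams:
    kw = {k: float(row[k]) for k in ("a", "n", "c", "eta", "m", "b")}
    if stage == "peak":
        kw.update(d=float(row["d"]), q0=float(row["q0"]), sigma=float(row["sigma"]))
    return HierParams(stage=stage, **kw)


def truth_trajectory(truth: pd.DataFrame, stage: str = "peak") -> ParamTrajectory:
    """Wrap a truth table as a ParamTrajectory (for oracle comparisons)."""
    results = [
        FitResult(
            params=_truth_params(row, stage), residual_norm=0.0,
            n_points_used=0, converged=True,
            d_star=float(row["d_star"]) if stage == "peak" else None,
        )
        for _, row in truth.iterrows()
    ]
    return ParamTrajectory(times=truth["time_min"].to_numpy(), results=results,
                           mode="gdl" if stage == "peak" else "methanol")


def _noisy_series(
    clean: np.ndarray,
    q: np.ndarray,
    times: np.ndarray,
    noise: float,
    floor: float,
    seed: int,
    **series_kwargs,
) -> CurveSeries:
    rng = np.random.default_rng(seed)
    frames = []
    for i, t in enumerate(times):
        eps = rng.normal(0.0, 1.0, size=q.size)
        add = rng.normal(0.0, 1.0, size=q.size)
        intensity = clean[i] * (1.0 + noise * eps) + floor * add
        d_i = np.sqrt((noise * clean[i]) ** 2 + floor**2)
        frames.append(
            ScatteringCurve(q=q, intensity=intensity, uncertainty=d_i, time_min=t)
        )
    return CurveSeries(frames=tuple(frames), **series_kwargs)


def simulate_sans_series(
    truth: pd.DataFrame,
    q_grid: np.ndarray | None = None,
    noise: float = 0.02,
    seed: int = 0,
    gdl_percent: float = 1.0,
    rsf_mg_ml: float = 10.0,
) -> CurveSeries:
    """Forward-model the scripted truth into a noisy GdL-pathway series.

    I(q, t) = peak-stage model of the truth row, times multiplicative
    Gaussian noise of relative sd ``noise``, plus an additive floor of
    background × noise (background/50 at the nominal 2% level — reduced
    data carry roughly relative errors at mid-q and an absolute floor at
    high q; the floor vanishes with the noise so a zero-noise series is an
    exact inverse crime).  dI records the noise-model sd.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    clean = np.vstack(
        [eval_peak_model(_truth_params(row, "peak"), q_grid)
         for _, row in truth.iterrows()]
    )
    # additive floor scales with the noise level (background/50 at 2%)
    floor = float(truth["b"].median()) * noise
    return _noisy_series(
        clean, q_grid, truth["time_min"].to_numpy(), noise, floor, seed,
        sample_label=f"synthetic RSF {rsf_mg_ml:g} mg/ml, {gdl_percent:g}% GdL",
        trigger="gdl", gdl_percent=gdl_percent, rsf_mg_ml=rsf_mg_ml,
    )


def simulate_methanol_series(
    q_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    noise: float = 0.02,
    seed: int = 0,
    rsf_mg_ml: float = 10.0,
) -> CurveSeries:
    """Methanol pathway: rapid continuous aggregation, no correlation peak.

    The network-stage model with monotonically growing power-law and
    Lorentzian amplitudes — low-q intensity rises steadily and the mid-q
    window stays monotone, so no q⁺ is detectable.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    if t_grid is None:
        t_grid = default_time_grid(200.0)
    t = np.asarray(t_grid, dtype=float)
    g = 1.0 - np.exp(-t / 40.0)  # fast saturating growth
    clean = []
    truth_rows = []
    for gi in g:
        p = HierParams(
            a=2e-7 * (1.0 + 30.0 * gi), n=2.5 + 1.0 * gi,
            c=0.8 * (1.0 + 3.0 * gi), eta=40.0, m=2.5, b=0.03,
            stage="network",
        )
        truth_rows.append(p)
        clean.append(eval_network_model(p, q_grid))
    series = _noisy_series(
        np.vstack(clean), q_grid, t, noise, 0.03 * noise, seed,
        sample_label=f"synthetic RSF {rsf_mg_ml:g} mg/ml, 15% methanol",
        trigger="methanol", methanol_percent=15.0, rsf_mg_ml=rsf_mg_ml,
    )
    return series


def simulate_tht(
    t_grid: np.ndarray | None = None,
    baseline: float = 50.0,
    A: float = 900.0,
    t_m: float = THT_TM,
    tau: float = THT_TAU,
    noise: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Logistic ThT trace; defaults give onset 87 min and midpoint 128 min."""
    if t_grid is None:
        t_grid = np.arange(0.0, 421.0, 1.0)
    t = np.asarray(t_grid, dtype=float)
    v = baseline + A / (1.0 + np.exp(-(t - t_m) / tau))
    rng = np.random.default_rng(seed)
    v = v + rng.normal(0.0, noise * A, size=t.size)
    return KineticTrace(time_min=t, value=v, kind="tht")


def simulate_turbidity(
    t_grid: np.ndarray | None = None,
    baseline: float = 100.0,
    A: float = 400.0,
    t_m: float = 210.0,
    tau: float = 35.0,
    noise: float = 0.0,
    seed: int = 1,
) -> KineticTrace:
    """Turbidity proxy: a slower logistic rise than ThT (mesoscale density
    lags the β-sheet onset)."""
    trace = simulate_tht(t_grid, baseline, A, t_m, tau, noise, seed)
    return KineticTrace(time_min=trace.time_min, value=trace.value, kind="turbidity")


def simulate_emission_series(
    t_grid: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    tht_kwargs: dict | None = None,
    turbidity_kwargs: dict | None = None,
    noise: float = 0.01,
    seed: int = 0,
) -> SpectrumSeries:
    """Fluorescence emission spectra with a 485 nm ThT band whose amplitude
    follows the logistic ThT waveform and a narrow 450 nm channel following
    the turbidity waveform."""
    if t_grid is None:
        t_grid = default_time_grid()
    if wavelengths is None:
        wavelengths = np.arange(400.0, 601.0, 2.0)
    t = np.asarray(t_grid, dtype=float)
    lam = np.asarray(wavelengths, dtype=float)
    tht = simulate_tht(t, noise=0.0, **(tht_kwargs or {}))
    turb = simulate_turbidity(t, noise=0.0, **(turbidity_kwargs or {}))
    band_tht = np.exp(-((lam - 485.0) ** 2) / (2.0 * 15.0**2))
    band_turb = np.exp(-((lam - 450.0) ** 2) / (2.0 * 6.0**2))
    spectra = np.outer(tht.value, band_tht) + np.outer(turb.value, band_turb)
    rng = np.random.default_rng(seed)
    scale = float(np.max(spectra))
    spectra = spectra + rng.normal(0.0, noise * scale, size=spectra.shape)
    return SpectrumSeries(axis=lam, spectra=spectra, time_min=t,
                          kind="fluorescence_emission")


def simulate_ftir_series(
    t_grid: np.ndarray | None = None,
    axis: np.ndarray | None = None,
    amp_1620: float = 0.4,
    amp_1695: float = 0.2,
    t_m_1620: float = 150.0,
    tau_1620: float = 25.0,
    tau_1695: float = 40.0,
    sigma_1620: float = 8.0,
    sigma_1695: float = 7.0,
    noise: float = 0.01,
    seed: int = 0,
    buffer_level: float = 0.20,
) -> tuple[SpectrumSeries, np.ndarray]:
    """Amide-I spectral series and its buffer spectrum.

    Two Gaussian β bands grow on a broad random-coil band (1648 cm⁻¹) and
    a slow linear baseline drift: the 1695 cm⁻¹ band (antiparallel
    β-contacts) saturates fast, 1 − exp(−t/τ); the 1620 cm⁻¹ band
    (crystalline β-sheet) follows a lagged sigmoid — so the 1695
    half-rise precedes the 1620 half-rise.  The coil amplitude declines
    exactly as the β-band areas grow (secondary-structure redistribution
    conserves the total amide-I oscillator strength), so the area
    normalisation in preprocessing does not distort the band waveforms.
    Noise is multiplicative (source and ATR-contact fluctuations scale
    with absorbance).
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 421.0, 4.0)
    if axis is None:
        axis = np.arange(1580.0, 1731.0, 2.0)
    t = np.asarray(t_grid, dtype=float)
    ax = np.asarray(axis, dtype=float)
    coil_sigma = 18.0
    coil = np.exp(-((ax - 1648.0) ** 2) / (2.0 * coil_sigma**2))
    band20 = np.exp(-((ax - 1620.0) ** 2) / (2.0 * sigma_1620**2))
    band95 = np.exp(-((ax - 1695.0) ** 2) / (2.0 * sigma_1695**2))
    w20 = amp_1620 / (1.0 + np.exp(-(t - t_m_1620) / tau_1620))
    w95 = amp_1695 * (1.0 - np.exp(-t / tau_1695))
    # coil loses exactly the area the beta bands gain
    coil_amp = 1.0 - (w20 * sigma_1620 + w95 * sigma_1695) / coil_sigma
    drift = 0.02 * (t / max(t[-1], 1.0))  # slow linear baseline drift
    buffer_spectrum = buffer_level + 0.0005 * (ax - ax[0])
    spectra = (
        buffer_spectrum[None, :]
        + np.outer(coil_amp, coil)
        + np.outer(w20, band20)
        + np.outer(w95, band95)
        + drift[:, None] * np.linspace(0.0, 1.0, ax.size)[None, :]
    )
    rng = np.random.default_rng(seed)
    spectra = spectra * (1.0 + rng.normal(0.0, noise, size=spectra.shape))
    series = SpectrumSeries(axis=ax, spectra=spectra, time_min=t, kind="ftir")
    return series, buffer_spectrum


def simulate_joint_truth(
    n_times: int = 60,
    n_q: int = 60,
    n_lambda: int = 50,
    noise: float = 0.01,
    seed: int = 0,
) -> dict:
    """Exactly bilinear three-component joint matrix with known truth.

    The concentration waveforms mirror the resolved gelation species: C1
    (solvated chains) decays, C2 (correlated clusters, with a correlation
    peak in its scattering signature) rises and falls, and C3 (β-sheet
    network, carrying the 485 nm emission) accumulates.  Returns the data
    matrix, truth factors and metadata for MCR recovery tests.
    """
    t = np.linspace(5.0, 300.0, n_times)
    q = default_q_grid(n_q)
    lam = np.linspace(420.0, 560.0, n_lambda)

    def sig(x: np.ndarray, x0: float, w: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(x - x0) / w))

    c1 = 1.0 - sig(t, 60.0, 20.0)
    c2 = sig(t, 40.0, 12.0) * (1.0 - sig(t, 190.0, 25.0))
    c3 = sig(t, 180.0, 25.0)
    c = np.column_stack([c1, c2, c3])

    s1_q = 0.3 * np.exp(-((np.log(q / 0.05)) ** 2))  # featureless hump
    s2_q = 0.6 / (1.0 + (60.0 * q) ** 2.5) + 0.8 * np.exp(
        -((q - 0.0165) ** 2) / (2.0 * 0.003**2)
    )
    s3_q = 1.0 / (1.0 + (35.0 * q) ** 2.0)  # shoulder-like
    s1_l = 0.02 * np.exp(-((lam - 450.0) ** 2) / (2.0 * 8.0**2))
    s2_l = 0.05 * np.exp(-((lam - 450.0) ** 2) / (2.0 * 8.0**2))
    s3_l = 1.0 * np.exp(-((lam - 485.0) ** 2) / (2.0 * 15.0**2))
    s = np.column_stack(
        [np.concatenate([s1_q, s1_l]), np.concatenate([s2_q, s2_l]),
         np.concatenate([s3_q, s3_l])]
    )
    x_clean = c @ s.T
    rng = np.random.default_rng(seed)
    x = x_clean * (1.0 + noise * rng.normal(size=x_clean.shape))
    return {
        "X": x, "X_clean": x_clean, "C": c, "S": s, "time_min": t,
        "q": q, "wavelengths": lam, "n_q": n_q, "noise": noise,
        "block_slices": {"sans": slice(0, n_q), "fluor": slice(n_q, n_q + n_lambda)},
    }


def reference_dataset(seed: int = 1, noise: float = 0.02, t_end: float = 420.0) -> dict:
    """The packaged synthetic reference: one complete GdL sample.

    Returns SANS series + truth table, ThT / turbidity / pH traces, the
    emission spectral series, and the FTIR series with its buffer.
    """
    t_frames = default_time_grid(t_end)
    script = default_phase_script(seed=seed, noise=noise)
    truth = simulate_param_trajectory(script, t_frames)
    sans = simulate_sans_series(truth, noise=noise, seed=seed + 1)
    t_fine = np.arange(0.0, t_end + 1.0, 1.0)
    tht = simulate_tht(t_fine, noise=0.02, seed=seed + 2)
    turb = simulate_turbidity(t_fine, noise=0.02, seed=seed + 3)
    ph = simulate_ph(1.0, t_fine, noise=0.01, seed=seed + 4)
    emission = simulate_emission_series(t_frames, noise=0.01, seed=seed + 5)
    ftir, buffer_spectrum = simulate_ftir_series(noise=0.01, seed=seed + 6)
    return {
        "script": script, "truth": truth, "sans": sans,
        "tht": tht, "turbidity": turb, "ph": ph,
        "emission": emission, "ftir": ftir, "ftir_buffer": buffer_spectrum,
    }
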