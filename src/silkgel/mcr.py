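"""Joint SANS + fluorescence multivariate curve resolution (MCR-ALS).

The two time-resolved measurements are concatenated column-wise into one
matrix sharing the time dimension (rows = SANS frames, columns = q points
then emission wavelengths), so every resolved component owns a single
concentration profile C(t) with both a scattering signature I(q) and a
fluorescence emission signature.  Alternating non-negativity-constrained
least squares factorises X ≈ C·Sᵀ; the complementary probes constrain the
rotational ambiguity that a single block would leave.

Constraints: non-negativity on C and both S blocks only — no closure (the
components are not an exhaustive mass balance) and no unimodality.  Scale
indeterminacy is fixed by normalising each component signature to unit
maximum, pushing the compensating scale into C; the reconstruction is
invariant under this renormalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import CurveSeries, KineticTrace, SpectrumSeries, resample_trace

__all__ = [
    "JointMatrix",
    "MCRResult",
    "build_joint_matrix",
    "select_rank",
    "mcr_als_solve",
    "envelopes",
    "correlation_map",
]


@dataclass(frozen=True)
class JointMatrix:
    """Row-augmented data matrix: rows = time points, columns = blocks."""

    X: np.ndarray
    time_min: np.ndarray
    block_slices: dict[str, slice]
    block_weights: dict[str, float]
    sans_q: np.ndarray | None = None
    fluor_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("joint matrix entries must be finite")
        if self.X.shape[0] != self.time_min.size:
            raise ValueError("row count must equal the number of time points")

    def block(self, name: str) -> np.ndarray:
        return self.X[:, self.block_slices[name]]


@dataclass
class MCRResult:
    """Resolved concentration profiles and per-block component signatures."""

    C: np.ndarray  # (n_times, k), non-negative
    S: np.ndarray  # (n_columns, k), non-negative, unit-max per component
    time_min: np.ndarray
    block_slices: dict[str, slice]
    lack_of_fit: float  # percent
    lof_history: np.ndarray
    converged: bool
    envelopes: dict[str, np.ndarray] | None = None

    @property
    def k(self) -> int:
        return self.C.shape[1]

    @property
    def S_sans(self) -> np.ndarray:
        return self.S[self.block_slices["sans"], :]

    @property
    def S_fluor(self) -> np.ndarray:
        return self.S[self.block_slices["fluor"], :]

    def reconstruction(self) -> np.ndarray:
        return self.C @ self.S.T

    def profiles_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.C, columns=[f"C{i + 1}" for i in range(self.k)]
        )
        df.insert(0, "time_min", self.time_min)
        return df


def _total_variance(block: np.ndarray) -> float:
    return float(np.sum(np.var(block, axis=0)))


def build_joint_matrix(
    sans: CurveSeries, fluor: SpectrumSeries
) -> JointMatrix:
    """Assemble the joint matrix on the SANS frame-time grid.

    Every fluorescence wavelength channel is linearly resampled onto the
    SANS frame times (frames outside the fluorescence time range are
    truncated away).  Each block is scaled to unit maximum, then the
    fluorescence block is rescaled so the two blocks carry equal total
    variance — neither probe dominates the factorisation.
    """
    frame_times = sans.times
    lo = max(frame_times[0], fluor.time_min[0])
    hi = min(frame_times[-1], fluor.time_min[-1])
    keep = (frame_times >= lo) & (frame_times <= hi)
    if not np.any(keep):
        raise ValueError("SANS and fluorescence series do not overlap in time")
    t = frame_times[keep]
    sans_block = sans.intensity_matrix()[keep]
    fluor_block = np.column_stack(
        [np.interp(t, fluor.time_min, fluor.spectra[:, j])
         for j in range(fluor.axis.size)]
    )
    sans_block = sans_block / float(np.max(np.abs(sans_block)))
    fluor_block = fluor_block / float(np.max(np.abs(fluor_block)))
    v1, v2 = _total_variance(sans_block), _total_variance(fluor_block)
    s = np.sqrt(v1 / v2) if v1 > 0 and v2 > 0 else 1.0
    fluor_block = fluor_block * s
    n_q = sans_block.shape[1]
    # block_weights record each block's final maximum (= its scale factor
    # relative to the unit-max normalisation)
    return JointMatrix(
        X=np.hstack([sans_block, fluor_block]),
        time_min=t,
        block_slices={"sans": slice(0, n_q),
                      "fluor": slice(n_q, n_q + fluor_block.shape[1])},
        block_weights={"sans": 1.0, "fluor": s},
        sans_q=sans.q,
        fluor_axis=fluor.axis,
    )


def select_rank(
    matrix: JointMatrix | np.ndarray, threshold: float = 0.995
) -> tuple[int, np.ndarray]:
    """Smallest rank whose singular values explain ``threshold`` of the
    total variance, together with the full scree (fraction explained)."""
    x = matrix.X if isinstance(matrix, JointMatrix) else np.asarray(matrix)
    s = np.linalg.svd(x, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("matrix has no variance")
    scree = np.cumsum(s**2) / total
    k = int(np.searchsorted(scree, threshold) + 1)
    return k, scree


def _purest_rows(x: np.ndarray, k: int) -> np.ndarray:
    """Mutually most dissimilar rows: start from the largest row, then
    repeatedly add the row with the largest residual after projecting out
    the span of the chosen rows."""
    chosen = [int(np.argmax(np.linalg.norm(x, axis=1)))]
    for _ in range(1, k):
        basis = x[chosen]
        qmat, _ = np.linalg.qr(basis.T)
        resid = x - (x @ qmat) @ qmat.T
        norms = np.linalg.norm(resid, axis=1)
        norms[chosen] = -1.0
        chosen.append(int(np.argmax(norms)))
    return np.maximum(x[chosen], 0.0) + 1e-12


def _nnls_rows(basis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve min ||basis @ w - target|| with w >= 0 for each target column."""
    out = np.empty((targets.shape[1], basis.shape[1]))
    for j in range(targets.shape[1]):
        out[j], _ = nnls(basis, targets[:, j])
    return out


def _normalise_scale(c: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-max signatures; compensating scale moves into C (CSᵀ invariant)."""
    scale = s.max(axis=0)
    scale[scale == 0] = 1.0
    return c * scale, s / scale


def mcr_als_solve(
    matrix: JointMatrix | np.ndarray,
    k: int = 3,
    init: str = "purest_rows",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MCRResult:
    """Alternating non-negativity-constrained least squares.

    Fix S, solve each row of C by NNLS; fix C, solve each column of S;
    iterate until the relative lack-of-fit change drops below ``tol`` or
    ``max_iter`` is reached.  lack_of_fit = 100·sqrt(SSE / total SS) and is
    non-increasing by construction (each half-step is an exact constrained
    minimiser given the other factor).  Deterministic given ``seed``.
    """
    if isinstance(matrix, JointMatrix):
        x = matrix.X
        times = matrix.time_min
        slices = matrix.block_slices
    else:
        x = np.asarray(matrix, dtype=float)
        times = np.arange(x.shape[0], dtype=float)
        slices = {"sans": slice(0, x.shape[1]), "fluor": slice(x.shape[1], x.shape[1])}
    n_rows, n_cols = x.shape
    if not 1 <= k <= min(n_rows, n_cols):
        raise ValueError(f"k must be in [1, {min(n_rows, n_cols)}]")
    if k == n_rows:
        warnings.warn("k equals the number of time points; overparameterised",
                      stacklevel=2)
    if init == "purest_rows":
        s = _purest_rows(x, k).T  # (n_cols, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.1, 1.0, size=(n_cols, k))
    elif isinstance(init, np.ndarray):
        s = np.asarray(init, dtype=float)
    else:
        raise ValueError(f"unknown init {init!r}")
    total_ss = float(np.sum(x**2))
    lof_hist: list[float] = []
    converged = False
    c = np.zeros((n_rows, k))
    for _ in range(max_iter):
        c = _nnls_rows(s, x.T)  # rows of C from X[i] ≈ S @ C[i]
        s = _nnls_rows(c, x)  # columns of S from X[:, j] ≈ C @ S[j]
        sse = float(np.sum((x - c @ s.T) ** 2))
        lof = 100.0 * np.sqrt(sse / total_ss)
        if lof_hist and lof > lof_hist[-1] + 1e-9:
            raise AssertionError("lack of fit increased during ALS")
        done = bool(lof_hist) and (
            lof_hist[-1] == 0.0 or (lof_hist[-1] - lof) / max(lof_hist[-1], 1e-300) < tol
        )
        lof_hist.append(lof)
        if done:
            converged = True
            break
    c, s = _normalise_scale(c, s)
    return MCRResult(
        C=c, S=s, time_min=times, block_slices=slices,
        lack_of_fit=lof_hist[-1], lof_history=np.asarray(lof_hist),
        converged=converged,
    )


def _match_components(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Permutation of ``other``'s components best matching ``ref`` by
    profile correlation (greedy on the correlation matrix)."""
    k = ref.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            ri = np.corrcoef(ref[:, i], other[:, j])[0, 1]
            corr[i, j] = -2.0 if np.isnan(ri) else ri
    perm = np.full(k, -1)
    used: set[int] = set()
    for i, j in sorted(
        ((i, j) for i in range(k) for j in range(k)),
        key=lambda ij: -corr[ij[0], ij[1]],
    ):
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return perm


def envelopes(
    matrix: JointMatrix | np.ndarray,
    k: int = 3,
    n_restarts: int = 8,
    seed: int = 0,
    keep_within: float = 0.05,
    **solve_kwargs,
) -> MCRResult:
    """Restart-based uncertainty envelopes around the best MCR solution.

    The purest-rows solution plus ``n_restarts`` random restarts are run;
    solutions whose lack of fit is within ``keep_within`` (relative) of the
    best are kept, component-matched to the best by profile correlation,
    and the pointwise min/max over the kept concentration profiles forms
    the envelope (which therefore always contains the best profiles).
    """
    if n_restarts < 2:
        raise ValueError("need at least 2 restarts")
    best = mcr_als_solve(matrix, k=k, init="purest_rows", seed=seed, **solve_kwargs)
    solutions = [best]
    for r in range(n_restarts):
        sol = mcr_als_solve(matrix, k=k, init="random", seed=seed + 1 + r,
                            **solve_kwargs)
        solutions.append(sol)
        if sol.lack_of_fit < best.lack_of_fit:
            best = sol
    floor = best.lack_of_fit
    kept = [
        s for s in solutions
        if s.lack_of_fit <= floor * (1.0 + keep_within) + 1e-12
    ]
    stacks = []
    for s in kept:
        perm = _match_components(best.C, s.C)
        c = s.C[:, perm]
        # remove residual per-component scale before band-building
        for i in range(k):
            denom = float(np.max(c[:, i]))
            ref_max = float(np.max(best.C[:, i]))
            if denom > 0 and ref_max > 0:
                c[:, i] = c[:, i] * (ref_max / denom)
        stacks.append(c)
    arr = np.stack(stacks)
    best.envelopes = {"lo": arr.min(axis=0), "hi": arr.max(axis=0)}
    return best


def _minmax(v: np.ndarray) -> np.ndarray:
    span = float(np.max(v) - np.min(v))
    if span == 0.0:
        return np.full_like(v, np.nan)
    return (v - np.min(v)) / span


def correlation_map(
    result: MCRResult | np.ndarray,
    signals: dict[str, KineticTrace | tuple[np.ndarray, np.ndarray]],
    time_min: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each component profile with each named signal.

    Signals are min-max normalised, linearly resampled onto the component
    time grid and truncated to the common overlap before correlating
    (min-max scaling does not change |r| or its sign).  Constant signals
    yield NaN.  Typical columns: the eight model parameters plus ThT and
    turbidity — the 3 × 10 bubble-matrix layout.
    """
    if isinstance(result, MCRResult):
        c, t_c = result.C, result.time_min
    else:
        c = np.asarray(result, dtype=float)
        if time_min is None:
            raise ValueError("time_min required when passing a bare C matrix")
        t_c = np.asarray(time_min, dtype=float)
    if t_c.size < 3:
        raise ValueError("need at least 3 matched time points")
    # common overlap across all signals
    lo, hi = t_c[0], t_c[-1]
    prepared: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, sig in signals.items():
        if isinstance(sig, KineticTrace):
            ts, vs = sig.time_min, sig.value
        else:
            ts, vs = (np.asarray(a, dtype=float) for a in sig)
        lo, hi = max(lo, ts[0]), min(hi, ts[-1])
        prepared[name] = (ts, vs)
    keep = (t_c >= lo) & (t_c <= hi)
    if np.count_nonzero(keep) < 3:
        raise ValueError("fewer than 3 overlapping time points")
    t = t_c[keep]
    rows = {}
    for name, (ts, vs) in prepared.items():
        v = np.interp(t, ts, _minmax(vs))
        col = []
        for i in range(c.shape[1]):
            ci = c[keep, i]
            if np.all(v == v[0]) or np.isnan(v).any() or np.all(ci == ci[0]):
                col.append(np.nan)
            else:
                col.append(float(np.corrcoef(ci, v)[0, 1]))
        rows[name] = col
    return pd.DataFrame(rows, index=[f"C{i + 1}" for i in range(c.shape[1])])
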