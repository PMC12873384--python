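"""DBSCAN phase mapping of the fitted parameter trajectories.

The eight fitted parameters (a, n, c, η, m, d, q0, σ — the background b
is excluded) are Z-scored per sample and clustered with DBSCAN
(Euclidean metric, eps = 1.0, min_samples = 5).  Clusters are assigned to
the four gelation phases — Initiation, Pre-assembly, Network Assembly,
Maturation — by their median member time; per-phase convex-hull volumes
(in the most correlated (n, m, d) subspace by default) and η/d*
statistics summarise the map.

DBSCAN neighbourhood convention: closed ball (distance ≤ eps) with the
point itself counted toward min_samples — implementations differ, so this
is stated explicitly and matched by the test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN

from .model import CLUSTER_PARAMS, TWO_PI, ParamTrajectory

__all__ = [
    "PHASE_NAMES",
    "PhaseAssignment",
    "zscore_matrix",
    "dbscan",
    "assign_phases",
    "hull_volumes",
    "phase_statistics",
    "cluster_phases",
]

PHASE_NAMES = ("Initiation", "Pre-assembly", "Network Assembly", "Maturation")
NOISE_LABEL = "Noise"
#: default convex-hull subspace: the most correlated parameter triple
DEFAULT_HULL_SUBSPACE = ("n", "m", "d")


@dataclass
class PhaseAssignment:
    """Per-frame phase labels with hull volumes and per-phase statistics."""

    labels: np.ndarray  # per-frame phase name (or "Noise")
    cluster_ids: np.ndarray  # raw DBSCAN ids (-1 = noise)
    times: np.ndarray
    hull_volume_pct: dict[str, float] = field(default_factory=dict)
    phase_stats: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "cluster_id": self.cluster_ids,
             "phase": self.labels}
        )

    def summary(self) -> pd.DataFrame:
        """Phase-level table: hull volume share and η/d* mean ± sd."""
        if self.phase_stats is None:
            raise ValueError("phase statistics not computed")
        out = self.phase_stats.copy()
        out.insert(1, "volume_pct",
                   [self.hull_volume_pct.get(p, 0.0) for p in out["phase"]])
        return out


def trajectory_param_matrix(traj: ParamTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """(frames × 8) parameter matrix and the matching frame times.

    Failed frames are dropped.  Requires peak-stage fits (the Gaussian
    parameters are part of the eight-dimensional space).
    """
    rows, times = [], []
    for t, r in zip(traj.times, traj.results):
        if r.params is None:
            continue
        if r.params.stage != "peak":
            raise ValueError("phase clustering requires peak-stage fits")
        rows.append([getattr(r.params, k) for k in CLUSTER_PARAMS])
        times.append(t)
    if len(rows) < 2:
        raise ValueError("need at least 2 fitted frames")
    return np.asarray(rows, dtype=float), np.asarray(times, dtype=float)


def zscore_matrix(traj: ParamTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Z-score the eight-parameter trajectory (per-parameter mean 0, sd 1).

    Zero-variance parameters are set to all-zeros with a warning rather
    than dividing by zero.  Returns ``(points, times)``.
    """
    x, times = trajectory_param_matrix(traj)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population sd
    # identical values can leave a ~1e-22 rounding sd; treat as zero
    sd[sd <= 1e-12 * np.maximum(np.abs(mean), 1e-300)] = 0.0
    z = np.zeros_like(x)
    for j in range(x.shape[1]):
        if sd[j] == 0.0:
            warnings.warn(
                f"parameter {CLUSTER_PARAMS[j]!r} has zero variance; "
                "column set to 0", stacklevel=2,
            )
        else:
            z[:, j] = (x[:, j] - mean[j]) / sd[j]
    return z, times


def dbscan(points: np.ndarray, eps: float = 1.0, min_samples: int = 5) -> np.ndarray:
    """DBSCAN cluster ids (noise = -1), Euclidean metric.

    Core points have at least ``min_samples`` neighbours within ``eps``
    (closed ball, self counted); border points join a core's cluster;
    unreachable points are noise.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    points = np.asarray(points, dtype=float)
    return DBSCAN(eps=eps, min_samples=min_samples, metric="euclidean").fit_predict(
        points
    )


def assign_phases(cluster_ids: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Map raw cluster ids to phase names by dominant time.

    Clusters ordered by median member time take the canonical phase names
    in order.  With more than four clusters, the four most populous keep
    the names (re-ordered by median time) and the rest become noise; with
    fewer, only the earliest names are used.  Both cases warn.
    """
    cluster_ids = np.asarray(cluster_ids)
    times = np.asarray(times, dtype=float)
    ids = [c for c in np.unique(cluster_ids) if c != -1]
    if not ids:
        raise ValueError("all points are noise; no clusters to label")
    if len(ids) > 4:
        sizes = {c: int(np.sum(cluster_ids == c)) for c in ids}
        keep = sorted(sorted(ids), key=lambda c: -sizes[c])[:4]
        warnings.warn(
            f"{len(ids)} clusters found; demoting the {len(ids) - 4} smallest "
            "to noise", stacklevel=2,
        )
        ids = keep
    medians = {c: float(np.median(times[cluster_ids == c])) for c in ids}
    ordered = sorted(ids, key=lambda c: medians[c])
    if len(ordered) < 4:
        warnings.warn(
            f"only {len(ordered)} clusters found; later phase names unused",
            stacklevel=2,
        )
    name_of = {c: PHASE_NAMES[k] for k, c in enumerate(ordered)}
    return np.array([name_of.get(c, NOISE_LABEL) for c in cluster_ids])


def _hull_volume(pts: np.ndarray) -> float:
    if pts.shape[0] < pts.shape[1] + 1:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0  # degenerate geometry (coplanar/collinear)


def hull_volumes(
    points: np.ndarray,
    labels: np.ndarray,
    subspace: tuple[int, ...] | None = None,
) -> dict[str, float]:
    """Per-phase convex-hull volume as a percentage of the summed volumes.

    ``points`` are the Z-scored coordinates; ``subspace`` selects column
    indices (callers clustering the eight-parameter space pass the
    (n, m, d) triple by default — see :func:`cluster_phases`).  Noise is
    excluded; phases with fewer than dim+1 points or degenerate geometry
    get volume 0.  Raises when every hull is degenerate.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if subspace is not None:
        points = points[:, list(subspace)]
    phases = [p for p in PHASE_NAMES if p in labels]
    vols = {p: _hull_volume(points[labels == p]) for p in phases}
    total = sum(vols.values())
    if total <= 0.0:
        raise ValueError("all phase hulls are degenerate; percentages undefined")
    return {p: 100.0 * v / total for p, v in vols.items()}


def phase_statistics(traj: ParamTrajectory, labels: np.ndarray) -> pd.DataFrame:
    """Mean ± sd of η and d* per phase (population sd, so single-member
    phases report ± 0)."""
    x, times = trajectory_param_matrix(traj)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels do not cover the trajectory's fitted frames")
    eta = x[:, CLUSTER_PARAMS.index("eta")]
    d_star = TWO_PI / x[:, CLUSTER_PARAMS.index("q0")]
    rows = []
    for p in PHASE_NAMES:
        mask = labels == p
        if not np.any(mask):
            continue
        rows.append(
            {
                "phase": p,
                "n_frames": int(mask.sum()),
                "eta_mean": float(np.mean(eta[mask])),
                "eta_sd": float(np.std(eta[mask])),
                "dstar_mean": float(np.mean(d_star[mask])),
                "dstar_sd": float(np.std(d_star[mask])),
            }
        )
    return pd.DataFrame(rows)


def cluster_phases(
    traj: ParamTrajectory,
    eps: float = 1.0,
    min_samples: int = 5,
    hull_subspace: tuple[str, ...] = DEFAULT_HULL_SUBSPACE,
) -> PhaseAssignment:
    """Full phase map: Z-score → DBSCAN → phase labels → hulls → stats.

    The hull subspace defaults to the (n, m, d) triple where the phase
    envelopes are visualised; an eight-dimensional hull is available by
    passing all parameter names, but on ~60 frames it is noise-dominated.
    """
    z, times = zscore_matrix(traj)
    ids = dbscan(z, eps=eps, min_samples=min_samples)
    labels = assign_phases(ids, times)
    idx = tuple(CLUSTER_PARAMS.index(k) for k in hull_subspace)
    volumes = hull_volumes(z, labels, subspace=idx)
    stats = phase_statistics(traj, labels)
    return PhaseAssignment(
        labels=labels, cluster_ids=ids, times=times,
        hull_volume_pct=volumes, phase_stats=stats,
    )
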