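import warnings

import numpy as np
import pandas as pd
import pytest

import silkgel as sg
from silkgel.clustering import (
    PHASE_NAMES,
    assign_phases,
    dbscan,
    hull_volumes,
    phase_statistics,
    zscore_matrix,
)
from silkgel.model import FitResult, HierParams, ParamTrajectory, TWO_PI


def brute_force_dbscan(points, eps=1.0, min_samples=5):
    """Independent O(n^2) neighbourhood-expansion implementation.

    Closed-ball neighbourhoods, self counted toward min_samples, border
    points join the first core that reaches them.
    """
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbours = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbours])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neighbours[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels


def partitions_equal(a, b):
    """Same partition up to cluster-id permutation (noise must match)."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def make_trajectory(param_rows, times=None):
    times = np.arange(5.0, 5.0 * (len(param_rows) + 1), 5.0) if times is None \
        else np.asarray(times)
    results = [
        FitResult(
            params=HierParams(stage="peak", **row), residual_norm=0.0,
            n_points_used=100, converged=True, d_star=TWO_PI / row["q0"],
        )
        for row in param_rows
    ]
    return ParamTrajectory(times=times, results=results)


def base_row(**over):
    row = dict(a=1e-6, n=3.0, c=1.0, eta=50.0, m=2.5, d=0.2, q0=0.016,
               sigma=0.003, b=0.03)
    row.update(over)
    return row


class TestZscore:
    def test_two_frames_become_plus_minus_one(self):
        traj = make_trajectory([base_row(n=2.0), base_row(n=4.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, _ = zscore_matrix(traj)
        n_col = z[:, 1]
        np.testing.assert_allclose(sorted(n_col), [-1.0, 1.0])

    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        rows = [base_row(n=3 + rng.normal(), eta=50 + 5 * rng.normal(),
                         d=0.2 + 0.05 * rng.normal())
                for _ in range(20)]
        z, _ = zscore_matrix(make_trajectory(rows))
        varying = z.std(axis=0) > 0
        assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
        np.testing.assert_allclose(z[:, varying].std(axis=0), 1.0)

    def test_constant_column_zeroed_with_warning(self):
        rows = [base_row(n=2.0 + k) for k in range(5)]  # sigma constant
        with pytest.warns(UserWarning, match="sigma"):
            z, _ = zscore_matrix(make_trajectory(rows))
        sigma_col = z[:, 7]
        np.testing.assert_array_equal(sigma_col, 0.0)


class TestDbscan:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, (10, 3))
        b = rng.normal(10, 0.1, (10, 3))
        labels = dbscan(np.vstack([a, b]), eps=1.0, min_samples=5)
        assert len(set(labels)) == 2 and -1 not in labels

    def test_isolated_points_are_noise(self):
        pts = np.diag([10.0, 20.0, 30.0, 40.0])
        labels = dbscan(pts, eps=1.0, min_samples=5)
        assert set(labels) == {-1}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1.5, (60, 8))
        assert partitions_equal(
            dbscan(pts, eps=1.0, min_samples=5),
            brute_force_dbscan(pts, eps=1.0, min_samples=5),
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.5, (20, 4)), rng.normal(5, 0.5, (20, 4))])
        perm = rng.permutation(len(pts))
        l1 = dbscan(pts)
        l2 = dbscan(pts[perm])
        assert partitions_equal(l1[perm], l2)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            dbscan(np.zeros((3, 2)), eps=0.0)
        with pytest.raises(ValueError):
            dbscan(np.zeros((3, 2)), min_samples=0)


class TestAssignPhases:
    def test_canonical_order_by_median_time(self):
        ids = np.array([2, 2, 0, 0, 3, 3, 1, 1])
        times = np.array([10, 12, 100, 110, 250, 260, 400, 410.0])
        labels = assign_phases(ids, times)
        assert list(labels[:2]) == ["Initiation"] * 2
        assert list(labels[2:4]) == ["Pre-assembly"] * 2
        assert list(labels[4:6]) == ["Network Assembly"] * 2
        assert list(labels[6:]) == ["Maturation"] * 2

    def test_two_clusters_use_earliest_names(self):
        ids = np.array([0, 0, 1, 1])
        times = np.array([10, 20, 200, 210.0])
        with pytest.warns(UserWarning, match="2 clusters"):
            labels = assign_phases(ids, times)
        assert set(labels) == {"Initiation", "Pre-assembly"}

    def test_fifth_smallest_cluster_demoted_to_noise(self):
        ids = np.array([0] * 6 + [1] * 6 + [2] * 6 + [3] * 6 + [4] * 3)
        times = np.arange(len(ids), dtype=float)
        with pytest.warns(UserWarning, match="demoting"):
            labels = assign_phases(ids, times)
        assert list(labels[-3:]) == ["Noise"] * 3
        assert set(labels[:-3]) == set(PHASE_NAMES)

    def test_all_noise_is_error(self):
        with pytest.raises(ValueError):
            assign_phases(np.array([-1, -1, -1]), np.array([1.0, 2.0, 3.0]))


class TestHullVolumes:
    def test_cube_versus_tetrahedron_closed_form(self):
        cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                         for z in (0, 1)], dtype=float)  # volume 1
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / (2 * np.sqrt(2)) + 5.0  # edge 1
        pts = np.vstack([cube, tet])
        labels = np.array(["Initiation"] * 8 + ["Pre-assembly"] * 4)
        pct = hull_volumes(pts, labels)
        # volumes 1 and 1/(6*sqrt(2)) = 0.117851: shares 89.457% / 10.543%
        tet_vol = 1.0 / (6.0 * np.sqrt(2.0))
        assert pct["Initiation"] == pytest.approx(100.0 / (1 + tet_vol), abs=1e-6)
        assert pct["Pre-assembly"] == pytest.approx(100.0 * tet_vol / (1 + tet_vol),
                                                    abs=1e-6)

    def test_single_phase_is_100(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        pct = hull_volumes(pts, np.array(["Maturation"] * 10))
        assert pct == {"Maturation": pytest.approx(100.0)}

    def test_coplanar_phase_gets_zero(self):
        rng = np.random.default_rng(0)
        solid = rng.normal(size=(8, 3))
        flat = np.column_stack([rng.normal(size=(5, 2)), np.zeros(5)])
        pts = np.vstack([solid, flat])
        labels = np.array(["Initiation"] * 8 + ["Pre-assembly"] * 5)
        pct = hull_volumes(pts, labels)
        assert pct["Pre-assembly"] == 0.0
        assert pct["Initiation"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(4, 2, (10, 3))])
        labels = np.array(["Initiation"] * 10 + ["Maturation"] * 10)
        assert sum(hull_volumes(pts, labels).values()) == pytest.approx(100.0,
                                                                        abs=1e-6)

    def test_all_degenerate_is_error(self):
        pts = np.zeros((6, 3))
        labels = np.array(["Initiation"] * 6)
        with pytest.raises(ValueError):
            hull_volumes(pts, labels)


class TestPhaseStatistics:
    def test_two_member_phase_mean_sd(self):
        traj = make_trajectory([base_row(eta=40.0), base_row(eta=60.0)])
        stats = phase_statistics(traj, np.array(["Initiation"] * 2))
        row = stats.iloc[0]
        assert row.eta_mean == pytest.approx(50.0)
        assert row.eta_sd == pytest.approx(10.0)  # population sd

    def test_single_member_phase_has_zero_sd(self):
        traj = make_trajectory([base_row(eta=40.0), base_row(eta=60.0)])
        stats = phase_statistics(
            traj, np.array(["Initiation", "Maturation"])
        )
        assert (stats.set_index("phase").loc["Maturation", "eta_sd"]
                == pytest.approx(0.0))

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(9)
        rows = [base_row(eta=float(50 + 10 * rng.normal()),
                         q0=float(rng.uniform(0.014, 0.024)))
                for _ in range(30)]
        labels = np.array(rng.choice(PHASE_NAMES, size=30))
        traj = make_trajectory(rows)
        stats = phase_statistics(traj, labels).set_index("phase")
        df = pd.DataFrame(
            {"eta": [r["eta"] for r in rows],
             "dstar": [TWO_PI / r["q0"] for r in rows], "phase": labels}
        )
        oracle = df.groupby("phase").agg(["mean", lambda v: v.std(ddof=0)])
        for phase in stats.index:
            assert stats.loc[phase, "eta_mean"] == pytest.approx(
                oracle.loc[phase, ("eta", "mean")], rel=1e-12
            )
            assert stats.loc[phase, "dstar_sd"] == pytest.approx(
                oracle.loc[phase, ("dstar", "<lambda_0>")], rel=1e-12, abs=1e-12
            )
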