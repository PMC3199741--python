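import numpy as np
import pytest

import fissionfusion as ff
from fissionfusion.association import AssociationMatrix
from fissionfusion.dyad_dynamics import TrajectorySet


def matrices_from_stack(stack, ids):
    """stack: (n_seasons, n, n) symmetric SRI arrays."""
    out = []
    for arr in stack:
        arr = np.asarray(arr, dtype=float)
        out.append(
            AssociationMatrix(ids, arr, (arr > 0).astype(int), 10, np.zeros(arr.shape, int))
        )
    return out


SEASONS = ["T1", "D1", "W1", "D2", "W2"]


class TestBuildTrajectories:
    def test_inclusion_and_exclusion(self):
        ids = ["a", "b", "c"]
        zero = np.zeros((3, 3))
        one = zero.copy()
        one[0, 1] = one[1, 0] = 0.4  # a-b associate in season 2 only
        mats = matrices_from_stack([zero, one, zero, zero, zero], ids)
        ts = ff.build_trajectories(mats, ids, SEASONS)
        assert ts.dyads == [("a", "b")]
        np.testing.assert_allclose(ts.values[0], [0, 0.4, 0, 0, 0])

    def test_candidate_count_before_filter(self):
        ids = [f"i{k:02d}" for k in range(10)]
        full = np.full((10, 10), 0.2)
        np.fill_diagonal(full, 0)
        mats = matrices_from_stack([full] * 5, ids)
        ts = ff.build_trajectories(mats, ids, SEASONS)
        assert len(ts) == 10 * 9 // 2

    def test_missing_id_counts_as_zero(self):
        ids = ["a", "b"]
        m = np.array([[0, 0.5], [0.5, 0]])
        mats = matrices_from_stack([m], ids) + matrices_from_stack(
            [np.zeros((1, 1))], ["a"]
        )
        ts = ff.build_trajectories(mats, ["a", "b"], ["s1", "s2"])
        np.testing.assert_allclose(ts.values[0], [0.5, 0.0])


class TestSplitStable:
    def test_examples(self):
        ts = TrajectorySet(
            [("a", "b"), ("a", "c")],
            np.array([[0.4, 0.35, 0.9, 0.31, 0.5], [0.4, 0.29, 0.9, 0.31, 0.5]]),
            SEASONS,
        )
        type_a, rest = ff.split_stable(ts, floor=0.3)
        assert type_a == [("a", "b")]
        assert rest.dyads == [("a", "c")]

    def test_zero_floor_everything_stable(self):
        ts = TrajectorySet([("a", "b")], np.array([[0.1, 0, 0, 0, 0]]), SEASONS)
        type_a, rest = ff.split_stable(ts, floor=0.0)
        assert len(type_a) == 1 and len(rest) == 0

    def test_partition_property(self, paper_like_pipeline):
        p = paper_like_pipeline
        mats = [p["mats"][lab] for lab in p["cfg"].season_labels]
        ts = ff.build_trajectories(mats, sorted(p["core"]), SEASONS)
        type_a, rest = ff.split_stable(ts, 0.3)
        assert len(type_a) + len(rest) == len(ts)


class TestCorrelationDistance:
    def test_affine_transform_gives_zero(self):
        u = np.array([0.1, 0.5, 0.2, 0.9, 0.3])
        assert ff.correlation_distance(u, 2 * u + 1) == pytest.approx(0.0)

    def test_anticorrelated_gives_two(self):
        u = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        assert ff.correlation_distance(u, -u) == pytest.approx(2.0)

    def test_hand_computed_value(self):
        u = np.array([0, 1, 0, 0, 0], dtype=float)
        v = np.array([0, 0, 1, 0, 0], dtype=float)
        assert ff.correlation_distance(u, v) == pytest.approx(1.25)

    def test_flat_vector_flagged(self):
        with pytest.raises(ValueError):
            ff.correlation_distance(np.ones(5), np.arange(5.0))


def template_trajectories(n, templates, noise_sd_frac, rng):
    rows = []
    for i in range(n):
        t = templates[i % len(templates)]
        rows.append(np.clip(t + rng.normal(0, noise_sd_frac * t.max(), len(t)), 0, 1))
    dyads = [(f"x{i}", f"y{i}") for i in range(n)]
    return TrajectorySet(dyads, np.array(rows), SEASONS)


class TestSelectK:
    def test_recovers_three_templates(self):
        templates = np.array(
            [
                [0.05, 0.5, 0.05, 0.05, 0.05],
                [0.05, 0.05, 0.05, 0.5, 0.05],
                [0.4, 0.05, 0.3, 0.05, 0.05],
            ]
        )
        rng = np.random.default_rng(0)
        ts = template_trajectories(60, templates, 0.1, rng)
        sel = ff.select_k_by_bic(ts, k_range=range(2, 9), runs_per_k=20, seed=0)
        assert sel.k_opt == 3
        assert set(sel.mean_bic) == set(range(2, 9))  # full curve for plotting

    def test_degenerate_input_reports_failure(self):
        ts = TrajectorySet(
            [(f"a{i}", f"b{i}") for i in range(10)],
            np.tile([0.1, 0.2, 0.1, 0.05, 0.02], (10, 1)),
            SEASONS,
        )
        with pytest.raises(ValueError):
            ff.select_k_by_bic(ts, k_range=range(2, 5), runs_per_k=5, seed=0)


class TestClusterTrajectories:
    def test_two_exact_shapes_separate_perfectly(self):
        templates = np.array([[0.1, 0.6, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.6, 0.1]])
        rng = np.random.default_rng(1)
        ts = template_trajectories(20, templates, 0.0, rng)
        res = ff.cluster_trajectories(ts, k=2, runs=10, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-20)
        groups = {}
        for (a, _), c in res.assignment.items():
            groups.setdefault(c, set()).add(int(a[1:]) % 2)
        assert all(len(v) == 1 for v in groups.values())

    def test_reproducible_and_monotone_in_restarts(self):
        templates = np.array(
            [[0.05, 0.5, 0.05, 0.05, 0.05], [0.05, 0.05, 0.05, 0.5, 0.05],
             [0.4, 0.05, 0.3, 0.05, 0.05]]
        )
        rng = np.random.default_rng(2)
        ts = template_trajectories(45, templates, 0.15, rng)
        r1 = ff.cluster_trajectories(ts, k=4, runs=30, seed=7)
        r2 = ff.cluster_trajectories(ts, k=4, runs=30, seed=7)
        assert r1.assignment == r2.assignment and r1.inertia == r2.inertia
        r_few = ff.cluster_trajectories(ts, k=4, runs=2, seed=7)
        assert r1.inertia <= r_few.inertia + 1e-12

    def test_scale_invariance_of_assignment(self):
        """Correlation distance ignores uniform scaling of one trajectory."""
        templates = np.array([[0.1, 0.6, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.6, 0.1]])
        rng = np.random.default_rng(3)
        ts = template_trajectories(20, templates, 0.05, rng)
        scaled = TrajectorySet(ts.dyads, ts.values.copy(), ts.season_labels)
        scaled.values[0] *= 3.7
        r1 = ff.cluster_trajectories(ts, k=2, runs=10, seed=0)
        r2 = ff.cluster_trajectories(scaled, k=2, runs=10, seed=0)
        same = {d: (r1.assignment[d] == r1.assignment[ts.dyads[0]]) for d in ts.dyads}
        same2 = {d: (r2.assignment[d] == r2.assignment[ts.dyads[0]]) for d in ts.dyads}
        assert same == same2

    def test_flat_unstable_bin(self):
        vals = np.array([[0.1, 0.1, 0.1, 0.1, 0.1],
                         [0.1, 0.6, 0.1, 0.1, 0.1],
                         [0.1, 0.1, 0.1, 0.6, 0.1],
                         [0.2, 0.1, 0.6, 0.1, 0.1]])
        ts = TrajectorySet([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")], vals, SEASONS)
        res = ff.cluster_trajectories(ts, k=2, runs=5, seed=0)
        assert res.flat_unstable == [("a", "b")]
        assert ("a", "b") not in res.assignment


class TestLabelTypes:
    def test_single_interior_peak(self):
        labels = ff.label_trajectory_types(
            np.array([[0.1, 0.5, 0.1, 0.1, 0.1]]), SEASONS
        )
        assert labels[0] == ("B", ["D1"])

    def test_two_peaks_is_cyclic(self):
        labels = ff.label_trajectory_types(
            np.array([[0.1, 0.5, 0.1, 0.5, 0.1]]), SEASONS
        )
        assert labels[0] == ("C", ["D1", "D2"])

    def test_monotone_increasing_peaks_at_last_season(self):
        labels = ff.label_trajectory_types(
            np.array([[0.1, 0.2, 0.3, 0.4, 0.5]]), SEASONS
        )
        assert labels[0] == ("B", ["W2"])

    def test_flat_centroid_labeled_flat(self):
        labels = ff.label_trajectory_types(np.array([[0.2] * 5]), SEASONS)
        assert labels[0][0] == "flat"
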