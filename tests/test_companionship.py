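import numpy as np
import pytest

import fissionfusion as ff
from fissionfusion.association import AssociationMatrix


def null_slot_mc_se(N, n, S, m, reps):
    """Monte-Carlo SE of the simulated F(m), from the analytic per-replicate
    variance (partner m-counts treated as independent binomials; their
    coupling through the without-replacement draw is weakly negative, so this
    bound is slightly conservative)."""
    from math import comb

    q = n / (N - 1)
    p_m = comb(S, m) * q**m * (1 - q) ** (S - m)
    var_k = (N - 1) * p_m * (1 - p_m)
    var_f = var_k * (m / (S * n)) ** 2
    return float(np.sqrt(var_f / reps))


def matrix_from_rows(rows, ids):
    arr = np.asarray(rows, dtype=float)
    return AssociationMatrix(ids, arr, (arr > 0).astype(int), 10, np.zeros(arr.shape, int))


class TestTopN:
    def setup_method(self):
        # ego a: b 0.5, c 0.2, d 0.0
        self.ids = ["a", "b", "c", "d"]
        arr = np.zeros((4, 4))
        arr[0, 1] = arr[1, 0] = 0.5
        arr[0, 2] = arr[2, 0] = 0.2
        self.m = matrix_from_rows(arr, self.ids)

    def test_ranking_skips_zero_sri(self):
        assert ff.top_n_associates(self.m, "a", 2) == ["b", "c"]

    def test_short_list_when_few_partners(self):
        assert ff.top_n_associates(self.m, "a", 5) == ["b", "c"]

    def test_deterministic_tie_break(self):
        arr = np.zeros((4, 4))
        for j in (1, 2, 3):
            arr[0, j] = arr[j, 0] = 0.3
        m = matrix_from_rows(arr, self.ids)
        counts = {"b": 5, "c": 9, "d": 1}
        top = ff.top_n_associates(m, "a", 2, sighting_counts=counts)
        assert top == ["c", "b"]  # more sightings first, then lexicographic
        top2 = ff.top_n_associates(m, "a", 2)
        assert top2 == ["b", "c"]

    def test_unknown_ego_errors(self):
        with pytest.raises(KeyError):
            ff.top_n_associates(self.m, "zz", 2)


class TestSlotAllocation:
    def test_worked_ranking_example(self):
        """Partner ranked 3rd, 2nd, 6th, 5th, 9th over 5 seasons with n=5
        occupies exactly 3 companion slots (a 3-term associate)."""
        ranks = [3, 2, 6, 5, 9]
        others = [f"o{k}" for k in range(9)]
        lists = []
        for r in ranks:
            # construct a season top-5 in which partner 'p' sits at rank r
            season = others[:4] if r > 5 else others[: r - 1] + ["p"] + others[r - 1 : 4]
            lists.append(season[:5])
        alloc = ff.slot_allocation({"ego": lists})
        m_of_p = sum("p" in lst for lst in lists)
        assert m_of_p == 3
        assert alloc.k["ego"][3] >= 1
        assert alloc.f["ego"][3] == pytest.approx(alloc.k["ego"][3] * 3 / 25)

    def test_perfect_fidelity(self):
        lists = [["b", "c", "d", "e", "f"]] * 5
        alloc = ff.slot_allocation({"a": lists})
        assert alloc.k["a"][5] == 5
        assert alloc.f["a"][5] == pytest.approx(1.0)
        assert all(alloc.f["a"][m] == 0 for m in range(1, 5))

    def test_fractions_sum_to_one_when_slots_filled(self):
        rng = np.random.default_rng(0)
        others = [f"o{k}" for k in range(20)]
        topn = {
            f"e{i}": [list(rng.choice(others, 5, replace=False)) for _ in range(5)]
            for i in range(12)
        }
        alloc = ff.slot_allocation(topn)
        for ego in topn:
            assert sum(alloc.f[ego].values()) == pytest.approx(1.0)
            assert alloc.shortfall[ego] == 0

    def test_shortfall_reported(self):
        lists = [["b", "c"], ["b"], ["b", "c"], ["b"], ["b"]]
        alloc = ff.slot_allocation({"a": lists})
        assert alloc.shortfall["a"] == 5 * 2 - 7
        assert sum(alloc.f["a"].values()) < 1.0


class TestNullSlots:
    def test_analytic_long_term_fraction(self):
        F = ff.null_slot_allocation(51, 5, 5, mode="analytic")
        assert F[5] == pytest.approx((5 / 50) ** 4, rel=1e-12)  # = 0.0001

    def test_analytic_fractions_sum_to_one(self):
        F = ff.null_slot_allocation(30, 4, 5, mode="analytic")
        assert sum(F.values()) == pytest.approx(1.0)

    def test_simulation_agrees_with_analytic(self):
        F = ff.null_slot_allocation(51, 5, 5, mode="analytic")
        reps = 4000
        sim = ff.null_slot_allocation(51, 5, 5, mode="simulate", reps=reps, seed=0)
        for m in range(1, 6):
            assert abs(sim[m] - F[m]) <= 3 * null_slot_mc_se(51, 5, 5, m, reps)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ff.null_slot_allocation(5, 5, 5)
        with pytest.raises(ValueError):
            ff.null_slot_allocation(51, 5, 5, mode="wrong")


class TestTurnover:
    def test_full_retention_and_full_turnover(self):
        same = {"a": [["b", "c", "d", "e", "f"]] * 5}
        assert ff.companion_turnover(same).retained["a"] == 5
        others = [f"o{k}" for k in range(25)]
        disjoint = {"a": [others[5 * s : 5 * s + 5] for s in range(5)]}
        assert ff.companion_turnover(disjoint).retained["a"] == 0

    def test_histogram_sums_to_one(self):
        rng = np.random.default_rng(1)
        pool = [f"o{k}" for k in range(12)]
        topn = {
            f"e{i}": [list(rng.choice(pool, 5, replace=False)) for _ in range(5)]
            for i in range(20)
        }
        hist = ff.companion_turnover(topn).histogram()
        assert sum(hist.values()) == pytest.approx(1.0)
        assert set(hist) == set(range(6))

    def test_needs_two_seasons(self):
        with pytest.raises(ValueError):
            ff.companion_turnover({"a": [["b"]]})


class TestUShape:
    def test_fixed_pool_plus_transients_gives_u_shape(self):
        """A long-term companion pool plus per-season transients yields slot
        fractions concentrated at m=1 and m=5 (U-shaped fidelity)."""
        rng = np.random.default_rng(2)
        transients = [f"t{k}" for k in range(60)]
        topn = {}
        for i in range(30):
            fixed = [f"f{i}_{j}" for j in range(3)]
            lists = []
            for s in range(5):
                extra = list(rng.choice(transients, 2, replace=False))
                lists.append(fixed + extra)
            topn[f"e{i}"] = lists
        alloc = ff.slot_allocation(topn)
        F = alloc.population_mean_f()
        assert F[1] > F[3] + F[4]
        assert F[5] > F[3] + F[4]


class TestGregariousnessTradeoff:
    def test_single_partner_degenerate_point(self):
        ids = ["a", "b", "c"]
        arr = np.zeros((3, 3))
        arr[0, 1] = arr[1, 0] = 1.0
        arr[1, 2] = arr[2, 1] = 0.5
        mats = [matrix_from_rows(arr, ids)] * 5
        out = ff.gregariousness_tradeoff(mats, ids)
        assert out["points"]["a"] == (1.0, 1.0)

    def test_scaling_sri_scales_strength_not_degree(self):
        rng = np.random.default_rng(3)
        a = rng.random((8, 8)) * (rng.random((8, 8)) < 0.5)
        a = np.triu(a, 1) + np.triu(a, 1).T
        ids = [f"i{k}" for k in range(8)]
        m1 = ff.gregariousness_tradeoff([matrix_from_rows(a, ids)], ids)
        m2 = ff.gregariousness_tradeoff([matrix_from_rows(a / 2, ids)], ids)
        for ego in m1["points"]:
            x1, y1 = m1["points"][ego]
            x2, y2 = m2["points"][ego]
            assert x1 == x2 and y2 == pytest.approx(y1 / 2)

    def test_planted_tradeoff_detected(self):
        """Time budget split evenly among partners (SRI ~ c/degree) gives a
        significant negative degree-strength slope."""
        rng = np.random.default_rng(4)
        n = 50
        ids = [f"i{k}" for k in range(n)]
        arr = np.zeros((n, n))
        degrees = rng.integers(1, 11, size=n)
        for i in range(n):
            partners = rng.choice([j for j in range(n) if j != i], degrees[i], replace=False)
            for j in partners:
                w = 0.6 / degrees[i] * float(rng.uniform(0.8, 1.2))
                arr[i, j] = arr[j, i] = max(arr[i, j], w)
        out = ff.gregariousness_tradeoff([matrix_from_rows(arr, ids)], ids)
        assert out["slope"] < 0
        assert out["p_value"] < 0.05
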