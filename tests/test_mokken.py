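"""Mokken-stage checks: H coefficients against hand and brute-force oracles,
AISP behaviour on known structures, hypothesis diagnostics, reliability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icfscale.mokken as mk
from conftest import random_binary_matrix, simulate_rasch
from icfscale.matrices import BinaryResponseMatrix, ValidationError
from icfscale.synthetic import ItemSpec, SimulationConfig, simulate_dichotomous


def brute_force_h(values):
    """H, Hi, Hij straight from the Guttman-error definition by double loops."""
    n, k = values.shape
    p = values.mean(axis=0)
    order = sorted(range(k), key=lambda i: (-p[i], i))
    rank = {item: pos for pos, item in enumerate(order)}
    F = np.zeros((k, k))
    E = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            e, h = (i, j) if rank[i] < rank[j] else (j, i)
            F[i, j] = sum(1 for row in values if row[e] == 0 and row[h] == 1)
            E[i, j] = n * (1 - p[e]) * p[h]
    Hij = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i != j and E[i, j] > 0:
                Hij[i, j] = 1 - F[i, j] / E[i, j]
    Hi = np.array([1 - F[i].sum() / E[i].sum() for i in range(k)])
    tot_f = sum(F[i, j] for i in range(k) for j in range(i + 1, k))
    tot_e = sum(E[i, j] for i in range(k) for j in range(i + 1, k))
    return 1 - tot_f / tot_e, Hi, Hij


class TestScalability:
    def test_hand_worked_pair(self):
        """Joint counts (1,1)=4,(1,0)=2,(0,1)=1,(0,0)=3: both closed forms give 0.5."""
        values = np.array([[1, 1]] * 4 + [[1, 0]] * 2 + [[0, 1]] * 1 + [[0, 0]] * 3)
        res = mk.scalability(BinaryResponseMatrix(values), n_boot=0)
        assert res.Hij[0, 1] == pytest.approx(0.5)
        # Guttman-error route: easier item is column 0 (p=0.6), F=1, E=10*0.4*0.5
        assert 1 - 1 / (10 * 0.4 * 0.5) == pytest.approx(0.5)
        assert res.H == pytest.approx(0.5)

    def test_perfect_guttman_scale_has_h_one(self):
        values = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0], [1, 1, 0]])
        res = mk.scalability(BinaryResponseMatrix(values), n_boot=0)
        assert res.H == pytest.approx(1.0)
        assert np.allclose(res.Hi, 1.0)

    def test_independent_items_have_h_near_zero(self):
        rng = np.random.default_rng(99)
        values = (rng.random((5000, 6)) < np.linspace(0.3, 0.7, 6)).astype(int)
        res = mk.scalability(BinaryResponseMatrix(values), n_boot=200, seed=1)
        assert abs(res.H) < 3 * res.H_se

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_covariance_and_guttman_error_routes_agree(self, seed):
        """The covariance-ratio and 1 - F/E formulations coincide exactly."""
        rng = np.random.default_rng(seed)
        m = random_binary_matrix(rng)
        res = mk.scalability(m, n_boot=0)
        H, Hi, Hij = brute_force_h(m.values)
        assert res.H == pytest.approx(H, abs=1e-12)
        assert np.allclose(res.Hi, Hi, atol=1e-12)
        mask = ~np.isnan(Hij)
        assert np.allclose(res.Hij[mask], Hij[mask], atol=1e-12)

    def test_constant_item_rejected(self):
        values = np.ones((10, 2), dtype=int)
        values[:5, 1] = 0
        with pytest.raises(ValidationError):
            mk.scalability(BinaryResponseMatrix(values), n_boot=0)


FAST_GA = mk.GaParams(n_generations=120)


class TestAisp:
    def test_unidimensional_items_form_one_scale(self):
        m = simulate_rasch(np.linspace(-2, 2, 12), n=500, seed=21, discrimination=2.0)
        res = mk.aisp(m, 0.3, FAST_GA, seed=5)
        assert res.n_in_scale(1) == 12

    def test_two_independent_blocks_partition(self):
        rng = np.random.default_rng(17)
        theta1, theta2 = rng.standard_normal((2, 800))
        bs = np.linspace(-1.2, 1.2, 6)
        from scipy.special import expit

        block1 = (rng.random((800, 6)) < expit(2.5 * (theta1[:, None] - bs))).astype(int)
        block2 = (rng.random((800, 6)) < expit(2.5 * (theta2[:, None] - bs))).astype(int)
        m = BinaryResponseMatrix(
            np.hstack([block1, block2]),
            item_codes=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
        )
        res = mk.aisp(m, 0.42, FAST_GA, seed=5)
        assert len(res.scales) >= 2
        first_two = [set(s) for s in res.scales[:2]]
        blocks = [{f"a{i}" for i in range(6)}, {f"b{i}" for i in range(6)}]
        assert first_two in ([blocks[0], blocks[1]], [blocks[1], blocks[0]])

    def test_infeasible_cut_marks_everything_unscalable(self, rng):
        m = random_binary_matrix(rng, n=80, k=6)
        res = mk.aisp(m, 0.99, FAST_GA, seed=2)
        assert all(v == 0 for v in res.assignment.values())
        assert res.scales == []

    def test_retained_scales_are_feasible(self):
        m = simulate_rasch(np.linspace(-1.5, 1.5, 8), n=300, seed=31)
        for cut in (0.3, 0.42):
            res = mk.aisp(m, cut, FAST_GA, seed=3)
            for scale in res.scales:
                sub = m.select_items(scale)
                scal = mk.scalability(sub, n_boot=0)
                assert (scal.Hi >= cut).all()
                off = ~np.eye(sub.n_items, dtype=bool)
                assert (scal.Hij[off] > 0).all()

    def test_scan_grid_monotone_and_deterministic(self):
        m = simulate_rasch(np.linspace(-1.5, 1.5, 8), n=400, seed=41, discrimination=1.5)
        scan = mk.aisp_scan(m, ga_params=FAST_GA, seed=9)
        assert len(scan) == 9
        sizes = [r.n_in_scale(1) for r in scan]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        scan2 = mk.aisp_scan(m, ga_params=FAST_GA, seed=9)
        assert [r.assignment for r in scan] == [r.assignment for r in scan2]
        table = mk.aisp_scan_table(scan)
        assert table.shape == (8, 9)


class TestConditionalAssociation:
    def test_fence_follows_tukey_rule(self, rng):
        """fence = Q3 + 3 (Q3 - M): with M = 6 and Q3 = 10 the fence is 22."""
        w = np.array([2.0, 4.0, 6.0, 6.0, 10.0, 10.0, 12.0])
        med, q3 = np.percentile(w, [50, 75])
        assert (med, q3) == (6.0, 10.0)
        assert q3 + 3 * (q3 - med) == 22.0
        m = random_binary_matrix(rng, n=200, k=7)
        res = mk.check_conditional_association(m)
        med, q3 = np.percentile(res.W_plus[~np.isnan(res.W_plus)], [50, 75])
        assert res.fence == pytest.approx(q3 + 3 * (q3 - med))

    def test_locally_independent_data_mostly_unflagged(self):
        """Quartile fences on only 10 items are jumpy, so occasional false
        flags are expected; most seeds should still come back clean."""
        clean = 0
        for seed in range(10):
            m = simulate_rasch(np.linspace(-1.5, 1.5, 10), n=1000, seed=100 + seed)
            res = mk.check_conditional_association(m)
            clean += not res.flagged_items
        assert clean >= 5

    def test_cloned_item_pair_is_flagged(self):
        """A nearly duplicated item breaks local independence: negative
        conditional covariances appear for pairs whose rest score contains
        the clone's partner, lifting W+ of the pair over the fence."""
        n = 2000
        m = simulate_rasch(np.linspace(-1.5, 1.5, 9), n=n, seed=8)
        rng = np.random.default_rng(1)
        clone = m.values[:, 4].copy()
        flip = rng.random(n) < 0.05
        clone[flip] = 1 - clone[flip]
        values = np.hstack([m.values, clone[:, None]])
        m2 = BinaryResponseMatrix(values, item_codes=m.item_codes + ["clone"])
        res = mk.check_conditional_association(m2)
        assert set(res.flagged_items) & {"i05", "clone"}
        # the clone sits among the two largest W+ values
        top2 = {res.item_codes[i] for i in np.argsort(res.W_plus)[-2:]}
        assert "clone" in top2 or "i05" in top2


class TestMonotonicity:
    def test_model_consistent_data_have_no_significant_violations(self):
        """Small sample wiggles above minvi can occur on clean data, but none
        should reach one-sided significance."""
        m = simulate_rasch(np.linspace(-2, 2, 10), n=1000, seed=11)
        res = mk.check_monotonicity(m)
        for r in res.items:
            assert r.significant == 0
            assert 0 <= r.significant <= r.violations <= r.active_comparisons
            if r.violations == 0:
                assert r.max_violation == 0.0

    def test_planted_irf_drop_detected(self):
        """An item whose pass rate falls 0.15 between low and high rest scores."""
        rng = np.random.default_rng(5)
        n_half = 250
        rest_low = (rng.random((n_half, 9)) < 0.25).astype(int)
        rest_high = (rng.random((n_half, 9)) < 0.75).astype(int)
        item = np.concatenate(
            [(rng.random(n_half) < 0.75).astype(int), (rng.random(n_half) < 0.60).astype(int)]
        )
        values = np.column_stack([np.vstack([rest_low, rest_high]), item])
        res = mk.check_monotonicity(BinaryResponseMatrix(values))
        target = res.items[-1]
        assert target.violations >= 1
        assert target.significant >= 1
        assert target.crit > 0

    def test_minsize_grouping_respected(self):
        m = simulate_rasch(np.linspace(-1, 1, 6), n=300, seed=13)
        res = mk.check_monotonicity(m, minsize=50)
        for r in res.items:
            assert r.active_comparisons == r.n_groups * (r.n_groups - 1) // 2


class TestMiio:
    def test_identical_columns_never_violate_each_other(self):
        """A duplicated column has pairwise difference 0 <= minvi everywhere,
        so the duplicate pair itself can never appear as a violation."""
        m = simulate_rasch(np.linspace(-1, 1, 4), n=400, seed=19)
        values = np.column_stack([m.values, m.values[:, 0]])
        codes = m.item_codes + ["dup"]
        res = mk.check_miio(BinaryResponseMatrix(values, item_codes=codes))
        pair_rows = res.pairwise[
            res.pairwise[["easier", "harder"]]
            .apply(set, axis=1)
            .eq({"i01", "dup"})
        ] if len(res.pairwise) else res.pairwise
        assert len(pair_rows) == 0

    def test_crossing_irfs_trigger_removal(self):
        """Items with slopes 0.5 vs 3 crossing at theta = 0 violate an invariant
        ordering; backward selection removes one of the crossing pair."""
        rng = np.random.default_rng(23)
        from scipy.special import expit

        n = 2000
        theta = rng.standard_normal(n)
        flat = (rng.random(n) < expit(0.5 * (theta - 0.3))).astype(int)
        steep = (rng.random(n) < expit(3.0 * (theta + 0.3))).astype(int)
        filler_bs = np.linspace(-1.5, 1.5, 6)
        filler = (rng.random((n, 6)) < expit(theta[:, None] - filler_bs)).astype(int)
        values = np.column_stack([flat, steep, filler])
        codes = ["flat", "steep"] + [f"f{i}" for i in range(6)]
        res = mk.check_miio(BinaryResponseMatrix(values, item_codes=codes))
        assert any(r["significant"] for _, r in res.pairwise.iterrows())
        assert set(res.removed_items) & {"flat", "steep"}

    def test_iio_consistent_items_all_survive(self):
        kept = 0
        for seed in range(5):
            m = simulate_rasch(np.linspace(-2, 2, 8), n=800, seed=200 + seed)
            res = mk.check_miio(m)
            kept += len(res.final_items) == 8
        assert kept >= 4


class TestReliability:
    def test_closed_form_two_parallel_items(self):
        """Unit variances, correlation 0.5: alpha = lambda2 = 2*0.5/1.5 = 0.6667."""
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert mk.cronbach_alpha_from_cov(cov) == pytest.approx(2 / 3)
        assert mk.lambda2_from_cov(cov) == pytest.approx(2 / 3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_lambda2_never_below_alpha(self, seed):
        rng = np.random.default_rng(seed)
        m = random_binary_matrix(rng, n=30, k=6)
        res = mk.reliability(m, seed=0)
        assert res.guttman_lambda2 >= res.cronbach_alpha - 1e-12

    def test_parallel_items_match_quadrature_oracle(self):
        """All four coefficients near the true reliability var(E[X|theta])/var(X)."""
        from scipy.integrate import quad
        from scipy.special import expit

        k, n = 10, 2000
        items = [ItemSpec(f"i{j}", 0.0) for j in range(k)]
        m = simulate_dichotomous(SimulationConfig(n, items, seed=77))
        phi = lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi)
        e1, _ = quad(lambda t: expit(t) * phi(t), -10, 10)
        e2, _ = quad(lambda t: expit(t) ** 2 * phi(t), -10, 10)
        var_true = k * k * (e2 - e1 * e1)
        var_x = var_true + k * (e1 - e2)
        rho_true = var_true / var_x
        res = mk.reliability(m, seed=1)
        for value in (res.cronbach_alpha, res.guttman_lambda2, res.ms_rho, res.lcrc):
            assert abs(value - rho_true) < 0.05

    def test_invariant_under_item_reordering(self):
        m = simulate_rasch(np.linspace(-1.5, 1.5, 7), n=400, seed=55)
        res1 = mk.reliability(m, seed=3)
        perm = [3, 0, 6, 1, 5, 2, 4]
        m2 = BinaryResponseMatrix(
            m.values[:, perm], item_codes=[m.item_codes[i] for i in perm]
        )
        res2 = mk.reliability(m2, seed=3)
        assert res1.cronbach_alpha == pytest.approx(res2.cronbach_alpha)
        assert res1.guttman_lambda2 == pytest.approx(res2.guttman_lambda2)
        assert res1.ms_rho == pytest.approx(res2.ms_rho)
        assert abs(res1.lcrc - res2.lcrc) < 0.01  # EM restarts differ only by draw order
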