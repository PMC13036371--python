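"""Saltelli designs, Sobol index estimators, and the brute-force oracle."""

import numpy as np
import pytest

from photosense.bounds import FactorBounds
from photosense.sobol import (
    brute_force_sobol,
    estimate_sobol,
    saltelli_sample,
    test_functions as analytic_functions,
)


def unit_bounds(d):
    return [FactorBounds(f"x{i}", 0.0, 1.0) for i in range(d)]


class TestSaltelliDesign:
    @pytest.mark.parametrize("N,D", [(256, 5), (1, 1), (64, 3), (8, 2)])
    def test_row_count_is_n_times_d_plus_2(self, N, D):
        design = saltelli_sample(unit_bounds(D), N=N, seed=0)
        assert design.rows.shape == (N * (D + 2), D)
        assert design.n_rows == N * (D + 2)

    def test_study_design_size(self):
        """The default study configuration (N=256, D=5) yields 1792 rows."""
        bounds = [
            FactorBounds("brightness", 0.5, 1.5),
            FactorBounds("contrast", 0.8, 1.2),
            FactorBounds("sharpness", 0.8, 1.2),
            FactorBounds("saturation", 0.5, 1.5),
            FactorBounds("hue", -0.1, 0.1),
        ]
        assert saltelli_sample(bounds, N=256, seed=2021).n_rows == 1792

    def test_rows_respect_bounds(self):
        bounds = [FactorBounds("a", -2.0, 3.0), FactorBounds("b", 0.5, 0.75)]
        rows = saltelli_sample(bounds, N=128, seed=7).rows
        assert rows[:, 0].min() >= -2.0 and rows[:, 0].max() <= 3.0
        assert rows[:, 1].min() >= 0.5 and rows[:, 1].max() <= 0.75

    def test_serialization_order_a_b_then_ab_blocks(self):
        design = saltelli_sample(unit_bounds(3), N=16, seed=1)
        rows = design.rows
        np.testing.assert_array_equal(rows[:16], design.A)
        np.testing.assert_array_equal(rows[16:32], design.B)
        for i in range(3):
            block = rows[32 + 16 * i : 32 + 16 * (i + 1)]
            np.testing.assert_array_equal(block, design.AB[i])
            # AB_i is A with column i from B
            expected = design.A.copy()
            expected[:, i] = design.B[:, i]
            np.testing.assert_array_equal(block, expected)

    def test_identical_seed_gives_bitwise_identical_design(self):
        a = saltelli_sample(unit_bounds(4), N=64, seed=2021)
        b = saltelli_sample(unit_bounds(4), N=64, seed=2021)
        np.testing.assert_array_equal(a.rows, b.rows)
        c = saltelli_sample(unit_bounds(4), N=64, seed=2022)
        assert not np.array_equal(a.rows, c.rows)

    def test_degenerate_bounds_collapse_all_rows(self):
        bounds = [FactorBounds("a", 1.0, 1.0), FactorBounds("b", -0.5, -0.5)]
        rows = saltelli_sample(bounds, N=8, seed=0).rows
        np.testing.assert_array_equal(rows, np.tile([1.0, -0.5], (32, 1)))

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError, match="lo"):
            FactorBounds("a", 2.0, 1.0)
        with pytest.raises(ValueError):
            saltelli_sample(unit_bounds(2), N=0, seed=0)
        with pytest.raises(ValueError):
            saltelli_sample([], N=8, seed=0)

    def test_non_power_of_two_warns_but_succeeds(self):
        with pytest.warns(UserWarning, match="power of two"):
            design = saltelli_sample(unit_bounds(2), N=100, seed=0)
        assert design.n_rows == 400


class TestEstimators:
    def test_additive_model_s1_equals_st(self):
        tf = analytic_functions("additive_linear")
        design = saltelli_sample(list(tf.bounds), N=1024, seed=5)
        res = estimate_sobol(design, tf.f(design.rows))
        np.testing.assert_allclose(res.S1, [0.5, 0.5], atol=0.05)
        np.testing.assert_allclose(res.ST - res.S1, 0.0, atol=0.05)

    def test_additive_interaction_within_bootstrap_se(self):
        """|ST - S1| stays within 3 bootstrap SEs for an additive response."""
        tf = analytic_functions("additive_linear")
        design = saltelli_sample(list(tf.bounds), N=1024, seed=5)
        y = tf.f(design.rows)
        res = estimate_sobol(design, y)
        yA, yB, yAB = design.split_responses(y)
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(200):
            idx = rng.integers(0, design.N, size=design.N)
            Vy = np.var(np.concatenate([yA[idx], yB[idx]]))
            s1 = np.array([np.mean(yB[idx] * (yAB[i][idx] - yA[idx])) for i in range(2)]) / Vy
            st = np.array([np.mean((yA[idx] - yAB[i][idx]) ** 2) for i in range(2)]) / (2 * Vy)
            diffs.append(st - s1)
        se = np.std(diffs, axis=0, ddof=1)
        assert np.all(np.abs(res.ST - res.S1) <= 3 * np.maximum(se, 1e-6))

    def test_ishigami_recovery(self):
        tf = analytic_functions("ishigami")
        design = saltelli_sample(list(tf.bounds), N=4096, seed=2021)
        res = estimate_sobol(design, tf.f(design.rows))
        np.testing.assert_allclose(res.S1, tf.S1, atol=0.02)
        np.testing.assert_allclose(res.ST, tf.ST, atol=0.03)
        assert not res.degenerate

    def test_g_function_recovery(self):
        tf = analytic_functions("g_function")
        design = saltelli_sample(list(tf.bounds), N=4096, seed=2021)
        res = estimate_sobol(design, tf.f(design.rows))
        np.testing.assert_allclose(res.S1, tf.S1, atol=0.02)
        np.testing.assert_allclose(res.ST, tf.ST, atol=0.03)

    def test_constant_response_sets_degenerate_flag(self):
        design = saltelli_sample(unit_bounds(3), N=32, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            res = estimate_sobol(design, np.full(design.n_rows, 0.7))
        assert res.degenerate
        np.testing.assert_array_equal(res.S1, 0.0)
        np.testing.assert_array_equal(res.ST, 0.0)

    def test_response_length_mismatch_raises(self):
        design = saltelli_sample(unit_bounds(2), N=16, seed=0)
        with pytest.raises(ValueError, match="length"):
            estimate_sobol(design, np.zeros(10))

    def test_clipped_view_lies_in_unit_interval(self):
        tf = analytic_functions("ishigami")
        design = saltelli_sample(list(tf.bounds), N=64, seed=9)
        res = estimate_sobol(design, tf.f(design.rows))
        assert res.S1_clipped.min() >= 0 and res.ST_clipped.max() <= 1

    def test_identical_inputs_identical_indices(self):
        tf = analytic_functions("g_function")
        design = saltelli_sample(list(tf.bounds), N=256, seed=3)
        y = tf.f(design.rows)
        a, b = estimate_sobol(design, y), estimate_sobol(design, y)
        np.testing.assert_array_equal(a.S1, b.S1)
        np.testing.assert_array_equal(a.ST, b.ST)


class TestBruteForceOracle:
    def test_g_function_against_closed_form(self):
        tf = analytic_functions("g_function")
        res = brute_force_sobol(tf.f, list(tf.bounds), seed=17)
        np.testing.assert_allclose(res.S1, tf.S1, atol=0.03)
        np.testing.assert_allclose(res.ST, tf.ST, atol=0.03)

    @pytest.mark.parametrize("name", ["ishigami", "g_function", "additive_linear"])
    def test_oracle_agrees_with_saltelli_estimator(self, name):
        """Two independent estimation routes agree on every registry function."""
        tf = analytic_functions(name)
        design = saltelli_sample(list(tf.bounds), N=4096, seed=2021)
        est = estimate_sobol(design, tf.f(design.rows))
        oracle = brute_force_sobol(tf.f, list(tf.bounds), seed=17)
        np.testing.assert_allclose(est.S1, oracle.S1, atol=0.05)
        np.testing.assert_allclose(est.ST, oracle.ST, atol=0.05)

    def test_constant_function_all_zero(self):
        res = brute_force_sobol(
            lambda X: np.full(X.shape[0], 3.3), unit_bounds(2),
            n_outer=50, n_inner=50, seed=0,
        )
        assert res.degenerate
        np.testing.assert_array_equal(res.S1, 0.0)

    def test_desk_scale_guards(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="D <= 4"):
            brute_force_sobol(f, unit_bounds(5), n_outer=10, n_inner=10)
        with pytest.raises(ValueError, match="budget"):
            brute_force_sobol(f, unit_bounds(2), n_outer=2000, n_inner=2000)


class TestRegistry:
    def test_ishigami_closed_form_values(self):
        tf = analytic_functions("ishigami")
        np.testing.assert_allclose(tf.S1, [0.3139, 0.4424, 0.0], atol=5e-4)
        np.testing.assert_allclose(tf.ST[2], 0.2437, atol=5e-4)

    def test_inert_factor_has_zero_total_index(self):
        """A factor the function ignores gets ST ~ 0 (ishigami has none inert
        for ST, so check x3's S1 and an explicitly inert additive factor)."""
        tf = analytic_functions("ishigami")
        assert tf.S1[2] == 0.0
        bounds = unit_bounds(3)
        design = saltelli_sample(bounds, N=1024, seed=4)
        y = design.rows[:, 0] + design.rows[:, 1]  # x2 index 2 inert
        res = estimate_sobol(design, y)
        assert abs(res.ST[2]) < 0.01

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError, match="unknown"):
            analytic_functions("nope")
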