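import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cabc import (
    abc_analysis,
    assign_sets,
    compute_abc_points,
    compute_limits,
    find_break_even,
    find_pareto_point,
    find_submarginal,
    fit_curve,
)
from cabc.curves import identity_curve, uniform_abc_curve
from cabc.theoretical import DistributionSpec, generate_sample, theoretical_abc

# Exact optima on the uniform[0,b] closed form ABC(p) = -p^2 + 2p, frozen from
# independent brute-force grid minimization (step 5e-7) of the two distance
# objectives: p^2 + (1-p)^4 (Pareto) and (p-0.5)^2 + (1-p)^4 (SubMarginal).
UNIFORM_PARETO = 0.4102455
UNIFORM_SUBMARGINAL = 0.6145415


def brute_force_effort(curve, anchor, lower, step=1e-5):
    grid = np.arange(lower, 1.0 + step, step)
    grid = np.clip(grid, 0.0, 1.0)
    d2 = (grid - anchor) ** 2 + (1.0 - curve.evaluate(grid)) ** 2
    return float(grid[int(np.argmin(d2))])


class TestCharacteristicPoints:
    def test_uniform_pareto_point(self):
        curve = uniform_abc_curve(0.0, 1.0)
        pt = find_pareto_point(curve)
        assert pt.effort == pytest.approx(UNIFORM_PARETO, abs=1e-6)
        assert pt.gain == pytest.approx(2 - 2 * UNIFORM_PARETO, abs=1e-5)

    def test_identity_pareto_point_is_half(self):
        assert find_pareto_point(identity_curve()).effort == pytest.approx(0.5, abs=1e-6)

    def test_uniform_break_even_at_half(self):
        pt = find_break_even(uniform_abc_curve(0.0, 1.0))
        assert pt.effort == pytest.approx(0.5, abs=1e-7)
        assert not pt.degenerate

    def test_identity_break_even_degenerate_left_endpoint(self):
        pt = find_break_even(identity_curve())
        assert pt.effort == 0.0
        assert pt.degenerate

    def test_uniform_submarginal_point(self):
        curve = uniform_abc_curve(0.0, 1.0)
        be = find_break_even(curve)
        pt = find_submarginal(curve, be)
        assert pt.effort == pytest.approx(UNIFORM_SUBMARGINAL, abs=1e-6)

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("uniform"),
            DistributionSpec("exponential"),
            DistributionSpec("chi_squared", {"df": 1}),
            DistributionSpec("gaussian", {"mean": 5, "sd": 1}),
            DistributionSpec("lognormal", {"s": 3}),
            DistributionSpec("pareto", {"alpha": 1.5}),
        ],
    )
    def test_optimizers_match_brute_force_on_theoretical_curves(self, spec):
        curve = theoretical_abc(spec)
        pareto = find_pareto_point(curve)
        assert pareto.effort == pytest.approx(
            brute_force_effort(curve, 0.0, 0.0), abs=1e-4
        )
        be = find_break_even(curve)
        sub = find_submarginal(curve, be if be.effort >= pareto.effort else pareto)
        anchor = max(be.effort, pareto.effort)
        assert sub.effort == pytest.approx(
            brute_force_effort(curve, anchor, anchor), abs=1e-4
        )

    @pytest.mark.parametrize("n", [8, 50, 1000])
    @pytest.mark.parametrize("family", ["uniform", "lognormal", "chi_squared"])
    def test_empirical_points_are_exact_knot_minimizers(self, n, family, rng):
        # on empirical curves the candidates are the n realizable selections
        x = generate_sample(DistributionSpec(family), n, rng)
        curve = fit_curve(compute_abc_points(x))
        pareto = find_pareto_point(curve)
        e, y = curve.knots
        d2 = e**2 + (1 - y) ** 2
        assert pareto.effort == pytest.approx(e[np.argmin(d2)], abs=1e-12)
        limits = compute_limits(curve)
        anchor = max(limits.pareto.effort, limits.break_even.effort)
        mask = e >= anchor - 1e-12
        d2 = (e[mask] - anchor) ** 2 + (1 - y[mask]) ** 2
        assert limits.submarginal.effort == pytest.approx(
            e[mask][np.argmin(d2)], abs=1e-12
        )


class TestComputeLimits:
    def test_uniform_thresholds_and_no_swap(self):
        limits = compute_limits(uniform_abc_curve(0.0, 1.0))
        assert limits.t_ab == pytest.approx(UNIFORM_PARETO, abs=1e-6)
        assert limits.t_bc == pytest.approx(UNIFORM_SUBMARGINAL, abs=1e-6)
        assert not limits.swapped
        assert limits.t_ab <= limits.t_bc

    def test_uniform_set_b_gain_bracket(self):
        # gains over set B run from the SubMarginal gain up to the Pareto gain
        curve = uniform_abc_curve(0.0, 1.0)
        limits = compute_limits(curve)
        lo = curve.derivative(limits.t_bc)
        hi = curve.derivative(limits.t_ab)
        assert lo == pytest.approx(2 - 2 * UNIFORM_SUBMARGINAL, abs=1e-5)
        assert hi == pytest.approx(2 - 2 * UNIFORM_PARETO, abs=1e-5)
        mid_gains = curve.derivative(np.linspace(limits.t_ab, limits.t_bc, 50))
        assert np.all((mid_gains >= lo - 1e-9) & (mid_gains <= hi + 1e-9))

    def test_swap_rule_on_eigenvalue_spectrum(self, pca_eigenvalues):
        # Pareto effort exceeds BreakEven effort here: the points swap roles
        limits = compute_limits(fit_curve(compute_abc_points(pca_eigenvalues)))
        assert limits.swapped
        assert limits.pareto.effort > limits.break_even.effort
        assert limits.t_ab == limits.break_even.effort
        assert limits.t_ab <= limits.t_bc

    @pytest.mark.parametrize(
        "spec,n",
        [
            (DistributionSpec("uniform"), 200),
            (DistributionSpec("chi_squared", {"df": 1}), 500),
            (DistributionSpec("lognormal", {"s": 3}), 500),
            (DistributionSpec("gaussian", {"mean": 5, "sd": 1}), 200),
        ],
    )
    def test_cond1_and_cond3(self, spec, n, rng):
        # COND1: profit gain >= 1 throughout set A; COND3: gain at t_BC <= gain at t_AB
        x = generate_sample(spec, n, rng)
        _, curve, limits, _ = abc_analysis(x)
        assert curve.derivative(limits.t_ab) >= 1 - 1e-6
        assert curve.derivative(limits.t_bc) <= curve.derivative(limits.t_ab) + 1e-9

    def test_equality_data_degenerate_flag(self):
        _, curve, limits, _ = abc_analysis([5.0, 5.0, 5.0, 5.0, 5.0])
        assert limits.degenerate
        np.testing.assert_allclose(curve.derivative(np.linspace(0, 1, 11)), 1.0, atol=1e-9)

    def test_scale_invariance_of_limits(self, rng):
        x = rng.exponential(1.0, 50)
        l1 = compute_limits(fit_curve(compute_abc_points(x)))
        l2 = compute_limits(fit_curve(compute_abc_points(x * 173.5)))
        assert l1.t_ab == l2.t_ab and l1.t_bc == l2.t_bc


class TestAssignSets:
    def test_eigenvalues_partition_counts(self, pca_eigenvalues):
        # set C holds the four smallest eigenvalues; A and B the four largest
        *_, partition = abc_analysis(pca_eigenvalues)
        assert partition.counts["C"] == 4
        assert partition.counts["A"] + partition.counts["B"] == 4
        assert set(partition.c_indices) == {4, 5, 6, 7}

    def test_partition_is_complete_and_disjoint(self, pca_eigenvalues):
        *_, partition = abc_analysis(pca_eigenvalues)
        all_idx = np.concatenate(
            [partition.a_indices, partition.b_indices, partition.c_indices]
        )
        assert sorted(all_idx) == list(range(8))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=3, max_size=80))
    def test_partition_completeness_on_random_inputs(self, values):
        *_, partition = abc_analysis(values)
        n = len(values)
        all_idx = np.concatenate(
            [partition.a_indices, partition.b_indices, partition.c_indices]
        )
        assert sorted(all_idx) == list(range(n))
        x = np.asarray(values)
        if partition.counts["A"] and partition.counts["B"]:
            assert x[partition.a_indices].min() >= x[partition.b_indices].max() - 1e-12
        if partition.counts["B"] and partition.counts["C"]:
            assert x[partition.b_indices].min() >= x[partition.c_indices].max() - 1e-12

    def test_uniform_sample_set_a_size(self):
        # continuous optimum t_AB ~ 0.4102 -> about 410 of 1000 items in A
        x = generate_sample(DistributionSpec("uniform"), 1000, seed=99)
        *_, partition = abc_analysis(x)
        assert abs(partition.counts["A"] - 410) <= 15

    def test_rank_threshold_rounding(self, pca_eigenvalues):
        limits = compute_limits(fit_curve(compute_abc_points(pca_eigenvalues)))
        part = assign_sets(pca_eigenvalues, limits)
        n = len(pca_eigenvalues)
        assert part.counts["A"] == math.floor(n * limits.t_ab + 1e-9)
        assert part.counts["A"] + part.counts["B"] == math.floor(n * limits.t_bc + 1e-9)

    def test_yield_shares_sum_to_one(self, rng):
        x = rng.random(40)
        *_, partition = abc_analysis(x)
        assert sum(partition.yield_shares.values()) == pytest.approx(1.0, abs=1e-12)


class TestPipeline:
    def test_deterministic_repeat(self, rng):
        x = rng.chisquare(1.0, 300)
        r1 = abc_analysis(x)
        r2 = abc_analysis(x)
        assert r1.limits == r2.limits
        np.testing.assert_array_equal(
            r1.partition.labels(x.size), r2.partition.labels(x.size)
        )

    def test_errors_propagate(self):
        with pytest.raises(Exception, match="degenerate total yield"):
            abc_analysis([0.0, 0.0, 0.0])
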