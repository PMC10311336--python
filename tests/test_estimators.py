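import math

import numpy as np
import pytest

from castles.estimators import (
    QuartetParams,
    _balanced_cherry_diff,
    delta_from_T1,
    estimate_T1,
    estimate_internal_su,
    estimate_root_balanced,
    estimate_root_unbalanced,
    estimate_terminal_balanced,
    estimate_terminal_cherry,
    estimate_terminal_sibling,
    expected_gene_quartet_deltas,
    invert_delta,
    solve_T1_exact,
)


def _deltas(T1, T2, mu1, mu2, mu3):
    return expected_gene_quartet_deltas(QuartetParams(T1, T2, mu1, mu2, mu3))


class TestForwardModel:
    def test_zero_internal_branch_kills_internal_and_root_deltas(self):
        d = _deltas(0.0, 1.3, 1.0, 1.7, 0.6)
        assert d.internal == pytest.approx(0.0, abs=1e-15)
        assert d.root_adjacent == pytest.approx(0.0, abs=1e-15)

    def test_equal_upper_rates_reduce_to_single_rate_form(self):
        # the internal difference must equal 3 mu1 (e^-T1 - 1 + T1)/(3 - 2 e^-T1)
        # for any T2 when mu2 == mu3
        rng = np.random.default_rng(42)
        for _ in range(100):
            T1 = float(rng.uniform(0.01, 3.0))
            T2 = float(rng.uniform(0.01, 3.0))
            mu1 = float(rng.uniform(0.2, 3.0))
            mu23 = float(rng.uniform(0.2, 3.0))
            d = _deltas(T1, T2, mu1, mu23, mu23)
            e1 = math.exp(-T1)
            expected = 3.0 * mu1 * (e1 - 1.0 + T1) / (3.0 - 2.0 * e1)
            assert d.internal == pytest.approx(expected, abs=1e-12, rel=1e-12)

    def test_known_value_at_unit_parameters(self):
        # homogeneous rates, T1 = 1: internal difference = 3 e^-1/(3-2 e^-1)
        # ~ 0.48742, independent of T2
        for T2 in (0.2, 1.0, 50.0):
            d = _deltas(1.0, T2, 1.0, 1.0, 1.0)
            assert d.internal == pytest.approx(0.4874208, abs=1e-6)

    def test_cherry_limit_matches_t2_infinity_form(self):
        # large T2 reproduces the closed T2->inf limit used by the terminal
        # estimator derivation
        for T1, mu1, mu2 in [(0.5, 1.0, 1.5), (1.2, 0.7, 0.7), (0.2, 2.0, 0.5)]:
            d = _deltas(T1, 60.0, mu1, mu2, mu2 * 1.3)
            e1 = math.exp(-T1)
            lim = (-6 * mu1 * (e1 - 1 + T1) - (5 - 4 * e1) * mu2) / (6 - 4 * e1)
            assert d.cherry == pytest.approx(lim, rel=1e-10, abs=1e-10)

    def test_sibling_limit_matches_t2_infinity_form(self):
        for T1, mu2 in [(0.5, 1.5), (1.2, 0.7)]:
            d = _deltas(T1, 60.0, 1.0, mu2, 0.9)
            e1 = math.exp(-T1)
            lim = mu2 * (2 - e1) / (3 - 2 * e1)
            assert d.sibling == pytest.approx(lim, rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            QuartetParams(-0.1, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            QuartetParams(0.1, 1.0, 0.0, 1.0, 1.0)


class TestInternalSolvers:
    def test_delta_at_zero(self):
        assert delta_from_T1(0.0) == 0.0
        assert solve_T1_exact(0.0) == 0.0
        assert estimate_T1(0.0) == 0.0

    @pytest.mark.parametrize("T1", [0.05, 0.3, 0.7, 1.5, 3.0, 8.0])
    def test_exact_round_trip(self, T1):
        assert solve_T1_exact(delta_from_T1(T1)) == pytest.approx(T1, abs=1e-9)

    def test_taylor_closed_form_value(self):
        # delta = 0.3: T = 0.15 + sqrt(0.9 * 4.9)/6 = 0.5 exactly
        assert estimate_T1(0.3) == pytest.approx(0.5, abs=1e-12)

    def test_taylor_discrepancy_curve(self):
        """Taylor inversion vs exact root across delta in (0, 1]: the absolute
        deviation shrinks to zero towards delta -> 0 while the relative
        deviation stays bounded (the Taylor form is biased low throughout)."""
        deltas = np.linspace(1.0, 1e-3, 60)
        abs_dev = []
        for d in deltas:
            exact = solve_T1_exact(float(d))
            taylor = estimate_T1(float(d))
            assert taylor <= exact  # biased low
            assert (exact - taylor) / exact < 0.31  # bounded relative deviation
            abs_dev.append(exact - taylor)
        # decreasing towards zero as delta -> 0
        assert abs_dev[-1] < 0.01
        assert all(b <= a + 1e-12 for a, b in zip(abs_dev, abs_dev[1:]))

    def test_invert_delta_dispatch(self):
        assert invert_delta(0.3, "taylor") == estimate_T1(0.3)
        assert invert_delta(0.3, "exact") == solve_T1_exact(0.3)
        with pytest.raises(ValueError):
            invert_delta(0.3, "newton")

    def test_negative_delta_rejected_by_exact(self):
        with pytest.raises(ValueError):
            solve_T1_exact(-0.1)


class TestInternalEstimator:
    def test_taylor_path_reproduces_printed_formula(self):
        assert estimate_internal_su(1.0, 0.3, solver="taylor") == pytest.approx(0.5)

    def test_exact_path_recovers_true_length_from_expectations(self):
        for T1 in (0.1, 0.5, 1.0, 2.0):
            mu1 = 1.3
            delta = delta_from_T1(T1)
            t = estimate_internal_su(mu1, mu1 * delta, solver="exact")
            assert t == pytest.approx(mu1 * T1, rel=1e-8)

    def test_negative_delta_floors(self):
        assert estimate_internal_su(1.0, -0.1) == 1e-6
        assert estimate_internal_su(1.0, -0.1, floor=1e-3) == 1e-3

    def test_zero_nonmatch_mean_rejected(self):
        with pytest.raises(ValueError):
            estimate_internal_su(0.0, 0.1)


class TestTerminalEstimators:
    def test_cherry_zero_corrections(self):
        assert estimate_terminal_cherry(0.7, 0.0, 0.0, 0.0) == pytest.approx(0.7)

    def test_cherry_forward_limit_round_trip(self):
        # feed the exact T2->inf limits as observations; the estimator must
        # return the true terminal length (algebraic identity)
        for T1, mu1, mu2, tA in [(0.5, 1.0, 1.4, 0.3), (1.1, 0.6, 0.6, 0.05),
                                 (0.2, 2.0, 1.0, 1.7)]:
            e1 = math.exp(-T1)
            la_nm = T1 * mu1 + tA + (5.0 / 6.0) * mu2
            diff = (-6 * mu1 * (e1 - 1 + T1) - (5 - 4 * e1) * mu2) / (6 - 4 * e1)
            est = estimate_terminal_cherry(la_nm, diff, mu1, T1)
            assert est == pytest.approx(tA, abs=1e-12)

    def test_sibling_zero_difference(self):
        assert estimate_terminal_sibling(1.0, 0.0, 0.7) == pytest.approx(1.0)

    def test_sibling_printed_value(self):
        est = estimate_terminal_sibling(1.0, 0.3, 0.5)
        assert est == pytest.approx(0.8717633, abs=1e-6)

    def test_sibling_forward_limit_round_trip(self):
        for T1, mu2, tC in [(0.5, 1.4, 0.3), (1.1, 0.6, 0.05)]:
            e1 = math.exp(-T1)
            lc_nm = mu2 / 3.0 + tC
            diff = mu2 * (2 - e1) / (3 - 2 * e1)
            assert estimate_terminal_sibling(lc_nm, diff, T1) == pytest.approx(
                tC, abs=1e-12
            )

    def test_root_zero_difference(self):
        assert estimate_root_unbalanced(1.5, 0.0, 0.8) == pytest.approx(1.5)

    def test_root_forward_limit_round_trip(self):
        # with mu2 == mu3 the exact expectations are LD' = t2 + tD + 2 mu2/3
        # and diff = mu2 (1 - e^-T1)/(3 - 2 e^-T1)
        for T1, mu2, s in [(0.5, 1.4, 1.1), (1.1, 0.6, 0.4)]:
            e1 = math.exp(-T1)
            ld_nm = s + 2.0 * mu2 / 3.0
            diff = mu2 * (1 - e1) / (3 - 2 * e1)
            assert estimate_root_unbalanced(ld_nm, diff, T1) == pytest.approx(
                s, abs=1e-12
            )

    def test_root_guard_is_finite_at_tiny_T1(self):
        val = estimate_root_unbalanced(1.0, 1e-9, 0.0)
        assert math.isfinite(val)
        assert val == pytest.approx(1.0, abs=1e-2)

    def test_floors(self):
        assert estimate_terminal_cherry(0.0, -10.0, 1.0, 0.5) == 1e-6
        assert estimate_terminal_sibling(0.0, 10.0, 0.5) == 1e-6
        assert estimate_root_unbalanced(0.0, 10.0, 0.5) == 1e-6


class TestBalancedRoot:
    def test_sum_recovered_from_exact_expectations(self):
        for S, mu in [(0.3, 1.0), (1.1, 0.7), (2.5, 1.9)]:
            t = estimate_root_balanced(mu, mu * delta_from_T1(S))
            assert t == pytest.approx(mu * S, rel=1e-8)

    def test_zero_difference_limit(self):
        # no discordance difference: the root path collapses to length ~0,
        # floored
        assert estimate_root_balanced(1.0, 0.0) == 1e-6

    def test_cherry_recovered_from_exact_expectations(self):
        for T1, T2, mu, t in [(0.4, 0.6, 1.0, 0.3), (0.2, 1.0, 1.5, 0.8),
                              (1.0, 0.5, 0.6, 0.0)]:
            S = T1 + T2
            nm = t + mu * (T1 + 2.0 / 3.0)
            diff = mu * _balanced_cherry_diff(T1, S)
            est = estimate_terminal_balanced(nm, diff, mu, S)
            assert est == pytest.approx(max(t, 1e-6), abs=1e-8)

    def test_cherry_diff_is_decreasing_in_T1(self):
        S = 1.2
        vals = [_balanced_cherry_diff(t, S) for t in np.linspace(0, S, 25)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_cherry_clamps_out_of_range_difference(self):
        # observed difference larger than attainable at T1=0 -> clamp to T1=0
        est = estimate_terminal_balanced(1.0, 10.0, 1.0, 0.5)
        assert est == pytest.approx(1.0 - (0.0 + 2.0 / 3.0), abs=1e-9)
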