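import dataclasses

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from enrichtest import TestStats as TStats
from enrichtest import (
    DesignSpec,
    EffectScenario,
    SufficientStats,
    closed_test,
    compute_test_statistics,
    condition_a,
    condition_b,
    effect_scale_decision,
    intersection_test,
    sample_sufficient_stats,
)

from conftest import SEED


def T(ts, tc, design):
    return TStats.from_subgroup(ts, tc, design)


class TestConditionA:
    def test_no_harm_rule_at_b_zero(self, design_b0):
        # b=0 at p=0.5 reduces to: subgroup significant and complement not harmed
        assert condition_a(T(2.0, 0.1, design_b0), design_b0)
        assert not condition_a(T(2.0, -0.1, design_b0), design_b0)

    def test_null_statistics_never_reject(self, design_b0):
        assert not condition_a(T(0.0, 0.0, design_b0), design_b0)

    def test_negative_b_permits_limited_harm(self):
        d = DesignSpec(150, 150, b=-0.25, k=0.26)
        assert condition_a(T(2.5, -0.5, d), d)      # -0.5 > -0.25*2.5
        assert not condition_a(T(2.5, -0.7, d), d)  # -0.7 < -0.625


class TestConditionB:
    def test_symmetric_point_rejects(self, design_b0):
        # combined statistic 0.7071*3.2 = 2.263 clears the critical value and
        # the retention ratios hold trivially by symmetry
        assert condition_b(T(1.6, 1.6, design_b0), design_b0)

    def test_lopsided_point_fails_retention_despite_significance(self, design_b0):
        # 0.7071*(2.6+0.2) = 1.980 > 1.964 but (2-k)*0.2 < k*2.6
        assert not condition_b(T(2.6, 0.2, design_b0), design_b0)
        assert (2 - 0.59) * 0.2 < 0.59 * 2.6

    @pytest.mark.parametrize("p_design", [DesignSpec(150, 150, k=1 - 1e-12), DesignSpec(200, 100, k=1 - 1e-12)])
    def test_k_of_one_empties_the_overall_path(self, p_design):
        # k -> 1 requires T_c > T_s and T_s > T_c simultaneously (up to scaling)
        d = p_design
        stats = sample_sufficient_stats(d, EffectScenario(0, 0), 10**5, SEED)
        Tn = compute_test_statistics(stats, d)
        assert not np.any(condition_b(Tn, d))

    def test_equal_effects_pass_retention_for_any_k_below_one(self):
        for k in (-0.9, 0.0, 0.59, 0.99):
            d = DesignSpec(150, 150, k=k)
            assert condition_b(T(2.0, 2.0, d), d)


class TestWorkedRegion:
    """The b=0, k=0.59, p=0.5 example: both paths in their simplified forms."""

    def test_retention_cone_coefficient(self, design_b0):
        # k/(2-k) = 0.4184 at k=0.59 (printed as ~0.41 with a rounded k)
        r = 0.59 / (2 - 0.59)
        assert r == pytest.approx(0.4184, abs=5e-4)
        # a point just inside the cone rejects, just outside fails
        assert condition_b(T(2.0, r * 2.0 + 0.01, design_b0), design_b0)
        assert not condition_b(T(2.0, r * 2.0 - 0.01, design_b0), design_b0)

    def test_region_membership_examples(self, design_b0):
        assert condition_a(T(2.5, 1.0, design_b0), design_b0)
        assert intersection_test(T(2.5, 1.0, design_b0), design_b0)
        # below both paths
        assert not intersection_test(T(1.5, 0.5, design_b0), design_b0)


class TestEffectScaleEquivalence:
    """The T-scale inequalities are an exact rewriting of the effect-scale rules."""

    @pytest.mark.parametrize(
        "design",
        [
            DesignSpec(150, 150, b=0.0, k=0.59),
            DesignSpec(200, 100, b=-0.25, k=0.73),
            DesignSpec(100, 200, b=0.5, k=-0.15),
            DesignSpec(150, 150, alpha_s=0.025, alpha_o=0.0125, b=-0.25, k=0.26),
        ],
    )
    def test_paths_agree_on_random_trials(self, design):
        rng = np.random.default_rng(SEED)
        n = 10**5
        stats = SufficientStats(
            theta_hat_s=rng.normal(0, 0.5, n),
            theta_hat_c=rng.normal(0, 0.5, n),
            sigma_hat_sq=rng.chisquare(design.df, n) / design.df,
            df=design.df,
        )
        Tn = compute_test_statistics(stats, design)
        path_a, path_b = effect_scale_decision(stats, design)
        assert np.array_equal(path_a, condition_a(Tn, design))
        assert np.array_equal(path_b, condition_b(Tn, design))

    @settings(max_examples=200, deadline=None)
    @given(
        th_s=st.floats(-2, 2),
        th_c=st.floats(-2, 2),
        s2=st.floats(0.1, 4),
        b=st.floats(-0.95, 0.95),
        k=st.floats(-0.95, 0.95),
    )
    def test_pointwise_equivalence_property(self, th_s, th_c, s2, b, k):
        design = DesignSpec(120, 60, b=b, k=k)
        # keep away from the measure-zero constraint boundaries, where the two
        # algebraically identical forms can disagree by one float rounding
        th_o = design.p * th_s + (1 - design.p) * th_c
        assume(abs(th_c - b * th_s) > 1e-6)
        assume(abs(th_s - k * th_o) > 1e-6 and abs(th_c - k * th_o) > 1e-6)
        stats = SufficientStats(th_s, th_c, s2, design.df)
        Tn = compute_test_statistics(stats, design)
        path_a, path_b = effect_scale_decision(stats, design)
        assert bool(path_a) == bool(condition_a(Tn, design))
        assert bool(path_b) == bool(condition_b(Tn, design))


class TestClosedTest:
    def test_overall_claim_recovered_at_family_level(self):
        """Overall p 0.023 fails its intersection path at alpha_o=0.0125 but is
        retested at the family level 0.025 once the subgroup path rejects."""
        d = DesignSpec(150, 150, alpha_s=0.025, alpha_o=0.0125, b=-0.25, k=0.26)
        t_o = sps.t.ppf(1 - 0.023, d.df)  # overall p-value 0.023
        # pick T_s clearing the subgroup path, back out T_c from the identity
        t_s = 2.9
        t_c = (t_o - np.sqrt(0.5) * t_s) / np.sqrt(0.5)
        Tn = T(t_s, t_c, d)
        assert Tn.t_o == pytest.approx(t_o)
        out = closed_test(Tn, d)
        assert not out.via_condition_b  # T_o below t_{0.0125}
        assert out.via_condition_a and out.intersection_rejected
        assert out.claim_o  # retested at 0.025: p=0.023 passes
        assert out.claim_s

    def test_both_paths_and_both_claims(self, design_b0):
        out = closed_test(T(3.0, 3.0, design_b0), design_b0)
        assert out.via_condition_a and out.via_condition_b
        assert out.claim_s and out.claim_o

    def test_null_statistics_make_no_claims(self, design_b0):
        out = closed_test(T(0.0, 0.0, design_b0), design_b0)
        assert not (out.intersection_rejected or out.claim_s or out.claim_o)

    def test_invalid_family_alpha(self, design_b0):
        with pytest.raises(ValueError):
            closed_test(T(1.0, 1.0, design_b0), design_b0, family_alpha=0.7)

    @pytest.mark.parametrize("constrained", [False, True])
    def test_outcome_invariants_on_random_draws(self, constrained):
        d = DesignSpec(150, 150, alpha_s=0.025, alpha_o=0.0125, b=-0.25, k=0.26)
        stats = sample_sufficient_stats(d, EffectScenario(0.2, 0.0), 10**5, SEED)
        out = closed_test(compute_test_statistics(stats, d), d, constrained=constrained)
        assert np.array_equal(out.intersection_rejected, out.via_condition_a | out.via_condition_b)
        # any elementary claim implies the intersection was rejected
        assert not np.any((out.claim_s | out.claim_o) & ~out.intersection_rejected)
        if not constrained:
            # and rejection always yields at least one claim
            assert not np.any(out.intersection_rejected & ~(out.claim_s | out.claim_o))

    def test_diagonal_monotonicity(self):
        """A common positive shift of (T_s, T_c) never un-rejects the intersection.

        (Coordinatewise monotonicity does not hold: the region deliberately
        surrenders lopsided corners, so raising one statistic alone can exit
        the retention cone.)
        """
        rng = np.random.default_rng(SEED)
        for b, k in [(0.0, 0.59), (0.08, 0.43), (0.2, 0.15), (-0.25, 0.82)]:
            d = DesignSpec(150, 150, b=b, k=k)
            ts = rng.normal(0, 2, 20000)
            tc = rng.normal(0, 2, 20000)
            shift = rng.uniform(0, 3, 20000)
            before = intersection_test(T(ts, tc, d), d)
            after = intersection_test(T(ts + shift, tc + shift, d), d)
            assert not np.any(before & ~after)

    def test_coordinatewise_monotonicity_fails_by_design(self, design_b0):
        # inside via the overall path at (1.8, 1.8); raising T_c alone exits the cone
        assert intersection_test(T(1.8, 1.8, design_b0), design_b0)
        assert not intersection_test(T(1.8, 10.0, design_b0), design_b0)
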