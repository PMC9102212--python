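"""The estimation core: Wald ratios, IVW, meta-analysis, Q, scale conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr.harmonize import HarmonizedInstrument
from tsmr.mr import (
    PooledEstimate,
    RatioEstimate,
    chisq_upper_p,
    fixed_effects_meta,
    ivw_pool,
    normal_two_sided_p,
    to_or_scale,
    wald_ratio,
)


def inst(variant_id="rs1", bx=0.1, sx=0.01, by=0.02, sy=0.01, **kw):
    return HarmonizedInstrument(
        variant_id=variant_id, effect_allele="C", other_allele="T",
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
        action_taken="as_is", **kw,
    )


class TestWaldRatio:
    def test_hand_arithmetic(self):
        r = wald_ratio(inst(bx=0.1, by=0.02, sy=0.01))
        assert r.theta == pytest.approx(0.2)
        assert r.se_theta == pytest.approx(0.1)

    def test_zero_numerator(self):
        assert wald_ratio(inst(by=0.0)).theta == 0.0

    def test_negative_exposure_beta_flips_sign_not_se(self):
        r = wald_ratio(inst(bx=-0.1, by=0.02, sy=0.01))
        assert r.theta == pytest.approx(-0.2)
        assert r.se_theta == pytest.approx(0.1)

    def test_zero_exposure_beta_is_undefined(self):
        with pytest.raises(ZeroDivisionError, match="rs1"):
            wald_ratio(inst(bx=0.0))

    def test_excluded_instrument_refused(self):
        bad = HarmonizedInstrument(
            variant_id="rs9", effect_allele="A", other_allele="T",
            beta_exposure=0.1, se_exposure=0.01, beta_outcome=None,
            se_outcome=None, excluded=True, exclusion_reason="palindromic_ambiguous",
        )
        with pytest.raises(ValueError, match="excluded"):
            wald_ratio(bad)

    def test_second_order_se_adds_exposure_term(self):
        first = wald_ratio(inst(bx=0.1, sx=0.02, by=0.02, sy=0.01))
        second = wald_ratio(inst(bx=0.1, sx=0.02, by=0.02, sy=0.01), second_order=True)
        expected = math.sqrt(0.01**2 / 0.1**2 + 0.02**2 * 0.02**2 / 0.1**4)
        assert second.se_theta == pytest.approx(expected)
        assert second.se_theta > first.se_theta

    def test_scale_equivariance(self):
        """Rescaling the exposure divides theta and its SE by the same
        constant; z-scores and p-values are unchanged."""
        c = 3.7
        base = inst(bx=0.1, sx=0.01, by=0.02, sy=0.01)
        scaled = inst(bx=0.1 * c, sx=0.01 * c, by=0.02, sy=0.01)
        r0, r1 = wald_ratio(base), wald_ratio(scaled)
        assert r1.theta == pytest.approx(r0.theta / c)
        assert r1.se_theta == pytest.approx(r0.se_theta / c)
        p0 = ivw_pool([r0]).pvalue
        p1 = ivw_pool([r1]).pvalue
        assert p0 == pytest.approx(p1, rel=1e-12)


def ratio(theta, se, vid="rs1"):
    return RatioEstimate(variant_id=vid, theta=theta, se_theta=se)


class TestIvwPool:
    def test_single_ratio_is_identity(self):
        p = ivw_pool([ratio(0.3, 0.2)])
        assert p.beta == 0.3 and p.se == 0.2
        assert p.Q == 0.0 and p.Q_df == 0 and p.Q_p is None

    def test_two_ratio_hand_oracle(self):
        # weights 100 and 25; weighted mean 30/125 = 0.24;
        # Q = 100*(0.04)^2 + 25*(0.16)^2 = 0.8
        p = ivw_pool([ratio(0.2, 0.1, "rs1"), ratio(0.4, 0.2, "rs2")])
        assert p.beta == pytest.approx(0.24)
        assert p.se == pytest.approx(0.089443, abs=5e-7)
        assert p.Q == pytest.approx(0.8)
        assert p.Q_df == 1

    def test_identical_ratios_no_dispersion(self):
        p = ivw_pool([ratio(0.15, 0.1, "rs1"), ratio(0.15, 0.1, "rs2")])
        assert p.beta == pytest.approx(0.15)
        assert p.Q == pytest.approx(0.0, abs=1e-12)

    def test_se_is_reciprocal_root_summed_weights(self):
        ses = [0.1, 0.2, 0.5]
        p = ivw_pool([ratio(0.1, s, f"rs{i}") for i, s in enumerate(ses)])
        assert p.se == pytest.approx(sum(1 / s**2 for s in ses) ** -0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ivw_pool([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False),
                st.floats(0.01, 3.0, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariance(self, data, seed):
        ratios = [ratio(t, s, f"rs{i}") for i, (t, s) in enumerate(data)]
        a = ivw_pool(ratios)
        shuffled = list(ratios)
        np.random.default_rng(seed).shuffle(shuffled)
        b = ivw_pool(shuffled)
        assert a.beta == pytest.approx(b.beta, rel=1e-12, abs=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)
        assert a.Q == pytest.approx(b.Q, rel=1e-9, abs=1e-12)

    def test_matches_statsmodels_wls(self):
        """Independent cross-check: IVW equals weighted least squares of the
        ratios on a constant with fixed weights 1/se^2."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(25):
            k = int(rng.integers(2, 9))
            thetas = rng.normal(0, 0.5, k)
            ses = rng.uniform(0.05, 1.0, k)
            pool = ivw_pool([ratio(t, s, f"rs{i}") for i, (t, s) in enumerate(zip(thetas, ses))])
            fit = sm.WLS(thetas, np.ones(k), weights=1 / ses**2).fit()
            assert pool.beta == pytest.approx(fit.params[0], rel=1e-10)
            # fixed-weight (not scaled) SE:
            assert pool.se == pytest.approx(
                float(fit.bse[0] / np.sqrt(fit.scale)), rel=1e-10
            )


class TestMeta:
    def cohort(self, beta, se, outcome="AD", label="c"):
        or_, lo, hi = to_or_scale(beta, se)
        return PooledEstimate(
            label=label, outcome_name=outcome, n_units=2, beta=beta, se=se,
            or_=or_, ci_low=lo, ci_high=hi, pvalue=0.5, Q=0.0, Q_df=1, Q_p=1.0,
        )

    def test_homogeneous_cohorts(self):
        m = fixed_effects_meta([self.cohort(0.1, 0.2, label=f"c{i}") for i in range(3)])
        assert m.beta == pytest.approx(0.1)
        assert m.se == pytest.approx(0.2 / math.sqrt(3))
        assert m.Q == pytest.approx(0.0, abs=1e-12) and m.Q_df == 2
        assert m.label == "META"

    def test_hand_oracle_matches_ivw(self):
        m = fixed_effects_meta([self.cohort(0.2, 0.1), self.cohort(0.4, 0.2, label="d")])
        assert m.beta == pytest.approx(0.24)
        assert m.Q == pytest.approx(0.8) and m.Q_df == 1

    def test_single_cohort_passthrough(self):
        c = self.cohort(0.3, 0.15)
        m = fixed_effects_meta([c])
        assert (m.beta, m.se) == (c.beta, c.se)
        assert m.label == "META" and m.Q_df == 0 and m.Q_p is None

    def test_mixed_outcomes_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            fixed_effects_meta([self.cohort(0.1, 0.2, "AD"), self.cohort(0.1, 0.2, "PD")])

    def test_two_stage_equals_pooled_single_stage(self):
        """Meta-analysis of per-cohort IVW estimates equals one IVW over the
        union of all ratios (beta and se exactly; Q differs by partition)."""
        rng = np.random.default_rng(7)
        cohorts, union = [], []
        for c in range(4):
            k = int(rng.integers(1, 5))
            rs = [
                ratio(rng.normal(), float(rng.uniform(0.05, 1)), f"rs{c}_{i}")
                for i in range(k)
            ]
            union.extend(rs)
            cohorts.append(ivw_pool(rs, label=f"c{c}", outcome_name="AD"))
        two_stage = fixed_effects_meta(cohorts)
        one_stage = ivw_pool(union)
        assert two_stage.beta == pytest.approx(one_stage.beta, rel=1e-12)
        assert two_stage.se == pytest.approx(one_stage.se, rel=1e-12)

    def test_q_additivity_equal_weights(self):
        """With equal SEs, Q = (k-1) * sample variance / se^2."""
        rng = np.random.default_rng(3)
        betas = rng.normal(size=6)
        se = 0.3
        m = fixed_effects_meta([self.cohort(b, se, label=f"c{i}") for i, b in enumerate(betas)])
        expected = (len(betas) - 1) * np.var(betas, ddof=1) / se**2
        assert m.Q == pytest.approx(expected, rel=1e-10)


class TestTailProbabilities:
    def test_published_heterogeneity_statistics(self):
        # three cohorts combined (df 2) and two (df 1)
        assert round(chisq_upper_p(0.59, 2), 2) == 0.74
        assert round(chisq_upper_p(1.73, 1), 2) == 0.19

    def test_zero_statistic_gives_one(self):
        assert chisq_upper_p(0.0, 1) == 1.0
        assert chisq_upper_p(0.0, 5) == 1.0

    def test_df_zero_undefined(self):
        with pytest.raises(ValueError):
            chisq_upper_p(0.5, 0)

    def test_normal_two_sided(self):
        assert normal_two_sided_p(0.0) == 1.0
        assert normal_two_sided_p(1.959964) == pytest.approx(0.05, abs=5e-5)
        assert normal_two_sided_p(-1.959964) == normal_two_sided_p(1.959964)

    def test_extreme_z_never_truncated_to_zero(self):
        assert 0 < normal_two_sided_p(40.0) < 1e-300


class TestOrScale:
    def test_null_effect(self):
        or_, lo, hi = to_or_scale(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)  # log-symmetric about 1

    def test_ad_scale_example(self):
        or_, lo, hi = to_or_scale(-0.1393, 0.0711, alpha=0.05)
        assert or_ == pytest.approx(0.870, abs=5e-4)
        assert hi == pytest.approx(1.00, abs=5e-3)

    def test_larger_alpha_narrower_interval(self):
        _, lo05, hi05 = to_or_scale(0.2, 0.1, alpha=0.05)
        _, lo32, hi32 = to_or_scale(0.2, 0.1, alpha=0.32)
        assert lo32 > lo05 and hi32 < hi05

    def test_exact_normal_quantile_not_196(self):
        _, lo, _ = to_or_scale(0.0, 1.0, alpha=0.05)
        assert math.log(lo) == pytest.approx(-1.959964, abs=5e-7)
        assert math.log(lo) != -1.96
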