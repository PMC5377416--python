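"""SMD meta-analysis: effect sizes, pooling, heterogeneity, bias tests."""

import math

import numpy as np
import pytest

from mirmeta.cohort import DegenerateInputError, GroupSummary, StudySummary
from mirmeta.meta import (
    EffectSize,
    begg_test,
    egger_test,
    funnel_points,
    hedges_g,
    leave_one_out,
    pool_fixed,
    pool_random,
    select_model,
)
from mirmeta.synth import MetaPanelSpec, gen_meta_panel


def _study(n1, m1, s1, n2, m2, s2, sid="S"):
    return StudySummary(sid, GroupSummary(n1, m1, s1), GroupSummary(n2, m2, s2))


class TestHedgesG:
    def test_large_cohort_row(self, study_by_id):
        e = hedges_g(study_by_id["TCGA-2016"])
        assert e.g == pytest.approx(-0.583, abs=0.001)
        assert e.se == pytest.approx(0.152, abs=0.001)

    def test_equal_means_give_zero_effect(self):
        e = hedges_g(_study(10, 5.0, 1.0, 15, 5.0, 2.0))
        j = 1 - 3 / (4 * 23 - 1)
        assert e.g == 0.0
        assert e.variance == pytest.approx(j**2 * 25 / 150, rel=1e-12)

    def test_doubling_both_sds_halves_g(self):
        a = hedges_g(_study(12, 3.0, 1.0, 12, 2.0, 1.5))
        b = hedges_g(_study(12, 3.0, 2.0, 12, 2.0, 3.0))
        assert b.g == pytest.approx(a.g / 2, rel=1e-12)

    def test_zero_pooled_sd_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            hedges_g(_study(5, 1.0, 0.0, 5, 2.0, 0.0))


class TestPooling:
    def test_single_study_passthrough(self):
        e = EffectSize("A", -0.4, 0.04)
        r = pool_fixed([e])
        assert r.pooled == pytest.approx(-0.4) and r.Q == 0.0

    def test_equal_variances_pool_to_mean(self):
        effects = [EffectSize("A", -0.2, 0.05), EffectSize("B", -0.6, 0.05)]
        assert pool_fixed(effects).pooled == pytest.approx(-0.4)

    def test_random_equals_fixed_without_heterogeneity(self):
        effects = [EffectSize(str(i), -0.5, 0.05) for i in range(4)]
        rf, rr = pool_fixed(effects), pool_random(effects)
        assert rr.tau2 == 0.0
        assert rr.pooled == pytest.approx(rf.pooled)
        assert rr.ci_low == pytest.approx(rf.ci_low)

    def test_random_se_not_smaller_than_fixed(self, study_table):
        effects = [hedges_g(s) for s in study_table]
        rf, rr = pool_fixed(effects), pool_random(effects)
        width_f = rf.ci_high - rf.ci_low
        width_r = rr.ci_high - rr.ci_low
        assert width_r >= width_f

    def test_pooled_within_effect_range(self):
        panels = [gen_meta_panel(MetaPanelSpec(K=8, true_smd=-0.5, tau=0.4, seed=s)) for s in range(5)]
        for panel in panels:
            effects = [hedges_g(s) for s in panel]
            g = [e.g for e in effects]
            for pool in (pool_fixed, pool_random):
                r = pool(effects)
                assert min(g) <= r.pooled <= max(g)
                assert 0 <= r.I2 <= 100 and r.tau2 >= 0 and r.Q >= 0

    def test_equal_variance_random_pools_to_arithmetic_mean(self):
        effects = [EffectSize(str(i), g, 0.02) for i, g in enumerate([-0.9, -0.1, -0.5, 0.3])]
        r = pool_random(effects)
        assert r.pooled == pytest.approx(np.mean([-0.9, -0.1, -0.5, 0.3]))

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])


class TestModelSelection:
    def test_heterogeneous_published_panel_uses_random(self, study_table):
        r = select_model([hedges_g(s) for s in study_table])
        assert r.model == "random" and r.I2 > 50

    def test_homogeneous_panel_uses_fixed(self):
        panel = gen_meta_panel(
            MetaPanelSpec(K=10, true_smd=-0.5, tau=0.0, n_range=(200, 300), seed=11)
        )
        r = select_model([hedges_g(s) for s in panel])
        assert r.model == "fixed"

    def test_or_rule_low_i2_significant_q_uses_random(self):
        # 41 equal-variance effects alternating ±a: Q = 41·a²/v, I² ≈ 33% < 50
        # while p_Q ≈ 0.02 < 0.05 — the OR rule must still pick random effects
        a = math.sqrt(60 / 41 * 0.02)
        effects = [
            EffectSize(str(i), a if i % 2 == 0 else -a, 0.02) for i in range(41)
        ]
        fixed = pool_fixed(effects)
        assert fixed.I2 < 50 and fixed.p_Q < 0.05
        assert select_model(effects).model == "random"


class TestBiasTests:
    def test_published_panel_shows_no_bias(self, study_table):
        effects = [hedges_g(s) for s in study_table]
        assert egger_test(effects).p > 0.05
        assert begg_test(effects).p > 0.05
        geo = [hedges_g(s) for s in study_table if s.source == "GEO"]
        assert egger_test(geo).p > 0.05
        assert begg_test(geo).p > 0.05

    @pytest.mark.parametrize("func", [egger_test, begg_test])
    def test_small_panels_rejected(self, func):
        with pytest.raises(ValueError):
            func([EffectSize("A", 0.1, 0.02), EffectSize("B", 0.2, 0.03)])

    def test_egger_constant_precision_is_degenerate(self):
        effects = [EffectSize(str(i), 0.1 * i, 0.04) for i in range(5)]
        with pytest.raises(DegenerateInputError):
            egger_test(effects)

    def test_egger_null_rejection_rate_near_nominal(self):
        # symmetric funnel: no effect, no heterogeneity, K=20
        rejections = 0
        reps = 500
        for r in range(reps):
            panel = gen_meta_panel(
                MetaPanelSpec(K=20, true_smd=0.0, tau=0.0, n_range=(20, 100), seed=40_000 + r)
            )
            if egger_test([hedges_g(s) for s in panel]).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08

    def test_begg_detects_censored_funnel(self):
        # publication censoring: only studies with g/se > 1 survive, so small
        # (high-variance) studies need large effects — Begg should reject often
        rejections = 0
        reps = 100
        for r in range(reps):
            panel = gen_meta_panel(
                MetaPanelSpec(K=150, true_smd=0.0, tau=0.1, n_range=(5, 150), seed=10_000 + r)
            )
            kept = [e for e in (hedges_g(s) for s in panel) if e.g / e.se > 1.0][:30]
            if len(kept) >= 10 and begg_test(kept).p < 0.05:
                rejections += 1
        assert rejections / reps > 0.5


class TestTables:
    def test_funnel_single_effect(self):
        df = funnel_points([EffectSize("A", -0.3, 0.02)])
        assert len(df) == 1 and df.loc[0, "pooled"] == pytest.approx(-0.3)

    def test_funnel_published_panel_sorted_by_se(self, study_table):
        df = funnel_points([hedges_g(s) for s in study_table])
        assert len(df) == 11
        assert df["se"].is_monotonic_increasing

    def test_leave_one_out_emits_one_row_per_study(self, study_table):
        effects = [hedges_g(s) for s in study_table]
        df = leave_one_out(effects)
        assert len(df) == 11
        assert set(df["omitted"]) == {e.study_id for e in effects}
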