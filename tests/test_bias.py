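"""Egger regression, Begg rank correlation, and funnel data export."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from snpmeta import (
    DegenerateDesignError,
    EffectEstimate,
    GeneticModel,
    InsufficientStudiesError,
    begg_test,
    derive_2x2,
    egger_test,
    funnel_data,
    pool_random_dl,
    study_effect,
)
from snpmeta.bias import _kendall_s


def make_effect(log_or, se, sid):
    return EffectEstimate(
        study_id=sid, log_or=log_or, se=se, or_=math.exp(log_or),
        ci_low=0.0, ci_high=math.inf,
    )


def symmetric_funnel(mu=0.3, pairs=((0.1, 0.05), (0.25, 0.1), (0.5, 0.2))):
    """Pairs of effects equidistant above/below mu at matched precision."""
    effects = []
    for i, (se, d) in enumerate(pairs):
        effects.append(make_effect(mu + d, se, f"up{i}"))
        effects.append(make_effect(mu - d, se, f"dn{i}"))
    return effects


def allele_effects(glioma):
    return [
        study_effect(derive_2x2(s.cases, s.controls, GeneticModel.ALLELE), s.study_id)
        for s in glioma
    ]


class TestEgger:
    def test_hand_solvable_regression(self):
        # precisions 1, 2, 3 with standard normal deviates 1, 2, 3:
        # the points lie on the line through the origin with slope 1
        # log OR fixed at 1 makes SND = 1/se = precision exactly
        effects = [make_effect(1.0, se, str(i))
                   for i, se in enumerate([1.0, 0.5, 1 / 3])]
        res = egger_test(effects)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.slope == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_funnel_has_zero_intercept(self):
        res = egger_test(symmetric_funnel())
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_negating_effects_flips_the_intercept(self, glioma):
        effects = allele_effects(glioma)
        flipped = [make_effect(-e.log_or, e.se, e.study_id) for e in effects]
        a, b = egger_test(effects), egger_test(flipped)
        assert b.intercept == pytest.approx(-a.intercept, rel=1e-9)
        assert b.p == pytest.approx(a.p, rel=1e-9)

    def test_fixture_allele_matches_independent_regression(self, glioma):
        # oracle values computed with R metafor::regtest(model="lm")
        res = egger_test(allele_effects(glioma))
        assert res.p == pytest.approx(0.4560616, abs=1e-6)
        assert res.df == 2
        assert res.p > 0.05

    def test_equal_precisions_are_degenerate(self):
        effects = [make_effect(x, 0.2, str(i)) for i, x in enumerate([0.1, 0.3, 0.5])]
        with pytest.raises(DegenerateDesignError):
            egger_test(effects)

    def test_requires_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([make_effect(0.1, 0.1, "a"), make_effect(0.2, 0.2, "b")])


class TestBegg:
    def test_perfect_discordance_gives_tau_minus_one(self):
        effects = [make_effect(lo, se, str(i)) for i, (lo, se) in
                   enumerate([(1.0, 0.1), (0.5, 0.2), (0.0, 0.3), (-0.5, 0.4)])]
        assert begg_test(effects).kendall_tau == -1.0

    def test_kendall_score_against_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(3, 7))
            x, y = rng.normal(size=k), rng.normal(size=k)
            s, conc, disc = _kendall_s(x, y)
            tau = s / (k * (k - 1) / 2)
            assert tau == pytest.approx(scipy.stats.kendalltau(x, y).statistic,
                                        abs=1e-12)
            assert conc + disc <= k * (k - 1) / 2

    def test_continuity_corrected_z_small_k(self):
        # S = 2 of 6 pairs => tau = 1/3; var(S) = 4*3*13/18; z = (2-1)/sqrt(var)
        x = np.array([2.0, 1.0, 4.0, 3.0])
        s, _, _ = _kendall_s(np.array([1.0, 2.0, 3.0, 4.0]), x)
        assert s == 2
        var_s = 4 * 3 * 13 / 18
        expected_z = (abs(s) - 1) / math.sqrt(var_s)
        assert expected_z == pytest.approx(0.33968, abs=1e-4)

    def test_fixture_allele_matches_independent_rank_test(self, glioma):
        # tau oracle: R metafor::ranktest gives tau = -1/3 on these effects
        res = begg_test(allele_effects(glioma))
        assert res.kendall_tau == pytest.approx(-1 / 3, abs=1e-12)
        assert res.continuity_corrected
        assert res.p > 0.05

    def test_requires_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            begg_test([make_effect(0.1, 0.1, "a")])


class TestFunnelData:
    def test_fixture_allele_rows_sorted_by_se(self, glioma):
        effects = allele_effects(glioma)
        df = funnel_data(effects, pool_random_dl(effects))
        assert len(df) == 4
        assert list(df["se"]) == sorted(df["se"])
        assert df["se"].between(0.09, 0.21).all()

    def test_single_study_guides_bracket_iff_equal_to_pool(self):
        e = make_effect(0.4, 0.2, "only")
        pooled = pool_random_dl([e])
        df = funnel_data([e], pooled)
        assert len(df) == 1
        assert df.loc[0, "guide_low"] < e.log_or < df.loc[0, "guide_high"]

    def test_equal_se_gives_constant_guide_width(self):
        effects = [make_effect(x, 0.25, str(i)) for i, x in enumerate([0.1, 0.2, 0.3])]
        df = funnel_data(effects, pool_random_dl(effects))
        widths = df["guide_high"] - df["guide_low"]
        assert widths.nunique() == 1
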