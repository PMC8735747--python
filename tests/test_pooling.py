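"""Fixed-effect and DerSimonian-Laird pooling, and heterogeneity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpmeta import (
    EffectEstimate,
    GeneticModel,
    InsufficientStudiesError,
    PoolingMethod,
    derive_2x2,
    heterogeneity,
    pool_fixed_iv,
    pool_mantel_haenszel,
    pool_random_dl,
    run_model,
    study_effect,
)


def make_effect(log_or, se, sid="x"):
    import math

    return EffectEstimate(
        study_id=sid,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.959963984540054 * se),
        ci_high=math.exp(log_or + 1.959963984540054 * se),
    )


def fixture_effects(glioma, model, ids=None):
    out = []
    for s in glioma:
        if ids is not None and s.study_id not in ids:
            continue
        out.append(study_effect(derive_2x2(s.cases, s.controls, model), s.study_id))
    return out


ASIAN = ("gao2016", "chen2012", "zhang2016")

effect_lists = st.lists(
    st.builds(
        make_effect,
        log_or=st.floats(-2, 2, allow_nan=False),
        se=st.floats(0.05, 1.5, allow_nan=False),
        sid=st.uuids().map(str),
    ),
    min_size=2,
    max_size=8,
    unique_by=lambda e: e.study_id,
)


class TestHeterogeneity:
    def test_fixture_allele_q_and_i2(self, glioma):
        q, df, p_q, i2 = heterogeneity(fixture_effects(glioma, GeneticModel.ALLELE))
        assert df == 3
        assert p_q == pytest.approx(0.029, abs=5e-4)
        assert i2 == pytest.approx(66.8, abs=0.05)

    def test_asian_allele_stratum_is_homogeneous(self, glioma):
        _, _, p_q, i2 = heterogeneity(
            fixture_effects(glioma, GeneticModel.ALLELE, ASIAN)
        )
        assert i2 == 0.0
        assert p_q == pytest.approx(0.640, abs=5e-4)

    def test_identical_effects_have_zero_q(self):
        q, df, p_q, i2 = heterogeneity([make_effect(0.3, 0.1, "a"),
                                        make_effect(0.3, 0.1, "b")])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0

    def test_single_study_is_insufficient(self):
        with pytest.raises(InsufficientStudiesError):
            heterogeneity([make_effect(0.1, 0.2)])


class TestFixedIV:
    def test_single_study_passthrough(self):
        e = make_effect(0.4, 0.15)
        r = pool_fixed_iv([e])
        assert r.log_or == pytest.approx(e.log_or)
        assert r.se == pytest.approx(e.se)
        assert (r.ci_low, r.ci_high) == (
            pytest.approx(e.ci_low),
            pytest.approx(e.ci_high),
        )
        assert r.Q is None and r.i2 is None and r.p_q is None

    def test_equal_precision_studies_pool_to_the_mean(self):
        r = pool_fixed_iv([make_effect(0.2, 0.3, "a"), make_effect(0.6, 0.3, "b")])
        assert r.log_or == pytest.approx(0.4)

    def test_asian_recessive_matches_published_interval(self, glioma):
        r = pool_fixed_iv(fixture_effects(glioma, GeneticModel.RECESSIVE, ASIAN))
        assert round(r.or_, 2) == 2.24
        assert round(r.ci_low, 2) == 1.49
        assert round(r.ci_high, 2) == 3.36


class TestRandomDL:
    def test_fixture_allele_matches_published_interval(self, glioma):
        r = pool_random_dl(fixture_effects(glioma, GeneticModel.ALLELE))
        assert round(r.or_, 2) == 1.20
        assert round(r.ci_low, 2) == 0.93
        assert round(r.ci_high, 2) == 1.54
        assert r.p == pytest.approx(0.162, abs=5e-4)

    def test_homogeneous_stratum_reduces_to_fixed_effect_bit_for_bit(self, glioma):
        for model in GeneticModel:
            effs = fixture_effects(glioma, model, ASIAN)
            dl = pool_random_dl(effs)
            iv = pool_fixed_iv(effs)
            assert dl.tau2 == 0.0  # Q <= df in every Asian stratum
            assert dl.log_or == iv.log_or and dl.se == iv.se

    def test_cross_check_against_statsmodels_dl(self, glioma):
        from statsmodels.stats.meta_analysis import combine_effects

        effs = fixture_effects(glioma, GeneticModel.ALLELE)
        res = combine_effects(
            np.array([e.log_or for e in effs]),
            np.array([e.var for e in effs]),
            method_re="dl",
        )
        mine = pool_random_dl(effs)
        frame = res.summary_frame()
        assert mine.log_or == pytest.approx(frame.loc["random effect", "eff"], abs=1e-10)
        assert mine.se == pytest.approx(frame.loc["random effect", "sd_eff"], abs=1e-10)
        assert mine.tau2 == pytest.approx(res.tau2, abs=1e-10)

    @given(effects=effect_lists)
    @settings(max_examples=50, deadline=None)
    def test_pooling_properties(self, effects):
        dl = pool_random_dl(effects)
        iv = pool_fixed_iv(effects)
        los = [e.log_or for e in effects]
        for r in (dl, iv):
            assert min(los) - 1e-9 <= r.log_or <= max(los) + 1e-9  # convexity
            assert sum(w for _, w in r.weights) == pytest.approx(1.0, abs=1e-12)
        if dl.tau2 == 0.0:
            assert dl.log_or == iv.log_or and dl.se == iv.se
        # negating every effect negates the pool, leaves heterogeneity alone
        neg = pool_random_dl(
            [make_effect(-e.log_or, e.se, e.study_id) for e in effects]
        )
        assert neg.log_or == pytest.approx(-dl.log_or, abs=1e-9)
        assert neg.Q == pytest.approx(dl.Q, abs=1e-9)
        assert neg.tau2 == pytest.approx(dl.tau2, abs=1e-9)


class TestMantelHaenszel:
    def test_close_to_iv_on_homogeneous_fixture_stratum(self, glioma):
        tables = [
            derive_2x2(s.cases, s.controls, GeneticModel.RECESSIVE)
            for s in glioma
            if s.study_id in ASIAN
        ]
        mh = pool_mantel_haenszel(tables, ASIAN)
        iv = pool_fixed_iv(fixture_effects(glioma, GeneticModel.RECESSIVE, ASIAN))
        assert mh.method is PoolingMethod.FIXED_MH
        assert mh.or_ == pytest.approx(iv.or_, rel=0.02)


class TestRunModel:
    def test_reports_both_pools_and_flags_selection(self, glioma):
        res = run_model(glioma, GeneticModel.ALLELE, method="random")
        assert res.selected is PoolingMethod.RANDOM_DL
        assert res.pooled is res.random
        assert res.fixed.method is PoolingMethod.FIXED_IV
        assert len(res.effects) == 4

    def test_auto_gate_uses_q_test_at_point_one(self, glioma):
        allele = run_model(glioma, GeneticModel.ALLELE, method="auto")
        hetero = run_model(glioma, GeneticModel.HETEROZYGOTE, method="auto")
        assert allele.selected is PoolingMethod.RANDOM_DL  # p_q = .029 < .10
        assert hetero.selected is PoolingMethod.FIXED_IV  # p_q = .487
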