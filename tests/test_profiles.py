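"""Effect sizes, post-hoc tests, and module effect profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from modulearn import (
    ContrastSpec,
    NoiseSpec,
    build_profile,
    cohens_d,
    fit_final_logistic,
    generate,
    paper_effect_spec,
    profile_frame,
    radar_profile,
    welch_t,
)
from modulearn.design import Cohort, CohortDesign
from modulearn.errors import (
    ContractError,
    InsufficientDataError,
    SeparationWarning,
    UndefinedEffectError,
)

values = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False),
    min_size=3,
    max_size=20,
)


class TestCohensD:
    def test_closed_form(self):
        # means 0.5 vs 1.5, pooled variance 0.5
        assert cohens_d([0, 1], [1, 2], direction=1) == pytest.approx(np.sqrt(2))

    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3], direction=1) == 0.0

    def test_improvement_orientation(self):
        # group a decreased more (distress-coded improvement)
        a = [-2.0, -1.5, -2.5]
        b = [0.1, -0.1, 0.0]
        assert cohens_d(a, b, direction=1) > 0
        assert cohens_d(a, b, direction=-1) < 0

    @given(a=values, b=values)
    def test_direction_flip_negates(self, a, b):
        try:
            d_plus = cohens_d(a, b, 1)
        except UndefinedEffectError:
            return
        assert cohens_d(a, b, -1) == pytest.approx(-d_plus, rel=1e-9, abs=1e-12)

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d([1, 1, 1], [1, 1, 1], 1)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            cohens_d([1], [1, 2], 1)


class TestWelchT:
    def test_hand_computed_example(self):
        # a=(1,2,3) vs b=(4,5,6): t = 3 / sqrt(2/3), Satterthwaite df = 4
        t, p = welch_t([1, 2, 3], [4, 5, 6], direction=1)
        assert t == pytest.approx(3.674, abs=1e-3)
        assert p == pytest.approx(stats.t.sf(3.6742, 4), abs=1e-4)
        assert p < 0.05

    def test_identical_groups_p_half(self):
        _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1)
        assert p == pytest.approx(0.5)

    def test_single_observation_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_t([1], [1, 2], 1)

    def test_pooled_variant_matches_student(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 40)
        t, p = welch_t(a, b, direction=1, pooled=True)
        ref = stats.ttest_ind(b, a, equal_var=True, alternative="greater")
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_orientation_matches_cohens_d(self):
        rng = np.random.default_rng(0)
        a = rng.normal(-0.5, 1, 60)
        b = rng.normal(0.0, 1, 80)
        for direction in (1, -1):
            t, _ = welch_t(a, b, direction)
            d = cohens_d(a, b, direction)
            assert np.sign(t) == np.sign(d)


class TestFinalLogistic:
    def test_sign_follows_planted_direction(self):
        rng = np.random.default_rng(11)
        n = 400
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"v": rng.standard_normal(n) + y * 1.0})
        coefs = fit_final_logistic(X, y)
        assert coefs.loc["v", "coefficient"] > 0
        assert coefs.loc["v", "p"] < 0.05

    def test_null_predictor_rarely_significant(self):
        # Wald p-values are mildly anticonservative at n=200 (~8% measured
        # over 200 null replicates), so bound the rejection rate at 15%
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(300 + seed)
            y = np.repeat([0, 1], 100)
            X = pd.DataFrame({"v": rng.standard_normal(200)})
            hits += fit_final_logistic(X, y).loc["v", "p"] < 0.05
        assert hits <= 9

    def test_class_flip_negates_coefficients(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 150)
        X = pd.DataFrame(
            {"v1": rng.standard_normal(300) + y, "v2": rng.standard_normal(300)}
        )
        direct = fit_final_logistic(X, y)
        flipped = fit_final_logistic(X, 1 - y)
        np.testing.assert_allclose(
            direct["coefficient"], -flipped["coefficient"], rtol=1e-4, atol=1e-6
        )

    def test_empty_selection_rejected(self):
        with pytest.raises(ContractError):
            fit_final_logistic(pd.DataFrame(index=range(10)), np.repeat([0, 1], 5))

    def test_separation_falls_back_with_warning(self):
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame({"v": np.concatenate([np.zeros(20), np.ones(20)])})
        with pytest.warns(SeparationWarning):
            coefs = fit_final_logistic(X, y)
        assert np.isfinite(coefs.loc["v", "se"])
        assert coefs.loc["v", "coefficient"] > 0


@pytest.fixture(scope="module")
def strong_profile():
    from modulearn import default_design, default_panel

    panel = default_panel()
    ds = generate(
        default_design(), panel, paper_effect_spec().scaled(4), NoiseSpec(), seed=3
    )
    selected = sorted(
        {v for (m, v) in paper_effect_spec().entries if m in ("Presence", "Affect")}
    )
    entries = build_profile(ds, ContrastSpec("PresenceVsAffect"), selected)
    return entries, selected


class TestBuildProfile:
    def test_planted_attribution_recovered(self, strong_profile):
        entries, _ = strong_profile
        truth = {
            v: m for (m, v) in paper_effect_spec().entries if m in ("Presence", "Affect")
        }
        for e in entries:
            assert e.module == truth[e.variable_id], e.variable_id

    def test_presence_variables_specific(self, strong_profile):
        entries, _ = strong_profile
        presence = [e for e in entries if e.module == "Presence"]
        assert {e.variable_id for e in presence} == {
            "pcs_helplessness", "tics_work_overload", "tics_social_overload"
        }
        assert all(e.specific_effect for e in presence)
        for e in presence:
            assert e.d_vs_retest > 0.5

    def test_profile_is_subset_of_selection(self, strong_profile):
        entries, selected = strong_profile
        assert {e.variable_id for e in entries} <= set(selected)

    def test_radar_contains_only_specific_effects(self, strong_profile):
        entries, _ = strong_profile
        radar = radar_profile(entries)
        flagged = {e.variable_id for e in entries if e.specific_effect}
        listed = {v for mod in radar.values() for v in mod}
        assert listed == flagged

    def test_null_data_yields_no_specific_effects(self, small_panel, small_design):
        flagged = 0
        total = 0
        for seed in range(20):
            ds = generate(small_design, small_panel, None, None, seed=600 + seed)
            entries = build_profile(
                ds, ContrastSpec("PresenceVsAffect"), ["qa_1", "qb_1"]
            )
            flagged += sum(e.specific_effect for e in entries)
            total += len(entries)
        assert flagged <= 0.1 * total

    def test_empty_selection_rejected(self, small_null_dataset):
        with pytest.raises(ContractError):
            build_profile(small_null_dataset, ContrastSpec("PresenceVsAffect"), [])

    def test_missing_retest_comparator_rejected(self, small_panel):
        design = CohortDesign(
            (Cohort("TC1", 30, ("Presence", "Affect")), Cohort("TC2", 30, ("Affect", "Presence")))
        )
        ds = generate(design, small_panel, None, None, seed=2)
        with pytest.raises(InsufficientDataError):
            build_profile(ds, ContrastSpec("PresenceVsAffect"), ["qa_1"])

    def test_bh_adjustment_only_raises_p_values(self, small_panel, small_design):
        ds = generate(small_design, small_panel, None, None, seed=77)
        raw = build_profile(ds, ContrastSpec("PresenceVsAffect"), ["qa_1", "qb_1", "qc_1"])
        adj = build_profile(
            ds, ContrastSpec("PresenceVsAffect"), ["qa_1", "qb_1", "qc_1"], adjust="bh"
        )
        for r, a in zip(raw, adj):
            assert a.p_vs_other_module >= r.p_vs_other_module - 1e-12
            assert a.p_vs_retest >= r.p_vs_retest - 1e-12

    def test_frame_columns(self, strong_profile):
        entries, _ = strong_profile
        df = profile_frame(entries)
        assert {
            "variable_id", "module", "coefficient", "d_vs_other_module",
            "d_vs_retest", "p_vs_retest", "specific_effect",
        } <= set(df.columns)
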