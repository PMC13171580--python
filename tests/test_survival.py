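"""Cox tertile models, FDR, splines, Fine-Gray and sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from actirisk.cohort import TertileExposure, make_tertiles
from actirisk.simulate import EffectConfig, SimConfig, simulate_cohort
from actirisk.survival import (
    adjust_fdr,
    bh_adjust,
    fine_gray,
    fit_cox,
    fit_rcs,
    rcs_basis,
    subgroup_and_sensitivity,
    trend_p,
)


class TestBenjaminiHochberg:
    def test_step_up_hand_computed(self):
        # m=3: adjusted p_(i) = min over j>=i of p_(j)*m/j -> all 0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(13)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestFitCox:
    def test_effect_recovery_and_reference(self, effect_cohort):
        cohort, _ = effect_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        res = fit_cox(cohort, exp, "M0")
        assert exp.reference == "T3"
        assert res.hr["T3"] == 1.0
        assert res.ci_low["T1"] < res.hr["T1"] < res.ci_high["T1"]
        assert res.ci_low["T1"] < 1.5 < res.ci_high["T1"]
        assert 0 < res.p_trend <= 1

    def test_null_cohort_hr_near_one(self, null_cohort):
        cohort, _ = null_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        res = fit_cox(cohort, exp, "M1")
        for t in ("T1", "T2"):
            assert res.ci_low[t] < 1.0 < res.ci_high[t]

    def test_reparameterization_invariance(self, effect_cohort):
        # negating the exposure swaps T1 and T3; with the reference swapped
        # accordingly the non-reference HRs must coincide
        cohort, _ = effect_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")  # ref T3
        neg = make_tertiles(-cohort["amplitude"], "IV")  # ref T1
        res_a = fit_cox(cohort, exp, "M0")
        res_b = fit_cox(cohort, neg, "M0")
        assert res_b.hr["T3"] == pytest.approx(res_a.hr["T1"], rel=1e-6)
        assert res_b.hr["T2"] == pytest.approx(res_a.hr["T2"], rel=1e-6)

    def test_time_rescaling_invariance(self, effect_cohort):
        cohort, _ = effect_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        days = cohort.copy()
        days["follow_up"] = days["follow_up"] * 365.25
        res_y = fit_cox(cohort, exp, "M0")
        res_d = fit_cox(days, exp, "M0")
        assert res_d.hr["T1"] == pytest.approx(res_y.hr["T1"], abs=1e-8)

    def test_incidence_bookkeeping(self, effect_cohort):
        cohort, _ = effect_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        res = fit_cox(cohort, exp, "M1")
        assert sum(res.n_events.values()) == int(cohort["event"].sum())
        assert sum(res.person_years.values()) == pytest.approx(
            cohort["follow_up"].sum()
        )
        for t in ("T1", "T2", "T3"):
            assert res.incidence_per_1000py[t] > 0

    def test_adjust_fdr_within_model(self, null_cohort):
        cohort, _ = null_cohort
        rng = np.random.default_rng(4)
        results = []
        for i in range(4):
            exp = make_tertiles(rng.standard_normal(len(cohort)), f"noise{i}")
            results.append(fit_cox(cohort, exp, "M0"))
        adjust_fdr(results)
        for r in results:
            assert r.p_trend_adjusted >= r.p_trend - 1e-12

    def test_epv_warning_flag(self):
        cfg = SimConfig(n_participants=1500, seed=51, effects=EffectConfig.null(),
                        event_target=40)
        cohort, _, _ = simulate_cohort(cfg, with_activity=False)
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        res = fit_cox(cohort, exp, "M2")
        assert any("events per variable" in f for f in res.flags)

    def test_trend_p_matches_full_fit(self, effect_cohort):
        cohort, _ = effect_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        res = fit_cox(cohort, exp, "M1")
        assert trend_p(cohort, exp, "M1") == pytest.approx(res.p_trend, rel=1e-9)


class TestSplines:
    def test_basis_linear_beyond_boundaries(self):
        knots = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.linspace(4.5, 8.0, 50)
        b = rcs_basis(x, knots)
        for j in range(1, b.shape[1]):
            slope = np.diff(b[:, j]) / np.diff(x)
            assert np.allclose(slope, slope[0], atol=1e-8)

    def test_reference_log_hr_zero(self, effect_cohort):
        cohort, _ = effect_cohort
        res = fit_rcs(cohort, cohort["amplitude"], "amplitude", "M1")
        ref = float(np.median(cohort["amplitude"]))
        i = int(np.argmin(np.abs(res.grid - ref)))
        # curve passes through 0 at the reference by construction
        assert abs(res.log_hr[i]) < 0.02
        assert 0 <= res.p_nonlinear <= 1

    def test_quadratic_hazard_detected(self):
        rng = np.random.default_rng(8)
        n = 15000
        x = rng.standard_normal(n)
        lp = 0.5 * x**2
        t = rng.exponential(1 / (0.005 * np.exp(lp)))
        cohort = pd.DataFrame({
            "follow_up": np.minimum(t, 10.0),
            "event": (t <= 10.0).astype(int),
            "age": rng.normal(56, 8, n),
            "sex_male": rng.binomial(1, 0.44, n),
        })
        res = fit_rcs(cohort, x, "x", "M1")
        assert res.p_nonlinear < 0.01


class TestFineGrayAndSensitivity:
    def test_no_competing_reduces_to_cox(self, effect_cohort):
        cohort, _ = effect_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        fg = fine_gray(cohort, exp, "M1")
        cox = fit_cox(cohort, exp, "M1")
        assert fg.hr["T1"] == pytest.approx(cox.hr["T1"], abs=1e-6)

    def test_subdistribution_matches_reference_implementation(self):
        # frozen oracle: cmprsk::crr on this exact simulated dataset gives
        # subdistribution log-HRs (0.8717, 0.2041) for (T1, T2) vs T3
        cfg = SimConfig(
            n_participants=800, seed=53,
            effects=EffectConfig.null(
                rar_t1_loghr=float(np.log(2.0)), competing_hazard=0.07
            ),
            baseline_hazard=0.02,
        )
        cohort, _, _ = simulate_cohort(cfg, with_activity=False)
        assert cohort["competing"].mean() > 0.3
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        fg = fine_gray(cohort, exp, "M0")
        assert np.log(fg.hr["T1"]) == pytest.approx(0.8717, abs=2e-3)
        assert np.log(fg.hr["T2"]) == pytest.approx(0.2041, abs=2e-3)
        # and it genuinely differs from the cause-specific fit here
        cs = fit_cox(cohort, exp, "M0")
        assert fg.hr["T1"] != pytest.approx(cs.hr["T1"], abs=1e-4)

    def test_landmark_without_first_year_events(self, effect_cohort):
        cohort, _ = effect_cohort
        mod = cohort.copy()
        # push all first-year events past the landmark so none are dropped
        early = (mod["event"] == 1) & (mod["follow_up"] <= 1.0)
        mod.loc[early, "follow_up"] = 1.0001
        mod = mod[mod["follow_up"] > 1.0].reset_index(drop=True)
        exp = make_tertiles(mod["amplitude"], "amplitude")
        lm = subgroup_and_sensitivity(mod, exp, "landmark-1y", "M0")["result"]
        main = fit_cox(mod, exp, "M0")
        assert lm.hr["T1"] == pytest.approx(main.hr["T1"], abs=1e-8)

    def test_subgroup_analysis_runs(self, rich_cohort):
        cohort, _ = rich_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        out = subgroup_and_sensitivity(cohort, exp, "subgroup:sex", "M1")
        assert set(out["strata"]) == {"male", "female"}
        assert 0 < out["p_interaction"] <= 1

    def test_adjustment_variants(self, rich_cohort):
        cohort, _ = rich_cohort
        exp = make_tertiles(cohort["amplitude"], "amplitude")
        prs_res = subgroup_and_sensitivity(cohort, exp, "adjust-prs", "M1")["result"]
        act_res = subgroup_and_sensitivity(cohort, exp, "adjust-activity", "M1")["result"]
        assert prs_res.hr["T1"] > 0 and act_res.hr["T1"] > 0
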