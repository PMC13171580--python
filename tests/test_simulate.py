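"""Synthetic cohort generator: determinism, closed forms, ground truth."""

import numpy as np
import pytest

from actirisk.cosinor import anti_logistic_curve
from actirisk.simulate import (
    EffectConfig,
    MissingnessConfig,
    NoiseConfig,
    RhythmPopulation,
    SimConfig,
    simulate_activity,
    simulate_cohort,
)


def fixed_rhythm_config(**kw):
    """Population with zero spread: every participant gets the same curve."""
    pop = RhythmPopulation(
        minimum_mean=10.0, minimum_sd=0.0, amplitude_mean=50.0, amplitude_sd=1e-9,
        acrophase_mean=14.0, acrophase_sd=0.0, alpha_mean=0.0, alpha_sd=0.0,
        beta_log_mean=float(np.log(2.0)), beta_log_sd=0.0,
    )
    defaults = dict(
        n_participants=2, seed=1, rhythm_population=pop,
        noise=NoiseConfig(ar1=0.0, innovation_sd=0.0, sigma=0.0),
        missingness=MissingnessConfig(0.0),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateActivity:
    def test_noiseless_series_equals_formula(self):
        cfg = fixed_rhythm_config()
        s = simulate_activity(cfg, 0)
        t = (np.arange(7 * 1440) / 60.0) % 24.0
        expected = anti_logistic_curve(t, 10.0, 50.0, 14.0, 0.0, 2.0)
        assert s.values == pytest.approx(expected)
        peak_minute = int(np.argmax(s.values[:1440]))
        assert abs(peak_minute / 60.0 - 14.0) < 0.1
        # extremes follow the anti-logistic closed form: minimum + amplitude
        # * expit(beta*(+-1 - alpha)); they approach 60 and 10 as beta grows
        from scipy.special import expit

        assert s.values.max() == pytest.approx(10 + 50 * expit(2.0), abs=1e-6)
        assert s.values.min() == pytest.approx(10 + 50 * expit(-2.0), abs=1e-6)
        steep = fixed_rhythm_config()
        steep.rhythm_population.beta_log_mean = float(np.log(12.0))
        s2 = simulate_activity(steep, 0)
        assert s2.values.max() == pytest.approx(60.0, abs=0.5)
        assert s2.values.min() == pytest.approx(10.0, abs=0.5)

    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_participants=2, seed=123)
        a = simulate_activity(cfg, 1)
        b = simulate_activity(cfg, 1)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.imputed, b.imputed)

    def test_ar1_residual_autocorrelation(self):
        cfg = fixed_rhythm_config(
            noise=NoiseConfig(ar1=0.5, innovation_sd=5.0, kind="additive"), seed=5
        )
        s = simulate_activity(cfg, 0)
        t = (np.arange(7 * 1440) / 60.0) % 24.0
        resid = s.values - anti_logistic_curve(t, 10.0, 50.0, 14.0, 0.0, 2.0)
        r = resid - resid.mean()
        rho1 = float(np.sum(r[1:] * r[:-1]) / np.sum(r * r))
        assert rho1 == pytest.approx(0.5, abs=0.05)

    def test_values_finite_nonnegative_with_missingness(self):
        cfg = SimConfig(n_participants=1, seed=9,
                        missingness=MissingnessConfig(expected_hours_per_day=2.0))
        s = simulate_activity(cfg, 0)
        assert np.all(np.isfinite(s.values)) and np.all(s.values >= 0)
        assert s.imputed.any()

    def test_invalid_epoch_seconds_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_participants=1, epoch_seconds=30)

    def test_out_of_range_participant(self):
        cfg = SimConfig(n_participants=2)
        with pytest.raises(IndexError):
            simulate_activity(cfg, 5)


class TestSimulateCohort:
    def test_null_event_fraction_closed_form(self):
        # all coefficients zero: cumulative incidence = 1 - exp(-h0 * t)
        h0, tc = 0.003 / 10.0, 10.0
        cfg = SimConfig(n_participants=50000, seed=17, effects=EffectConfig.null(),
                        baseline_hazard=h0, admin_censor_years=tc)
        cohort, _, _ = simulate_cohort(cfg, with_activity=False)
        expected = 1 - np.exp(-h0 * tc)
        frac = cohort["event"].mean()
        se = np.sqrt(expected * (1 - expected) / len(cohort))
        assert abs(frac - expected) < 4 * se

    def test_zero_a_path_decouples_mediator(self):
        cfg = SimConfig(n_participants=20000, seed=19,
                        effects=EffectConfig.null(rar_direct_loghr=0.38))
        cohort, _, truth = simulate_cohort(cfg, with_activity=False)
        r = np.corrcoef(truth["amplitude"], cohort["neutrophils"])[0, 1]
        assert abs(r) < 2 / np.sqrt(len(cohort))

    def test_event_fraction_monotone_in_baseline_hazard(self):
        fracs = []
        for h0 in (0.0005, 0.002, 0.008):
            cfg = SimConfig(n_participants=8000, seed=23, baseline_hazard=h0,
                            effects=EffectConfig.null())
            cohort, _, _ = simulate_cohort(cfg, with_activity=False)
            fracs.append(cohort["event"].mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_ground_truth_mediation_identity(self):
        eff = EffectConfig(mediator_a=0.3, mediator_loghr=0.0737, rar_direct_loghr=0.38)
        expected = 0.3 * 0.0737 / (0.3 * 0.0737 + 0.38)
        assert eff.design_proportion_mediated == pytest.approx(expected)
        cfg = SimConfig(n_participants=100, seed=3, effects=eff)
        _, _, truth = simulate_cohort(cfg, with_activity=False)
        assert truth["design_prop_mediated"].iloc[0] == pytest.approx(expected)

    def test_cohort_determinism(self):
        cfg = SimConfig(n_participants=500, seed=77)
        a, _, ta = simulate_cohort(cfg, with_activity=False)
        b, _, tb = simulate_cohort(cfg, with_activity=False)
        assert a.equals(b) and ta.equals(tb)

    def test_event_target_calibration(self):
        cfg = SimConfig(n_participants=10000, seed=41, event_target=250)
        cohort, _, _ = simulate_cohort(cfg, with_activity=False)
        assert abs(int(cohort["event"].sum()) - 250) < 4 * np.sqrt(250)

    def test_follow_up_positive_event_binary(self):
        cfg = SimConfig(n_participants=2000, seed=43, event_target=60)
        cohort, _, _ = simulate_cohort(cfg, with_activity=False)
        assert (cohort["follow_up"] > 0).all()
        assert set(cohort["event"].unique()) <= {0, 1}

    def test_prs_tertile_hazard_ratio_near_three(self):
        # PRS coefficient is calibrated so the top-vs-bottom tertile HR ~ 3
        from actirisk.cohort import prs_groups
        from lifelines import CoxPHFitter

        cfg = SimConfig(n_participants=40000, seed=47,
                        effects=EffectConfig.null(prs_loghr=EffectConfig().prs_loghr),
                        event_target=900)
        cohort, _, _ = simulate_cohort(cfg, with_activity=False)
        g = prs_groups(cohort["prs"])
        df = cohort[["follow_up", "event"]].copy()
        df["high"] = (g.labels == "high").astype(int).to_numpy()
        df["mid"] = (g.labels == "intermediate").astype(int).to_numpy()
        cph = CoxPHFitter().fit(df, "follow_up", "event")
        hr = float(np.exp(cph.params_["high"]))
        assert hr == pytest.approx(3.01, rel=0.25)
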