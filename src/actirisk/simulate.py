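"""Synthetic accelerometer cohort with known ground truth.

Generates a fully synthetic study population — minute-level wrist activity
traces with an anti-logistic diurnal shape, demographic and lifestyle
covariates, a polygenic score, inflammatory blood counts partially driven
by rhythm strength, and proportional-hazards event times for a rare
vascular outcome (~0.3% cumulative incidence over ~10 years by default,
inflatable for desk-scale power).  Every cohort ships with a GroundTruth
table holding the per-participant rhythm parameters, the true linear
predictor and the designed mediation paths; inference modules never read
it — it exists for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .preprocess import EpochSeries
from .cosinor import anti_logistic_curve

SECONDS_PER_DAY = 86400

# mean of the top tertile of a standard normal = 3*pdf(z_{2/3});
# the top-vs-bottom tertile mean gap is twice that.
_PRS_TERTILE_GAP = 2 * 3 * norm.pdf(norm.ppf(2 / 3))


@dataclass
class RhythmPopulation:
    """Population distributions of the anti-logistic rhythm parameters.

    Means/SDs of truncated normals for minimum and amplitude (mg), normal
    for acrophase (h, wrapped), alpha (width, clipped to (-0.95, 0.95)) and
    log-normal beta (steepness).
    """

    minimum_mean: float = 10.0
    minimum_sd: float = 3.0
    amplitude_mean: float = 45.0
    amplitude_sd: float = 12.0
    acrophase_mean: float = 14.0
    acrophase_sd: float = 1.2
    alpha_mean: float = -0.4
    alpha_sd: float = 0.15
    beta_log_mean: float = float(np.log(8.0))
    beta_log_sd: float = 0.4


@dataclass
class NoiseConfig:
    """Minute-level noise around the deterministic diurnal curve.

    ``multiplicative`` (default): value = curve * exp(sigma*a_t - sigma^2/2)
    with a_t a unit-variance AR(1) process — mean-preserving, nonnegative,
    and right-skewed like real minute-level wrist acceleration, where brief
    movement bursts dwarf the diurnal mean.  ``sigma`` is calibrated so the
    cosinor goodness-of-rhythm (pseudo-F) of a default 7-day series falls
    in the tertile band reported for population actigraphy (~50-150).

    ``additive``: classic AR(1) Gaussian noise (``innovation_sd`` mg) added
    to the curve and truncated at zero.
    """

    ar1: float = 0.5
    innovation_sd: float = 10.0
    kind: str = "multiplicative"
    sigma: float = 1.4

    def __post_init__(self) -> None:
        if not (0 <= self.ar1 < 1):
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if self.kind not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass
class MissingnessConfig:
    """Contiguous imputed blocks: uniform start, geometric length."""

    expected_hours_per_day: float = 0.5
    mean_block_minutes: float = 30.0


@dataclass
class EffectConfig:
    """Named log-hazard coefficients and mediation paths.

    The rhythm exposure enters two ways: tertile-coded (T1/T2 of the true
    amplitude vs T3) and continuously through z_weak, the standardized
    *negated* amplitude (higher = weaker rhythm).  The mediation design is
    z_weak -> mediator (path a, on the neutrophil-count scale) and
    mediator -> hazard (path b), with direct path c' = rar_direct_loghr;
    the designed proportion mediated is a*b/(a*b + c').
    """

    age_loghr: float = 0.08
    male_loghr: float = 0.9
    smoking_current_loghr: float = float(np.log(2.2))
    smoking_former_loghr: float = 0.25
    prs_loghr: float = float(np.log(3.01)) / _PRS_TERTILE_GAP
    rar_t1_loghr: float = 0.0
    rar_t2_loghr: float = 0.0
    rar_direct_loghr: float = 0.38
    mediator_a: float = 0.3
    mediator_loghr: float = 0.0737
    competing_hazard: float = 0.0

    @classmethod
    def null(cls, **overrides) -> "EffectConfig":
        """All coefficients zero except the ones overridden."""
        zero = {f: 0.0 for f in cls.__dataclass_fields__}
        zero.update(overrides)
        return cls(**zero)

    @property
    def design_proportion_mediated(self) -> float:
        ab = self.mediator_a * self.mediator_loghr
        denom = ab + self.rar_direct_loghr
        return ab / denom if denom != 0 else float("nan")


@dataclass
class SimConfig:
    n_participants: int = 1000
    days: int = 7
    epoch_seconds: int = 60
    seed: int = 0
    rhythm_population: RhythmPopulation = field(default_factory=RhythmPopulation)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    baseline_hazard: float = 0.000297  # events per person-year; ~0.3% over 10.1 y
    admin_censor_years: float = 10.1
    event_target: int | None = None
    weibull_shape: float | None = None  # None = exponential baseline
    start_date: str = "2014-06-02"

    def __post_init__(self) -> None:
        if self.epoch_seconds not in (5, 60):
            raise ValueError(f"epoch_seconds must be 5 or 60, got {self.epoch_seconds}")
        if self.n_participants <= 0 or self.days <= 0:
            raise ValueError("n_participants and days must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be > 0")
        if self.rhythm_population.amplitude_mean < 0:
            raise ValueError("amplitude distribution support must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("rhythm_population", RhythmPopulation),
            ("noise", NoiseConfig),
            ("missingness", MissingnessConfig),
            ("effects", EffectConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def participant_id(i: int) -> str:
    return f"P{i:06d}"


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + stream))


def rhythm_params(config: SimConfig, i: int) -> dict:
    """True anti-logistic rhythm parameters of participant ``i`` (seeded)."""
    pop = config.rhythm_population
    rng = _rng(config, 0, i)
    minimum = max(0.0, rng.normal(pop.minimum_mean, pop.minimum_sd))
    amplitude = max(0.0, rng.normal(pop.amplitude_mean, pop.amplitude_sd))
    acrophase = rng.normal(pop.acrophase_mean, pop.acrophase_sd) % 24.0
    alpha = float(np.clip(rng.normal(pop.alpha_mean, pop.alpha_sd), -0.95, 0.95))
    beta = float(np.exp(rng.normal(pop.beta_log_mean, pop.beta_log_sd)))
    return {
        "minimum": minimum,
        "amplitude": amplitude,
        "acrophase": acrophase,
        "alpha": alpha,
        "beta": beta,
    }


def simulate_activity(config: SimConfig, i: int) -> EpochSeries:
    """Simulate one participant's multi-day epoch activity series.

    value(t) = max(0, minimum + amplitude * F(cos(2*pi*(t - phi)/24)) + AR(1)),
    with F the anti-logistic transform.  Missing blocks (uniform start,
    geometric length) are flagged imputed and filled with the participant's
    time-of-day mean, mirroring an upstream imputation step.
    """
    if not (0 <= i < config.n_participants):
        raise IndexError(f"participant_index {i} out of range")
    p = rhythm_params(config, i)
    n = config.days * SECONDS_PER_DAY // config.epoch_seconds
    t_hours = np.arange(n) * config.epoch_seconds / 3600.0
    curve = anti_logistic_curve(
        t_hours % 24.0, p["minimum"], p["amplitude"], p["acrophase"], p["alpha"], p["beta"]
    )

    rng = _rng(config, 1, i)
    rho = config.noise.ar1

    def ar1_path(stationary_sd: float) -> np.ndarray:
        if stationary_sd <= 0:
            return np.zeros(n)
        innov_sd = stationary_sd * np.sqrt(1 - rho**2) if rho > 0 else stationary_sd
        eps = rng.normal(0.0, innov_sd, size=n)
        path = np.empty(n)
        path[0] = rng.normal(0.0, stationary_sd)
        for k in range(1, n):
            path[k] = rho * path[k - 1] + eps[k]
        return path

    if config.noise.kind == "multiplicative":
        sigma = config.noise.sigma
        if sigma > 0:
            a = ar1_path(1.0)
            values = curve * np.exp(sigma * a - sigma**2 / 2.0)
        else:
            values = curve.copy()
    else:  # additive AR(1), truncated at zero
        sd = config.noise.innovation_sd
        stat_sd = sd / np.sqrt(1 - rho**2) if rho > 0 else sd
        # innovation_sd is the AR(1) innovation scale, per the additive model
        if sd > 0:
            eps = rng.normal(0.0, sd, size=n)
            noise = np.empty(n)
            noise[0] = rng.normal(0.0, stat_sd)
            for k in range(1, n):
                noise[k] = rho * noise[k - 1] + eps[k]
        else:
            noise = np.zeros(n)
        values = np.maximum(0.0, curve + noise)

    imputed = np.zeros(n, dtype=bool)
    miss = config.missingness
    if miss.expected_hours_per_day > 0:
        mean_block = max(miss.mean_block_minutes, 1.0)
        lam = miss.expected_hours_per_day * 60.0 / mean_block  # blocks per day
        for d in range(config.days):
            n_blocks = rng.poisson(lam)
            day_start = d * SECONDS_PER_DAY // config.epoch_seconds
            day_len = SECONDS_PER_DAY // config.epoch_seconds
            for _ in range(n_blocks):
                length_min = rng.geometric(1.0 / mean_block)
                length = int(length_min * 60 // config.epoch_seconds)
                start = day_start + rng.integers(0, day_len)
                imputed[start : min(start + length, n)] = True
        if imputed.any() and not imputed.all():
            # fill imputed epochs with the time-of-day mean of observed epochs
            per_day = SECONDS_PER_DAY // config.epoch_seconds
            tod = np.arange(n) % per_day
            sums = np.bincount(tod[~imputed], weights=values[~imputed], minlength=per_day)
            cnts = np.bincount(tod[~imputed], minlength=per_day).astype(float)
            fill = np.where(cnts > 0, sums / np.maximum(cnts, 1), curve[:per_day])
            values = np.where(imputed, fill[tod], values)

    return EpochSeries(
        participant_id=participant_id(i),
        start=pd.Timestamp(config.start_date),
        epoch_seconds=config.epoch_seconds,
        values=values,
        imputed=imputed,
    )


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def _covariates(config: SimConfig, n: int) -> pd.DataFrame:
    """Demographics, lifestyle, medical history and daily activity durations."""
    rng = _rng(config, 2)
    df = pd.DataFrame({"participant_id": [participant_id(i) for i in range(n)]})
    df["age"] = np.round(_truncnorm(rng, 56.3, 7.8, 40, 70, n), 1)
    df["sex_male"] = rng.binomial(1, 0.439, n)
    df["education_university"] = rng.binomial(1, 0.445, n)
    df["employed"] = rng.binomial(1, 0.923, n)
    df["townsend"] = np.round(rng.normal(-1.8, 2.7, n), 2)
    df["shift_work"] = rng.binomial(1, 0.084, n)
    df["bmi"] = np.round(_truncnorm(rng, 26.7, 4.4, 15, 50, n), 1)
    df["smoking"] = rng.choice(
        np.array(["never", "former", "current"]), size=n, p=[0.394, 0.540, 0.066]
    )
    df["alcohol_heavy"] = rng.binomial(1, 0.55, n)
    df["healthy_diet"] = rng.binomial(1, 0.10, n)
    df["statin_use"] = rng.binomial(1, 0.124, n)
    df["vitamin_use"] = rng.binomial(1, 0.235, n)
    df["hypertension"] = rng.binomial(1, 0.274, n)
    df["diabetes"] = rng.binomial(1, 0.054, n)
    df["dyslipidemia"] = rng.binomial(1, 0.352, n)
    df["chronic_respiratory"] = rng.binomial(1, 0.129, n)
    df["chronic_liver"] = rng.binomial(1, 0.0026, n)
    df["chronic_kidney"] = rng.binomial(1, 0.0029, n)
    df["cardiovascular_disease"] = rng.binomial(1, 0.116, n)
    df["prs"] = rng.standard_normal(n)
    return df


def simulate_cohort(
    config: SimConfig, with_activity: bool = True
) -> tuple[pd.DataFrame, dict[str, EpochSeries] | None, pd.DataFrame]:
    """Simulate the full synthetic cohort.

    Returns (cohort table, per-participant epoch series or None, ground
    truth).  ``with_activity=False`` skips trace generation and copies the
    true rhythm parameters into the cohort table directly — used for
    large-n statistical replicates where the trace level is irrelevant.
    """
    n = config.n_participants
    eff = config.effects
    pop = config.rhythm_population

    truth = pd.DataFrame([rhythm_params(config, i) for i in range(n)])
    truth.insert(0, "participant_id", [participant_id(i) for i in range(n)])
    truth["mesor"] = truth["minimum"] + truth["amplitude"] / 2
    # standardized "weak rhythm" exposure: negated amplitude in population SD units
    truth["z_weak"] = (pop.amplitude_mean - truth["amplitude"]) / pop.amplitude_sd

    cov = _covariates(config, n)
    rng = _rng(config, 3)

    # blood counts; neutrophils and monocytes carry the a-path from rhythm weakness
    z = truth["z_weak"].to_numpy()
    smoking_current = (cov["smoking"] == "current").astype(float).to_numpy()
    neut = _truncnorm(rng, 4.0, 1.1, 0.5, 15, n) + eff.mediator_a * z + 0.5 * smoking_current
    mono = _truncnorm(rng, 0.5, 0.14, 0.05, 3, n) + eff.mediator_a * (0.14 / 1.1) * z
    lymph = _truncnorm(rng, 1.9, 0.5, 0.3, 8, n)
    plat = _truncnorm(rng, 250, 52, 50, 600, n)
    cov["neutrophils"] = np.maximum(neut, 0.2)
    cov["monocytes"] = np.maximum(mono, 0.02)
    cov["lymphocytes"] = lymph
    cov["platelets"] = plat

    # daily MVPA minutes, mildly coupled to rhythm strength
    base = np.maximum(5.0 + rng.normal(40.0 - 6.0 * z, 22.0), 0.0)
    daily = np.maximum(base[:, None] * rng.lognormal(0.0, 0.6, (n, 7)), 0.0)
    for d in range(7):
        cov[f"mvpa_day{d + 1}"] = np.round(daily[:, d], 1)
    cov["lpa_min_day"] = np.round(_truncnorm(rng, 300, 90, 30, 700, n), 1)
    cov["sedentary_min_day"] = np.round(_truncnorm(rng, 565, 100, 200, 1000, n), 1)
    cov["sleep_min_day"] = np.round(_truncnorm(rng, 530, 75, 180, 800, n), 1)

    # tertiles of the TRUE amplitude for the tertile-coded effect
    q1, q2 = np.quantile(truth["amplitude"], [1 / 3, 2 / 3])
    amp_t = np.where(truth["amplitude"] <= q1, 1, np.where(truth["amplitude"] <= q2, 2, 3))

    lp = (
        eff.age_loghr * (cov["age"].to_numpy() - 56.3)
        + eff.male_loghr * cov["sex_male"].to_numpy()
        + eff.smoking_current_loghr * smoking_current
        + eff.smoking_former_loghr * (cov["smoking"] == "former").astype(float).to_numpy()
        + eff.prs_loghr * cov["prs"].to_numpy()
        + eff.rar_t1_loghr * (amp_t == 1)
        + eff.rar_t2_loghr * (amp_t == 2)
        + eff.rar_direct_loghr * z
        + eff.mediator_loghr * (cov["neutrophils"].to_numpy() - 4.0)
    )
    lp = lp - lp.mean()  # baseline_hazard refers to the average participant

    h0 = config.baseline_hazard
    tc = config.admin_censor_years
    if config.event_target is not None:
        rel = np.exp(lp)

        def expected_events(scale):
            return float(np.sum(1 - np.exp(-scale * h0 * rel * tc))) - config.event_target

        try:
            scale = brentq(expected_events, 1e-6, 1e6)
        except ValueError:
            scale = 1.0
        h0 = scale * h0

    hazard = h0 * np.exp(lp)
    u = rng.random(n)
    if config.weibull_shape is not None:
        k = config.weibull_shape
        t_event = (-np.log(u) / hazard) ** (1.0 / k)
    else:
        t_event = -np.log(u) / hazard
    if eff.competing_hazard > 0:
        t_comp = rng.exponential(1.0 / eff.competing_hazard, n)
    else:
        t_comp = np.full(n, np.inf)
    t_obs = np.minimum(np.minimum(t_event, t_comp), tc)
    event = (t_event <= np.minimum(t_comp, tc)).astype(int)
    competing = ((t_comp < t_event) & (t_comp <= tc)).astype(int)

    cov["event"] = event
    cov["competing"] = competing
    cov["follow_up"] = np.maximum(t_obs, 1e-4)

    truth["amplitude_tertile"] = amp_t
    truth["linear_predictor"] = lp
    truth["path_a"] = eff.mediator_a
    truth["path_b"] = eff.mediator_loghr
    truth["path_c_direct"] = eff.rar_direct_loghr
    truth["design_prop_mediated"] = eff.design_proportion_mediated
    truth["baseline_hazard_used"] = h0

    series: dict[str, EpochSeries] | None = None
    if with_activity:
        series = {participant_id(i): simulate_activity(config, i) for i in range(n)}
    else:
        # copy true rhythm parameters into the cohort table for direct use
        for col in ("minimum", "amplitude", "mesor", "acrophase", "alpha", "beta"):
            cov[col] = truth[col].to_numpy()

    return cov, series, truth


def write_cohort(outdir, cohort: pd.DataFrame, series, truth: pd.DataFrame) -> None:
    """Write cohort.csv, ground_truth.csv and one epoch CSV per participant."""
    import os

    os.makedirs(outdir, exist_ok=True)
    cohort.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
    truth.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)
    if series:
        epoch_dir = os.path.join(outdir, "epochs")
        os.makedirs(epoch_dir, exist_ok=True)
        for pid, s in series.items():
            s.to_csv(os.path.join(epoch_dir, f"{pid}.csv"))
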