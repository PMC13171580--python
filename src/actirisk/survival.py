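"""Proportional-hazards inference for tertiled rhythm exposures.

Model 1 adjusts for age and sex; Model 2 additionally for education,
employment, deprivation, shift work, BMI, medical history, smoking, diet,
alcohol and statin/vitamin use.  Trend tests refit with the integer-scored
tertile; Benjamini-Hochberg adjustment is applied across the 13 rhythm
parameters within each model.  Sensitivity analyses: 1-year landmark,
Fine-Gray subdistribution hazards (Geskus censoring-weighted risk sets),
and additional adjustment for activity time or the polygenic score.
Restricted cubic splines probe nonlinearity of continuous exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import TertileExposure

MODEL1_COVARIATES = ["age", "sex_male"]
MODEL2_COVARIATES = MODEL1_COVARIATES + [
    "education_university",
    "employed",
    "townsend",
    "shift_work",
    "bmi",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "chronic_respiratory",
    "chronic_liver",
    "chronic_kidney",
    "cardiovascular_disease",
    "smoking_former",
    "smoking_current",
    "healthy_diet",
    "alcohol_heavy",
    "statin_use",
    "vitamin_use",
]

TERTILES = ["T1", "T2", "T3"]


@dataclass
class HazardResult:
    parameter_name: str
    model_tag: str
    reference: str
    hr: dict[str, float]  # tertile -> HR (reference = 1.0)
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_trend: float
    p_trend_adjusted: float | None
    schoenfeld_p: float
    n_events: dict[str, int]
    person_years: dict[str, float]
    flags: list[str] = field(default_factory=list)

    @property
    def incidence_per_1000py(self) -> dict[str, float]:
        return {
            t: 1000.0 * self.n_events[t] / self.person_years[t]
            if self.person_years.get(t)
            else float("nan")
            for t in self.n_events
        }

    def to_row(self) -> dict:
        row = {
            "parameter": self.parameter_name,
            "model": self.model_tag,
            "reference": self.reference,
            "p_trend": self.p_trend,
            "p_trend_adjusted": self.p_trend_adjusted,
            "schoenfeld_p": self.schoenfeld_p,
        }
        for t in TERTILES:
            row[f"HR_{t}"] = self.hr.get(t, np.nan)
            row[f"CI_low_{t}"] = self.ci_low.get(t, np.nan)
            row[f"CI_high_{t}"] = self.ci_high.get(t, np.nan)
            row[f"events_{t}"] = self.n_events.get(t, 0)
            row[f"rate1000_{t}"] = self.incidence_per_1000py.get(t, np.nan)
        return row


def _smoking_dummies(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "smoking" in out.columns and "smoking_current" not in out.columns:
        out["smoking_former"] = (out["smoking"] == "former").astype(int)
        out["smoking_current"] = (out["smoking"] == "current").astype(int)
    return out


def adjustment_columns(model_tag: str) -> list[str]:
    if model_tag == "M0":
        return []
    if model_tag == "M1":
        return list(MODEL1_COVARIATES)
    if model_tag == "M2":
        return list(MODEL2_COVARIATES)
    raise ValueError(f"unknown model tag {model_tag!r}")


def build_design(
    cohort: pd.DataFrame,
    exposure: TertileExposure,
    model_tag: str = "M2",
    extra_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Survival design frame: tertile indicators vs reference + adjusters."""
    df = _smoking_dummies(cohort)
    cols = adjustment_columns(model_tag) + (extra_columns or [])
    design = df[["follow_up", "event"] + cols].copy()
    labels = exposure.labels.reset_index(drop=True)
    exp_cols = []
    for t in TERTILES:
        if t == exposure.reference:
            continue
        col = f"exp_{t}"
        design[col] = (labels == t).astype(int).to_numpy()
        exp_cols.append(col)
    return design, exp_cols


def _tertile_bookkeeping(cohort: pd.DataFrame, exposure: TertileExposure):
    labels = exposure.labels.reset_index(drop=True)
    events, pyears = {}, {}
    for t in TERTILES:
        sel = (labels == t).to_numpy()
        events[t] = int(cohort.loc[sel, "event"].sum())
        pyears[t] = float(cohort.loc[sel, "follow_up"].sum())
    return events, pyears


def fit_cox(
    cohort: pd.DataFrame,
    exposure: TertileExposure,
    model_tag: str = "M2",
    extra_columns: list[str] | None = None,
    diagnostics: bool = True,
) -> HazardResult:
    """Covariate-adjusted Cox model for one tertiled exposure.

    Ties are handled by the Efron approximation (lifelines default).  The
    trend p comes from refitting with the integer-scored tertile; the
    Schoenfeld p is a global (rank-transform) test over the exposure terms.
    Non-convergence or an event-free tertile yields a flagged result.
    ``diagnostics=False`` skips the trend refit and Schoenfeld test, for
    replicate studies that only need the per-tertile estimates.
    """
    flags: list[str] = []
    events, pyears = _tertile_bookkeeping(cohort, exposure)
    if sum(v > 0 for v in events.values()) < 2:
        flags.append("fewer than 2 tertiles contain events")
    n_params = len(adjustment_columns(model_tag)) + 2
    if cohort["event"].sum() / max(n_params, 1) < 10:
        flags.append("events per variable < 10")

    design, exp_cols = build_design(cohort, exposure, model_tag, extra_columns)
    hr = {exposure.reference: 1.0}
    ci_lo = {}
    ci_hi = {}
    p_trend = np.nan
    sch_p = np.nan
    try:
        cph = CoxPHFitter()
        cph.fit(design, duration_col="follow_up", event_col="event")
        for col in exp_cols:
            t = col.split("_")[1]
            hr[t] = float(np.exp(cph.params_[col]))
            lo, hi = cph.confidence_intervals_.loc[col]
            ci_lo[t] = float(np.exp(lo))
            ci_hi[t] = float(np.exp(hi))
        if diagnostics:
            try:
                ph = proportional_hazard_test(cph, design, time_transform="rank")
                chi2 = float(ph.summary.loc[exp_cols, "test_statistic"].sum())
                dof = len(exp_cols)
                sch_p = float(stats.chi2.sf(chi2, dof))
            except Exception:
                flags.append("schoenfeld test failed")
            # trend: integer-scored tertile refit
            trend = design.drop(columns=exp_cols)
            trend["exp_score"] = exposure.scores().reset_index(drop=True).to_numpy()
            cph_t = CoxPHFitter()
            cph_t.fit(trend, duration_col="follow_up", event_col="event")
            p_trend = float(cph_t.summary.loc["exp_score", "p"])
    except Exception as err:  # ConvergenceError and friends
        flags.append(f"fit failed: {type(err).__name__}")

    return HazardResult(
        parameter_name=exposure.parameter_name,
        model_tag=model_tag,
        reference=exposure.reference,
        hr=hr,
        ci_low=ci_lo,
        ci_high=ci_hi,
        p_trend=p_trend,
        p_trend_adjusted=None,
        schoenfeld_p=sch_p,
        n_events=events,
        person_years=pyears,
        flags=flags,
    )


def trend_p(cohort: pd.DataFrame, exposure: TertileExposure, model_tag: str = "M0") -> float:
    """Trend-test p value alone (integer-scored tertile refit).

    Same construction as in :func:`fit_cox` without the per-tertile fit or
    diagnostics — the economical choice inside replicate studies.
    """
    df = _smoking_dummies(cohort)
    cols = adjustment_columns(model_tag)
    design = df[["follow_up", "event"] + cols].copy()
    design["exp_score"] = exposure.scores().reset_index(drop=True).to_numpy()
    cph = CoxPHFitter()
    cph.fit(design, duration_col="follow_up", event_col="event")
    return float(cph.summary.loc["exp_score", "p"])


def adjust_fdr(results: list[HazardResult]) -> list[HazardResult]:
    """Benjamini-Hochberg adjustment of trend p values within each model."""
    by_model: dict[str, list[HazardResult]] = {}
    for r in results:
        by_model.setdefault(r.model_tag, []).append(r)
    for group in by_model.values():
        ps = np.array([r.p_trend for r in group], dtype=float)
        ok = np.isfinite(ps)
        adj = np.full_like(ps, np.nan)
        if ok.any():
            adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
        for r, a in zip(group, adj):
            r.p_trend_adjusted = float(a) if np.isfinite(a) else None
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def results_table(results: list[HazardResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


# -- restricted cubic splines ------------------------------------------------

def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, Harrell scaling).

    Returns k-1 columns for k knots: the linear term plus k-2 restricted
    cubic terms, linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    tau = (knots[-1] - knots[0]) ** 2

    def d(j):
        p = np.maximum(x - knots[j], 0.0) ** 3
        return p

    cols = [x]
    for j in range(k - 2):
        term = (
            d(j)
            - d(k - 2) * (knots[-1] - knots[j]) / (knots[-1] - knots[-2])
            + d(k - 1) * (knots[-2] - knots[j]) / (knots[-1] - knots[-2])
        ) / tau
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class SplineResult:
    parameter_name: str
    knots: np.ndarray
    p_nonlinear: float
    grid: np.ndarray
    log_hr: np.ndarray
    log_hr_low: np.ndarray
    log_hr_high: np.ndarray


def fit_rcs(
    cohort: pd.DataFrame,
    exposure_values,
    parameter_name: str,
    model_tag: str = "M2",
    n_knots: int = 4,
    reference: float | None = None,
    n_grid: int = 100,
) -> SplineResult:
    """Restricted-cubic-spline dose-response inside the adjusted Cox model.

    Knots sit at the 5/35/65/95th percentiles (4 knots); the nonlinearity p
    is a likelihood-ratio test of the nonlinear basis terms against the
    linear-only model.  The returned curve is log-HR relative to the
    reference exposure value (median by default), hence 0 there.  Collinear
    bases fall back to 3 knots.
    """
    x = np.asarray(exposure_values, dtype=float)
    pct = {4: [5, 35, 65, 95], 3: [10, 50, 90]}[n_knots]
    knots = np.percentile(x, pct)
    if len(np.unique(knots)) < n_knots:
        if n_knots == 4:
            return fit_rcs(cohort, x, parameter_name, model_tag, 3, reference, n_grid)
        raise ValueError("degenerate knots")
    basis = rcs_basis(x, knots)
    df = _smoking_dummies(cohort)
    cols = adjustment_columns(model_tag)
    design = df[["follow_up", "event"] + cols].copy()
    bnames = [f"rcs_{j}" for j in range(basis.shape[1])]
    for j, name in enumerate(bnames):
        design[name] = basis[:, j]
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="follow_up", event_col="event")
    except Exception:
        if n_knots == 4:
            return fit_rcs(cohort, x, parameter_name, model_tag, 3, reference, n_grid)
        raise
    ll_full = cph.log_likelihood_
    design_lin = design.drop(columns=bnames[1:])
    cph_lin = CoxPHFitter()
    cph_lin.fit(design_lin, duration_col="follow_up", event_col="event")
    lr = 2 * (ll_full - cph_lin.log_likelihood_)
    p_nl = float(stats.chi2.sf(max(lr, 0.0), len(bnames) - 1))

    ref = float(np.median(x)) if reference is None else float(reference)
    grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), n_grid)
    bg = rcs_basis(grid, knots) - rcs_basis(np.full(n_grid, ref), knots)
    beta = cph.params_[bnames].to_numpy()
    cov = cph.variance_matrix_.loc[bnames, bnames].to_numpy()
    log_hr = bg @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", bg, cov, bg))
    z = stats.norm.ppf(0.975)
    return SplineResult(
        parameter_name=parameter_name,
        knots=knots,
        p_nonlinear=p_nl,
        grid=grid,
        log_hr=log_hr,
        log_hr_low=log_hr - z * se,
        log_hr_high=log_hr + z * se,
    )


# -- Fine-Gray subdistribution hazards ---------------------------------------

def fine_gray(
    cohort: pd.DataFrame,
    exposure: TertileExposure,
    model_tag: str = "M2",
) -> HazardResult:
    """Fine-Gray subdistribution-hazard fit with Geskus weighting.

    Subjects failing from the competing cause stay in the risk set past
    their competing-event time, down-weighted by G(t)/G(s) where G is the
    Kaplan-Meier estimate of the censoring distribution.  Without competing
    events this reduces exactly to the cause-specific Cox model.
    """
    comp = cohort.get("competing")
    if comp is None or int(comp.sum()) == 0:
        res = fit_cox(cohort, exposure, model_tag)
        res.flags.append("no competing events; identical to Cox")
        return res

    df = _smoking_dummies(cohort).reset_index(drop=True)
    cols = adjustment_columns(model_tag)
    labels = exposure.labels.reset_index(drop=True)
    exp_cols = []
    for t in TERTILES:
        if t == exposure.reference:
            continue
        df[f"exp_{t}"] = (labels == t).astype(int).to_numpy()
        exp_cols.append(f"exp_{t}")

    # KM of the censoring distribution (censoring = neither event nor competing)
    cens = ((df["event"] == 0) & (df["competing"] == 0)).astype(int)
    km = KaplanMeierFitter()
    km.fit(df["follow_up"], event_observed=cens)

    def G(t):
        return float(km.survival_function_at_times(t).iloc[0])

    event_times = np.sort(df.loc[df["event"] == 1, "follow_up"].unique())
    rows = []
    use_cols = cols + exp_cols
    for i, r in df.iterrows():
        if r["competing"] == 1:
            # at risk at own time with weight 1, then weighted intervals
            later = event_times[event_times > r["follow_up"]]
            g_s = max(G(r["follow_up"]), 1e-12)
            start = 0.0
            base = {c: r[c] for c in use_cols}
            prev = r["follow_up"]
            rows.append({**base, "start": 0.0, "stop": prev, "ev": 0, "w": 1.0, "id": i})
            for t in later:
                w = G(t) / g_s
                if w <= 0:
                    break
                rows.append({**base, "start": prev, "stop": t, "ev": 0, "w": w, "id": i})
                prev = t
        else:
            base = {c: r[c] for c in use_cols}
            rows.append(
                {
                    **base,
                    "start": 0.0,
                    "stop": r["follow_up"],
                    "ev": int(r["event"]),
                    "w": 1.0,
                    "id": i,
                }
            )
    long = pd.DataFrame(rows)
    long = long[long["stop"] > long["start"]]
    ctv = CoxTimeVaryingFitter()
    ctv.fit(
        long,
        id_col="id",
        start_col="start",
        stop_col="stop",
        event_col="ev",
        weights_col="w",
    )
    events, pyears = _tertile_bookkeeping(cohort, exposure)
    hr = {exposure.reference: 1.0}
    ci_lo, ci_hi = {}, {}
    for col in exp_cols:
        t = col.split("_")[1]
        hr[t] = float(np.exp(ctv.params_[col]))
        lo, hi = ctv.confidence_intervals_.loc[col]
        ci_lo[t] = float(np.exp(lo))
        ci_hi[t] = float(np.exp(hi))
    return HazardResult(
        parameter_name=exposure.parameter_name,
        model_tag=f"{model_tag}-finegray",
        reference=exposure.reference,
        hr=hr,
        ci_low=ci_lo,
        ci_high=ci_hi,
        p_trend=np.nan,
        p_trend_adjusted=None,
        schoenfeld_p=np.nan,
        n_events=events,
        person_years=pyears,
        flags=["fine-gray subdistribution"],
    )


# -- subgroups and sensitivity -----------------------------------------------

SUBGROUP_DEFS = {
    "age": lambda df: (df["age"] >= 60).map({True: "60plus", False: "under60"}),
    "sex": lambda df: df["sex_male"].map({1: "male", 0: "female"}),
    "bmi": lambda df: ((df["bmi"] >= 18.5) & (df["bmi"] <= 24.9)).map(
        {True: "normal", False: "outside"}
    ),
}

MIN_STRATUM_EVENTS = 10


def subgroup_and_sensitivity(
    cohort: pd.DataFrame,
    exposure: TertileExposure,
    plan: str,
    model_tag: str = "M2",
) -> dict:
    """One named subgroup or sensitivity analysis.

    plan in {'subgroup:age', 'subgroup:sex', 'subgroup:bmi', 'landmark-1y',
    'fine-gray', 'adjust-activity', 'adjust-prs'}.
    """
    if plan.startswith("subgroup:"):
        key = plan.split(":", 1)[1]
        strata = SUBGROUP_DEFS[key](cohort)
        out: dict = {"plan": plan, "strata": {}}
        for level in strata.unique():
            sel = (strata == level).to_numpy()
            sub = cohort.loc[sel].reset_index(drop=True)
            sub_exp = TertileExposure(
                parameter_name=exposure.parameter_name,
                cut_points=exposure.cut_points,
                labels=exposure.labels.reset_index(drop=True)[sel].reset_index(drop=True),
                reference=exposure.reference,
            )
            if sub["event"].sum() < MIN_STRATUM_EVENTS:
                out["strata"][level] = {"flag": "fewer than 10 events; suppressed"}
                continue
            out["strata"][level] = fit_cox(sub, sub_exp, model_tag)
        # interaction p: cross-product of integer score with stratum indicator
        design, _ = build_design(cohort, exposure, model_tag)
        design = design.drop(columns=[c for c in design if c.startswith("exp_")])
        if key == "sex" and "sex_male" in design.columns:
            design = design.drop(columns=["sex_male"])  # the stratum term replaces it
        design["exp_score"] = exposure.scores().reset_index(drop=True).to_numpy()
        design["stratum"] = (strata == strata.unique()[0]).astype(int).to_numpy()
        design["interaction"] = design["exp_score"] * design["stratum"]
        cph = CoxPHFitter()
        cph.fit(design, duration_col="follow_up", event_col="event")
        out["p_interaction"] = float(cph.summary.loc["interaction", "p"])
        return out

    if plan == "landmark-1y":
        keep = cohort["follow_up"] > 1.0
        sub = cohort.loc[keep].copy().reset_index(drop=True)
        sub["follow_up"] = sub["follow_up"] - 1.0
        sub_exp = TertileExposure(
            parameter_name=exposure.parameter_name,
            cut_points=exposure.cut_points,
            labels=exposure.labels.reset_index(drop=True)[keep.to_numpy()].reset_index(
                drop=True
            ),
            reference=exposure.reference,
        )
        res = fit_cox(sub, sub_exp, model_tag)
        res.model_tag = f"{model_tag}-landmark1y"
        return {"plan": plan, "result": res}

    if plan == "fine-gray":
        return {"plan": plan, "result": fine_gray(cohort, exposure, model_tag)}

    if plan == "adjust-activity":
        extra = ["lpa_min_day", "sedentary_min_day", "sleep_min_day", "mvpa_week"]
        extra = [c for c in extra if c in cohort.columns]
        res = fit_cox(cohort, exposure, model_tag, extra_columns=extra)
        res.model_tag = f"{model_tag}-adjact"
        return {"plan": plan, "result": res}

    if plan == "adjust-prs":
        res = fit_cox(cohort, exposure, model_tag, extra_columns=["prs"])
        res.model_tag = f"{model_tag}-adjprs"
        return {"plan": plan, "result": res}

    raise ValueError(f"unknown plan {plan!r}")
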