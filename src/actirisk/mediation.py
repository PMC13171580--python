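"""Causal mediation of the rhythm-outcome association by inflammation.

Mediator model: linear regression of the inflammatory marker on the
standardized exposure plus the full adjustment set.  Outcome model: Cox
proportional hazards of the event on exposure, mediator and adjusters;
with a rare outcome (~0.3% cumulative incidence) the log-hazard scale
approximates the log-odds/log-risk scale, so the product-of-coefficients
decomposition applies:

    ACME = a * b,  ADE = c',  total = a*b + c',
    proportion mediated = ACME / (ACME + ADE).

Uncertainty: quasi-Bayesian Monte Carlo — the mediator- and outcome-model
coefficients are drawn from their asymptotic normal distributions
(n_sim draws, default 1,000) and the decomposition recomputed per draw;
optional nonparametric bootstrap refits both models on resampled rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .survival import _smoking_dummies, adjustment_columns


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    acme: float
    ade: float
    total: float
    proportion_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    proportion_ci: tuple[float, float]
    n_simulations: int
    n_bootstrap: int
    flags: list[str] = field(default_factory=list)


def _fit_paths(
    df: pd.DataFrame, exposure_col: str, mediator_col: str, adjusters: list[str]
):
    """Return ((a, var_a), (b, c', cov_bc)) from the two path models."""
    X = sm.add_constant(df[[exposure_col] + adjusters])
    med_fit = sm.OLS(df[mediator_col], X).fit()
    a = float(med_fit.params[exposure_col])
    var_a = float(med_fit.cov_params().loc[exposure_col, exposure_col])

    design = df[["follow_up", "event", exposure_col, mediator_col] + adjusters]
    cph = CoxPHFitter()
    cph.fit(design, duration_col="follow_up", event_col="event")
    b = float(cph.params_[mediator_col])
    c_direct = float(cph.params_[exposure_col])
    cov_bc = cph.variance_matrix_.loc[
        [mediator_col, exposure_col], [mediator_col, exposure_col]
    ].to_numpy()
    return (a, var_a), (b, c_direct, cov_bc)


def mediate(
    cohort: pd.DataFrame,
    exposure: str,
    mediator: str,
    model_tag: str = "M2",
    n_sim: int = 1000,
    n_boot: int = 0,
    seed: int = 0,
    standardize_exposure: bool = True,
    negate_exposure: bool = True,
) -> MediationResult:
    """Estimate ACME, ADE and proportion mediated for one mediator.

    The exposure enters standardized and (by default) negated so that
    higher values mean a *weaker* rhythm, aligning the direct and indirect
    paths with the weak-rhythm -> inflammation -> event direction.  CIs are
    percentile intervals over the quasi-Bayesian draws; when ``n_boot`` > 0
    the proportion-mediated CI comes from bootstrap refits instead.
    """
    rng = np.random.default_rng(seed)
    df = _smoking_dummies(cohort).reset_index(drop=True)
    adjusters = [c for c in adjustment_columns(model_tag) if c != mediator]
    x = df[exposure].to_numpy(dtype=float)
    if standardize_exposure:
        x = (x - x.mean()) / x.std()
    if negate_exposure:
        x = -x
    work = df[["follow_up", "event", mediator] + adjusters].copy()
    work["_exposure"] = x

    (a, var_a), (b, c_direct, cov_bc) = _fit_paths(work, "_exposure", mediator, adjusters)
    acme = a * b
    ade = c_direct
    total = acme + ade
    pm = acme / total if total != 0 else float("nan")
    flags: list[str] = []
    if not (-1.0 <= pm <= 2.0):
        flags.append("proportion mediated outside [-1, 2]; ratio unstable")

    # quasi-Bayesian draws
    a_draws = rng.normal(a, np.sqrt(var_a), n_sim)
    bc_draws = rng.multivariate_normal([b, c_direct], cov_bc, n_sim)
    acme_d = a_draws * bc_draws[:, 0]
    ade_d = bc_draws[:, 1]
    tot_d = acme_d + ade_d
    with np.errstate(divide="ignore", invalid="ignore"):
        pm_d = np.where(tot_d != 0, acme_d / tot_d, np.nan)
    acme_ci = tuple(np.percentile(acme_d, [2.5, 97.5]))
    ade_ci = tuple(np.percentile(ade_d, [2.5, 97.5]))
    pm_ci = tuple(np.nanpercentile(pm_d, [2.5, 97.5]))

    if n_boot > 0:
        pms = []
        n = len(work)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            bs = work.iloc[idx].reset_index(drop=True)
            try:
                (ab, _), (bb, cb, _) = _fit_paths(bs, "_exposure", mediator, adjusters)
            except Exception:
                continue
            tot = ab * bb + cb
            if tot != 0:
                pms.append(ab * bb / tot)
        if len(pms) >= max(20, n_boot // 2):
            pm_ci = tuple(np.percentile(pms, [2.5, 97.5]))
        else:
            flags.append("bootstrap unstable; quasi-Bayesian CI retained")

    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        proportion_mediated=float(pm),
        acme_ci=(float(acme_ci[0]), float(acme_ci[1])),
        ade_ci=(float(ade_ci[0]), float(ade_ci[1])),
        proportion_ci=(float(pm_ci[0]), float(pm_ci[1])),
        n_simulations=n_sim,
        n_bootstrap=n_boot,
        flags=flags,
    )


def mediate_panel(
    cohort: pd.DataFrame,
    exposure: str,
    mediators: list[str],
    **kwargs,
) -> pd.DataFrame:
    """Run mediate() for several inflammatory markers; one row each."""
    rows = []
    for m in mediators:
        r = mediate(cohort, exposure, m, **kwargs)
        rows.append(
            {
                "exposure": exposure,
                "mediator": m,
                "ACME": r.acme,
                "ADE": r.ade,
                "total": r.total,
                "proportion_mediated": r.proportion_mediated,
                "pm_ci_low": r.proportion_ci[0],
                "pm_ci_high": r.proportion_ci[1],
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
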