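"""Multiplicative/additive interaction and joint-effect analysis.

Additive interaction is summarized by the relative excess risk due to
interaction, RERI = HR11 - HR10 - HR01 + 1, with a delta-method CI on the
log-HR covariance (bootstrap optional).  Joint-effect grids cross-classify
a rhythm exposure with a co-factor and report HRs against the lowest-risk
cell.  Multiplicative interaction is the Wald test of the cross-product
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .cohort import TertileExposure
from .survival import _smoking_dummies, adjustment_columns


def _droplist(drop) -> set:
    if drop is None:
        return set()
    if isinstance(drop, str):
        return {drop}
    return set(drop)


@dataclass
class InteractionResult:
    exposure_pair: tuple[str, str]
    reri: float
    reri_ci: tuple[float, float]
    p_multiplicative: float
    grid: pd.DataFrame  # columns: a, b, HR, CI_low, CI_high, n, events
    reference_cell: tuple[str, str]
    flags: list[str] = field(default_factory=list)


def reri_from_hrs(hr10: float, hr01: float, hr11: float) -> float:
    """RERI = HR11 - HR10 - HR01 + 1 (0 under exact additivity)."""
    return hr11 - hr10 - hr01 + 1.0


def reri_delta_ci(
    log_hrs: np.ndarray, cov: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Delta-method RERI and CI from (b10, b01, b11) log-HRs and covariance."""
    b10, b01, b11 = log_hrs
    reri = np.exp(b11) - np.exp(b10) - np.exp(b01) + 1.0
    grad = np.array([-np.exp(b10), -np.exp(b01), np.exp(b11)])
    var = float(grad @ cov @ grad)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(reri), (float(reri - half), float(reri + half))


def _binary_high(exposure: TertileExposure) -> pd.Series:
    """Collapse a tertiled exposure to high-risk (non-reference extreme) vs low.

    T1-referenced parameters: high = T3; T3-referenced: high = T1;
    T2-referenced: high = T1 or T3 pooled.
    """
    lab = exposure.labels.reset_index(drop=True)
    if exposure.reference == "T1":
        return (lab == "T3").astype(int)
    if exposure.reference == "T3":
        return (lab == "T1").astype(int)
    return (lab != "T2").astype(int)


def interaction_2x2(
    cohort: pd.DataFrame,
    exposure: TertileExposure,
    cofactor: pd.Series,
    model_tag: str = "M2",
    drop_adjuster: str | list[str] | None = None,
) -> InteractionResult:
    """RERI and multiplicative interaction on a 2x2 exposure grid.

    The rhythm exposure is collapsed to its high-risk extreme vs reference;
    the co-factor must already be binary (0/1).  Both enter one adjusted
    Cox model as indicator pairs plus their product.
    """
    return reri_binary(
        cohort,
        _binary_high(exposure),
        cofactor,
        model_tag=model_tag,
        drop_adjuster=drop_adjuster,
        pair_name=(exposure.parameter_name, getattr(cofactor, "name", "cofactor")),
    )


def reri_binary(
    cohort: pd.DataFrame,
    exposure_binary: pd.Series,
    cofactor: pd.Series,
    model_tag: str = "M2",
    drop_adjuster: str | list[str] | None = None,
    pair_name: tuple[str, str] | None = None,
) -> InteractionResult:
    """RERI / multiplicative interaction for two already-binary exposures."""
    df = _smoking_dummies(cohort).reset_index(drop=True)
    a = np.asarray(exposure_binary, dtype=int)
    b = np.asarray(cofactor, dtype=int)
    cols = [c for c in adjustment_columns(model_tag) if c not in _droplist(drop_adjuster)]
    design = df[["follow_up", "event"] + cols].copy()
    design["A"] = a
    design["B"] = b
    design["AB"] = a * b
    cph = CoxPHFitter()
    cph.fit(design, duration_col="follow_up", event_col="event")
    p_mult = float(cph.summary.loc["AB", "p"])

    # joint-cell log-HRs vs (0,0): b10 = A, b01 = B, b11 = A + B + AB
    names = ["A", "B", "AB"]
    beta = cph.params_[names].to_numpy()
    cov = cph.variance_matrix_.loc[names, names].to_numpy()
    tr = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 1]], dtype=float)
    log_hrs = tr @ beta
    cov_hrs = tr @ cov @ tr.T
    reri, ci = reri_delta_ci(log_hrs, cov_hrs)

    z = stats.norm.ppf(0.975)
    rows = [{"a": 0, "b": 0, "HR": 1.0, "CI_low": np.nan, "CI_high": np.nan}]
    for (ai, bi), lh, v in zip(
        [(1, 0), (0, 1), (1, 1)], log_hrs, np.diag(cov_hrs)
    ):
        se = np.sqrt(max(v, 0.0))
        rows.append(
            {
                "a": ai,
                "b": bi,
                "HR": float(np.exp(lh)),
                "CI_low": float(np.exp(lh - z * se)),
                "CI_high": float(np.exp(lh + z * se)),
            }
        )
    grid = pd.DataFrame(rows)
    counts = []
    for r in grid.itertuples():
        sel = (a == r.a) & (b == r.b)
        counts.append((int(sel.sum()), int(df.loc[sel, "event"].sum())))
    grid["n"] = [c[0] for c in counts]
    grid["events"] = [c[1] for c in counts]
    flags = []
    if (grid["n"] == 0).any():
        flags.append("empty cell; RERI suppressed")
        reri, ci = np.nan, (np.nan, np.nan)
    if pair_name is None:
        pair_name = (
            getattr(exposure_binary, "name", "exposure") or "exposure",
            getattr(cofactor, "name", "cofactor") or "cofactor",
        )
    return InteractionResult(
        exposure_pair=pair_name,
        reri=reri,
        reri_ci=ci,
        p_multiplicative=p_mult,
        grid=grid,
        reference_cell=("0", "0"),
        flags=flags,
    )


def joint_effects(
    cohort: pd.DataFrame,
    exposure: TertileExposure,
    cofactor: pd.Series,
    model_tag: str = "M2",
    drop_adjuster: str | list[str] | None = None,
) -> pd.DataFrame:
    """Full tertile x co-factor category grid vs the lowest-risk cell.

    All cells are fitted in one adjusted Cox model (indicator coding);
    estimates are then re-referenced by subtracting the smallest fitted
    cell coefficient, so the lowest-risk cell has HR exactly 1.
    """
    df = _smoking_dummies(cohort).reset_index(drop=True)
    lab = exposure.labels.reset_index(drop=True).astype(str)
    cof = pd.Series(cofactor).reset_index(drop=True).astype(str)
    cells = lab + ":" + cof
    levels = sorted(cells.unique())
    cols = [c for c in adjustment_columns(model_tag) if c not in _droplist(drop_adjuster)]
    design = df[["follow_up", "event"] + cols].copy()
    names = []
    for lv in levels[1:]:
        nm = f"cell_{lv}"
        design[nm] = (cells == lv).astype(int).to_numpy()
        names.append(nm)
    cph = CoxPHFitter()
    cph.fit(design, duration_col="follow_up", event_col="event")
    beta = np.concatenate([[0.0], cph.params_[names].to_numpy()])
    cov = np.zeros((len(levels), len(levels)))
    cov[1:, 1:] = cph.variance_matrix_.loc[names, names].to_numpy()
    # re-reference to the lowest-risk (smallest coefficient) cell
    ref_idx = int(np.argmin(beta))
    contrast = np.eye(len(levels))
    contrast[:, ref_idx] -= 1.0
    log_hr = contrast @ beta
    var = np.einsum("ij,jk,ik->i", contrast, cov, contrast)
    z = stats.norm.ppf(0.975)
    out = []
    for i, lv in enumerate(levels):
        tert, cf = lv.split(":", 1)
        sel = (cells == lv).to_numpy()
        se = np.sqrt(max(var[i], 0.0))
        is_ref = i == ref_idx
        out.append(
            {
                "tertile": tert,
                "cofactor": cf,
                "HR": float(np.exp(log_hr[i])),
                "CI_low": np.nan if is_ref else float(np.exp(log_hr[i] - z * se)),
                "CI_high": np.nan if is_ref else float(np.exp(log_hr[i] + z * se)),
                "n": int(sel.sum()),
                "events": int(df.loc[sel, "event"].sum()),
                "reference": is_ref,
            }
        )
    return pd.DataFrame(out)
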