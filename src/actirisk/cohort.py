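"""Cohort assembly: tertile exposures, inflammation indices, activity groups.

Every rhythm parameter is categorized into tertiles; the reference tertile
is the one associated with the lowest outcome risk — a fixed map: T1 for
IV, L5 and L5 start time; T2 for up-mesor, down-mesor, acrophase and M10
start time; T3 for the remaining seven parameters.  Inflammation indices:
SIRI = neutrophils x monocytes / lymphocytes, SII = neutrophils x
platelets / lymphocytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REFERENCE_MAP: dict[str, str] = {
    "IV": "T1",
    "L5": "T1",
    "L5_start": "T1",
    "up_mesor": "T2",
    "down_mesor": "T2",
    "acrophase": "T2",
    "M10_start": "T2",
    "IS": "T3",
    "RA": "T3",
    "M10": "T3",
    "pseudo_F": "T3",
    "amplitude": "T3",
    "mesor": "T3",
}

MVPA_ACTIVE_MIN_PER_WEEK = 150.0
WEEKEND_WARRIOR_SHARE = 0.5


class DegenerateExposureError(ValueError):
    """Fewer than 3 distinct values — tertiles are undefined."""


@dataclass
class TertileExposure:
    parameter_name: str
    cut_points: tuple[float, float]
    labels: pd.Series  # 'T1' / 'T2' / 'T3' per participant
    reference: str

    def scores(self) -> pd.Series:
        """Integer-scored tertile (1, 2, 3) for trend tests."""
        return self.labels.str.slice(1).astype(int)


def make_tertiles(values, parameter_name: str) -> TertileExposure:
    """Tertile an exposure with left-closed intervals; ties go low.

    Cut points are linear-interpolation empirical quantiles at 1/3 and 2/3.
    Reference tertile comes from the fixed risk map; variables outside the
    map default to T1.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    if v.nunique() < 3:
        raise DegenerateExposureError(
            f"{parameter_name}: need >= 3 distinct values, got {v.nunique()}"
        )
    q1, q2 = np.quantile(v.to_numpy(), [1 / 3, 2 / 3])
    labels = pd.Series(
        np.where(v <= q1, "T1", np.where(v <= q2, "T2", "T3")), index=v.index
    )
    return TertileExposure(
        parameter_name=parameter_name,
        cut_points=(float(q1), float(q2)),
        labels=labels,
        reference=REFERENCE_MAP.get(parameter_name, "T1"),
    )


def derive_inflammation(
    neutrophils, monocytes, lymphocytes, platelets
) -> pd.DataFrame:
    """SIRI and SII from the four blood counts (10^9/L); counts must be > 0."""
    arrs = {
        "neutrophils": np.asarray(neutrophils, dtype=float),
        "monocytes": np.asarray(monocytes, dtype=float),
        "lymphocytes": np.asarray(lymphocytes, dtype=float),
        "platelets": np.asarray(platelets, dtype=float),
    }
    for name, a in arrs.items():
        if np.any(a <= 0):
            raise ValueError(f"{name} must be strictly positive")
    siri = arrs["neutrophils"] * arrs["monocytes"] / arrs["lymphocytes"]
    sii = arrs["neutrophils"] * arrs["platelets"] / arrs["lymphocytes"]
    return pd.DataFrame({"SIRI": siri, "SII": sii})


def categorize_activity(daily_mvpa_minutes) -> tuple[str, str]:
    """WHO binary group and 3-class temporal pattern from 7 daily MVPA values.

    Active iff weekly MVPA >= 150 min.  Among the active, weekend warrior
    when the top-2 days contribute at least half the weekly total,
    regularly active otherwise.
    """
    d = np.asarray(daily_mvpa_minutes, dtype=float)
    if len(d) != 7 or np.any(d < 0):
        raise ValueError("need 7 nonnegative daily MVPA values")
    weekly = d.sum()
    if weekly < MVPA_ACTIVE_MIN_PER_WEEK:
        return "inactive", "inactive"
    top2 = np.sort(d)[-2:].sum()
    pattern = (
        "weekend_warrior" if top2 >= WEEKEND_WARRIOR_SHARE * weekly else "regularly_active"
    )
    return "active", pattern


def prs_groups(prs_values) -> TertileExposure:
    """Genetic risk groups: low / intermediate / high PRS tertiles."""
    t = make_tertiles(prs_values, "prs")
    mapping = {"T1": "low", "T2": "intermediate", "T3": "high"}
    return TertileExposure(
        parameter_name="prs",
        cut_points=t.cut_points,
        labels=t.labels.map(mapping),
        reference="low",
    )


def assemble_cohort(
    rar: pd.DataFrame, covariates: pd.DataFrame, rar_params: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Join RAR metrics with covariates into the analysis-ready table.

    Adds a ``<param>_tertile`` column for every rhythm parameter, SIRI/SII,
    the PRS group and the activity categories.  Returns the table (stably
    sorted by participant_id) and a sidecar dict of cut points and the
    reference map.
    """
    if rar_params is None:
        from .metrics import RAR_PARAMS

        rar_params = [p for p in RAR_PARAMS if p in rar.columns]
    df = covariates.merge(rar, on="participant_id", how="inner")
    df = df.sort_values("participant_id").reset_index(drop=True)
    sidecar: dict = {"cut_points": {}, "reference_map": {}}
    for p in rar_params:
        t = make_tertiles(df[p], p)
        df[f"{p}_tertile"] = t.labels.to_numpy()
        sidecar["cut_points"][p] = list(t.cut_points)
        sidecar["reference_map"][p] = t.reference
    infl = derive_inflammation(
        df["neutrophils"], df["monocytes"], df["lymphocytes"], df["platelets"]
    )
    df["SIRI"] = infl["SIRI"].to_numpy()
    df["SII"] = infl["SII"].to_numpy()
    g = prs_groups(df["prs"])
    df["prs_group"] = g.labels.to_numpy()
    sidecar["cut_points"]["prs"] = list(g.cut_points)
    mvpa_cols = [f"mvpa_day{d}" for d in range(1, 8)]
    if all(c in df.columns for c in mvpa_cols):
        cats = [categorize_activity(row) for row in df[mvpa_cols].to_numpy()]
        df["mvpa_group"] = [c[0] for c in cats]
        df["activity_pattern"] = [c[1] for c in cats]
        df["mvpa_week"] = df[mvpa_cols].sum(axis=1)
    return df, sidecar
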