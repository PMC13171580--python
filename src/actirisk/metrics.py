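"""Per-participant rest-activity rhythm parameter table.

Thirteen parameters: six from the anti-logistic cosinor fit (pseudo_F,
amplitude, mesor, up_mesor, down_mesor, acrophase) and seven nonparametric
(IS, IV, L5, M10, RA, L5_start, M10_start).  Up-/down-mesor are the clock
times at which the fitted curve crosses the mesor (ascending/descending).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cosinor import fit_extended_cosinor
from .nonparametric import nonparam_metrics
from .preprocess import EpochSeries, valid_day_mask

COSINOR_PARAMS = ["pseudo_F", "amplitude", "mesor", "up_mesor", "down_mesor", "acrophase"]
NONPARAM_PARAMS = ["IS", "IV", "L5", "M10", "RA", "L5_start", "M10_start"]
RAR_PARAMS = COSINOR_PARAMS + NONPARAM_PARAMS

MIN_VALID_MINUTES = 3 * 1440


def participant_metrics(
    series: EpochSeries,
    exclude_imputed: bool = False,
    seed: int = 0,
) -> dict:
    """Compute all 13 RAR parameters plus fit diagnostics for one series.

    The cosinor fit uses non-imputed minutes of valid days with their clock
    times; nonparametric metrics use the averaged profile and hourly bins.
    """
    vmask = valid_day_mask(series)
    fit_mask = vmask & ~series.imputed
    if fit_mask.sum() < MIN_VALID_MINUTES * 0.5:
        fit_mask = vmask  # fall back to imputed-included when sparse
    t_hours = series.minute_of_day()[fit_mask] / 60.0
    fit = fit_extended_cosinor(t_hours, series.values[fit_mask], seed=seed)
    np_m = nonparam_metrics(series, exclude_imputed=exclude_imputed)
    return {
        "participant_id": series.participant_id,
        "pseudo_F": fit.pseudo_F,
        "amplitude": fit.amplitude,
        "mesor": fit.mesor,
        "up_mesor": fit.up_mesor,
        "down_mesor": fit.down_mesor,
        "acrophase": fit.acrophase,
        "minimum": fit.minimum,
        "alpha": fit.alpha,
        "beta": fit.beta,
        "cosinor_rss": fit.rss,
        "cosinor_converged": fit.converged,
        "cosinor_degenerate": fit.degenerate,
        "IS": np_m.IS,
        "IV": np_m.IV,
        "L5": np_m.L5,
        "M10": np_m.M10,
        "RA": np_m.RA,
        "L5_start": np_m.L5_start,
        "M10_start": np_m.M10_start,
        "n_fit_minutes": int(fit_mask.sum()),
    }


def metrics_table(
    series_iter, exclude_imputed: bool = False, seed: int = 0
) -> pd.DataFrame:
    """One row of RAR metrics per participant, sorted by participant_id."""
    rows = [
        participant_metrics(s, exclude_imputed=exclude_imputed, seed=seed)
        for s in series_iter
    ]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("participant_id").reset_index(drop=True)
    return df
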