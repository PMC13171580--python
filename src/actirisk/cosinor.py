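"""Extended (anti-logistic) cosinor model for rest-activity rhythms.

The model passes a cosine of clock time through a sigmoidal transform,

    y(t) = minimum + amplitude * F(cos(2*pi*(t - phi)/24)),
    F(c) = exp(beta*(c - alpha)) / (1 + exp(beta*(c - alpha))),

which fits the flattened, nearly square waveform of human activity better
than a pure cosine.  ``phi`` (acrophase) is the clock time of the peak in
hours, ``alpha`` controls the width of the active period and ``beta`` the
steepness of the rest/activity transitions.  Derived quantities: the mesor
(minimum + amplitude/2), the up-/down-mesor crossing times, and a pseudo-F
goodness-of-rhythm statistic against the constant-mean model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

PERIOD_H = 24.0
N_PARAMS = 5  # minimum, amplitude, acrophase, alpha, beta


@dataclass
class CosinorFit:
    minimum: float
    amplitude: float
    acrophase: float
    alpha: float
    beta: float
    pseudo_F: float
    rss: float
    n_minutes: int
    converged: bool
    degenerate: bool = False

    @property
    def mesor(self) -> float:
        return self.minimum + self.amplitude / 2.0

    @property
    def up_mesor(self) -> float:
        """Clock time (h) of the ascending mesor crossing; NaN if degenerate."""
        return self._crossings()[0]

    @property
    def down_mesor(self) -> float:
        """Clock time (h) of the descending mesor crossing; NaN if degenerate."""
        return self._crossings()[1]

    def _crossings(self) -> tuple[float, float]:
        if self.degenerate or self.amplitude <= 0:
            return (float("nan"), float("nan"))
        return mesor_crossings(self.acrophase, self.alpha, self.beta)

    def predict(self, t_hours: np.ndarray) -> np.ndarray:
        return anti_logistic_curve(
            np.asarray(t_hours, dtype=float),
            self.minimum,
            self.amplitude,
            self.acrophase,
            self.alpha,
            self.beta,
        )


def anti_logistic_curve(
    t_hours: np.ndarray,
    minimum: float,
    amplitude: float,
    acrophase: float,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Evaluate the anti-logistic activity curve at clock times (hours)."""
    c = np.cos(2.0 * np.pi * (t_hours - acrophase) / PERIOD_H)
    return minimum + amplitude * expit(beta * (c - alpha))


def mesor_crossings(acrophase: float, alpha: float, beta: float) -> tuple[float, float]:
    """Clock times where the fitted 24-h curve crosses the mesor.

    Located on a 1-min grid then refined by bisection.  The curve equals
    the mesor where F(cos(...)) = 1/2; with alpha in (-1, 1) there is one
    ascending and one descending crossing per cycle.
    """
    grid = np.arange(0.0, PERIOD_H, 1.0 / 60.0)
    c = np.cos(2.0 * np.pi * (grid - acrophase) / PERIOD_H)
    g = c - alpha  # sign of (curve - mesor)
    up = float("nan")
    down = float("nan")

    def refine(lo: float, hi: float) -> float:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            val = np.cos(2.0 * np.pi * (mid - acrophase) / PERIOD_H) - alpha
            lo_val = np.cos(2.0 * np.pi * (lo - acrophase) / PERIOD_H) - alpha
            if lo_val * val <= 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    for i in range(len(grid)):
        j = (i + 1) % len(grid)
        a, b = g[i], g[j]
        if a == 0.0:
            t = grid[i]
            if g[i - 1] < 0:
                up = t
            else:
                down = t
            continue
        if a * b < 0:
            lo, hi = grid[i], grid[i] + 1.0 / 60.0
            t = refine(lo, hi) % PERIOD_H
            if a < 0:  # rising through the mesor
                up = t
            else:
                down = t
    return up, down


def _fit_once(
    t: np.ndarray, y: np.ndarray, x0: np.ndarray, bounds
) -> tuple[np.ndarray, float, bool]:
    def resid(p):
        return anti_logistic_curve(t, *p) - y

    try:
        res = least_squares(resid, x0, bounds=bounds, method="trf", max_nfev=2000)
    except ValueError:
        return x0, np.inf, False
    rss = float(np.sum(res.fun**2))
    return res.x, rss, bool(res.success)


def fit_extended_cosinor(
    t_hours: np.ndarray,
    values: np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
) -> CosinorFit:
    """Fit the anti-logistic cosinor by bounded nonlinear least squares.

    Parameters
    ----------
    t_hours : array
        Clock time of each observation in hours (need not be sorted;
        multiple days simply repeat clock times).
    values : array
        Activity in milli-g.
    n_restarts : int
        Jittered restarts attempted when the first fit fails to converge
        or lands on a boundary; the anti-logistic model is multimodal in
        (alpha, beta).

    Notes
    -----
    Initialization: minimum = 5th percentile, amplitude = 95th - 5th
    percentile, acrophase = hour of the smoothed profile maximum,
    alpha = 0, beta = 2.  A constant series yields a degenerate fit with
    amplitude 0 and pseudo-F 0 rather than an exception.
    """
    t = np.asarray(t_hours, dtype=float) % PERIOD_H
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n != len(t):
        raise ValueError("t_hours and values must have equal length")
    ybar = float(np.mean(y))
    rss0 = float(np.sum((y - ybar) ** 2))
    if rss0 == 0.0 or n <= N_PARAMS:
        return CosinorFit(
            minimum=ybar, amplitude=0.0, acrophase=0.0, alpha=0.0, beta=2.0,
            pseudo_F=0.0, rss=rss0, n_minutes=n, converged=True, degenerate=True,
        )

    # hour-of-day profile for acrophase initialization
    hours = np.floor(t).astype(int) % 24
    prof = np.bincount(hours, weights=y, minlength=24)
    cnt = np.bincount(hours, minlength=24).astype(float)
    cnt[cnt == 0] = np.nan
    prof = prof / cnt
    # 3-h circular smoothing
    prof_s = np.nanmean(
        np.column_stack([np.roll(prof, k) for k in (-1, 0, 1)]), axis=1
    )
    phi0 = float(np.nanargmax(prof_s)) + 0.5

    lo, hi = np.percentile(y, [5, 95])
    x0 = np.array([lo, max(hi - lo, 1e-3), phi0, 0.0, 2.0])
    bounds = (
        np.array([0.0, 0.0, 0.0, -0.999, 1e-3]),
        np.array([np.inf, np.inf, PERIOD_H, 0.999, 1000.0]),
    )

    best_p, best_rss, best_ok = _fit_once(t, y, x0, bounds)
    rng = np.random.default_rng(seed)
    tries = 0
    while (not best_ok or best_rss >= rss0) and tries < n_restarts:
        jitter = x0 * (1 + 0.2 * rng.standard_normal(5))
        jitter[2] = rng.uniform(0, PERIOD_H)
        jitter[3] = rng.uniform(-0.8, 0.8)
        jitter[4] = rng.uniform(0.5, 20.0)
        jitter = np.clip(jitter, bounds[0] + 1e-6, None)
        jitter = np.minimum(jitter, np.where(np.isfinite(bounds[1]), bounds[1] - 1e-6, jitter))
        p, rss, ok = _fit_once(t, y, jitter, bounds)
        if rss < best_rss:
            best_p, best_rss, best_ok = p, rss, ok
        tries += 1

    minimum, amplitude, phi, alpha, beta = best_p
    p = N_PARAMS
    denom = best_rss / (n - p)
    pseudo_f = ((rss0 - best_rss) / (p - 1)) / denom if denom > 0 else 0.0
    return CosinorFit(
        minimum=float(minimum),
        amplitude=float(amplitude),
        acrophase=float(phi % PERIOD_H),
        alpha=float(alpha),
        beta=float(beta),
        pseudo_F=float(max(pseudo_f, 0.0)),
        rss=float(best_rss),
        n_minutes=n,
        converged=best_ok,
        degenerate=(amplitude == 0.0),
    )
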