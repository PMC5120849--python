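"""Fit biomass-accumulation curves to space-for-time survey data.

Two fixed-effects forms are supported, matching the site curves:
the Gompertz curve y = a exp(-b c^age), fitted by nonlinear least
squares (scipy), and the power law ln y = a + b ln(age + 1), fitted by
ordinary least squares on the log scale (statsmodels).  Model choice
between the two uses small-sample-corrected AIC computed on a common
response scale: the log-form Gaussian likelihood is mapped back to the
original biomass scale with the Jacobian of the log transform, so the
criteria are directly comparable.

Observations are passed as a pandas DataFrame with columns
``site, fraction, age, biomass`` (extra columns are ignored); only
``age`` and ``biomass`` enter the fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm

from .curves import GOMPERTZ, LOGLINEAR, GrowthCurve

__all__ = [
    "FitResult",
    "FormComparison",
    "fit_gompertz",
    "fit_loglinear",
    "compare_forms",
    "read_observations",
    "write_fit_result",
]

OBS_COLUMNS = ["site", "fraction", "age", "biomass"]

#: Gompertz rate restarts tried when the default start fails to converge.
_C_GRID = (0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)


class FitError(RuntimeError):
    """Raised when a curve fit is infeasible or fails to converge."""


@dataclass(frozen=True)
class FitResult:
    """A fitted growth curve with its fit diagnostics.

    ``aicc`` is the small-sample-corrected AIC on the original biomass
    scale (comparable across forms); ``t_values`` are estimate/SE as in
    standard regression output.
    """

    curve: GrowthCurve
    residual_sd: float
    n_obs: int
    aicc: float
    converged: bool

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    @property
    def t_values(self) -> dict[str, float]:
        c = self.curve
        out = {"a": c.a / c.se_a if c.se_a else np.inf,
               "b": c.b / c.se_b if c.se_b else np.inf}
        if c.form == GOMPERTZ:
            out["c"] = c.c / c.se_c if c.se_c else np.inf
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy export with estimate, SE and t value per parameter."""
        c = self.curve
        names = ["a", "b"] + (["c"] if c.form == GOMPERTZ else [])
        est = [c.a, c.b] + ([c.c] if c.form == GOMPERTZ else [])
        se = [c.se_a, c.se_b] + ([c.se_c] if c.form == GOMPERTZ else [])
        t = [self.t_values[n] for n in names]
        return pd.DataFrame({"parameter": names, "estimate": est,
                             "se": se, "t_value": t})


def _extract(observations: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    obs = pd.DataFrame(observations)
    missing = {"age", "biomass"} - set(obs.columns)
    if missing:
        raise ValueError(f"observations lack columns {sorted(missing)}")
    x = obs["age"].to_numpy(dtype=float)
    y = obs["biomass"].to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("stand ages must be non-negative")
    if np.any(y < 0):
        raise ValueError("biomass must be non-negative")
    return x, y


def _gaussian_aicc(rss: float, n: int, k_mean: int) -> float:
    """AICc of a Gaussian model with ``k_mean`` mean parameters + sigma."""
    k = k_mean + 1
    rss = max(rss, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return aic


def _gompertz_model(x, a, b, c):
    return a * np.exp(-b * np.power(c, x))


def _gompertz_start(x: np.ndarray, y: np.ndarray, c0: float) -> tuple[float, float, float]:
    # a from the largest observation; b solved from the earliest one
    a0 = max(float(y.max()), 1e-6)
    i = int(np.argmin(x))
    y0 = y[i]
    if 0 < y0 < a0:
        b0 = -np.log(y0 / a0) / c0 ** x[i]
    else:
        b0 = 3.0
    return a0, float(np.clip(b0, 1e-3, 50.0)), c0


def fit_gompertz(observations: pd.DataFrame) -> FitResult:
    """Nonlinear least-squares fit of y = a exp(-b c^age).

    Requires at least 4 observations at 3 or more distinct ages.
    Starting values put ``a`` at the maximum observed biomass and solve
    ``b`` from the earliest observation at a rate start of c = 0.85; on
    non-convergence the fit restarts over a small grid of rate values.
    """
    x, y = _extract(observations)
    if x.size < 4 or np.unique(x).size < 3:
        raise FitError("Gompertz fit needs >= 4 observations at >= 3 distinct ages")
    bounds = ([1e-9, 0.0, 1e-6], [np.inf, np.inf, 1.0 - 1e-6])
    last_err: Exception | None = None
    for c0 in (0.85,) + _C_GRID:
        try:
            popt, pcov = scipy.optimize.curve_fit(
                _gompertz_model, x, y, p0=_gompertz_start(x, y, c0),
                bounds=bounds, maxfev=20_000)
        except (RuntimeError, ValueError) as err:  # pragma: no cover - restart path
            last_err = err
            continue
        if np.all(np.isfinite(pcov)):
            break
        last_err = RuntimeError("singular parameter covariance")
    else:
        raise FitError(f"Gompertz fit did not converge: {last_err}")
    a, b, c = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    resid = y - _gompertz_model(x, *popt)
    rss = float(resid @ resid)
    dof = max(x.size - 3, 1)
    curve = GrowthCurve(GOMPERTZ, a, b, c,
                        se_a=float(se[0]), se_b=float(se[1]), se_c=float(se[2]))
    return FitResult(curve=curve, residual_sd=float(np.sqrt(rss / dof)),
                     n_obs=int(x.size), aicc=_gaussian_aicc(rss, x.size, 3),
                     converged=True)


def fit_loglinear(observations: pd.DataFrame) -> FitResult:
    """OLS fit of ln y = a + b ln(age + 1).

    Requires strictly positive biomass and at least 3 observations at 2
    or more distinct ages.  The reported AICc is on the original biomass
    scale (log-likelihood adjusted by the Jacobian sum of ln y).
    """
    x, y = _extract(observations)
    if np.any(y <= 0):
        raise FitError("log-linear fit requires strictly positive biomass")
    if x.size < 3 or np.unique(x).size < 2:
        raise FitError("log-linear fit needs >= 3 observations at >= 2 distinct ages")
    ly = np.log(y)
    X = sm.add_constant(np.log(x + 1.0))
    res = sm.OLS(ly, X).fit()
    a, b = (float(v) for v in res.params)
    se_a, se_b = (float(v) for v in res.bse)
    rss_log = float(res.ssr)
    # Gaussian AICc on the log scale, mapped to the biomass scale by the
    # log-transform Jacobian: ll_orig = ll_log - sum(ln y).
    aicc = _gaussian_aicc(rss_log, x.size, 2) + 2.0 * float(ly.sum())
    dof = max(x.size - 2, 1)
    curve = GrowthCurve(LOGLINEAR, a, b, None, se_a=se_a, se_b=se_b)
    return FitResult(curve=curve, residual_sd=float(np.sqrt(rss_log / dof)),
                     n_obs=int(x.size), aicc=aicc, converged=True)


@dataclass(frozen=True)
class FormComparison:
    """Both candidate fits and the form selected by AICc."""

    chosen: str
    gompertz: FitResult
    loglinear: FitResult

    @property
    def chosen_fit(self) -> FitResult:
        return self.gompertz if self.chosen == GOMPERTZ else self.loglinear


def compare_forms(observations: pd.DataFrame) -> FormComparison:
    """Fit both forms and select the lower-AICc one (ties -> Gompertz)."""
    g = fit_gompertz(observations)
    l = fit_loglinear(observations)
    chosen = GOMPERTZ if g.aicc <= l.aicc else LOGLINEAR
    return FormComparison(chosen=chosen, gompertz=g, loglinear=l)


def read_observations(path) -> pd.DataFrame:
    """Read a survey CSV with header ``site,fraction,age,biomass``."""
    obs = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"observation file lacks columns {sorted(missing)}")
    return obs[OBS_COLUMNS + [c for c in obs.columns if c not in OBS_COLUMNS]]


def write_fit_result(result: FitResult, path) -> None:
    """Write estimate / SE / t-value rows to CSV or JSON (by suffix)."""
    path = Path(path)
    frame = result.to_frame()
    if path.suffix == ".json":
        path.write_text(frame.to_json(orient="records", indent=1))
    else:
        frame.to_csv(path, index=False)
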