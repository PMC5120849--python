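"""Biomass-accumulation curves and per-site carbon constants.

Stand biomass on British *Calluna* moorland is described as a function of
stand age (years since the last fire) by one of two forms fitted to
space-for-time survey data:

* a saturating Gompertz curve ``y = a * exp(-b * c**age)`` with asymptote
  ``a`` (t ha⁻¹), shape ``b`` and annual rate ``c`` in (0, 1); or
* a log-linear power law ``ln y = a + b * ln(age + 1)``, which has no
  asymptote over the observed age range.

Each site carries one curve per fuel fraction (live *Calluna* canopy and
the litter layer beneath it) plus the carbon mass fractions and prescribed
fire combustion-completeness values used to turn biomass into carbon loss.

Curves are only supported by field data for stand ages 2-50 years, so
evaluation is capped at the upper end of ``valid_age_range``: older stands
are assigned the age-50 biomass.  This is numerically inert for the
Gompertz form (already at its asymptote) and prevents unbounded
extrapolation of the power-law form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "CarbonParameters",
    "SiteParameterSet",
    "evaluate_curve",
    "curve_asymptote",
    "draw_curve_sample",
    "builtin_sites",
    "registry_to_frame",
    "registry_from_frame",
    "save_registry",
    "load_registry",
]

GOMPERTZ = "gompertz"
LOGLINEAR = "loglinear"

#: Age span (years since fire) covered by the underlying field surveys.
DEFAULT_AGE_RANGE = (2.0, 50.0)


@dataclass(frozen=True)
class GrowthCurve:
    """A fitted biomass-vs-stand-age model for one fuel fraction.

    Parameters
    ----------
    form
        ``"gompertz"`` (``y = a exp(-b c**age)``) or ``"loglinear"``
        (``ln y = a + b ln(age+1)``).
    a, b, c
        Curve parameters.  ``a`` is the asymptote (Gompertz, model units)
        or log-scale intercept (log-linear); ``b`` the shape/slope; ``c``
        the Gompertz annual rate in (0, 1), unused for the log-linear form.
    se_a, se_b, se_c
        Standard errors of the parameters, used for parameter-uncertainty
        draws.  Zero SEs make draws degenerate (equal to the point curve).
    unit_scale
        Multiplier converting model output to t ha⁻¹ (e.g. 0.01 for a
        curve fitted in g m⁻²).
    valid_age_range
        Ages (years) supported by data; evaluation is capped at the upper
        bound.
    """

    form: str
    a: float
    b: float
    c: float | None = None
    se_a: float = 0.0
    se_b: float = 0.0
    se_c: float = 0.0
    unit_scale: float = 1.0
    valid_age_range: tuple[float, float] = DEFAULT_AGE_RANGE

    def __post_init__(self) -> None:
        if self.form not in (GOMPERTZ, LOGLINEAR):
            raise ValueError(f"unknown curve form: {self.form!r}")
        if self.unit_scale <= 0:
            raise ValueError("unit_scale must be positive")
        if self.b < 0:
            raise ValueError("shape parameter b must be non-negative")
        if self.form == GOMPERTZ:
            if self.a <= 0:
                raise ValueError("gompertz asymptote a must be positive")
            if self.c is None or not (0.0 < self.c < 1.0):
                raise ValueError("gompertz rate c must lie in (0, 1)")
        if min(self.se_a, self.se_b, self.se_c) < 0:
            raise ValueError("standard errors must be non-negative")

    # -- evaluation ---------------------------------------------------

    def __call__(self, age):
        return evaluate_curve(self, age)

    def asymptote(self) -> float | None:
        return curve_asymptote(self)

    def sample(self, rng: np.random.Generator) -> "GrowthCurve":
        """Draw a parameter realisation from Normal(estimate, SE).

        Draws are independent per parameter (covariances are not
        reported for the built-in fits) and restricted to the feasible
        domain (a > 0, b >= 0, 0 < c < 1 for Gompertz) by rejection
        sampling, i.e. a truncated normal; predicted biomass is further
        truncated at zero at evaluation time.
        """
        def trunc(mean: float, sd: float, lo: float, hi: float) -> float:
            if sd == 0.0:
                return mean
            for _ in range(1000):
                v = float(rng.normal(mean, sd))
                if lo < v < hi:
                    return v
            return float(np.clip(mean, lo + 1e-9, hi - 1e-9))  # pragma: no cover

        eps = 1e-9
        b = trunc(self.b, self.se_b, -eps, np.inf)
        if self.form == GOMPERTZ:
            a = trunc(self.a, self.se_a, 0.0, np.inf)
            c = trunc(self.c, self.se_c, eps, 1.0 - eps)
        else:
            a = float(rng.normal(self.a, self.se_a))  # log-scale intercept
            c = self.c
        return replace(self, a=a, b=max(b, 0.0), c=c,
                       se_a=0.0, se_b=0.0, se_c=0.0)


def _capped_age(curve: GrowthCurve, age):
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("stand age must be non-negative")
    return np.minimum(age, curve.valid_age_range[1])


def evaluate_curve(curve: GrowthCurve, age):
    """Predicted biomass (t ha⁻¹) at a stand age (years since fire).

    Ages above the curve's valid range are evaluated at the range's upper
    bound.  Accepts scalars or arrays; returns the same shape.  Predicted
    biomass is truncated at zero (relevant only for sampled parameter
    sets with extreme draws).
    """
    scalar = np.isscalar(age)
    x = _capped_age(curve, age)
    if curve.form == GOMPERTZ:
        y = curve.a * np.exp(-curve.b * np.power(curve.c, x))
    else:
        y = np.exp(curve.a + curve.b * np.log(x + 1.0))
    y = np.maximum(curve.unit_scale * y, 0.0)
    return float(y) if scalar else y


def curve_asymptote(curve: GrowthCurve) -> float | None:
    """Large-age biomass limit in t ha⁻¹, or None if unbounded.

    The Gompertz form converges to ``unit_scale * a``; the log-linear
    power law grows without bound, returned as ``None``.
    """
    if curve.form == GOMPERTZ:
        return curve.unit_scale * curve.a
    return None


def draw_curve_sample(curve: GrowthCurve, age, rng: np.random.Generator):
    """Evaluate one parameter-uncertainty draw of the curve at ``age``.

    Each parameter is drawn independently from Normal(estimate, SE); the
    sampled curve is evaluated and the result truncated at zero.  With
    all SEs zero this equals :func:`evaluate_curve` exactly.
    """
    return evaluate_curve(curve.sample(rng), age)


@dataclass(frozen=True)
class CarbonParameters:
    """Carbon mass fractions and combustion completeness (CC).

    Carbon concentrations are per fuel fraction (mass fraction of dry
    biomass); CC is the fraction of above-ground biomass consumed in a
    prescribed fire, measured separately for canopy and litter.
    Wildfires are modelled as consuming the entire standing stock
    (``cc_wildfire = 1``) across all age classes.
    """

    c_frac_calluna: float = 0.483
    c_frac_calluna_sd: float = 0.001
    c_frac_litter: float = 0.490
    c_frac_litter_sd: float = 0.001
    cc_calluna: float = 0.714
    cc_calluna_sd: float = 0.026
    cc_litter: float = 0.545
    cc_litter_sd: float = 0.028
    cc_wildfire: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_frac_calluna", "c_frac_litter", "cc_calluna",
                     "cc_litter", "cc_wildfire"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("c_frac_calluna_sd", "c_frac_litter_sd",
                     "cc_calluna_sd", "cc_litter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def sample(self, rng: np.random.Generator) -> "CarbonParameters":
        """One bootstrap draw of concentrations and CC, clipped to [0, 1]."""
        def draw(mean: float, sd: float) -> float:
            return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))

        return CarbonParameters(
            c_frac_calluna=draw(self.c_frac_calluna, self.c_frac_calluna_sd),
            c_frac_calluna_sd=0.0,
            c_frac_litter=draw(self.c_frac_litter, self.c_frac_litter_sd),
            c_frac_litter_sd=0.0,
            cc_calluna=draw(self.cc_calluna, self.cc_calluna_sd),
            cc_calluna_sd=0.0,
            cc_litter=draw(self.cc_litter, self.cc_litter_sd),
            cc_litter_sd=0.0,
            cc_wildfire=self.cc_wildfire,
        )


@dataclass(frozen=True)
class SiteParameterSet:
    """One site's canopy and litter curves plus carbon constants."""

    site_name: str
    calluna_curve: GrowthCurve
    litter_curve: GrowthCurve
    carbon: CarbonParameters = field(default_factory=CarbonParameters)

    def sample(self, rng: np.random.Generator) -> "SiteParameterSet":
        """Draw curve parameters and carbon constants for one bootstrap rep."""
        return SiteParameterSet(
            site_name=self.site_name,
            calluna_curve=self.calluna_curve.sample(rng),
            litter_curve=self.litter_curve.sample(rng),
            carbon=self.carbon.sample(rng),
        )


def builtin_sites() -> dict[str, SiteParameterSet]:
    """Registry of the four built-in British moorland sites.

    Kerloch (NE Scotland), Moor House (N Pennines) and Dorset use
    Gompertz curves for both fractions; Howden (S Pennines) uses the
    log-linear form, with its litter curve fitted in g m⁻²
    (``unit_scale = 0.01`` converts to t ha⁻¹).
    """
    sites = {
        "Kerloch": SiteParameterSet(
            "Kerloch",
            GrowthCurve(GOMPERTZ, 22.96, 3.22, 0.88, 0.89, 0.46, 0.01),
            GrowthCurve(GOMPERTZ, 20.65, 2.61, 0.89, 0.79, 0.31, 0.01),
        ),
        "Moor House": SiteParameterSet(
            "Moor House",
            GrowthCurve(GOMPERTZ, 7.94, 8.07, 0.78, 0.80, 3.55, 0.04),
            GrowthCurve(GOMPERTZ, 8.90, 1.70, 0.70, 0.70, 10.83, 0.90),
        ),
        "Howden": SiteParameterSet(
            "Howden",
            GrowthCurve(LOGLINEAR, -0.93, 1.15, None, 0.05, 0.02, 0.0),
            GrowthCurve(LOGLINEAR, 3.86, 1.10, None, 0.04, 0.02, 0.0,
                        unit_scale=0.01),
        ),
        "Dorset": SiteParameterSet(
            "Dorset",
            GrowthCurve(GOMPERTZ, 20.15, 3.58, 0.86, 0.62, 0.53, 0.01),
            GrowthCurve(GOMPERTZ, 28.38, 8.67, 0.86, 2.96, 6.11, 0.04),
        ),
    }
    return sites


# -- registry serialisation -------------------------------------------

_COLUMNS = ["site", "fraction", "form", "a", "b", "c",
            "se_a", "se_b", "se_c", "unit_scale"]


def registry_to_frame(registry: Mapping[str, SiteParameterSet]) -> pd.DataFrame:
    """Flatten a site registry into a tidy table (one row per curve)."""
    rows = []
    for site in registry.values():
        for fraction, curve in (("calluna", site.calluna_curve),
                                ("litter", site.litter_curve)):
            rows.append({
                "site": site.site_name, "fraction": fraction,
                "form": curve.form, "a": curve.a, "b": curve.b,
                "c": curve.c if curve.c is not None else math.nan,
                "se_a": curve.se_a, "se_b": curve.se_b, "se_c": curve.se_c,
                "unit_scale": curve.unit_scale,
            })
    return pd.DataFrame(rows, columns=_COLUMNS)


def registry_from_frame(frame: pd.DataFrame) -> dict[str, SiteParameterSet]:
    """Rebuild a site registry from the tidy curve table."""
    registry: dict[str, SiteParameterSet] = {}
    for site_name, group in frame.groupby("site", sort=False):
        curves: dict[str, GrowthCurve] = {}
        for _, row in group.iterrows():
            c = row["c"]
            curves[row["fraction"]] = GrowthCurve(
                form=row["form"], a=float(row["a"]), b=float(row["b"]),
                c=None if pd.isna(c) else float(c),
                se_a=float(row["se_a"]), se_b=float(row["se_b"]),
                se_c=float(row["se_c"]), unit_scale=float(row["unit_scale"]),
            )
        missing = {"calluna", "litter"} - set(curves)
        if missing:
            raise ValueError(f"site {site_name!r} lacks curves for {missing}")
        registry[str(site_name)] = SiteParameterSet(
            str(site_name), curves["calluna"], curves["litter"])
    return registry


def save_registry(registry: Mapping[str, SiteParameterSet], path) -> None:
    """Write a registry to CSV or JSON (by file suffix)."""
    path = Path(path)
    frame = registry_to_frame(registry)
    if path.suffix == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        frame.to_csv(path, index=False)


def load_registry(path) -> dict[str, SiteParameterSet]:
    """Read a registry written by :func:`save_registry`."""
    path = Path(path)
    if path.suffix == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()), columns=_COLUMNS)
    else:
        frame = pd.read_csv(path)
    return registry_from_frame(frame)
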