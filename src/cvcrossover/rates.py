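"""Cause-specific mortality rates per 1,000 person-years by time band.

Rates come from Poisson log-linear models of death counts with
log person-years offsets over categorical time-since-diagnosis bands.
By default the model is fitted separately within each age stratum, i.e.
saturated in age x band, whose maximum-likelihood prediction in each
cell is the crude rate deaths / person-years; this closed form is used
directly.  A main-effects (age + band, no interaction) variant fits a
genuinely multiplicative model by iteratively reweighted least squares
via statsmodels.

Confidence intervals are log-rate Wald intervals,
``rate * exp(±z / sqrt(d))``, with an exact Poisson upper bound when a
cell has no deaths.  Curves can be truncated at the first band whose CI
is too wide to be informative, mirroring how sparse late-follow-up bands
are suppressed from survivorship mortality plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .persontime import DEATH_CATEGORIES, PersonTimeTable

#: Default CI-width threshold (per 1,000 person-years) above which a band
#: and all later bands are suppressed from a curve.
DEFAULT_MAX_CI_WIDTH = 50.0


class RateModelError(ValueError):
    """Raised when a rate model cannot be fitted."""


@dataclass
class RateCurve:
    """Predicted mortality rate by band midpoint for one stratum and cause.

    All rates are per 1,000 person-years.  ``defined`` is False for cells
    with zero person-years, whose prediction is undefined (never zero).
    ``truncation_index`` is the first band suppressed by
    :func:`truncate_curve`, or ``None``.
    """

    site: str
    age_group: str
    sex: str
    cause: str
    midpoints: np.ndarray
    rates: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    person_years: np.ndarray
    deaths: np.ndarray
    defined: np.ndarray
    truncation_index: int | None = None
    model: str = "stratified"

    def __post_init__(self) -> None:
        n = len(self.midpoints)
        for name in ("rates", "lower", "upper", "person_years", "deaths", "defined"):
            if len(getattr(self, name)) != n:
                raise RateModelError(f"RateCurve field {name} has wrong length")
        if np.any(np.diff(self.midpoints) <= 0):
            raise RateModelError("midpoints must be strictly increasing")
        ok = self.defined
        if np.any(self.rates[ok] < 0):
            raise RateModelError("negative predicted rate")

    @property
    def ci_width(self) -> np.ndarray:
        return self.upper - self.lower

    def visible(self) -> np.ndarray:
        """Mask of bands surviving truncation (all, if untruncated)."""
        out = self.defined.copy()
        if self.truncation_index is not None:
            out[self.truncation_index:] = False
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site": self.site,
                "age_group": self.age_group,
                "sex": self.sex,
                "cause": self.cause,
                "model": self.model,
                "band": np.arange(len(self.midpoints)),
                "midpoint": self.midpoints,
                "rate_per_1000py": self.rates,
                "ci_lower": self.lower,
                "ci_upper": self.upper,
                "person_years": self.person_years,
                "deaths": self.deaths,
                "defined": self.defined,
                "suppressed": ~self.visible(),
            }
        )
        return df


def rate_ci(deaths: int, person_years: float, level: float = 0.95) -> tuple[float, float]:
    """CI for a crude rate, per 1,000 person-years.

    Log-rate Wald interval ``rate * exp(±z / sqrt(d))`` for ``d >= 1``;
    with no deaths the lower bound is 0 and the upper bound is the exact
    one-sided Poisson bound ``-ln(alpha/2) / PY``.
    """
    if person_years <= 0:
        raise RateModelError(f"person_years must be positive, got {person_years}")
    if not 0 < level < 1:
        raise RateModelError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    if deaths == 0:
        return 0.0, -np.log(alpha / 2.0) / person_years * 1e3
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    rate = deaths / person_years * 1e3
    half = z / np.sqrt(deaths)
    return rate * np.exp(-half), rate * np.exp(half)


def _curve_from_predictions(
    sub: pd.DataFrame,
    site: str,
    age_group: str,
    sex: str,
    cause: str,
    rates_per_py: np.ndarray,
    level: float,
    model: str,
) -> RateCurve:
    n = len(sub)
    py = sub["person_years"].to_numpy(dtype=float)
    deaths = sub[f"deaths_{cause}"].to_numpy(dtype=int)
    defined = py > 0
    rates = np.full(n, np.nan)
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    rates[defined] = rates_per_py[defined] * 1e3
    for i in np.flatnonzero(defined):
        lower[i], upper[i] = rate_ci(int(deaths[i]), float(py[i]), level)
    return RateCurve(
        site=site,
        age_group=age_group,
        sex=sex,
        cause=cause,
        midpoints=sub["midpoint"].to_numpy(dtype=float),
        rates=rates,
        lower=lower,
        upper=upper,
        person_years=py,
        deaths=deaths,
        defined=defined,
        model=model,
    )


def fit_rates(
    table: PersonTimeTable,
    site: str,
    cause: str,
    age_interaction: bool = True,
    sex: str = "all",
    level: float = 0.95,
) -> dict[str, RateCurve]:
    """Fit cause-specific Poisson rate models for one site.

    Maximises the Poisson log-likelihood Σ (d log μ − μ) with
    μ = rate x person-years over a log-linear model in categorical band
    and age effects.  With ``age_interaction=True`` (default) the model
    is saturated within each age stratum and the MLE predicted rate in
    every cell is the closed form d/PY.  With ``age_interaction=False``
    a single main-effects model (band + age, multiplicative) is fitted
    by IRLS and each age stratum's predictions use its fitted age effect.

    Returns
    -------
    dict mapping age group -> :class:`RateCurve`
        Rates per 1,000 person-years at the band midpoints; cells with
        zero person-years are flagged undefined.
    """
    if cause not in DEATH_CATEGORIES:
        raise RateModelError(f"unknown cause category {cause!r}")
    data = table.data
    sub = data[(data["site"] == site) & (data["sex"] == sex)]
    if sub.empty or not (sub["person_years"] > 0).any():
        raise RateModelError(
            f"no positive person-years for site {site!r} (sex={sex!r})"
        )
    sub = sub.sort_values(["age_group", "band"])

    curves: dict[str, RateCurve] = {}
    if age_interaction:
        for age_group, cell in sub.groupby("age_group", sort=True):
            py = cell["person_years"].to_numpy(dtype=float)
            d = cell[f"deaths_{cause}"].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                pred = np.where(py > 0, d / np.maximum(py, 1e-300), np.nan)
            curves[age_group] = _curve_from_predictions(
                cell, site, age_group, sex, cause, pred, level, "stratified"
            )
        return curves

    import statsmodels.api as sm

    fit_cells = sub[sub["person_years"] > 0]
    if fit_cells["age_group"].nunique() < 1:
        raise RateModelError(f"no fittable cells for site {site!r}")
    X = pd.get_dummies(
        fit_cells[["band", "age_group"]].astype({"band": "category"}),
        columns=["band", "age_group"],
        drop_first=True,
        dtype=float,
    )
    X.insert(0, "const", 1.0)
    y = fit_cells[f"deaths_{cause}"].to_numpy(dtype=float)
    model = sm.GLM(
        y,
        X.to_numpy(),
        family=sm.families.Poisson(),
        offset=np.log(fit_cells["person_years"].to_numpy(dtype=float)),
    )
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RateModelError(
            f"main-effects Poisson fit did not converge for site {site!r}, "
            f"cause {cause!r}"
        )
    colnames = list(X.columns)

    def predict_log_rate(band: int, age_group: str) -> float:
        x = np.zeros(len(colnames))
        x[0] = 1.0
        for j, name in enumerate(colnames):
            if name == f"band_{band}" or name == f"age_group_{age_group}":
                x[j] = 1.0
        return float(x @ res.params)

    for age_group, cell in sub.groupby("age_group", sort=True):
        pred = np.array(
            [np.exp(predict_log_rate(int(b), age_group)) for b in cell["band"]]
        )
        curves[age_group] = _curve_from_predictions(
            cell, site, age_group, sex, cause, pred, level, "main_effects"
        )
    return curves


def truncate_curve(
    curve: RateCurve, max_ci_width: float = DEFAULT_MAX_CI_WIDTH
) -> RateCurve:
    """Suppress bands from the first one whose CI is too wide.

    A band trips the rule when its CI width (upper − lower, per 1,000
    person-years) exceeds ``max_ci_width``, when its prediction is
    undefined, or when it has zero deaths (its Wald width is not
    meaningful); every later band is suppressed with it, narrow or not.
    """
    n = len(curve.midpoints)
    trip = np.zeros(n, dtype=bool)
    for i in range(n):
        if not curve.defined[i] or curve.deaths[i] == 0:
            trip[i] = True
        elif curve.ci_width[i] > max_ci_width:
            trip[i] = True
    idx = int(np.argmax(trip)) if trip.any() else None
    return replace(curve, truncation_index=idx)
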