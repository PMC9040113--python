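"""Crossover between cardiovascular and cancer mortality rate curves.

The crossover point is the time since diagnosis at which the predicted
cardiovascular mortality rate first equals, then exceeds, the predicted
cancer mortality rate.  Both curves are evaluated at band midpoints, so
the crossover is found by scanning consecutive midpoint pairs for a sign
change of (cvd − cancer) from negative to non-negative and linearly
interpolating both curves between the flanking midpoints.  Uncertainty
comes from a percentile bootstrap: individuals are resampled with
replacement, the whole pipeline (split → tabulate → fit → interpolate)
is rerun per replicate, and the CI is the 2.5th/97.5th percentile of the
replicate crossover times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .persontime import BandScheme, tabulate
from .rates import RateCurve, fit_rates

#: Crossovers later than this (years since diagnosis) are reported as
#: not occurring within the observation horizon.
DEFAULT_HORIZON = 20.0

#: Comparison name -> cancer-outcome column suffix.
COMPARISONS = {
    "cvd_vs_primary_cancer": "primary_cancer",
    "cvd_vs_any_cancer": "any_cancer",
}

STATUS_CROSSED = "crossed"
STATUS_NEVER = "never_within_horizon"
STATUS_ALREADY = "already_overtaken_at_first_midpoint"
STATUS_UNDEFINED = "undefined_cells"


class CrossoverError(ValueError):
    """Raised for incompatible curves or invalid bootstrap settings."""


@dataclass
class CrossoverEstimate:
    """Estimated crossover time with optional bootstrap CI.

    ``time`` is in years since diagnosis and is ``None`` unless
    ``status == "crossed"``.  ``n_not_crossed`` counts bootstrap
    replicates whose resampled curves never crossed within the horizon;
    such replicates are excluded from the percentile computation but
    always reported, and the CI is flagged unstable when they exceed 5%
    of all replicates.
    """

    site: str
    age_group: str
    sex: str
    comparison: str
    status: str
    time: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_replicates: int = 0
    n_not_crossed: int = 0
    unstable: bool = False
    seed: int | None = None
    interpolation: str = "rate"

    def __post_init__(self) -> None:
        if self.status == STATUS_CROSSED and self.time is None:
            raise CrossoverError("crossed status requires a crossover time")
        if self.time is not None and self.ci_lower is not None and self.ci_upper is not None:
            if not (self.ci_lower <= self.time <= self.ci_upper):
                raise CrossoverError("CI does not bracket the point estimate")


def _interp_pair(m0, m1, a0, a1, b0, b1) -> float:
    """Intersection time of two segments linear on [m0, m1]."""
    gap0 = b0 - a0  # cancer minus cvd at the left midpoint (>= 0)
    gap1 = a1 - b1  # cvd minus cancer at the right midpoint (>= 0)
    return m0 + (m1 - m0) * gap0 / (gap0 + gap1)


def find_crossover(
    cvd: RateCurve,
    cancer: RateCurve,
    horizon: float = DEFAULT_HORIZON,
    log_scale: bool = False,
) -> CrossoverEstimate:
    """Locate where the cardiovascular curve overtakes the cancer curve.

    Scans consecutive midpoint pairs where both curves are defined for
    the first transition of cvd − cancer from negative to non-negative
    and interpolates both curves linearly (on the rate scale, or on the
    log-rate scale with ``log_scale``) between the flanking midpoints.
    Exact equality at a midpoint yields that midpoint.  A crossover
    later than ``horizon`` is reported as not occurring within the
    horizon; cvd at or above cancer already at the first defined
    midpoint has no numeric crossover time.
    """
    if cvd.midpoints.shape != cancer.midpoints.shape or not np.allclose(
        cvd.midpoints, cancer.midpoints
    ):
        raise CrossoverError("curves have mismatched midpoints")
    if (cvd.site, cvd.age_group, cvd.sex) != (cancer.site, cancer.age_group, cancer.sex):
        raise CrossoverError("curves are from different strata")
    meta = dict(
        site=cvd.site,
        age_group=cvd.age_group,
        sex=cvd.sex,
        comparison=f"cvd_vs_{cancer.cause}",
        interpolation="log" if log_scale else "rate",
    )
    ok = cvd.defined & cancer.defined
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return CrossoverEstimate(status=STATUS_UNDEFINED, **meta)
    a = cvd.rates
    b = cancer.rates
    if log_scale:
        with np.errstate(divide="ignore"):
            a = np.where(ok & (a > 0), np.log(np.maximum(a, 1e-300)), np.nan)
            b = np.where(ok & (b > 0), np.log(np.maximum(b, 1e-300)), np.nan)
        ok = ok & np.isfinite(a) & np.isfinite(b)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            return CrossoverEstimate(status=STATUS_UNDEFINED, **meta)
    m = cvd.midpoints

    first = idx[0]
    if a[first] > b[first]:
        return CrossoverEstimate(status=STATUS_ALREADY, **meta)
    if a[first] == b[first]:
        t = float(m[first])
        if t > horizon:
            return CrossoverEstimate(status=STATUS_NEVER, **meta)
        return CrossoverEstimate(status=STATUS_CROSSED, time=t, **meta)

    for i, j in zip(idx, idx[1:]):
        if a[i] < b[i] and a[j] >= b[j]:
            if a[j] == b[j]:
                t = float(m[j])
            else:
                t = _interp_pair(m[i], m[j], a[i], a[j], b[i], b[j])
            if t > horizon:
                return CrossoverEstimate(status=STATUS_NEVER, **meta)
            return CrossoverEstimate(status=STATUS_CROSSED, time=float(t), **meta)
    return CrossoverEstimate(status=STATUS_NEVER, **meta)


def crossover_from_records(
    records: pd.DataFrame,
    scheme: BandScheme,
    site: str,
    age_group: str,
    comparison: str = "cvd_vs_primary_cancer",
    cause_field: str = "underlying_cause",
    sex: str = "all",
    horizon: float = DEFAULT_HORIZON,
    age_interaction: bool = True,
    log_scale: bool = False,
) -> CrossoverEstimate:
    """Run split → tabulate → fit → find_crossover on raw records."""
    cancer_cause = COMPARISONS[comparison]
    table = tabulate(
        records, scheme, cause_field=cause_field, stratify_sex=(sex != "all")
    )
    cvd_curves = fit_rates(table, site, "cvd", age_interaction=age_interaction, sex=sex)
    ca_curves = fit_rates(
        table, site, cancer_cause, age_interaction=age_interaction, sex=sex
    )
    if age_group not in cvd_curves:
        raise CrossoverError(f"no data for age group {age_group!r} at site {site!r}")
    return find_crossover(
        cvd_curves[age_group], ca_curves[age_group], horizon=horizon, log_scale=log_scale
    )


def bootstrap_crossover(
    records: pd.DataFrame,
    scheme: BandScheme,
    site: str,
    age_group: str,
    comparison: str = "cvd_vs_primary_cancer",
    B: int = 200,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
    cause_field: str = "underlying_cause",
    sex: str = "all",
    age_interaction: bool = True,
    log_scale: bool = False,
    stratify_by_age: bool = False,
    unstable_fraction: float = 0.05,
) -> CrossoverEstimate:
    """Percentile-bootstrap CI for the crossover time.

    Draws ``B`` resamples of individuals with replacement from the site
    cohort (size preserved; within age group when ``stratify_by_age``),
    reruns the full pipeline per replicate and takes the 2.5th and
    97.5th percentiles (linear interpolation between order statistics,
    numpy default) of the replicate crossover times among replicates
    that crossed.  The point estimate comes from the original sample; if
    it did not cross, its status is returned and no CI is computed.
    """
    if B < 2:
        raise CrossoverError(f"need at least 2 bootstrap replicates, got {B}")
    if comparison not in COMPARISONS:
        raise CrossoverError(f"unknown comparison {comparison!r}")
    site_records = records[records["site"] == site].reset_index(drop=True)
    if site_records.empty:
        raise CrossoverError(f"no records for site {site!r}")

    kwargs = dict(
        scheme=scheme,
        site=site,
        age_group=age_group,
        comparison=comparison,
        cause_field=cause_field,
        sex=sex,
        horizon=horizon,
        age_interaction=age_interaction,
        log_scale=log_scale,
    )
    point = crossover_from_records(site_records, **kwargs)
    point.seed = seed
    if point.status != STATUS_CROSSED:
        return point

    rng = np.random.default_rng(seed)
    n = len(site_records)
    if stratify_by_age:
        group_idx = [
            site_records.index[site_records["age_group"] == g].to_numpy()
            for g in sorted(site_records["age_group"].unique())
        ]
    times = []
    n_not_crossed = 0
    for _ in range(B):
        if stratify_by_age:
            take = np.concatenate(
                [rng.choice(gi, size=len(gi), replace=True) for gi in group_idx]
            )
        else:
            take = rng.integers(0, n, size=n)
        rep = site_records.iloc[take].reset_index(drop=True)
        try:
            est = crossover_from_records(rep, **kwargs)
        except (CrossoverError, ValueError):
            n_not_crossed += 1
            continue
        if est.status == STATUS_CROSSED:
            times.append(est.time)
        else:
            n_not_crossed += 1

    point.n_replicates = B
    point.n_not_crossed = n_not_crossed
    point.unstable = n_not_crossed > unstable_fraction * B
    if times:
        lo, hi = np.percentile(times, [2.5, 97.5])  # linear interpolation
        point.ci_lower = float(min(lo, point.time))
        point.ci_upper = float(max(hi, point.time))
    return point
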