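"""Synthetic competing-risks survivor cohorts with known cause-specific hazards.

Generates cohorts of cancer survivors followed from 1 year after diagnosis,
with death attributable to one of four competing cause categories:

* ``cvd`` — cardiovascular disease,
* ``primary_cancer`` — the person's own (first) cancer,
* ``other_cancer`` — a cancer other than the primary,
* ``other`` — everything else.

Each stratum (cancer site x age group, optionally x sex) carries one
:class:`HazardSpec` per cause, a piecewise-constant or piecewise-linear
cause-specific hazard on the time-since-diagnosis axis.  Event times are
sampled exactly by inversion of the closed-form cumulative total hazard,
and the cause of death is drawn from the cause-specific hazard shares at
the sampled time.  Because the generating hazards are known analytically,
the time at which one hazard overtakes another (:func:`true_crossover`)
is available in closed form and serves as ground truth for the whole
downstream estimation pipeline.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CAUSES = ("cvd", "primary_cancer", "other_cancer", "other")

#: Follow-up starts one year after diagnosis.
ENTRY_YEARS = 1.0
#: Maximum supported follow-up horizon, years since diagnosis.
MAX_HORIZON = 25.0

#: Columns of the delimited cohort file, in order.
COHORT_COLUMNS = (
    "person_id",
    "site",
    "sex",
    "age_group",
    "entry_years",
    "exit_years",
    "died",
    "underlying_cause",
    "immediate_cause",
)

AGE_GROUPS = ("40-59", "60-79", "80+")

SITES = (
    "bladder",
    "breast",
    "colorectal",
    "leukemia",
    "lung",
    "melanoma",
    "nhl",
    "prostate",
    "uterus",
)


class SimulationError(ValueError):
    """Raised for invalid hazard specifications or simulation parameters."""


@dataclass(frozen=True)
class HazardSpec:
    """Piecewise cause-specific hazard for one stratum and cause.

    Parameters
    ----------
    cause:
        One of :data:`CAUSES`.
    site, age_group, sex:
        Stratum key.  ``sex`` may be ``None`` when the hazard does not
        differ between sexes.
    kind:
        ``"constant"`` — piecewise-constant: ``values[i]`` is the hazard on
        ``[breakpoints[i], breakpoints[i+1])`` and ``len(values) ==
        len(breakpoints) - 1``.
        ``"linear"`` — continuous piecewise-linear: ``values[i]`` is the
        hazard at ``breakpoints[i]`` and ``len(values) == len(breakpoints)``.
    breakpoints:
        Strictly increasing knots within ``[1, 25]`` years since diagnosis;
        the first must equal the entry time and the last the horizon of
        validity.
    values:
        Hazard values in events per person-year, all ``>= 0``.
    """

    cause: str
    site: str
    age_group: str
    kind: str
    breakpoints: tuple[float, ...]
    values: tuple[float, ...]
    sex: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.cause not in CAUSES:
            raise SimulationError(
                f"unknown cause {self.cause!r} for stratum {self.stratum}"
            )
        if self.kind not in ("constant", "linear"):
            raise SimulationError(f"unknown hazard kind {self.kind!r}")
        bp = self.breakpoints
        if len(bp) < 2 or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise SimulationError(
                f"breakpoints must be strictly increasing, got {bp} "
                f"for stratum {self.stratum}"
            )
        if bp[0] < ENTRY_YEARS - 1e-12 or bp[-1] > MAX_HORIZON + 1e-12:
            raise SimulationError(
                f"breakpoints must lie within [{ENTRY_YEARS}, {MAX_HORIZON}] "
                f"for stratum {self.stratum}"
            )
        expected = len(bp) - 1 if self.kind == "constant" else len(bp)
        if len(self.values) != expected:
            raise SimulationError(
                f"{self.kind} hazard needs {expected} values for "
                f"{len(bp)} breakpoints, got {len(self.values)} "
                f"for stratum {self.stratum}"
            )
        if any(v < 0 for v in self.values):
            raise SimulationError(
                f"negative hazard value for cause {self.cause!r} "
                f"in stratum {self.stratum}"
            )

    @property
    def stratum(self) -> tuple:
        key = (self.site, self.age_group)
        return key if self.sex is None else key + (self.sex,)

    # -- evaluation ---------------------------------------------------------

    def rate(self, t):
        """Hazard λ(t) in events per person-year; vectorised over ``t``.

        Right-continuous at breakpoints; beyond the last breakpoint the
        final value is carried forward (flat extrapolation).
        """
        t = np.asarray(t, dtype=float)
        bp = np.asarray(self.breakpoints)
        vals = np.asarray(self.values)
        if self.kind == "constant":
            idx = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, len(vals) - 1)
            out = vals[idx]
        else:
            out = np.interp(t, bp, vals)
        return out if out.shape else float(out)

    def segments(self) -> list[tuple[float, float, float, float]]:
        """Decompose into linear segments ``(start, end, value_at_start, slope)``."""
        segs = []
        bp = self.breakpoints
        if self.kind == "constant":
            for a, b, v in zip(bp, bp[1:], self.values):
                segs.append((a, b, v, 0.0))
        else:
            for a, b, va, vb in zip(bp, bp[1:], self.values, self.values[1:]):
                segs.append((a, b, va, (vb - va) / (b - a)))
        return segs


def _merged_segments(
    specs: Sequence[HazardSpec], horizon: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge several piecewise hazards into shared linear segments.

    Returns ``(starts, values, slopes)`` where segment ``i`` spans
    ``[starts[i], starts[i+1])`` with total hazard
    ``values[i] + slopes[i] * (t - starts[i])``; ``starts`` has one more
    entry than the segment arrays (the final element is ``horizon``).
    """
    knots = {ENTRY_YEARS, float(horizon)}
    for s in specs:
        knots.update(b for b in s.breakpoints if ENTRY_YEARS < b < horizon)
    starts = np.array(sorted(knots))
    seg_a = starts[:-1]
    values = np.zeros(len(seg_a))
    slopes = np.zeros(len(seg_a))
    for s in specs:
        values += s.rate(seg_a)
        # slope within each merged segment: finite difference is exact for
        # piecewise-linear pieces and zero for constants
        seg_b = starts[1:]
        mid = 0.5 * (seg_a + seg_b)
        slopes += (np.asarray(s.rate(mid)) - np.asarray(s.rate(seg_a))) / (mid - seg_a)
    return starts, values, slopes


def _cumulative_at_knots(starts: np.ndarray, values: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    widths = np.diff(starts)
    increments = values * widths + 0.5 * slopes * widths**2
    return np.concatenate([[0.0], np.cumsum(increments)])


def _invert_total_hazard(
    e: np.ndarray, starts: np.ndarray, values: np.ndarray, slopes: np.ndarray, cum: np.ndarray
) -> np.ndarray:
    """Solve H(t) = e for each exponential draw; +inf where never reached."""
    t = np.full(e.shape, np.inf)
    reached = e < cum[-1]
    idx = np.searchsorted(cum, e[reached], side="right") - 1
    idx = np.clip(idx, 0, len(values) - 1)
    rem = e[reached] - cum[idx]
    v, s = values[idx], slopes[idx]
    x = np.empty_like(rem)
    lin = np.abs(s) < 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        x[lin] = rem[lin] / v[lin]
        # 0.5 s x^2 + v x - rem = 0, positive root
        disc = v[~lin] ** 2 + 2.0 * s[~lin] * rem[~lin]
        x[~lin] = (-v[~lin] + np.sqrt(np.maximum(disc, 0.0))) / s[~lin]
    t[reached] = starts[idx] + x
    return t


def simulate_cohort(
    spec_set: Iterable[HazardSpec],
    n_per_stratum: int | Mapping[tuple, int],
    horizon: float = MAX_HORIZON,
    seed: int = 0,
    censor_window: tuple[float, float] | float | None = (5.0, 24.0),
    p_disagree: float = 0.05,
    female_fraction: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a multi-stratum survivor cohort under known hazards.

    Each person enters at 1 year since diagnosis.  A latent death time is
    drawn by exact inversion of the cumulative total hazard; a cause is
    then drawn with probability proportional to each cause-specific hazard
    at that time.  Administrative censoring truncates follow-up at
    ``entry + U(lo, hi)`` (per-person, emulating staggered diagnosis dates
    against a fixed study end), at a fixed offset if ``censor_window`` is a
    scalar, or only at ``horizon`` if it is ``None``.

    The recorded immediate cause equals the underlying cause except with
    probability ``p_disagree``, where a different cause category is drawn
    uniformly (emulating discordant death-certificate coding).

    Parameters
    ----------
    spec_set:
        Hazard specs covering all four causes for every stratum.
    n_per_stratum:
        Cohort size per stratum, either one integer for all strata or a
        mapping ``stratum key -> n``.
    horizon:
        Administrative end of follow-up, years since diagnosis, in
        ``(1, 25]``.
    seed:
        Seed for the random generator; identical seed and specs give an
        identical cohort.
    female_fraction:
        Optional ``site -> probability`` a person is female; defaults to
        0.5 everywhere.  Ignored for strata whose specs carry an explicit
        ``sex``.

    Returns
    -------
    pandas.DataFrame
        One row per person with columns :data:`COHORT_COLUMNS`.
    """
    specs = list(spec_set)
    if not specs:
        raise SimulationError("empty hazard spec set")
    if not (ENTRY_YEARS < horizon <= MAX_HORIZON):
        raise SimulationError(
            f"horizon must lie in ({ENTRY_YEARS}, {MAX_HORIZON}], got {horizon}"
        )
    if not 0.0 <= p_disagree <= 1.0:
        raise SimulationError(f"p_disagree must be a probability, got {p_disagree}")

    by_stratum: dict[tuple, dict[str, HazardSpec]] = {}
    for s in specs:
        by_stratum.setdefault(s.stratum, {})
        if s.cause in by_stratum[s.stratum]:
            raise SimulationError(
                f"duplicate spec for cause {s.cause!r} in stratum {s.stratum}"
            )
        by_stratum[s.stratum][s.cause] = s
    for key, causes in by_stratum.items():
        missing = [c for c in CAUSES if c not in causes]
        if missing:
            raise SimulationError(
                f"stratum {key} missing hazard specs for causes {missing}"
            )

    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for key in sorted(by_stratum):
        causes = by_stratum[key]
        if isinstance(n_per_stratum, Mapping):
            n = int(n_per_stratum[key])
        else:
            n = int(n_per_stratum)
        if n < 1:
            raise SimulationError(f"n_per_stratum must be >= 1 for stratum {key}")
        site, age_group = key[0], key[1]
        sex_fixed = key[2] if len(key) > 2 else None

        cause_specs = [causes[c] for c in CAUSES]
        starts, values, slopes = _merged_segments(cause_specs, horizon)
        cum = _cumulative_at_knots(starts, values, slopes)

        e = rng.exponential(size=n)
        t_event = _invert_total_hazard(e, starts, values, slopes, cum)

        if censor_window is None:
            t_admin = np.full(n, horizon)
        elif np.isscalar(censor_window):
            t_admin = np.minimum(ENTRY_YEARS + float(censor_window), horizon)
            t_admin = np.full(n, t_admin)
        else:
            lo, hi = censor_window
            if not (0 < lo <= hi):
                raise SimulationError(
                    f"censoring window must satisfy 0 < lo <= hi, got {censor_window}"
                )
            t_admin = np.minimum(ENTRY_YEARS + rng.uniform(lo, hi, size=n), horizon)

        died = t_event < t_admin
        exit_years = np.where(died, t_event, t_admin)

        # cause draw at the event time: multinomial on hazard shares
        underlying = np.full(n, "", dtype=object)
        immediate = np.full(n, "", dtype=object)
        d_idx = np.flatnonzero(died)
        if d_idx.size:
            td = t_event[d_idx]
            lam = np.column_stack([np.asarray(causes[c].rate(td), dtype=float).reshape(-1) for c in CAUSES])
            tot = lam.sum(axis=1)
            # a death can only occur where the total hazard is positive
            probs = lam / tot[:, None]
            u = rng.uniform(size=d_idx.size)
            picks = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            picks = np.clip(picks, 0, len(CAUSES) - 1)
            cause_arr = np.array(CAUSES, dtype=object)[picks]
            underlying[d_idx] = cause_arr
            immediate[d_idx] = cause_arr
            if p_disagree > 0:
                flip = rng.uniform(size=d_idx.size) < p_disagree
                if flip.any():
                    shift = rng.integers(1, len(CAUSES), size=int(flip.sum()))
                    immediate[d_idx[flip]] = np.array(CAUSES, dtype=object)[
                        (picks[flip] + shift) % len(CAUSES)
                    ]

        if sex_fixed is not None:
            sex = np.full(n, sex_fixed, dtype=object)
        else:
            pf = 0.5 if female_fraction is None else float(female_fraction.get(site, 0.5))
            sex = np.where(rng.uniform(size=n) < pf, "F", "M").astype(object)

        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.arange(offset, offset + n),
                    "site": site,
                    "sex": sex,
                    "age_group": age_group,
                    "entry_years": ENTRY_YEARS,
                    "exit_years": exit_years,
                    "died": died,
                    "underlying_cause": underlying,
                    "immediate_cause": immediate,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# analytic crossover of two hazard functions (ground truth)
# ---------------------------------------------------------------------------

def true_crossover(
    spec_a: HazardSpec, spec_b: HazardSpec, horizon: float = MAX_HORIZON
) -> float | None:
    """Exact first time in ``[1, horizon]`` at which hazard a overtakes hazard b.

    The crossover is the earliest point where the difference λ_a − λ_b
    changes sign from negative to non-negative — a root inside a linear
    piece, a touch-and-rise at a knot, or a jump across zero at a
    piecewise-constant breakpoint.  Returns ``None`` when λ_a never
    overtakes λ_b from below within the horizon (including when λ_a is
    already at or above λ_b at entry).
    """
    if (spec_a.site, spec_a.age_group, spec_a.sex) != (
        spec_b.site,
        spec_b.age_group,
        spec_b.sex,
    ):
        raise SimulationError("crossover requires specs on the same stratum")
    starts, _, _ = _merged_segments([spec_a, spec_b], horizon)
    eps = 1e-9

    def diff(t):
        return float(spec_a.rate(t)) - float(spec_b.rate(t))

    been_below = diff(ENTRY_YEARS) < -eps
    for a, b in zip(starts[:-1], starts[1:]):
        da_right = diff(min(a + eps, b))  # just inside the piece
        if been_below and diff(a) >= -eps and da_right > eps:
            # jump or touch at the knot itself
            return float(a)
        d0, d1 = diff(a), diff(b - eps)
        if d0 < -eps:
            been_below = True
            if d1 >= -eps:
                # linear piece crosses zero: root of d0 + slope*(t-a)
                slope = (d1 - d0) / (b - eps - a)
                t0 = a - d0 / slope if slope > 0 else b
                if diff(min(t0 + 1e-7, horizon)) > eps or d1 > eps:
                    return float(min(t0, b))
        elif d1 < -eps:
            been_below = True
    t_end = float(starts[-1])
    if been_below and diff(t_end) > eps:
        return t_end if t_end < horizon else None
    return None


# ---------------------------------------------------------------------------
# cohort file i/o
# ---------------------------------------------------------------------------

class CohortFileError(ValueError):
    """Raised when a cohort file violates the documented schema."""


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort to delimited text with the documented header."""
    out = records.loc[:, list(COHORT_COLUMNS)].copy()
    out["died"] = out["died"].astype(int)
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort file, validating every row.

    Raises :class:`CohortFileError` naming the first offending physical
    line (the header is line 1) when a row violates the record
    invariants: ``entry < exit <= 25``, cause labels present iff died,
    and recognised cause labels.
    """
    df = pd.read_csv(
        path,
        dtype={
            "person_id": "int64",
            "site": "string",
            "sex": "string",
            "age_group": "string",
        },
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFileError(f"cohort file missing columns {missing}")
    df = df.loc[:, list(COHORT_COLUMNS)]
    if df.empty:
        return _empty_cohort()
    df["underlying_cause"] = df["underlying_cause"].fillna("").astype(str)
    df["immediate_cause"] = df["immediate_cause"].fillna("").astype(str)
    df["died"] = df["died"].astype(bool)
    df["entry_years"] = df["entry_years"].astype(float)
    df["exit_years"] = df["exit_years"].astype(float)

    def _fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2  # +1 header, +1 one-based
            raise CohortFileError(f"line {line}: {message}")

    _fail(df["exit_years"] <= df["entry_years"], "exit_years <= entry_years")
    _fail(df["exit_years"] > MAX_HORIZON + 1e-9, f"exit_years beyond {MAX_HORIZON}")
    _fail(df["died"] & (df["underlying_cause"] == ""), "death without underlying cause")
    _fail(~df["died"] & (df["underlying_cause"] != ""), "cause recorded for survivor")
    _fail(
        df["died"] & ~df["underlying_cause"].isin(CAUSES),
        "unrecognised underlying cause",
    )
    _fail(
        df["died"] & ~df["immediate_cause"].isin(CAUSES),
        "unrecognised immediate cause",
    )
    df["site"] = df["site"].astype(object)
    df["sex"] = df["sex"].astype(object)
    df["age_group"] = df["age_group"].astype(object)
    return df


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": pd.Series(dtype="int64"),
            "site": pd.Series(dtype=object),
            "sex": pd.Series(dtype=object),
            "age_group": pd.Series(dtype=object),
            "entry_years": pd.Series(dtype=float),
            "exit_years": pd.Series(dtype=float),
            "died": pd.Series(dtype=bool),
            "underlying_cause": pd.Series(dtype=object),
            "immediate_cause": pd.Series(dtype=object),
        }
    )


# ---------------------------------------------------------------------------
# survivor-cohort preset: a plausible multi-site survivor cohort
# ---------------------------------------------------------------------------

#: Illustrative per-site multipliers on the primary-cancer hazard, reflecting
#: the ordering of early cancer mortality across sites (lung and colorectal
#: highest; breast and prostate lowest).
_SITE_SEVERITY = {
    "lung": 3.5,
    "colorectal": 1.6,
    "bladder": 1.0,
    "uterus": 0.9,
    "melanoma": 0.8,
    "nhl": 1.0,
    "leukemia": 1.1,
    "breast": 0.5,
    "prostate": 0.45,
}

#: Female fraction per site used by the preset simulator (breast and uterus
#: are treated as all-female, prostate all-male; others near parity).
PRESET_FEMALE_FRACTION = {
    "bladder": 0.24,
    "breast": 1.0,
    "colorectal": 0.45,
    "leukemia": 0.41,
    "lung": 0.44,
    "melanoma": 0.54,
    "nhl": 0.48,
    "prostate": 0.0,
    "uterus": 1.0,
}

# (cvd start, cvd end, cancer start, cancer end, other cancer, other),
# all per 1,000 person-years on [1, 25] years since diagnosis
_AGE_PROFILES = {
    "40-59": (2.0, 4.0, 40.0, 4.0, 3.0, 3.0),
    "60-79": (8.0, 40.0, 60.0, 8.0, 6.0, 15.0),
    "80+": (30.0, 95.0, 80.0, 12.0, 8.0, 60.0),
}


def survivor_cohort_specs(
    sites: Sequence[str] = SITES, age_groups: Sequence[str] = AGE_GROUPS
) -> list[HazardSpec]:
    """Hazard specs for a qualitatively realistic survivor cohort.

    Primary-cancer mortality declines linearly with time since diagnosis
    while cardiovascular mortality rises, steeply in the oldest stratum —
    so the cardiovascular hazard overtakes the cancer hazard early in old
    age, later (or never within the horizon) in younger strata.  Values
    are illustrative, not fitted to any dataset.
    """
    specs = []
    for site in sites:
        sev = _SITE_SEVERITY.get(site, 1.0)
        for age in age_groups:
            cvd0, cvd1, ca0, ca1, oc, oth = _AGE_PROFILES[age]
            specs += [
                HazardSpec("cvd", site, age, "linear", (1.0, 25.0), (cvd0 / 1e3, cvd1 / 1e3)),
                HazardSpec(
                    "primary_cancer",
                    site,
                    age,
                    "linear",
                    (1.0, 25.0),
                    (sev * ca0 / 1e3, min(sev * ca1, sev * ca0) / 1e3),
                ),
                HazardSpec("other_cancer", site, age, "constant", (1.0, 25.0), (oc / 1e3,)),
                HazardSpec("other", site, age, "constant", (1.0, 25.0), (oth / 1e3,)),
            ]
    return specs


def linear_crossing_specs(
    t_star: float,
    site: str = "colorectal",
    age_group: str = "60-79",
    cvd_start: float = 2.0,
    cvd_slope: float = 2.0,
    cancer_slope: float = 3.0,
    floor: float = 0.5,
    other_cancer: float = 3.0,
    other: float = 5.0,
) -> list[HazardSpec]:
    """Single-stratum spec set whose CVD hazard overtakes the cancer hazard
    at exactly ``t_star`` years since diagnosis.

    The CVD hazard rises linearly from ``cvd_start`` (per 1,000
    person-years, at entry) with slope ``cvd_slope``; the primary-cancer
    hazard falls through the crossing point with slope ``-cancer_slope``
    until it reaches ``floor``, then stays flat.  Because the CVD hazard
    keeps rising past the crossing, the crossover is unique and
    :func:`true_crossover` returns ``t_star`` exactly — a closed-form
    ground truth for recovery tests.
    """
    if not ENTRY_YEARS < t_star < MAX_HORIZON:
        raise SimulationError(f"t_star must lie in (1, 25), got {t_star}")
    cvd_at = lambda t: cvd_start + cvd_slope * (t - ENTRY_YEARS)
    cross_rate = cvd_at(t_star)
    cancer_at_entry = cross_rate + cancer_slope * (t_star - ENTRY_YEARS)
    t_floor = t_star + (cross_rate - floor) / cancer_slope
    if t_floor < MAX_HORIZON:
        cancer = HazardSpec(
            "primary_cancer", site, age_group, "linear",
            (ENTRY_YEARS, t_floor, MAX_HORIZON),
            (cancer_at_entry / 1e3, floor / 1e3, floor / 1e3),
        )
    else:
        cancer = HazardSpec(
            "primary_cancer", site, age_group, "linear",
            (ENTRY_YEARS, MAX_HORIZON),
            (cancer_at_entry / 1e3,
             (cross_rate - cancer_slope * (MAX_HORIZON - t_star)) / 1e3),
        )
    return [
        HazardSpec(
            "cvd", site, age_group, "linear",
            (ENTRY_YEARS, MAX_HORIZON),
            (cvd_at(ENTRY_YEARS) / 1e3, cvd_at(MAX_HORIZON) / 1e3),
        ),
        cancer,
        HazardSpec("other_cancer", site, age_group, "constant",
                   (ENTRY_YEARS, MAX_HORIZON), (other_cancer / 1e3,)),
        HazardSpec("other", site, age_group, "constant",
                   (ENTRY_YEARS, MAX_HORIZON), (other / 1e3,)),
    ]


def survivor_cohort_sizes(scale: float = 1.0) -> dict[tuple, int]:
    """Cohort sizes per (site, age group) stratum, of the order of a large
    national primary-care cohort; ``scale`` shrinks them proportionally."""
    from .pipeline import fixture_table1  # local import to avoid a cycle

    rows, _ = fixture_table1()
    return {
        (r.site, r.age_group): max(1, int(round(r.individuals * scale)))
        for r in rows.itertuples()
    }
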