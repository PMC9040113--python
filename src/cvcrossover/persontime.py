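"""Lexis splitting of follow-up into time-since-diagnosis bands.

Follow-up from 1 year after diagnosis is divided into half-open bands
``[a, b)`` on the time-since-diagnosis axis (default: 1-<2, 2-<3, 3-<4,
4-<5, 5-<10, 10-<15 and 15-25 years).  Each band accumulates
person-years at risk and cause-specific death counts per stratum; the
death, if any, sits in the band containing the exit time.  Rates are the
business of :mod:`cvcrossover.rates`; this module only tabulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CAUSES, ENTRY_YEARS

#: Death-count categories tabulated per cell.  ``any_cancer`` contains
#: every cancer death including the primary.
DEATH_CATEGORIES = ("cvd", "primary_cancer", "any_cancer", "other")


class PersonTimeError(ValueError):
    """Raised for records or schemes that cannot be tabulated."""


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous half-open time bands covering the follow-up axis.

    A band ``[a, b)`` owns every time ``t`` with ``a <= t < b``; a death at
    an exact boundary therefore belongs to the band the person was
    entering.  The representative plotting time of each band is its
    midpoint ``(a + b) / 2``.
    """

    edges: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 15.0, 25.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        if len(self.edges) < 2:
            raise PersonTimeError("a band scheme needs at least two edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise PersonTimeError(f"band edges must be strictly increasing: {self.edges}")

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(zip(self.edges, self.edges[1:]))

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def start(self) -> float:
        return self.edges[0]

    @property
    def end(self) -> float:
        return self.edges[-1]

    def __len__(self) -> int:
        return len(self.edges) - 1

    def band_of(self, t: float) -> int:
        """Index of the band containing ``t`` under the half-open rule.

        ``t`` equal to the final edge maps to the last band so that a
        death at the exact end of coverage is not lost.
        """
        if t < self.start or t > self.end:
            raise PersonTimeError(f"time {t} outside band coverage [{self.start}, {self.end}]")
        if t == self.end:
            return len(self) - 1
        return int(np.searchsorted(self.edges, t, side="right") - 1)


@dataclass
class PersonTimeTable:
    """Aggregated person-years and death counts per stratum x band cell.

    ``data`` holds one row per (site, age_group, sex, band) with columns
    ``band``, ``band_start``, ``band_end``, ``midpoint``, ``person_years``,
    ``n_persons`` (people contributing any time to the band) and one
    ``deaths_<category>`` column per entry of :data:`DEATH_CATEGORIES`.
    ``sex`` is the literal ``"all"`` when tabulation was not sex-stratified.
    """

    data: pd.DataFrame
    scheme: BandScheme
    cause_field: str = "underlying_cause"

    def cell(self, site: str, age_group: str, band: int, sex: str = "all") -> pd.Series:
        m = (
            (self.data["site"] == site)
            & (self.data["age_group"] == age_group)
            & (self.data["sex"] == sex)
            & (self.data["band"] == band)
        )
        sub = self.data.loc[m]
        if len(sub) != 1:
            raise KeyError((site, age_group, sex, band))
        return sub.iloc[0]

    def total_deaths(self, category: str) -> int:
        sub = self.data[self.data["sex"] == "all"]
        return int(sub[f"deaths_{category}"].sum())


def split_followup(
    record, scheme: BandScheme = BandScheme()
) -> list[tuple[int, float, str | None]]:
    """Split one person's follow-up across the bands of ``scheme``.

    Parameters
    ----------
    record:
        Mapping-like with ``entry_years``, ``exit_years``, ``died`` and
        ``underlying_cause`` (e.g. one cohort row).
    scheme:
        Band scheme; must cover the record's exit time.

    Returns
    -------
    list of (band index, person-years, cause-or-None)
        One entry per band receiving positive person-years, in band
        order; the cause label is attached to the band containing the
        exit time when the person died.  The person-years sum to
        ``exit - entry`` exactly (interval arithmetic, no rounding).
    """
    entry = float(record["entry_years"])
    exit_ = float(record["exit_years"])
    if exit_ <= entry:
        raise PersonTimeError(f"exit {exit_} must exceed entry {entry}")
    if entry < scheme.start or exit_ > scheme.end:
        raise PersonTimeError(
            f"follow-up [{entry}, {exit_}] outside band coverage "
            f"[{scheme.start}, {scheme.end}]"
        )
    died = bool(record["died"])
    cause = str(record["underlying_cause"]) if died else None
    death_band = scheme.band_of(exit_) if died else None
    out = []
    for i, (a, b) in enumerate(scheme.bands):
        py = min(exit_, b) - max(entry, a)
        if py > 0 or i == death_band:
            out.append((i, max(py, 0.0), cause if i == death_band else None))
    return out


def _split_vectorized(records: pd.DataFrame, scheme: BandScheme):
    """Band person-years matrix (n x bands) and death band per person."""
    entry = records["entry_years"].to_numpy(dtype=float)
    exit_ = records["exit_years"].to_numpy(dtype=float)
    if (exit_ <= entry).any():
        bad = records.loc[exit_ <= entry, "person_id"].tolist()
        raise PersonTimeError(f"exit <= entry for person ids {bad[:10]}")
    if entry.size and (entry.min() < scheme.start or exit_.max() > scheme.end):
        raise PersonTimeError(
            f"follow-up outside band coverage [{scheme.start}, {scheme.end}]"
        )
    edges = np.asarray(scheme.edges)
    a, b = edges[:-1], edges[1:]
    py = np.clip(
        np.minimum(exit_[:, None], b[None, :]) - np.maximum(entry[:, None], a[None, :]),
        0.0,
        None,
    )
    death_band = np.where(
        exit_ >= scheme.end,
        len(scheme) - 1,
        np.searchsorted(edges, exit_, side="right") - 1,
    )
    return py, death_band


def tabulate(
    records: pd.DataFrame,
    scheme: BandScheme = BandScheme(),
    cause_field: str = "underlying_cause",
    stratify_sex: bool = False,
) -> PersonTimeTable:
    """Aggregate a cohort into a person-time table.

    A death whose cause label is ``primary_cancer`` increments both the
    ``primary_cancer`` and ``any_cancer`` counts of its cell;
    ``other_cancer`` increments ``any_cancer`` only.  Follow-up is
    censored at all-cause death, so no person contributes time beyond
    their exit.  With ``stratify_sex`` the table carries sex-specific
    rows in addition to the pooled ``"all"`` rows.

    Raises :class:`PersonTimeError` listing offending person ids when a
    death carries an unrecognised cause label.
    """
    if cause_field not in ("underlying_cause", "immediate_cause"):
        raise PersonTimeError(f"unknown cause field {cause_field!r}")
    died = records["died"].to_numpy(dtype=bool)
    causes = records[cause_field].astype(str).to_numpy()
    bad = died & ~np.isin(causes, CAUSES)
    if bad.any():
        ids = records.loc[bad, "person_id"].tolist()
        raise PersonTimeError(f"unrecognised cause labels for person ids {ids[:10]}")

    py, death_band = _split_vectorized(records, scheme)

    sexes: list[str | np.ndarray] = ["all"]
    if stratify_sex:
        sexes += sorted(records["sex"].unique())

    frames = []
    strata = records[["site", "age_group"]].copy()
    for sex in sexes:
        mask = np.ones(len(records), dtype=bool) if sex == "all" else (
            records["sex"] == sex
        ).to_numpy()
        sub = strata.loc[mask]
        keys = pd.MultiIndex.from_frame(sub)
        groups = keys.unique().sort_values()
        code_of = {k: i for i, k in enumerate(groups)}
        codes = np.array([code_of[k] for k in keys])
        n_groups = len(groups)
        n_bands = len(scheme)

        py_cell = np.zeros((n_groups, n_bands))
        np.add.at(py_cell, codes, py[mask])
        persons = np.zeros((n_groups, n_bands), dtype=int)
        np.add.at(persons, codes, (py[mask] > 0).astype(int))

        deaths = {cat: np.zeros((n_groups, n_bands), dtype=int) for cat in DEATH_CATEGORIES}
        d = died[mask]
        if d.any():
            dcodes = codes[d]
            dbands = death_band[mask][d]
            dcauses = causes[mask][d]
            for cat in ("cvd", "other"):
                sel = dcauses == cat
                np.add.at(deaths[cat], (dcodes[sel], dbands[sel]), 1)
            sel = dcauses == "primary_cancer"
            np.add.at(deaths["primary_cancer"], (dcodes[sel], dbands[sel]), 1)
            sel = np.isin(dcauses, ("primary_cancer", "other_cancer"))
            np.add.at(deaths["any_cancer"], (dcodes[sel], dbands[sel]), 1)

        idx = pd.MultiIndex.from_product(
            [range(n_groups), range(n_bands)], names=["g", "band"]
        ).to_frame(index=False)
        frame = pd.DataFrame(
            {
                "site": [groups[g][0] for g in idx["g"]],
                "age_group": [groups[g][1] for g in idx["g"]],
                "sex": sex,
                "band": idx["band"],
                "band_start": [scheme.edges[b] for b in idx["band"]],
                "band_end": [scheme.edges[b + 1] for b in idx["band"]],
                "midpoint": [scheme.midpoints[b] for b in idx["band"]],
                "person_years": py_cell.ravel(),
                "n_persons": persons.ravel(),
            }
        )
        for cat in DEATH_CATEGORIES:
            frame[f"deaths_{cat}"] = deaths[cat].ravel()
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return PersonTimeTable(data=data, scheme=scheme, cause_field=cause_field)


# ---------------------------------------------------------------------------
# margin validation
# ---------------------------------------------------------------------------

@dataclass
class MarginReport:
    """Outcome of comparing observed against expected margins."""

    comparisons: pd.DataFrame  # site, age_group, quantity, expected, observed, ok
    passed: bool

    def failures(self) -> pd.DataFrame:
        return self.comparisons[~self.comparisons["ok"]]


def validate_margins(observed: pd.DataFrame, expected: pd.DataFrame) -> MarginReport:
    """Check observed count margins against an expected margins table.

    Both frames carry ``site`` and ``age_group`` key columns plus any
    subset of count columns (e.g. ``individuals``, ``female``,
    ``deaths_cvd``, ``deaths_primary_cancer``, ``deaths_any_cancer``);
    only columns present in *both* are compared.  An empty expected table
    passes vacuously.
    """
    keys = ["site", "age_group"]
    count_cols = [
        c for c in expected.columns if c not in keys and c in observed.columns
    ]
    if expected.empty or not count_cols:
        return MarginReport(
            comparisons=pd.DataFrame(
                columns=keys + ["quantity", "expected", "observed", "ok"]
            ),
            passed=True,
        )
    obs = observed.set_index(keys)
    rows = []
    for key, exp_row in expected.set_index(keys).iterrows():
        for col in count_cols:
            have = int(obs.loc[key, col]) if key in obs.index else None
            want = int(exp_row[col])
            rows.append(
                {
                    "site": key[0],
                    "age_group": key[1],
                    "quantity": col,
                    "expected": want,
                    "observed": have,
                    "ok": have == want,
                }
            )
    comparisons = pd.DataFrame(rows)
    return MarginReport(comparisons=comparisons, passed=bool(comparisons["ok"].all()))


def margins_from_table(table: PersonTimeTable) -> pd.DataFrame:
    """Derive site x age-group count margins from a person-time table.

    ``individuals`` is the number of people contributing time to the
    first band (everyone enters at the start of coverage, so this is the
    stratum cohort size); death margins sum over bands.
    """
    pooled = table.data[table.data["sex"] == "all"]
    first = pooled[pooled["band"] == 0].set_index(["site", "age_group"])["n_persons"]
    sums = pooled.groupby(["site", "age_group"])[
        [f"deaths_{c}" for c in DEATH_CATEGORIES]
    ].sum()
    out = sums.copy()
    out.insert(0, "individuals", first)
    return out.reset_index()
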