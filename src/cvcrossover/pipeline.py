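"""End-to-end orchestration: cohort → person-time → rates → crossovers.

A :class:`RunConfig` describes one full analysis run — simulate or load
a cohort, tabulate person-time, fit cause-specific rate curves for
every site x age group (overall and, optionally, by sex), estimate
crossover points with bootstrap CIs, and write delimited-text reports
plus a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .crossover import (
    COMPARISONS,
    STATUS_CROSSED,
    bootstrap_crossover,
)
from .persontime import BandScheme, tabulate
from .rates import DEFAULT_MAX_CI_WIDTH, fit_rates, truncate_curve

__version__ = "0.1.0"

logger = logging.getLogger("cvcrossover")


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    ``input_mode`` is ``"simulate"`` (generate a synthetic cohort from
    the built-in preset, scaled by ``simulate_scale``) or ``"load"``
    (read ``cohort_path``).  Bootstrap replicates ``B`` default to 200;
    crossovers later than ``horizon`` years are reported as not
    occurring.
    """

    output_dir: str = "cvcrossover-run"
    input_mode: str = "simulate"
    cohort_path: str | None = None
    simulate_scale: float = 1.0
    band_edges: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 15.0, 25.0)
    horizon: float = 20.0
    ci_level: float = 0.95
    max_ci_width: float = DEFAULT_MAX_CI_WIDTH
    B: int = 200
    seed: int = 0
    cause_field: str = "underlying_cause"
    stratify_sex: bool = False
    age_interaction: bool = True
    log_scale_interpolation: bool = False
    p_disagree: float = 0.05

    def __post_init__(self) -> None:
        if self.input_mode not in ("simulate", "load"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "load" and not self.cohort_path:
            raise ValueError("load mode requires cohort_path")
        if self.B < 2:
            raise ValueError("B must be >= 2")
        scheme = BandScheme(tuple(self.band_edges))
        if not (scheme.start < self.horizon <= scheme.end):
            raise ValueError(
                f"horizon {self.horizon} outside band coverage "
                f"({scheme.start}, {scheme.end}]"
            )

    @property
    def scheme(self) -> BandScheme:
        return BandScheme(tuple(self.band_edges))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "band_edges" in raw:
            raw["band_edges"] = tuple(raw["band_edges"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_edges"] = list(d["band_edges"])
        return d


def _load_or_simulate(config: RunConfig) -> pd.DataFrame:
    if config.input_mode == "load":
        return sim.read_cohort(config.cohort_path)
    specs = sim.survivor_cohort_specs()
    sizes = sim.survivor_cohort_sizes(config.simulate_scale)
    return sim.simulate_cohort(
        specs,
        sizes,
        horizon=sim.MAX_HORIZON,
        seed=config.seed,
        p_disagree=config.p_disagree,
        female_fraction=sim.PRESET_FEMALE_FRACTION,
    )


def run(config: RunConfig) -> dict:
    """Execute a full analysis run and write the report bundle.

    Writes to ``config.output_dir``:

    * ``person_time.csv`` — one row per stratum x band cell,
    * ``rate_curves.csv`` — one row per stratum x band x cause with CI
      and suppression flag,
    * ``crossovers.csv`` — one row per site x age group x comparison
      (x sex, if stratified): crossover time, bootstrap CI, status and
      non-crossed replicate count,
    * ``manifest.json`` — config echo, seeds, version, timings and any
      strata that failed.

    Strata whose fits fail are logged, recorded in the manifest and
    excluded from the crossover table; the run itself continues.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme

    records = _load_or_simulate(config)
    table = tabulate(
        records, scheme, cause_field=config.cause_field, stratify_sex=config.stratify_sex
    )
    table.data.to_csv(out / "person_time.csv", index=False)

    sexes = ["all"] + (sorted(records["sex"].unique()) if config.stratify_sex else [])
    sites = sorted(records["site"].unique())
    curve_rows = []
    cross_rows = []
    failures = []
    causes = sorted({"cvd"} | set(COMPARISONS.values()))
    for sex in sexes:
        for site in sites:
            curves_by_cause = {}
            for cause in causes:
                try:
                    curves = fit_rates(
                        table,
                        site,
                        cause,
                        age_interaction=config.age_interaction,
                        sex=sex,
                        level=config.ci_level,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    failures.append(
                        {"site": site, "sex": sex, "cause": cause, "error": str(exc)}
                    )
                    continue
                curves_by_cause[cause] = curves
                for age_group, curve in curves.items():
                    trunc = truncate_curve(curve, config.max_ci_width)
                    if trunc.truncation_index is not None:
                        logger.info(
                            "curve truncated: site=%s age=%s sex=%s cause=%s band=%d",
                            site, age_group, sex, cause, trunc.truncation_index,
                        )
                    curve_rows.append(trunc.to_frame())
            if "cvd" not in curves_by_cause:
                continue
            for comparison, cancer_cause in COMPARISONS.items():
                if cancer_cause not in curves_by_cause:
                    continue
                for age_group in sorted(curves_by_cause["cvd"]):
                    try:
                        est = bootstrap_crossover(
                            records[records["sex"] == sex] if sex != "all" else records,
                            scheme,
                            site,
                            age_group,
                            comparison=comparison,
                            B=config.B,
                            seed=config.seed,
                            horizon=config.horizon,
                            cause_field=config.cause_field,
                            sex="all",
                            age_interaction=config.age_interaction,
                            log_scale=config.log_scale_interpolation,
                        )
                    except Exception as exc:
                        failures.append(
                            {
                                "site": site,
                                "sex": sex,
                                "age_group": age_group,
                                "comparison": comparison,
                                "error": str(exc),
                            }
                        )
                        continue
                    if est.unstable:
                        logger.warning(
                            "unstable bootstrap CI: site=%s age=%s comparison=%s "
                            "(%d/%d replicates did not cross)",
                            site, age_group, comparison, est.n_not_crossed, est.n_replicates,
                        )
                    cross_rows.append(
                        {
                            "site": site,
                            "age_group": age_group,
                            "sex": sex,
                            "comparison": comparison,
                            "status": est.status,
                            "crossover_years": est.time,
                            "ci_lower": est.ci_lower,
                            "ci_upper": est.ci_upper,
                            "n_replicates": est.n_replicates,
                            "n_not_crossed": est.n_not_crossed,
                            "unstable": est.unstable,
                        }
                    )

    pd.concat(curve_rows, ignore_index=True).to_csv(out / "rate_curves.csv", index=False)
    crossovers = pd.DataFrame(cross_rows)
    crossovers.to_csv(out / "crossovers.csv", index=False)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_records": int(len(records)),
        "n_failures": len(failures),
        "failures": failures,
        "elapsed_seconds": round(time.time() - t0, 3),
        "outputs": ["person_time.csv", "rate_curves.csv", "crossovers.csv"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "records": records,
        "table": table,
        "crossovers": crossovers,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# published denominators fixture
# ---------------------------------------------------------------------------

def fixture_table1() -> tuple[pd.DataFrame, dict]:
    """Published study-population margins for a 9-site survivor cohort.

    Returns the 27 site x age-group rows (individuals, female count and
    cardiovascular / primary-cancer / all-cancer death counts) shipped
    with the package, together with the study-level totals printed in
    the source report, for margin validation.
    """
    ref = importlib.resources.files("cvcrossover").joinpath("data/table1.csv")
    with importlib.resources.as_file(ref) as path:
        rows = pd.read_csv(path)
    totals = {
        "individuals": 104028,
        "female": 52713,
        "female_percent": 50.7,
        "deaths_cvd": 7091,
        "deaths_primary_cancer": 19758,
        "deaths_any_cancer": 25666,
    }
    return rows, totals
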