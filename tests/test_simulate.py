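"""Simulator correctness: exact inversion sampling, cause attribution,
analytic crossover ground truth, and cohort file round-trips."""

import numpy as np
import pandas as pd
import pytest

import cvcrossover as cv
from conftest import constant_specs, grid_crossover


class TestHazardSpec:
    def test_negative_hazard_rejected(self):
        with pytest.raises(cv.SimulationError, match="negative hazard"):
            cv.HazardSpec("cvd", "breast", "60-79", "constant", (1, 25), (-0.1,))

    def test_breakpoints_must_increase(self):
        with pytest.raises(cv.SimulationError, match="strictly increasing"):
            cv.HazardSpec("cvd", "breast", "60-79", "constant", (1, 1), (0.1,))

    def test_breakpoints_within_followup_window(self):
        with pytest.raises(cv.SimulationError, match="within"):
            cv.HazardSpec("cvd", "breast", "60-79", "linear", (0.5, 25), (0.1, 0.1))

    def test_value_count_must_match_kind(self):
        with pytest.raises(cv.SimulationError, match="values"):
            cv.HazardSpec("cvd", "breast", "60-79", "linear", (1, 25), (0.1,))

    def test_linear_rate_interpolates(self):
        s = cv.HazardSpec("cvd", "breast", "60-79", "linear", (1, 25), (0.0, 0.24))
        assert s.rate(13.0) == pytest.approx(0.12)

    def test_constant_rate_right_continuous(self):
        s = cv.HazardSpec("cvd", "breast", "60-79", "constant", (1, 10, 25), (0.1, 0.2))
        assert s.rate(10.0) == pytest.approx(0.2)
        assert s.rate(9.999999) == pytest.approx(0.1)


class TestSimulateCohort:
    def test_empty_spec_set_rejected(self):
        with pytest.raises(cv.SimulationError, match="empty"):
            cv.simulate_cohort([], 10)

    def test_missing_cause_names_stratum(self):
        specs = constant_specs(primary=0.1)[:3]
        with pytest.raises(cv.SimulationError, match="breast"):
            cv.simulate_cohort(specs, 10)

    def test_bad_horizon_rejected(self):
        with pytest.raises(cv.SimulationError, match="horizon"):
            cv.simulate_cohort(constant_specs(primary=0.1), 10, horizon=30.0)

    def test_zero_hazards_everyone_censored_alive(self):
        rec = cv.simulate_cohort(constant_specs(), 500, seed=1, censor_window=10.0)
        assert not rec["died"].any()
        assert np.allclose(rec["exit_years"], 11.0)
        assert (rec["underlying_cause"] == "").all()

    def test_truncated_exponential_mean(self):
        # single constant hazard, administrative censoring only at horizon 25:
        # time from entry is min(Exp(0.2), 24); closed-form expectation
        lam, tau, n = 0.2, 24.0, 100_000
        rec = cv.simulate_cohort(
            constant_specs(primary=lam), n, horizon=25.0, seed=11, censor_window=None
        )
        t = (rec["exit_years"] - rec["entry_years"]).to_numpy()
        expected_mean = (1.0 - np.exp(-lam * tau)) / lam  # E[min(T, tau)]
        var = 2.0 / lam**2 * (1 - np.exp(-lam * tau) * (1 + lam * tau)) - expected_mean**2
        se = np.sqrt(var / n)
        assert abs(t.mean() - expected_mean) < 3 * se

    def test_cause_split_matches_hazard_shares(self):
        # constant hazards 0.1 vs 0.3: P(cause b | death) = 0.75
        n = 100_000
        rec = cv.simulate_cohort(
            constant_specs(cvd=0.1, primary=0.3), n, seed=12, censor_window=None
        )
        deaths = rec[rec["died"]]
        frac_b = (deaths["underlying_cause"] == "primary_cancer").mean()
        se = np.sqrt(0.75 * 0.25 / len(deaths))
        assert abs(frac_b - 0.75) < 3 * se

    def test_event_times_follow_truncated_exponential(self):
        from scipy import stats

        lam, tau = 0.15, 24.0
        rec = cv.simulate_cohort(
            constant_specs(other=lam), 50_000, horizon=25.0, seed=13, censor_window=None
        )
        t = (rec.loc[rec["died"], "exit_years"] - 1.0).to_numpy()
        z = 1.0 - np.exp(-lam * tau)

        def cdf(x):
            return (1.0 - np.exp(-lam * np.asarray(x))) / z

        d, p = stats.kstest(t, cdf)
        crit = 1.628 / np.sqrt(len(t))  # alpha = 0.01
        assert d < crit

    def test_identical_seed_identical_cohort(self):
        specs = cv.survivor_cohort_specs(sites=("breast",))
        a = cv.simulate_cohort(specs, 300, seed=99)
        b = cv.simulate_cohort(specs, 300, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_immediate_cause_agreement_extremes(self):
        specs = constant_specs(cvd=0.1, primary=0.2, other=0.05)
        agree = cv.simulate_cohort(specs, 2000, seed=5, p_disagree=0.0)
        d = agree[agree["died"]]
        assert (d["underlying_cause"] == d["immediate_cause"]).all()
        flip = cv.simulate_cohort(specs, 2000, seed=5, p_disagree=1.0)
        d = flip[flip["died"]]
        assert (d["underlying_cause"] != d["immediate_cause"]).all()

    def test_per_person_uniform_censoring_window(self):
        rec = cv.simulate_cohort(
            constant_specs(), 5000, seed=6, censor_window=(5.0, 24.0)
        )
        fu = rec["exit_years"] - rec["entry_years"]
        assert fu.min() >= 5.0 and fu.max() <= 24.0
        assert fu.nunique() > 100  # genuinely per-person


class TestTrueCrossover:
    def test_linear_hazards_cross_where_algebra_says(self):
        # per 1,000 p-y: cvd = 2 + t rises, cancer = 20 - t falls -> t = 9
        a = cv.HazardSpec("cvd", "x", "60-79", "linear", (1, 25), (3e-3, 27e-3))
        b = cv.HazardSpec(
            "primary_cancer", "x", "60-79", "linear", (1, 20, 25), (19e-3, 0.0, 0.0)
        )
        assert cv.true_crossover(a, b, 25.0) == pytest.approx(9.0, abs=1e-9)

    def test_parallel_constants_never_cross(self):
        a = cv.HazardSpec("cvd", "x", "60-79", "constant", (1, 25), (5e-3,))
        b = cv.HazardSpec("primary_cancer", "x", "60-79", "constant", (1, 25), (10e-3,))
        assert cv.true_crossover(a, b, 25.0) is None

    def test_piecewise_constant_swap_crosses_at_breakpoint(self):
        bands = (1.0, 5.0, 10.0, 15.0, 25.0)
        a = cv.HazardSpec("cvd", "x", "60-79", "constant", bands, (3e-3, 4e-3, 8e-3, 8e-3))
        b = cv.HazardSpec(
            "primary_cancer", "x", "60-79", "constant", bands, (3e-3, 8e-3, 4e-3, 4e-3)
        )
        t = cv.true_crossover(a, b, 25.0)
        oracle = grid_crossover(a.rate, b.rate, 1.0, 25.0)
        assert t == pytest.approx(10.0, abs=1e-9)
        assert t == pytest.approx(oracle, abs=2e-4)

    def test_matches_grid_oracle_on_random_piecewise_specs(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(50):
            kind = rng.choice(["constant", "linear"])
            bp = np.sort(rng.uniform(1.0, 25.0, size=3))
            bp = tuple([1.0] + [float(x) for x in bp if 1.5 < x < 24.5] + [25.0])
            nv = len(bp) - 1 if kind == "constant" else len(bp)
            a = cv.HazardSpec("cvd", "x", "60-79", kind,
                              bp, tuple(rng.uniform(0, 0.05, size=nv)))
            b = cv.HazardSpec("primary_cancer", "x", "60-79", kind,
                              bp, tuple(rng.uniform(0, 0.05, size=nv)))
            t = cv.true_crossover(a, b, 25.0)
            oracle = grid_crossover(a.rate, b.rate, 1.0, 25.0)
            if oracle is None or t is None:
                assert t == oracle
            else:
                assert t == pytest.approx(oracle, abs=2e-4)
                checked += 1
        assert checked >= 10

    def test_linear_crossing_preset_truth_is_exact(self):
        for t_star in (3.0, 8.0, 14.5, 18.0):
            specs = cv.linear_crossing_specs(t_star)
            cvd = next(s for s in specs if s.cause == "cvd")
            cancer = next(s for s in specs if s.cause == "primary_cancer")
            assert cv.true_crossover(cvd, cancer, 25.0) == pytest.approx(
                t_star, abs=1e-9
            )

    def test_mismatched_strata_rejected(self):
        a = cv.HazardSpec("cvd", "x", "60-79", "constant", (1, 25), (5e-3,))
        b = cv.HazardSpec("primary_cancer", "y", "60-79", "constant", (1, 25), (1e-3,))
        with pytest.raises(cv.SimulationError, match="same stratum"):
            cv.true_crossover(a, b, 25.0)


class TestCohortFiles:
    def test_roundtrip_identity(self, tmp_path):
        rec = cv.simulate_cohort(
            cv.survivor_cohort_specs(sites=("breast", "lung")), 500, seed=21
        )
        path = tmp_path / "cohort.csv"
        cv.write_cohort(rec, path)
        back = cv.read_cohort(path)
        pd.testing.assert_frame_equal(rec, back)

    def test_exit_before_entry_names_line(self, tmp_path):
        rec = cv.simulate_cohort(cv.survivor_cohort_specs(sites=("breast",)), 20, seed=3)
        rec.loc[5, "exit_years"] = 0.5  # data row 6 -> physical line 7
        path = tmp_path / "bad.csv"
        cv.write_cohort(rec, path)
        with pytest.raises(cv.CohortFileError, match="line 7"):
            cv.read_cohort(path)

    def test_unknown_cause_rejected(self, tmp_path):
        rec = cv.simulate_cohort(
            constant_specs(primary=0.2), 20, seed=3, censor_window=None
        )
        assert rec["died"].any()
        i = rec.index[rec["died"]][0]
        rec.loc[i, "underlying_cause"] = "volcano"
        path = tmp_path / "bad.csv"
        cv.write_cohort(rec, path)
        with pytest.raises(cv.CohortFileError, match=f"line {i + 2}"):
            cv.read_cohort(path)

    def test_header_only_file_is_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(cv.COHORT_COLUMNS) + "\n")
        back = cv.read_cohort(path)
        assert len(back) == 0
        assert list(back.columns) == list(cv.COHORT_COLUMNS)
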