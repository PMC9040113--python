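import numpy as np
import pytest

import cvcrossover as cv


def constant_specs(
    cvd=0.0, primary=0.0, other_cancer=0.0, other=0.0,
    site="breast", age="60-79",
):
    """Four constant hazards (events per person-year) for one stratum."""
    vals = {
        "cvd": cvd,
        "primary_cancer": primary,
        "other_cancer": other_cancer,
        "other": other,
    }
    return [
        cv.HazardSpec(c, site, age, "constant", (1.0, 25.0), (v,))
        for c, v in vals.items()
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """Multi-site preset cohort, small enough for fast tests."""
    return cv.simulate_cohort(
        cv.survivor_cohort_specs(sites=("breast", "lung", "colorectal")),
        2000,
        seed=42,
        female_fraction=cv.simulate.PRESET_FEMALE_FRACTION,
    )


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return cv.tabulate(small_cohort)


def grid_crossover(rate_a, rate_b, t0, t1, step=1e-4):
    """Brute-force first negative -> non-negative sign change of a - b."""
    t = np.arange(t0, t1 + step, step)
    d = np.asarray(rate_a(t)) - np.asarray(rate_b(t))
    below = d < 0
    change = below[:-1] & ~below[1:]
    idx = np.flatnonzero(change)
    if idx.size == 0:
        return None
    i = idx[0]
    # refine linearly within the bracketing step
    d0, d1 = d[i], d[i + 1]
    if d1 == d0:
        return float(t[i + 1])
    frac = -d0 / (d1 - d0)
    return float(t[i] + min(max(frac, 0.0), 1.0) * step)
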