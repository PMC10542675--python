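import numpy as np
import pandas as pd
import pytest

from drisk.cohort import apply_analysis_filters, build_panel
from drisk.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across tests (seeded)."""
    cfg = SimConfig(n_participants=250)
    raw, truth = simulate_cohort(cfg, seed=11)
    return raw, truth, cfg


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    raw, truth, cfg = small_cohort
    panel, report = apply_analysis_filters(build_panel(raw))
    return panel


def random_behaviour_row(rng):
    """A random valid raw-response row (possibly with missing fields)."""
    def maybe(v, p=0.07):
        return np.nan if rng.random() < p else v

    row = {
        "drinks_per_week": maybe(round(float(rng.uniform(0, 30)), 1)),
        "max_drinks_per_occasion": maybe(round(float(rng.uniform(0, 10)), 1)),
        "abstains": maybe(bool(rng.random() < 0.2)),
        "smoking": maybe(str(rng.choice(["none", "occasional", "weekly_or_more"]))),
        "height_m": maybe(round(float(rng.uniform(1.4, 2.0)), 2)),
        "weight_kg": maybe(round(float(rng.uniform(45, 140)), 1)),
        "light_min": maybe(round(float(rng.uniform(0, 400)), 0)),
        "moderate_min": maybe(round(float(rng.uniform(0, 400)), 0)),
        "vigorous_min": maybe(round(float(rng.uniform(0, 200)), 0)),
    }
    for i in range(1, 15):
        row[f"mind_{i}"] = maybe(float(rng.choice([0.0, 0.5, 1.0])))
    for i in range(1, 12):
        row[f"cog_{i}"] = maybe(int(rng.integers(0, 6)))
    for pref in ("htn", "chol", "diab"):
        row[f"{pref}_diagnosis"] = maybe(str(rng.choice(["yes", "no", "unsure"])))
        row[f"{pref}_checkups"] = maybe(bool(rng.random() < 0.6))
        row[f"{pref}_managed"] = maybe(str(rng.choice(
            ["medically_managed", "working_toward", "unmanaged", "n/a"])))
    return row


@pytest.fixture(scope="session")
def random_rows():
    rng = np.random.default_rng(20240917)
    return pd.DataFrame([random_behaviour_row(rng) for _ in range(2000)])
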