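import numpy as np
import pandas as pd
import pytest

from engagejm import (
    GeneratorConfig,
    LinkedCohort,
    LongitudinalDataset,
    SurvivalDataset,
    generate_cohort,
)


def make_cohort(long_rows, surv_rows) -> LinkedCohort:
    """Build a LinkedCohort from plain tuples (helper for handcrafted fixtures)."""
    lf = pd.DataFrame(long_rows, columns=["subject_id", "time_weeks", "engagement_days"])
    sf = pd.DataFrame(
        surv_rows,
        columns=["subject_id", "event_time_weeks", "event", "age_years", "male", "race"],
    )
    return LinkedCohort(LongitudinalDataset(lf), SurvivalDataset(sf))


@pytest.fixture
def toy_cohort() -> LinkedCohort:
    """Two subjects: A observed weeks 0-2 then drops out at week 3; B censored."""
    return make_cohort(
        [("A", 0, 5.0), ("A", 1, 4.0), ("A", 2, 3.0), ("B", 0, 6.0), ("B", 1, 6.5)],
        [("A", 3.0, 1, 30.0, 1, "white"), ("B", 2.0, 0, 45.0, 0, "black")],
    )


@pytest.fixture(scope="session")
def small_mnar_cohort():
    """A small study-like cohort with informative dropout (shared across tests)."""
    cohort, truth = generate_cohort(GeneratorConfig(n_subjects=80), seed=42)
    return cohort, truth


@pytest.fixture(scope="session")
def no_dropout_config() -> GeneratorConfig:
    """Nearly no dropout: tiny baseline hazard, no staggered censoring."""
    return GeneratorConfig(
        n_subjects=300, alpha=0.0, rates=(1e-6,) * 5, staggered_fraction=0.0, gamma=(0,) * 5
    )


def rng_cohort_frames(rng: np.random.Generator, n_subjects: int = 4):
    """Random valid cohort tables (for round-trip property tests)."""
    races = np.array(["white", "black", "hispanic", "other"])
    long_rows, surv_rows = [], []
    for i in range(n_subjects):
        sid = f"P{i}"
        n_i = int(rng.integers(1, 6))
        times = np.sort(rng.uniform(0, 20, n_i))
        times = np.unique(np.round(times, 3))
        for t in times:
            long_rows.append((sid, float(t), float(rng.uniform(0, 7))))
        event_time = float(times.max() + rng.uniform(0.01, 5.0))
        surv_rows.append(
            (
                sid,
                event_time,
                int(rng.integers(0, 2)),
                float(rng.uniform(18, 60)),
                int(rng.integers(0, 2)),
                str(rng.choice(races)),
            )
        )
    lf = pd.DataFrame(long_rows, columns=["subject_id", "time_weeks", "engagement_days"])
    sf = pd.DataFrame(
        surv_rows,
        columns=["subject_id", "event_time_weeks", "event", "age_years", "male", "race"],
    )
    return lf, sf
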