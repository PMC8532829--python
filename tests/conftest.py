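import numpy as np
import pandas as pd
import pytest

from fatgrade import pipeline, synth


@pytest.fixture(scope="session")
def default_cohort():
    """One default 50-animal cohort (Table-1-style calibration), seed 123."""
    import dataclasses

    cfg = dataclasses.replace(synth.CohortConfig(), seed=123)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def measured_table():
    """Default cohort simulated, rendered and measured in memory, seed 123."""
    return pipeline.simulate_and_measure(seed=123)


@pytest.fixture()
def noise_free_config():
    """Image config with zero intensity noise and zero brightness jitter."""
    return synth.noise_free()


def make_record(fat_fraction: float) -> pd.Series:
    """Minimal animal record for image-generation tests."""
    return pd.Series(
        {
            "animal_id": "T001",
            "seurop_score": 5,
            "seurop_label": "2",
            "hcw_kg": 360.0,
            "cutting_fat_pct": 9.0,
            "true_fat_fraction_pct": fat_fraction,
        }
    )


@pytest.fixture()
def record_factory():
    return make_record
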