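import numpy as np
import pandas as pd
import pytest

from metabopls import CohortSimConfig, PeakTable, SampleMetadata, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """3 features x 4 samples (2 study, 2 QC) toy peak table + metadata."""
    features = pd.DataFrame(
        {
            "compound": ["alanine", "choline", "histidine"],
            "formula": ["C3H7NO2", "C5H13NO", "C6H9N3O2"],
            "mz": [90.054955, 104.107384, 156.076614],
            "rt": [10.2, 15.0, 14.0],
            "mode": ["pos", "pos", "pos"],
        },
        index=pd.Index(["F1", "F2", "F3"], name="feature_id"),
    )
    intens = pd.DataFrame(
        {
            "S1": [100.0, 50.0, 10.0],
            "S2": [120.0, 55.0, 12.0],
            "QC1": [110.0, 52.0, 11.0],
            "QC2": [112.0, 53.0, 11.5],
        },
        index=features.index,
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "injection_order": [2, 3, 1, 4],
                "sample_type": ["study", "study", "qc", "qc"],
                "outcome_label": [0.0, 1.0, np.nan, np.nan],
            },
            index=pd.Index(["S1", "S2", "QC1", "QC2"], name="sample_id"),
        )
    )
    return PeakTable(features, intens), meta


@pytest.fixture
def default_cohort():
    return generate_cohort(CohortSimConfig(seed=11))


def make_cohort(**overrides):
    return generate_cohort(CohortSimConfig(**overrides))
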