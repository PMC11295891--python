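import numpy as np
import pandas as pd
import pytest

from pupillight import qc, synth


@pytest.fixture(scope="session")
def default_config() -> synth.GeneratorConfig:
    return synth.GeneratorConfig()


@pytest.fixture(scope="session")
def clean_config() -> synth.GeneratorConfig:
    """Generator without missingness/saturation, for analyses that assume QC-clean data."""
    return synth.GeneratorConfig(
        low_confidence_fraction=0.0, saturation_probability=0.0, misestimate_probability=0.0
    )


@pytest.fixture(scope="session")
def small_cohort(default_config) -> list[synth.Participant]:
    return synth.sample_cohort(12, 1234, default_config)


@pytest.fixture(scope="session")
def field_observations(small_cohort, default_config) -> pd.DataFrame:
    return synth.simulate_field(small_cohort, 40, default_config, 99)


@pytest.fixture(scope="session")
def qc_field(field_observations) -> pd.DataFrame:
    retained, _ = qc.apply_filters(field_observations)
    return retained


def make_observations(
    pupil, confidence=None, saturated=None, participant="P0", condition="field", medi=10.0
) -> pd.DataFrame:
    """Hand-built observation table for QC edge-case tests."""
    pupil = np.asarray(pupil, dtype=float)
    n = pupil.size
    return pd.DataFrame(
        {
            "participant_id": participant if isinstance(participant, (list, np.ndarray)) else [participant] * n,
            "timestamp_s": np.arange(n) * 10.0,
            "condition": condition,
            "pupil_mm": pupil,
            "confidence": np.ones(n) if confidence is None else np.asarray(confidence, dtype=float),
            "saturated": np.zeros(n, dtype=bool) if saturated is None else np.asarray(saturated, dtype=bool),
            "melanopic_edi_lx": medi,
            "illuminance_lx": medi,
        }
    )
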