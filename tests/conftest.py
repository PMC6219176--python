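import numpy as np
import pandas as pd
import pytest

from fetalweight import GeneratorConfig, generate_cohort, estimate_biometric


@pytest.fixture(scope="session")
def default_cohort():
    """Large default cohort reused by the calibration-sensitive tests."""
    return generate_cohort(GeneratorConfig(n=10_000, seed=2024))


@pytest.fixture(scope="session")
def default_cohort_frame(default_cohort):
    frame = pd.DataFrame(
        {
            "fh_cm": [r.fh_cm for r in default_cohort],
            "ga_weeks": [r.ga_weeks for r in default_cohort],
            "efw_recorded_g": [r.efw_recorded_g for r in default_cohort],
            "abw_g": [r.abw_g for r in default_cohort],
        }
    )
    frame["hc_est_mm"] = [
        estimate_biometric("australian", "HC", g) for g in frame["ga_weeks"]
    ]
    frame["ac_est_mm"] = [
        estimate_biometric("australian", "AC", g) for g in frame["ga_weeks"]
    ]
    return frame


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(GeneratorConfig(n=300, seed=7))
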