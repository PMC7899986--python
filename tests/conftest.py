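import pytest

import polmorph as pm


@pytest.fixture(scope="session")
def calibration():
    """Packaged (distance, probability) calibration pairs."""
    return pm.datasets.discrimination_calibration()


@pytest.fixture(scope="session")
def calibrated_model(calibration):
    return pm.fit_psychometric(calibration, seed=1)


@pytest.fixture(scope="session")
def records():
    """Packaged tagged-plant records expanded from the count tables."""
    return pm.datasets.deep_lead_records()


@pytest.fixture(scope="session")
def natural_records(records):
    return [r for r in records if r.treatment == "natural"]
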