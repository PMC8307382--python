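from pathlib import Path

import pytest

from tutorplan.fixtures import build_af_fixture, build_backpain_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def af():
    """(kb, patient_id, scripted learner) for the anticoagulation use case."""
    return build_af_fixture()


@pytest.fixture
def backpain():
    """(kb, patient_id, scripted learner) for the lower-back-pain use case."""
    return build_backpain_fixture()
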