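import numpy as np
import pytest

from cjskit.design import StudyDesign, simple_design
from cjskit.encounter import EncounterHistory


@pytest.fixture(scope="session")
def default_design() -> StudyDesign:
    return StudyDesign.default()


@pytest.fixture
def design5() -> StudyDesign:
    return simple_design(5)


def make_histories(rows, design, sex="female", panel="panel-1"):
    """Build EncounterHistory objects from (count, detections) pairs."""
    out = []
    i = 0
    for count, det in rows:
        for _ in range(count):
            i += 1
            out.append(EncounterHistory(
                f"h{i:05d}", sex, panel, np.asarray(det, dtype=np.int8)))
    return out


@pytest.fixture
def history_factory():
    return make_histories
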