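import numpy as np
import pytest

from heartsmap_u import (
    AssessmentRecord,
    Timepoint,
    default_instrument,
)


@pytest.fixture(scope="session")
def defn():
    return default_instrument()


def make_record(
    scores: dict[str, int] | None = None,
    participant_id: str = "P0",
    timepoint: Timepoint = Timepoint.BASELINE,
    accessed: dict[str, bool] | None = None,
) -> AssessmentRecord:
    """Build a valid record: unlisted sections score 0, access flags are
    auto-filled (False) for every scored-positive section."""
    base = {s: 0 for s in default_instrument().sections}
    base.update(scores or {})
    flags = {s: False for s, v in base.items() if v >= 1}
    flags.update(accessed or {})
    return AssessmentRecord(
        participant_id=participant_id,
        timepoint=timepoint,
        section_scores=base,
        access_flags=flags,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
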