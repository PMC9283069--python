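import numpy as np
import pytest

from anthro.cohort import Cohort, ParticipantRecord
from anthro.simulate import default_params, generate_cohort


def make_record(**overrides) -> ParticipantRecord:
    base = dict(
        id="r1", sex="female", age=42, height=1.55, weight=66.1, waist=92.0,
        hip=102.0, wrist=16.2, arm=29.5, sbp=113.0, dbp=74.0, pulse=72.0,
        on_antihypertensive=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


def random_physiologic_records(n: int, seed: int = 0) -> list[ParticipantRecord]:
    """Uniformly random records well inside the physiologic ranges."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        sbp = rng.uniform(95, 180)
        records.append(ParticipantRecord(
            id=f"x{i}",
            sex="female" if rng.uniform() < 0.5 else "male",
            age=int(rng.integers(18, 81)),
            height=rng.uniform(1.4, 1.95),
            weight=rng.uniform(45, 130),
            waist=rng.uniform(60, 140),
            hip=rng.uniform(70, 150),
            wrist=rng.uniform(12, 22),
            arm=rng.uniform(20, 45),
            sbp=sbp,
            dbp=rng.uniform(50, min(sbp - 5, 110)),
            pulse=rng.uniform(45, 110),
            on_antihypertensive=bool(rng.uniform() < 0.05),
        ))
    return records


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The default study conditions at the reference size n=1150."""
    return generate_cohort(default_params(), seed=42)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    return generate_cohort(default_params().model_copy(update={"n": 400}), seed=7)
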