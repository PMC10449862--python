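import numpy as np
import pytest

from dynexpect.behavior import ChoiceEvent, ChoiceTimeseries
from dynexpect.outcomes import CONDITION_ORDER, OutcomeClass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_3s():
    """Standard 50-ms stop-locked grid over the last 3 s of deceleration."""
    return np.arange(-3.0, 1e-9, 0.05)


def make_series(grid, values, outcome=OutcomeClass.MATCH, participant="P1", trial=0,
                n_switches=1, sure_amount=5.0):
    return ChoiceTimeseries(
        grid=grid,
        values=np.asarray(values),
        outcome=outcome,
        sure_amount=sure_amount,
        participant=participant,
        trial=trial,
        n_switches=n_switches,
    )


@pytest.fixture
def random_participant_curves(rng, grid_3s):
    """Participant-level condition curves with random values in [0, 1]."""
    from dynexpect.behavior import ConditionCurves

    out = {}
    for pid in ["P1", "P2", "P3", "P4", "P5"]:
        curves = {oc: rng.random(grid_3s.size) for oc in CONDITION_ORDER}
        out[pid] = ConditionCurves(grid=grid_3s, curves=curves, level="participant")
    return out
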