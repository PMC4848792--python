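import numpy as np
import pytest

from gcredist.cause_map import default_cause_map
from gcredist.causes import CAUSE_IDS
from gcredist.strata import Stratum, StratumDataset
from gcredist.taxonomy import default_target_matrix


@pytest.fixture(scope="session")
def icd9_map():
    return default_cause_map(9)


@pytest.fixture(scope="session")
def icd10_map():
    return default_cause_map(10)


@pytest.fixture(scope="session")
def target_matrix():
    return default_target_matrix()


def make_dataset(
    y,
    M=None,
    year=None,
    state_idx=None,
    place_idx=None,
    race_idx=None,
    targets=("B.2", "B.3.1"),
    n_states=1,
    n_places=1,
    n_races=1,
    pred=None,
):
    """Hand-build a StratumDataset for model-level tests.

    ``pred`` optionally supplies (ids, year, M, state_idx, place_idx, race_idx)
    for the prediction part.
    """
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    J = len(CAUSE_IDS)
    M = np.zeros((n, J), dtype=np.int8) if M is None else np.asarray(M, dtype=np.int8)
    year = np.zeros(n) if year is None else np.asarray(year, dtype=float)
    zeros = np.zeros(n, dtype=np.int64)
    state_idx = zeros if state_idx is None else np.asarray(state_idx, dtype=np.int64)
    place_idx = zeros if place_idx is None else np.asarray(place_idx, dtype=np.int64)
    race_idx = zeros if race_idx is None else np.asarray(race_idx, dtype=np.int64)
    kwargs = {}
    if pred is not None:
        ids, py, pM, ps, pp, pr = pred
        kwargs = dict(
            pred_ids=tuple(ids),
            pred_year=np.asarray(py, dtype=float),
            pred_M=np.asarray(pM, dtype=np.int8),
            pred_state_idx=np.asarray(ps, dtype=np.int64),
            pred_place_idx=np.asarray(pp, dtype=np.int64),
            pred_race_idx=np.asarray(pr, dtype=np.int64),
        )
    return StratumDataset(
        stratum=Stratum(10, "male", "70-74", "heart_failure"),
        targets=tuple(targets),
        dropped_targets=(),
        state_levels=tuple(f"S{i}" for i in range(n_states)),
        place_levels=tuple(f"P{i}" for i in range(n_places)),
        race_levels=tuple(f"R{i}" for i in range(n_races)),
        y=y,
        year=year,
        M=M,
        state_idx=state_idx,
        place_idx=place_idx,
        race_idx=race_idx,
        **kwargs,
    )
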