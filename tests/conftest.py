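import numpy as np
import pytest

from pupilmem.config import AnalysisConfig, SimulationConfig
from pupilmem import synth


@pytest.fixture(scope="session")
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tiny_cfg():
    # small but structurally complete: every condition/item type present
    return SimulationConfig(n_participants=6, n_blocks=3, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    events, recordings, pairs, items, gt = synth.simulate(tiny_cfg, seed=7)
    return dict(events=events, recordings=recordings, pairs=pairs,
                items=items, gt=gt, cfg=tiny_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_recording(pupil, participant="P001", block=1, rate=250.0, valid=None):
    from pupilmem.dataio import PupilRecording
    pupil = np.asarray(pupil, dtype=float)
    n = len(pupil)
    step = 1000.0 / rate
    time = (np.arange(n) * step).astype(np.int64)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return PupilRecording(participant_id=participant, block_id=block,
                          sampling_rate=rate, time=time, pupil=pupil,
                          valid=np.asarray(valid, dtype=bool))
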