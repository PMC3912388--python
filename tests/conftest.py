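import numpy as np
import pytest

from cerecoh import simulate as sim
from cerecoh.config import AnalysisConfig
from cerecoh.core import ContinuousSignal, EpochSet


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def train_protocol():
    """33-trial 100 Hz / 1 s train protocol, one train every 5 s."""
    return sim.gen_stim_protocol("train", 33)


@pytest.fixture(scope="session")
def triplet_protocol():
    """72-trial triplet-burst protocol, one burst every 2 s."""
    return sim.gen_stim_protocol("triplet", 72)


@pytest.fixture(scope="session")
def coupled_pair():
    """One 60-s theta-coupled LFP pair (x drives y) plus ground truth."""
    return sim.gen_coupled_lfp(sim.CoupledLFPParams(duration=60.0, seed=11))


@pytest.fixture(scope="session")
def full_epochs():
    return EpochSet([[0.0, 60.0]], "all")


def white_pair(seed: int, duration: float = 100.0, fs: float = 2000.0):
    """Two independent unit-variance white-noise channels."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    return (ContinuousSignal(rng.standard_normal(n), fs=fs, label="a"),
            ContinuousSignal(rng.standard_normal(n), fs=fs, label="b"))
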