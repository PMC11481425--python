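import numpy as np
import pytest

from hyperdifc import PairedBlock, Recording, SynthConfig, generate_pair_session
from hyperdifc.montage import unit_positions
from hyperdifc.recording import EEG, EOG


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """Small but structurally complete session: 8 EEG (incl. mastoids) + EOG,
    20 s blocks at 1000 Hz."""
    return SynthConfig(n_lover_pairs=1, n_stranger_pairs=1, fs=1000.0,
                       block_s=20.0, n_eeg=8, bad_channel_prob=0.0, seed=7)


@pytest.fixture(scope="session")
def lover_session(tiny_config):
    return generate_pair_session(tiny_config, "L01", "lover")


def make_recording(data: np.ndarray, names: list[str], fs: float = 100.0,
                   eog: np.ndarray | None = None,
                   subject_id: str = "s1", role: str = "male") -> Recording:
    """Hand-built recording over real 10-20 positions for unit tests."""
    channels = [(n, EEG) for n in names]
    rows = [np.asarray(data, dtype=float)]
    if eog is not None:
        channels.append(("EOG", EOG))
        rows.append(np.asarray(eog, dtype=float)[None, :])
    return Recording(subject_id=subject_id, role=role, fs=fs,
                     channels=channels, data=np.vstack(rows),
                     montage=unit_positions(names))


def make_pair(male: Recording, female: Recording, pair_id: str = "P1",
              relationship: int = 1, hand: str = "on") -> PairedBlock:
    return PairedBlock(pair_id=pair_id, relationship=relationship, hand=hand,
                       male=male, female=female)
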