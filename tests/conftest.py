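import numpy as np
import pytest

from neofba.io import EEGRecording
from neofba.synthetic import CohortConfig, simulate_recording

FS = 256.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


def make_recording(signal: np.ndarray, labels=None, fs: float = FS, **kw) -> EEGRecording:
    """Minimal referential recording around a raw signal matrix."""
    signal = np.atleast_2d(signal)
    if labels is None:
        labels = ["Fp1", "Fp2", "C3", "C4", "Cz", "T3", "T4", "O1", "O2"][: signal.shape[0]]
    defaults = dict(subject_id="t0", pma_weeks=30.0, ga_weeks=26.0,
                    sample_rate_hz=fs, channel_labels=labels, signal=signal)
    defaults.update(kw)
    return EEGRecording(**defaults)


@pytest.fixture(scope="session")
def short_sim_recording() -> EEGRecording:
    """One 3-minute synthetic referential recording at 30 weeks PMA."""
    cfg = CohortConfig(epoch_minutes=3.0, seed=11)
    return simulate_recording(30.0, 0.0, cfg, seed=11)
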