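import numpy as np
import pytest

from cyclicity import Recording


@pytest.fixture
def small_recording() -> Recording:
    rng = np.random.default_rng(42)
    return Recording(rng.normal(size=(4, 60)), ["a", "b", "c", "d"], dt=0.72, id="r0")


@pytest.fixture
def recording_csv(tmp_path, small_recording):
    path = tmp_path / "rec.csv"
    small_recording.to_frame().to_csv(path, index=False)
    return path
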