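import numpy as np
import pytest

from fogbench.preprocess import Recording


def sinusoid_recording(
    freq_hz: float,
    fs: float = 200.0,
    duration_s: float = 10.0,
    amplitude: float = 1.0,
    axis: int = 2,
    offset: np.ndarray | None = None,
) -> Recording:
    """A single-axis sinusoid recording for spectral checks."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    samples = np.zeros((n, 3))
    if offset is not None:
        samples += np.asarray(offset)[None, :]
    samples[:, axis] += amplitude * np.sin(2 * np.pi * freq_hz * t)
    return Recording(subject_id="test", session="OFF", fs=fs, samples=samples)


def cosine_window(
    bin_index: int, n: int = 128, amplitude: float = 1.0, axis: int = 0
) -> np.ndarray:
    """An (n, 3) window holding a bin-aligned cosine on one axis."""
    w = np.zeros((n, 3))
    w[:, axis] = amplitude * np.cos(2 * np.pi * bin_index * np.arange(n) / n)
    return w


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
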