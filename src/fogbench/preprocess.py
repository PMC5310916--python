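"""Signal conditioning for waist-worn accelerometer recordings.

The detection pipeline operates on triaxial acceleration sampled at 200 Hz.
Before feature extraction the signal is decimated to 40 Hz (sufficient for
human-movement analysis and for the 3–8 Hz freeze band), low-pass filtered
with a 2nd-order Butterworth at 15 Hz to strip high-frequency noise, and cut
into 128-sample windows (3.2 s) overlapped at 50% (stride 1.6 s).

All times are seconds, 0-based, with half-open interval conventions: a window
starting at ``t`` covers ``[t, t + 3.2)``.  Acceleration is kept in g
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

# Pipeline constants: defaults reproduce the published configuration.
FS_RAW = 200.0
FS_TARGET = 40.0
FILTER_ORDER = 2
FILTER_CUTOFF_HZ = 15.0
WINDOW_SAMPLES = 128
WINDOW_OVERLAP = 0.5

#: Duration of one analysis window in seconds (128 samples at 40 Hz).
WINDOW_DURATION_S = WINDOW_SAMPLES / FS_TARGET
#: Stride between window starts in seconds (50% overlap).
WINDOW_STRIDE_S = WINDOW_DURATION_S * (1.0 - WINDOW_OVERLAP)
#: A single positive window already spans 3.2 s, so no shorter episode can be
#: reported; detection timing resolves to one stride (1.6 s).
MIN_DETECTABLE_EPISODE_S = WINDOW_DURATION_S


@dataclass
class Recording:
    """A triaxial acceleration time series for one subject/session.

    Parameters
    ----------
    subject_id : opaque subject identifier.
    session : ``"OFF"`` (unmedicated-like) or ``"ON"`` (medicated-like).
    fs : sampling rate in Hz.
    t0 : start time of the first sample, seconds.
    samples : array of shape (n, 3), columns (ax, ay, az) in g.
    """

    subject_id: str
    session: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(
                f"samples must have shape (n, 3), got {self.samples.shape}"
            )
        if len(self.samples) < 1:
            raise ValueError("recording must contain at least one sample")
        if self.session not in ("OFF", "ON"):
            raise ValueError(f"session must be 'OFF' or 'ON', got {self.session!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "ax_g": self.samples[:, 0],
                "ay_g": self.samples[:, 1],
                "az_g": self.samples[:, 2],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        subject_id: str = "unknown",
        session: str = "OFF",
        fs: float | None = None,
    ) -> "Recording":
        """Load a ``time_s,ax_g,ay_g,az_g`` CSV; fs inferred from timestamps
        unless given."""
        df = pd.read_csv(path)
        required = ["time_s", "ax_g", "ay_g", "az_g"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"signal CSV missing columns: {missing}")
        t = df["time_s"].to_numpy(dtype=float)
        if fs is None:
            if len(t) < 2:
                raise ValueError("cannot infer sampling rate from one sample")
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(
            subject_id=subject_id,
            session=session,
            fs=float(fs),
            t0=float(t[0]),
            samples=df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        )


@dataclass
class WindowSeries:
    """Fixed-length overlapping windows — the unit of classification.

    ``windows`` has shape (n_windows, N, 3); ``start_times`` are seconds.
    """

    subject_id: str
    session: str
    fs: float
    windows: np.ndarray
    start_times: np.ndarray
    n_per_window: int = WINDOW_SAMPLES
    stride: int = WINDOW_SAMPLES // 2

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.start_times = np.asarray(self.start_times, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[1:] != (self.n_per_window, 3):
            raise ValueError(
                f"windows must have shape (n, {self.n_per_window}, 3), "
                f"got {self.windows.shape}"
            )
        if len(self.windows) != len(self.start_times):
            raise ValueError("windows and start_times length mismatch")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def duration_s(self) -> float:
        return self.n_per_window / self.fs

    @property
    def stride_s(self) -> float:
        return self.stride / self.fs


def resample(rec: Recording, target_fs: float = FS_TARGET) -> Recording:
    """Resample a recording to ``target_fs`` with polyphase decimation.

    ``scipy.signal.resample_poly`` applies its built-in anti-alias low-pass
    before decimation, so content above the output Nyquist (20 Hz for the
    default 200→40 Hz case) is suppressed rather than folded into the band of
    interest.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling not supported: target {target_fs} Hz > source {rec.fs} Hz"
        )
    if target_fs == rec.fs:
        return replace(rec, samples=rec.samples.copy())
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(
        rec.samples, ratio.numerator, ratio.denominator, axis=0, padtype="line"
    )
    return replace(rec, fs=target_fs, samples=out)


def lowpass(
    rec: Recording,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> Recording:
    """Causal Butterworth low-pass, applied once per axis.

    Forward-only (not zero-phase) filtering: the method targets real-time
    execution on the sensor node, which cannot filter backwards.  The state
    is initialised to the steady state for the first sample so the constant
    gravity offset does not produce a switch-on transient.
    """
    if rec.fs <= 2 * cutoff_hz:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie below the Nyquist frequency "
            f"{rec.fs / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    # causal filtering; state initialised to steady state for the first
    # sample, so the constant gravity offset does not ring at switch-on
    zi = signal.sosfilt_zi(sos)
    out = np.empty_like(rec.samples)
    for j in range(3):
        out[:, j], _ = signal.sosfilt(sos, rec.samples[:, j], zi=zi * rec.samples[0, j])
    return replace(rec, samples=out)


def make_windows(rec: Recording, n: int = WINDOW_SAMPLES, overlap: float = WINDOW_OVERLAP) -> WindowSeries:
    """Segment a conditioned recording into overlapping fixed-length windows.

    Trailing samples that do not fill a complete window are dropped; the
    number of windows is ``floor((L - n)/stride) + 1``.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    stride = int(round(n * (1.0 - overlap)))
    length = rec.n_samples
    if length < n:
        raise ValueError(
            f"recording has {length} samples, shorter than one {n}-sample window"
        )
    n_windows = (length - n) // stride + 1
    idx = np.arange(n_windows)[:, None] * stride + np.arange(n)[None, :]
    windows = rec.samples[idx]  # (n_windows, n, 3)
    start_times = rec.t0 + np.arange(n_windows) * stride / rec.fs
    return WindowSeries(
        subject_id=rec.subject_id,
        session=rec.session,
        fs=rec.fs,
        windows=windows,
        start_times=start_times,
        n_per_window=n,
        stride=stride,
    )


def preprocess_recording(
    rec: Recording,
    target_fs: float = FS_TARGET,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
    window_samples: int = WINDOW_SAMPLES,
    overlap: float = WINDOW_OVERLAP,
) -> WindowSeries:
    """Full conditioning chain: resample → low-pass → window."""
    return make_windows(
        lowpass(resample(rec, target_fs), cutoff_hz, order),
        n=window_samples,
        overlap=overlap,
    )
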