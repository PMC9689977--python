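"""Audio I/O and pre-processing: resampling, amplitude normalization, framing.

All recordings entering the analysis pipeline are brought to a common
sampling rate (22.05 kHz by default) and peak-normalized to the [-1, 1]
range, so that descriptors computed downstream are comparable across
heterogeneous sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

from .errors import ConfigError, DegenerateInputError

DEFAULT_FS_HZ = 22050


@dataclass
class Recording:
    """A mono sustained-vowel recording.

    Attributes
    ----------
    samples : np.ndarray
        Real-valued mono waveform (dimensionless amplitude).
    fs_hz : float
        Sampling rate in Hz.
    label : str | None
        Optional class label (e.g. ``"healthy"``).
    source_id : str
        Identifier of the recording's origin (file path or simulator tag).
    """

    samples: np.ndarray
    fs_hz: float
    label: str | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording.samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording.samples must be finite")
        if self.fs_hz <= 0:
            raise ValueError("Recording.fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


def load_recording(path, target_fs_hz: float = DEFAULT_FS_HZ) -> Recording:
    """Read a WAV file, down-mix, resample to ``target_fs_hz`` and peak-normalize.

    Multi-channel input is down-mixed by the channel mean before resampling.
    Raises :class:`DegenerateInputError` for silent (all-zero) audio.
    """
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.size == 0:
        raise DegenerateInputError(f"empty audio file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(-np.iinfo(data.dtype).min)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    rec = Recording(samples=data, fs_hz=float(fs), source_id=str(path))
    rec = resample(rec, target_fs_hz)
    return normalize_amplitude(rec)


def save_recording(path, recording: Recording, subtype: str = "float32") -> None:
    """Write a recording to WAV (``"float32"`` or ``"pcm16"``)."""
    if subtype == "float32":
        wavfile.write(path, int(round(recording.fs_hz)), recording.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(recording.samples, -1.0, 1.0)
        wavfile.write(path, int(round(recording.fs_hz)), np.round(clipped * 32767.0).astype(np.int16))
    else:
        raise ConfigError(f"unknown WAV subtype: {subtype!r}")


def resample(recording: Recording, target_fs_hz: float) -> Recording:
    """Band-limited (polyphase) resampling to ``target_fs_hz``."""
    if target_fs_hz <= 0:
        raise ConfigError("target sampling rate must be positive")
    if target_fs_hz == recording.fs_hz:
        return recording
    ratio = Fraction(target_fs_hz / recording.fs_hz).limit_denominator(10000)
    out = resample_poly(recording.samples, ratio.numerator, ratio.denominator)
    return replace(recording, samples=out, fs_hz=float(target_fs_hz))


def normalize_amplitude(recording: Recording) -> Recording:
    """Scale so that ``max|samples| == 1``; sign is preserved."""
    peak = np.max(np.abs(recording.samples)) if recording.samples.size else 0.0
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero recording")
    return replace(recording, samples=recording.samples / peak)


def frame_signal(
    samples: np.ndarray,
    fs_hz: float,
    frame_ms: float = 50.0,
    hop_ms: float = 25.0,
    window: str = "hamming",
):
    """Slice a signal into overlapping windowed frames.

    Returns ``(frames, starts, short_flag)`` where ``frames`` is an
    ``(n_frames, frame_len)`` array of window-multiplied slices and
    ``starts`` holds the frame start indices. A signal shorter than one
    frame yields a single zero-padded frame with ``short_flag=True``.

    Frame count for N >= frame_len is ``floor((N - frame_len)/hop) + 1``.
    """
    if frame_ms <= 0 or hop_ms <= 0:
        raise ConfigError("frame_ms and hop_ms must be positive")
    x = np.asarray(samples, dtype=np.float64)
    frame_len = int(round(frame_ms * fs_hz / 1000.0))
    hop = int(round(hop_ms * fs_hz / 1000.0))
    if frame_len < 1 or hop < 1:
        raise ConfigError("frame/hop shorter than one sample at this rate")
    win = frame_window(window, frame_len)
    if len(x) < frame_len:
        padded = np.zeros(frame_len)
        padded[: len(x)] = x
        return padded[None, :] * win, np.array([0]), True
    n_frames = (len(x) - frame_len) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = np.stack([x[s : s + frame_len] for s in starts]) * win
    return frames, starts, False


def frame_window(name: str, length: int) -> np.ndarray:
    """Window by name; ``"hamming"`` uses the periodic-(L-1) textbook form."""
    if name in ("rect", "rectangular", "boxcar"):
        return np.ones(length)
    if name == "hamming":
        # symmetric 0.54 - 0.46 cos(2 pi n/(L-1))
        return np.hamming(length) if length > 1 else np.ones(length)
    try:
        return get_window(name, length, fftbins=False)
    except ValueError as exc:
        raise ConfigError(f"unknown window: {name!r}") from exc
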