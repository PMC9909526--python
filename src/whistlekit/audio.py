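"""Audio containers and file I/O.

Recordings are represented by :class:`AudioClip`, an immutable-ish
dataclass holding a ``(n_channels, n_samples)`` float array in [-1, 1]
plus its sample rate and provenance.  All downstream filters operate on
clips.  Time coordinates throughout the package are seconds from the
start of the source recording; intervals are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioClip:
    """A sampled multi-channel waveform.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes, dimensionless, nominally in [-1, 1].
    sample_rate : float
        Sampling frequency in Hz.
    start_time : float
        Offset of the first sample within the source recording, seconds.
    source_id : str
        Identifier of the originating recording.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError("samples must be 1-D or 2-D (channels, samples)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if arr.shape[1] == 0:
            raise ValueError("clip must contain at least one sample")
        self.samples = arr

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.n_samples / self.sample_rate

    def channel(self, idx: int) -> np.ndarray:
        return self.samples[idx]

    def mono(self) -> np.ndarray:
        """Return the single channel of a mono clip as a 1-D array."""
        if self.n_channels != 1:
            raise ValueError(f"expected mono clip, got {self.n_channels} channels")
        return self.samples[0]

    def with_samples(self, samples: np.ndarray) -> "AudioClip":
        """Copy of this clip with new sample data, metadata preserved."""
        return replace(self, samples=samples)

    def slice_time(self, t0: float, t1: float) -> "AudioClip":
        """Extract ``[t0, t1)`` (seconds relative to clip start)."""
        i0 = max(0, int(round(t0 * self.sample_rate)))
        i1 = min(self.n_samples, int(round(t1 * self.sample_rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{t0}, {t1})")
        return AudioClip(
            self.samples[:, i0:i1],
            self.sample_rate,
            start_time=self.start_time + i0 / self.sample_rate,
            source_id=self.source_id,
        )


_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): 2**7}


def load_audio(path: str | os.PathLike, channels: Sequence[int] | None = None) -> AudioClip:
    """Load a WAV file into an :class:`AudioClip`.

    PCM 16/24/32-bit and float WAV are supported; integer samples are
    rescaled to [-1, 1].  No resampling is performed.  ``channels``
    optionally selects a subset of channels by index.

    FLAC decoding is not available in this build; convert FLAC archives
    to WAV upstream (e.g. ``ffmpeg -i in.flac out.wav``).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"audio file not found: {path}")
    if path.lower().endswith(".flac"):
        raise IOError(
            f"cannot decode FLAC ({path}): no FLAC codec available; convert to WAV first"
        )
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises ValueError on non-WAV bytes
        raise IOError(f"unreadable audio file: {path}: {exc}") from exc
    data = np.atleast_2d(data.T if data.ndim == 2 else data)
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        offset = scale if data.dtype == np.dtype(np.uint8) else 0
        data = (data.astype(np.float64) - offset) / scale
    else:
        data = data.astype(np.float64)
    if channels is not None:
        channels = list(channels)
        if any(c < 0 or c >= data.shape[0] for c in channels):
            raise ValueError(
                f"requested channels {channels} out of range for {data.shape[0]}-channel file"
            )
        data = data[channels]
    name = os.path.splitext(os.path.basename(path))[0]
    return AudioClip(data, float(rate), source_id=name)


def save_wav(path: str | os.PathLike, clip: AudioClip) -> None:
    """Write a clip as float32 WAV (channels interleaved)."""
    data = clip.samples.astype(np.float32)
    out = data[0] if clip.n_channels == 1 else data.T
    wavfile.write(os.fspath(path), int(round(clip.sample_rate)), out)


def average_channels(clip: AudioClip) -> AudioClip:
    """Collapse a multi-channel clip to mono by arithmetic mean.

    Averaging the two hydrophone channels before spectrogram analysis
    reduces uncorrelated noise while preserving the coherent whistle.
    """
    if clip.n_channels < 1:
        raise ValueError("clip must have at least one channel")
    return clip.with_samples(clip.samples.mean(axis=0, keepdims=True))
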