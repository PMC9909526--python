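"""Spectrogram-image generation for the CNN detectors.

Conditioned audio is cut into overlapping fixed-length segments
(default 0.8 s advancing by 0.4 s), each segment is transformed with a
Blackman-windowed STFT (2048-point window, hop = 0.8 x window = 1638
samples), the power spectral density is expressed in dB and cropped to
the 3-20 kHz whistle band, rendered as a grayscale raster in [0, 1],
and finally resized to a 224 x 224 x 3 tensor (identical channels,
intensities already in [0, 1]) for the classifiers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import signal as sps
from skimage.transform import resize as _sk_resize

from whistlekit.audio import AudioClip
from whistlekit.annotations import WhistleAnnotation, overlap_seconds

MODEL_INPUT_SIZE = 224


@dataclass
class SpectrogramConfig:
    """STFT and segmentation parameters.

    ``hop`` defaults to ``round(0.8 * window_len)`` — the window
    advances by 80% of its length between frames (20% overlap).
    ``segment_len_s`` covers the longest retained whistle (~0.78 s);
    ``segment_shift_s`` is the 0.4 s stride between classified images.
    """

    window_len: int = 2048
    window_type: str = "blackman"
    hop: int | None = None
    segment_len_s: float = 0.8
    segment_shift_s: float = 0.4
    f_min: float = 3000.0
    f_max: float = 20000.0
    db_floor: float = -120.0

    def __post_init__(self) -> None:
        if self.hop is None:
            self.hop = int(round(0.8 * self.window_len))
        if not (0 < self.hop <= self.window_len):
            raise ValueError(f"hop must be in (0, window_len], got {self.hop}")
        if not (0 <= self.f_min < self.f_max):
            raise ValueError("need 0 <= f_min < f_max")
        if self.segment_shift_s > self.segment_len_s:
            raise ValueError("segment_shift_s must not exceed segment_len_s")


@dataclass
class SpectrogramImage:
    """Power spectrogram (dB) with axes, plus an optional rendered raster.

    ``power_db`` is indexed ``(frequency bin, time frame)`` with
    ``freqs`` ascending; ``raster`` holds grayscale values in [0, 1]
    with the same indexing (row 0 = lowest frequency).
    """

    power_db: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    raster: np.ndarray | None = None
    source_id: str = ""
    t_start: float = 0.0
    t_end: float = 0.0


@dataclass
class ModelInput:
    """A 224 x 224 x 3 tensor in [0, 1] ready for the classifiers."""

    tensor: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=np.float32)
        if t.shape != (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE, 3):
            raise ValueError(f"tensor must be {MODEL_INPUT_SIZE}x{MODEL_INPUT_SIZE}x3, got {t.shape}")
        self.tensor = t


def segment_audio(clip: AudioClip, cfg: SpectrogramConfig) -> list[AudioClip]:
    """Cut a mono clip into overlapping fixed-length segments.

    Segments start at 0, shift, 2*shift, ...; a trailing partial
    segment is dropped.  A clip shorter than one segment yields an
    empty list.
    """
    if clip.n_channels != 1:
        raise ValueError("segment_audio expects a single-channel clip")
    seg_len = int(round(cfg.segment_len_s * clip.sample_rate))
    shift = int(round(cfg.segment_shift_s * clip.sample_rate))
    out = []
    start = 0
    while start + seg_len <= clip.n_samples:
        out.append(
            AudioClip(
                clip.samples[:, start : start + seg_len],
                clip.sample_rate,
                start_time=clip.start_time + start / clip.sample_rate,
                source_id=clip.source_id,
            )
        )
        start += shift
    return out


def compute_spectrogram(segment: AudioClip, cfg: SpectrogramConfig) -> SpectrogramImage:
    """Blackman-windowed power spectrogram of one segment, in dB.

    Magnitude-squared STFT (periodic Blackman taper, configured hop),
    converted with 10*log10 floored at ``db_floor`` and cropped to
    ``[f_min, f_max]``.  Frame count is
    ``floor((n_samples - window_len)/hop) + 1``.
    """
    if segment.n_channels != 1:
        raise ValueError("compute_spectrogram expects a single-channel clip")
    if cfg.window_len > segment.n_samples:
        raise ValueError(
            f"window ({cfg.window_len}) longer than segment ({segment.n_samples} samples)"
        )
    window = sps.get_window(cfg.window_type, cfg.window_len, fftbins=True)
    freqs, times, psd = sps.spectrogram(
        segment.mono(),
        fs=segment.sample_rate,
        window=window,
        nperseg=cfg.window_len,
        noverlap=cfg.window_len - cfg.hop,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    band = (freqs >= cfg.f_min) & (freqs <= cfg.f_max)
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(psd[band])
    power_db = np.maximum(power_db, cfg.db_floor)
    return SpectrogramImage(
        power_db=power_db,
        freqs=freqs[band],
        times=times + segment.start_time,
        source_id=segment.source_id,
        t_start=segment.start_time,
        t_end=segment.start_time + segment.duration,
    )


def render_grayscale(
    spec: SpectrogramImage,
    scaling: str = "per_image_minmax",
    fixed_range_db: tuple[float, float] = (-120.0, 0.0),
) -> SpectrogramImage:
    """Map the dB matrix to a grayscale raster in [0, 1].

    ``per_image_minmax`` stretches each image's own [min, max] dB onto
    [0, 1] (what a default colormap rendering does); ``fixed_range``
    clips to the configured dB bounds.  A constant-valued image maps to
    uniform 0.5.
    """
    if spec.power_db.size == 0:
        raise ValueError("empty spectrogram")
    p = spec.power_db
    if scaling == "per_image_minmax":
        lo, hi = p.min(), p.max()
    elif scaling == "fixed_range":
        lo, hi = fixed_range_db
    else:
        raise ValueError(f"unknown scaling mode: {scaling!r}")
    if hi - lo <= 0:
        raster = np.full_like(p, 0.5)
    else:
        raster = np.clip((p - lo) / (hi - lo), 0.0, 1.0)
    spec.raster = raster
    return spec


def to_model_input(spec: SpectrogramImage, label: int | None = None) -> ModelInput:
    """Resize the raster to 224 x 224 (bilinear) and replicate to 3 channels."""
    if spec.raster is None:
        raise ValueError("raster not rendered; call render_grayscale first")
    img = _sk_resize(
        spec.raster.astype(np.float64),
        (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE),
        order=1,
        mode="edge",
        anti_aliasing=True,
        preserve_range=True,
    )
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return ModelInput(tensor=np.repeat(img[:, :, np.newaxis], 3, axis=2), label=label)


def label_segments(
    segments: list[AudioClip],
    annotations: list[WhistleAnnotation],
    min_overlap_frac: float = 0.05,
) -> list[int]:
    """Label each segment whistle (1) or noise (0) by interval overlap.

    A segment is positive iff it overlaps at least ``min_overlap_frac``
    of some whistle annotation's interval, the fraction measured against
    the annotation's duration.
    """
    whistles = [a for a in annotations if a.is_whistle]
    labels = []
    for seg in segments:
        s0, s1 = seg.start_time, seg.start_time + seg.duration
        hit = any(
            overlap_seconds(s0, s1, a.t_start, a.t_end) / a.duration >= min_overlap_frac
            for a in whistles
        )
        labels.append(int(hit))
    return labels


def save_png(spec: SpectrogramImage, png_path: str | os.PathLike) -> None:
    """Write the raster as 8-bit grayscale PNG plus a JSON axis sidecar.

    The PNG is stored with frequency increasing downward in row order
    matching ``power_db``; the sidecar records axes and provenance so
    the image can be reloaded losslessly to within 1/255.
    """
    if spec.raster is None:
        raise ValueError("raster not rendered")
    png_path = os.fspath(png_path)
    img = np.round(255.0 * spec.raster).astype(np.uint8)
    Image.fromarray(img, mode="L").save(png_path)
    sidecar = {
        "freqs_hz": spec.freqs.tolist(),
        "times_s": spec.times.tolist(),
        "source_id": spec.source_id,
        "t_start": spec.t_start,
        "t_end": spec.t_end,
    }
    with open(png_path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_png(png_path: str | os.PathLike) -> SpectrogramImage:
    """Reload a raster written by :func:`save_png` (power_db unavailable)."""
    png_path = os.fspath(png_path)
    raster = np.asarray(Image.open(png_path), dtype=np.float32) / 255.0
    with open(png_path + ".json") as fh:
        sidecar = json.load(fh)
    return SpectrogramImage(
        power_db=np.full_like(raster, np.nan),
        freqs=np.asarray(sidecar["freqs_hz"]),
        times=np.asarray(sidecar["times_s"]),
        raster=raster,
        source_id=sidecar["source_id"],
        t_start=sidecar["t_start"],
        t_end=sidecar["t_end"],
    )
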