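"""Whistle annotations: labeled time intervals with optional contours.

Interchange format: a CSV with columns ``source_id, t_start, t_end,
label`` (one row per annotation, implicit row-order ids) and an optional
sidecar JSON mapping annotation id -> list of ``[t, f_hz, db]`` contour
points.  Times are seconds from the start of the source recording;
intervals are half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_WHISTLE = "whistle"
LABEL_NOISE = "noise"


@dataclass
class WhistleAnnotation:
    """A labeled time interval, optionally carrying a time-frequency contour.

    ``contour`` is an ``(n, 3)`` array of ``(time_s, freq_hz, intensity_db)``
    rows with nondecreasing times inside ``[t_start, t_end]``.
    """

    t_start: float
    t_end: float
    label: str = LABEL_WHISTLE
    contour: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")
        if self.label not in (LABEL_WHISTLE, LABEL_NOISE):
            raise ValueError(f"label must be '{LABEL_WHISTLE}' or '{LABEL_NOISE}'")
        if self.contour is not None:
            c = np.asarray(self.contour, dtype=np.float64)
            if c.ndim != 2 or c.shape[1] != 3:
                raise ValueError("contour must be an (n, 3) array of (t, f_hz, db)")
            t = c[:, 0]
            if np.any(np.diff(t) < 0):
                raise ValueError("contour times must be nondecreasing")
            eps = 1e-9
            if t.size and (t[0] < self.t_start - eps or t[-1] > self.t_end + eps):
                raise ValueError("contour times must lie within [t_start, t_end]")
            self.contour = c

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def is_whistle(self) -> bool:
        return self.label == LABEL_WHISTLE


def overlap_seconds(a0: float, a1: float, b0: float, b1: float) -> float:
    """Length of the intersection of [a0, a1) and [b0, b1)."""
    return max(0.0, min(a1, b1) - max(a0, b0))


def write_annotations(
    csv_path: str | os.PathLike,
    annotations: list[WhistleAnnotation],
    contour_json_path: str | os.PathLike | None = None,
) -> None:
    """Write annotations as CSV plus optional contour sidecar JSON."""
    df = pd.DataFrame(
        {
            "source_id": [a.source_id for a in annotations],
            "t_start": [a.t_start for a in annotations],
            "t_end": [a.t_end for a in annotations],
            "label": [a.label for a in annotations],
        }
    )
    df.to_csv(csv_path, index=False)
    if contour_json_path is not None:
        contours = {
            str(i): a.contour.tolist()
            for i, a in enumerate(annotations)
            if a.contour is not None
        }
        with open(contour_json_path, "w") as fh:
            json.dump(contours, fh)


def read_annotations(
    csv_path: str | os.PathLike,
    contour_json_path: str | os.PathLike | None = None,
) -> list[WhistleAnnotation]:
    """Read annotations written by :func:`write_annotations`."""
    df = pd.read_csv(csv_path)
    required = {"source_id", "t_start", "t_end", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    contours: dict[str, list] = {}
    if contour_json_path is not None and os.path.exists(os.fspath(contour_json_path)):
        with open(contour_json_path) as fh:
            contours = json.load(fh)
    out = []
    for i, row in df.iterrows():
        contour = contours.get(str(i))
        out.append(
            WhistleAnnotation(
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                label=str(row.label),
                contour=np.asarray(contour) if contour is not None else None,
                source_id=str(row.source_id),
            )
        )
    return out
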