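"""Temperature extraction from thermal frames.

An 8-bit thermal frame stores gray levels 0-255 together with the
minimum and maximum temperature present in the frame; the affine map

    T = (t_max - t_min) / 255 * P + t_min

converts a gray level P back to degrees Celsius.  The per-pig body
temperature estimate is the maximum temperature over the paired left and
right ear-root boxes — the ear root is the hottest, least hair-covered
surface region and using the warmer of the two ears suppresses the
posture- and viewing-angle-dependent degradation that affects a single
ear.

Reference values for agreement analysis come from a manually placed
*reference line*: a band (default 5 px wide) along the brightest ear-root
axis whose maximum temperature serves as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import OrientedBox, rasterize_mask
from .io import FrameRecord
from .pairing import EarPair

__all__ = [
    "NoMeasurementError",
    "ReferenceLine",
    "TemperatureRecord",
    "gray_to_temp",
    "temp_to_gray",
    "quantization_step",
    "roi_max_temp",
    "reference_line_temp",
    "reference_line_mask",
    "pig_temperature",
]


class NoMeasurementError(ValueError):
    """A region of interest contains no pixels; no temperature can be reported."""


def gray_to_temp(gray, t_min: float, t_max: float):
    """Map gray level(s) 0-255 to temperature(s) in degrees Celsius.

    Affine and strictly increasing; P = 0 maps exactly to ``t_min`` and
    P = 255 exactly to ``t_max``.  Accepts scalars or arrays.
    """
    if not t_max > t_min:
        raise ValueError(f"t_max ({t_max}) must exceed t_min ({t_min})")
    g = np.asarray(gray, dtype=float)
    if np.any(g < 0) or np.any(g > 255):
        raise ValueError("gray level out of range [0, 255]")
    t = (t_max - t_min) / 255.0 * g + t_min
    return float(t) if np.isscalar(gray) else t


def temp_to_gray(temp, t_min: float, t_max: float):
    """Inverse of :func:`gray_to_temp` with rounding to the nearest gray level."""
    if not t_max > t_min:
        raise ValueError(f"t_max ({t_max}) must exceed t_min ({t_min})")
    t = np.asarray(temp, dtype=float)
    g = np.rint((t - t_min) / (t_max - t_min) * 255.0)
    g = np.clip(g, 0, 255).astype(np.uint8)
    return g if t.ndim else int(g)


def quantization_step(frame: FrameRecord) -> float:
    """Temperature represented by one gray level, (t_max - t_min) / 255."""
    return (frame.t_max - frame.t_min) / 255.0


def roi_max_temp(frame: FrameRecord, box: OrientedBox) -> float:
    """Maximum temperature over the pixels covered by an oriented box.

    Membership is the pixel-center-inside test of
    :func:`pigtherm.geometry.rasterize_mask`, clipped to the frame.

    Raises
    ------
    NoMeasurementError
        If the box covers no pixel of the frame.
    """
    mask = rasterize_mask(box, frame.shape)
    if not mask.any():
        raise NoMeasurementError("box covers no pixel inside the frame")
    return gray_to_temp(int(frame.pixels[mask].max()), frame.t_min, frame.t_max)


@dataclass(frozen=True)
class ReferenceLine:
    """A straight band of given width (pixels) between two endpoints."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    width: float = 5.0

    def __post_init__(self) -> None:
        if math.dist(self.p0, self.p1) < 1e-9:
            raise ValueError("reference line endpoints must be distinct")
        if self.width < 1.0:
            raise ValueError(f"width must be >= 1 pixel, got {self.width}")


def reference_line_mask(line: ReferenceLine, frame_shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers lie within width/2 perpendicular distance of the segment.

    Membership also requires the center's projection onto the segment's
    axis to fall between the endpoint projections (a rectangular band,
    not a capsule).
    """
    rows, cols = frame_shape
    p0 = np.asarray(line.p0, dtype=float)
    p1 = np.asarray(line.p1, dtype=float)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    axis = axis / length
    normal = np.array([-axis[1], axis[0]])
    half_w = line.width / 2.0
    lo = np.minimum(p0, p1) - half_w - 1
    hi = np.maximum(p0, p1) + half_w + 1
    r0 = max(0, int(math.floor(lo[1] - 0.5)))
    r1 = min(rows - 1, int(math.ceil(hi[1] - 0.5)))
    c0 = max(0, int(math.floor(lo[0] - 0.5)))
    c1 = min(cols - 1, int(math.ceil(hi[0] - 0.5)))
    mask = np.zeros((rows, cols), dtype=bool)
    if r0 > r1 or c0 > c1:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    centers = np.stack([cc + 0.5, rr + 0.5], axis=-1) - p0
    t = centers @ axis
    d = np.abs(centers @ normal)
    inside = (d <= half_w) & (t >= 0.0) & (t <= length)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return mask


def reference_line_temp(frame: FrameRecord, line: ReferenceLine) -> float:
    """Maximum temperature over a reference-line band.

    Raises
    ------
    NoMeasurementError
        If the band covers no pixel of the frame.
    """
    mask = reference_line_mask(line, frame.shape)
    if not mask.any():
        raise NoMeasurementError("reference line covers no pixel inside the frame")
    return gray_to_temp(int(frame.pixels[mask].max()), frame.t_min, frame.t_max)


@dataclass(frozen=True)
class TemperatureRecord:
    """Per-pig ear-root temperatures (deg C, full precision retained).

    ``t_pig`` is the maximum of the available per-ear values.  When one
    ear's box covers no pixel the record is flagged ``degraded`` and the
    remaining ear carries the estimate alone.
    """

    frame_id: str
    pair_index: int
    t_left: float | None
    t_right: float | None
    t_pig: float
    degraded: bool = False


def pig_temperature(frame: FrameRecord, pair: EarPair, pair_index: int = 0) -> TemperatureRecord:
    """Body-temperature estimate for one paired pig.

    Raises
    ------
    NoMeasurementError
        If neither ear box covers any pixel of the frame.
    """
    t_left = t_right = None
    try:
        t_left = roi_max_temp(frame, pair.left)
    except NoMeasurementError:
        pass
    try:
        t_right = roi_max_temp(frame, pair.right)
    except NoMeasurementError:
        pass
    available = [t for t in (t_left, t_right) if t is not None]
    if not available:
        raise NoMeasurementError("both ear boxes cover no pixel inside the frame")
    return TemperatureRecord(
        frame_id=frame.frame_id,
        pair_index=pair_index,
        t_left=t_left,
        t_right=t_right,
        t_pig=max(available),
        degraded=len(available) < 2,
    )
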