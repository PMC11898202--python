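"""Reading and writing the pipeline's on-disk formats.

Three formats are supported:

* **YOLO-OBB TXT** — one object per line,
  ``class x1 y1 x2 y2 x3 y3 x4 y4 [confidence]``, class 0 = left ear
  root, class 1 = right ear root.  Two coordinate dialects exist in the
  wild: ``normalized`` (fractions of the frame width/height, the YOLO
  ecosystem default) and ``pixel`` (absolute pixel coordinates).  Both
  are supported; normalized needs the frame shape to scale.
* **roLabelImg XML** — rotated-box annotations ``(cx, cy, w, h, angle)``
  with the angle in radians, clockwise in the image frame (the tool's
  convention); converted to four-vertex boxes.
* **8-bit grayscale frames** (PNG/TIFF) with a JSON sidecar carrying the
  frame's minimum and maximum temperature in degrees Celsius — 8-bit
  images cannot carry a radiometric scale themselves.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image

from .geometry import DegenerateBoxError, EarSide, OrientedBox

__all__ = [
    "FormatError",
    "FrameRecord",
    "LabelSet",
    "read_obb_txt",
    "write_obb_txt",
    "convert_rolabelimg",
    "read_frame",
    "write_frame",
]

Dialect = Literal["normalized", "pixel"]

#: roLabelImg class-name strings mapped to detector classes.
CLASS_NAMES = {"Left ear root": EarSide.LEFT, "Right ear root": EarSide.RIGHT}


class FormatError(ValueError):
    """A file does not conform to the expected format."""


@dataclass
class FrameRecord:
    """One thermal frame: 8-bit grayscale pixels plus its temperature scale.

    ``t_min``/``t_max`` are the temperatures (deg C) that gray levels 0 and
    255 map to.  The nominal frame size is 288 rows x 384 cols, but any
    size is accepted.
    """

    frame_id: str
    pixels: np.ndarray
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"frame must be a single-channel 2-D image, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"frame must be 8-bit (uint8), got dtype {self.pixels.dtype}")
        self.t_min = float(self.t_min)
        self.t_max = float(self.t_max)
        if not (self.t_max > self.t_min):
            raise FormatError(f"t_max ({self.t_max}) must exceed t_min ({self.t_min})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (rows, cols)


@dataclass
class LabelSet:
    """All ear-root boxes of one frame (ground truth or detections)."""

    frame_id: str
    boxes: list[OrientedBox] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)


def _parse_obb_line(tokens: list[str], lineno: int, dialect: Dialect,
                    frame_shape: tuple[int, int] | None) -> OrientedBox:
    if len(tokens) not in (9, 10):
        raise FormatError(f"line {lineno}: expected 9 or 10 tokens, got {len(tokens)}")
    try:
        values = [float(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric token ({exc})") from None
    cls = values[0]
    if cls not in (0.0, 1.0):
        raise FormatError(f"line {lineno}: class index must be 0 or 1, got {tokens[0]}")
    coords = np.array(values[1:9], dtype=float).reshape(4, 2)
    if dialect == "normalized":
        rows, cols = frame_shape  # type: ignore[misc]
        coords[:, 0] *= cols
        coords[:, 1] *= rows
    confidence = values[9] if len(values) == 10 else None
    try:
        return OrientedBox(coords, EarSide(int(cls)), confidence)
    except (DegenerateBoxError, ValueError) as exc:
        raise FormatError(f"line {lineno}: {exc}") from None


def read_obb_txt(path: str | Path, dialect: Dialect = "normalized",
                 frame_shape: tuple[int, int] | None = None) -> LabelSet:
    """Read a YOLO-OBB TXT label/detection file.

    Parameters
    ----------
    path
        TXT file, one box per non-empty line.
    dialect
        ``"normalized"`` (coordinates are fractions of the frame, requires
        `frame_shape`) or ``"pixel"`` (absolute coordinates).
    frame_shape
        ``(rows, cols)`` of the frame the labels refer to.
    """
    path = Path(path)
    if dialect == "normalized" and frame_shape is None:
        raise ValueError("frame_shape is required for the normalized dialect")
    if dialect not in ("normalized", "pixel"):
        raise ValueError(f"unknown dialect {dialect!r}")
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            boxes.append(_parse_obb_line(tokens, lineno, dialect, frame_shape))
    return LabelSet(frame_id=path.stem, boxes=boxes)


def write_obb_txt(labels: LabelSet, path: str | Path, dialect: Dialect = "normalized",
                  frame_shape: tuple[int, int] | None = None) -> None:
    """Write a LabelSet in the format read by :func:`read_obb_txt`.

    Detections carry their confidence as a tenth token; ground-truth boxes
    (confidence ``None``) write nine tokens.
    """
    if dialect == "normalized" and frame_shape is None:
        raise ValueError("frame_shape is required for the normalized dialect")
    if dialect not in ("normalized", "pixel"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    for box in labels.boxes:
        coords = box.vertices.copy()
        if dialect == "normalized":
            rows, cols = frame_shape  # type: ignore[misc]
            coords[:, 0] /= cols
            coords[:, 1] /= rows
        tokens = [str(int(box.label if box.label is not None else 0))]
        tokens += [f"{v:.9g}" for v in coords.ravel()]
        if box.confidence is not None:
            tokens.append(f"{box.confidence:.6g}")
        lines.append(" ".join(tokens))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def rotated_rect_vertices(cx: float, cy: float, w: float, h: float, angle: float) -> np.ndarray:
    """Four vertices of a rotated rectangle, angle in radians clockwise in the image frame."""
    # with y down, the standard rotation matrix rotates +x toward +y, which
    # reads as clockwise on screen
    ca, sa = math.cos(angle), math.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    offsets = np.array([[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]])
    return np.array([cx, cy]) + offsets @ rot.T


def convert_rolabelimg(xml_path: str | Path) -> LabelSet:
    """Convert a roLabelImg XML annotation file to a LabelSet.

    Each ``<robndbox>`` record ``(cx, cy, w, h, angle)`` is expanded to
    four vertices; object names must be the two ear-root class strings.
    """
    xml_path = Path(xml_path)
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{xml_path.name}: malformed XML ({exc})") from None
    boxes = []
    for i, obj in enumerate(root.iter("object"), start=1):
        name = obj.findtext("name")
        if name not in CLASS_NAMES:
            raise FormatError(f"{xml_path.name}: object {i}: unknown label {name!r}")
        rb = obj.find("robndbox")
        if rb is None:
            raise FormatError(f"{xml_path.name}: object {i}: missing <robndbox>")
        try:
            cx, cy, w, h, angle = (float(rb.findtext(tag)) for tag in ("cx", "cy", "w", "h", "angle"))
        except (TypeError, ValueError):
            raise FormatError(f"{xml_path.name}: object {i}: incomplete or non-numeric <robndbox>") from None
        verts = rotated_rect_vertices(cx, cy, w, h, angle)
        try:
            boxes.append(OrientedBox(verts, CLASS_NAMES[name]))
        except DegenerateBoxError as exc:
            raise FormatError(f"{xml_path.name}: object {i}: {exc}") from None
    return LabelSet(frame_id=xml_path.stem, boxes=boxes)


def _default_meta_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def read_frame(image_path: str | Path, meta_path: str | Path | None = None) -> FrameRecord:
    """Load an 8-bit grayscale frame plus its JSON temperature sidecar.

    The sidecar is ``{"t_min": <degC>, "t_max": <degC>}``; by default it
    sits next to the image with a ``.json`` suffix.
    """
    image_path = Path(image_path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(image_path)
    if not meta_path.exists():
        raise FormatError(f"missing temperature sidecar {meta_path}")
    with Image.open(image_path) as img:
        if img.mode != "L":
            raise FormatError(f"{image_path.name}: expected 8-bit single-channel image, got mode {img.mode!r}")
        pixels = np.asarray(img, dtype=np.uint8)
    meta = json.loads(meta_path.read_text())
    try:
        t_min, t_max = float(meta["t_min"]), float(meta["t_max"])
    except (KeyError, TypeError, ValueError):
        raise FormatError(f"{meta_path.name}: sidecar must provide numeric t_min and t_max") from None
    return FrameRecord(frame_id=image_path.stem, pixels=pixels, t_min=t_min, t_max=t_max)


def write_frame(frame: FrameRecord, image_path: str | Path,
                meta_path: str | Path | None = None) -> None:
    """Write a frame as PNG/TIFF plus its JSON temperature sidecar."""
    image_path = Path(image_path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(image_path)
    Image.fromarray(frame.pixels, mode="L").save(image_path)
    meta_path.write_text(json.dumps({"t_min": frame.t_min, "t_max": frame.t_max}) + "\n")
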