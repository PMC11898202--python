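"""Synthetic thermal scenes with full ground truth.

The generator emulates the statistical structure the pipeline assumes so
that every stage is testable without a camera or a trained detector:

* each pig contributes two elongated hot ear-root boxes splayed like the
  character "八" about the head axis, long axes converging ahead of the
  head, with the same-pig ear-center distance drawn from a configured
  window (default 80-160 px);
* each ear carries a hotter 5-px-wide central line along its axis (the
  reference-line region), the ear regions are the hottest pixels in the
  frame, and the frame is quantized to 8 bits exactly the way the
  grayscale-to-temperature map assumes;
* the ``touching_heads`` adversarial mode places a second pig as the
  point reflection of the first through a point just behind its ears, so
  both cross-pig left/right distances are smaller than the same-pig
  distances and greedy rough pairing provably mispairs; the
  ``edge_clip`` mode pushes a pig partially outside the frame.

Anatomical convention: the *left* ear root lies on the pig's left when
facing along its heading (heading direction rotated -90 degrees in the
y-down image frame).  This is the calibration anchor for the polar
left/right classification rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .geometry import EarSide, OrientedBox, box_from_center, rasterize_mask, unit_vector
from .io import FrameRecord, LabelSet, write_frame, write_obb_txt
from .thermometry import ReferenceLine, reference_line_mask

__all__ = [
    "SceneConfig",
    "PigTruth",
    "SyntheticScene",
    "PlacementError",
    "generate_pig",
    "generate_scene",
    "generate_dataset",
]

AdversarialMode = Literal["none", "touching_heads", "edge_clip"]


class PlacementError(RuntimeError):
    """No feasible pig placement was found within the retry budget."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Distances are pixels, angles degrees, temperatures degrees Celsius.
    ``ear_distance`` is the same-pig ear-center distance window;
    ``splay_half_angle`` is the angle between each ear's long axis and
    the head axis.  ``ear_noise_scale`` is the mean of an exponential
    per-ear temperature degradation (posture/viewing-angle losses are
    asymmetric and can only lower the apparent ear temperature);
    ``sensor_noise_sd`` is Gaussian pixel noise in gray-level units.
    """

    frame_shape: tuple[int, int] = (288, 384)  # (rows, cols)
    n_pigs: int = 1
    ear_distance: tuple[float, float] = (80.0, 160.0)
    splay_half_angle: tuple[float, float] = (25.0, 40.0)
    ear_length: tuple[float, float] = (30.0, 50.0)
    ear_width: tuple[float, float] = (6.0, 10.0)
    background_temp: tuple[float, float] = (21.0, 0.8)  # mean, sd
    body_temp: tuple[float, float] = (30.0, 34.0)
    ear_peak_temp: tuple[float, float] = (37.5, 40.0)
    ear_noise_scale: float = 0.0
    sensor_noise_sd: float = 0.0
    adversarial: AdversarialMode = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ear_distance", "splay_half_angle", "ear_length", "ear_width",
                     "body_temp", "ear_peak_temp"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} range must be ordered, got ({lo}, {hi})")
        if self.ear_peak_temp[0] <= self.body_temp[1]:
            raise ValueError("ear peak temperatures must exceed body temperatures")
        if self.body_temp[0] <= self.background_temp[0]:
            raise ValueError("body temperatures must exceed the background mean")
        if self.adversarial not in ("none", "touching_heads", "edge_clip"):
            raise ValueError(f"unknown adversarial mode {self.adversarial!r}")
        if self.n_pigs < 1:
            raise ValueError("n_pigs must be >= 1")


@dataclass(frozen=True)
class PigTruth:
    """Ground truth for one generated pig."""

    pig_id: int
    heading_deg: float            # y-up degrees; the direction the pig faces
    head_point: np.ndarray        # convergence point of the ear long axes
    left_box: OrientedBox
    right_box: OrientedBox
    true_temp: float              # intended (pre-degradation) peak temperature
    ear_peak_left: float          # rendered peak of the left ear
    ear_peak_right: float
    body_temp: float
    ref_left: ReferenceLine
    ref_right: ReferenceLine


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered frame plus everything needed to score the pipeline on it."""

    frame: FrameRecord
    labels: LabelSet
    pigs: tuple[PigTruth, ...]
    config: SceneConfig

    @property
    def true_pairs(self) -> list[tuple[OrientedBox, OrientedBox]]:
        return [(p.left_box, p.right_box) for p in self.pigs]


def _build_pig(pig_id: int, head: np.ndarray, heading: float, s: float,
               gamma: float, length: float, width: float, true_temp: float,
               peaks: tuple[float, float], body_temp: float) -> PigTruth:
    """Construct one pig's boxes and reference lines from its parameters.

    The left ear's long axis points backward-outward at ``heading + 180 -
    gamma`` (y-up degrees), the right ear's at ``heading + 180 + gamma``;
    both axes pass through the head point, so the outer lines of the two
    boxes intersect head-ward.  The ear centers sit at the radius that
    makes their separation exactly ``s``.
    """
    rho = (s / 2.0) / math.sin(math.radians(gamma))
    axis_left = heading + 180.0 - gamma
    axis_right = heading + 180.0 + gamma
    c_left = head + rho * unit_vector(axis_left)
    c_right = head + rho * unit_vector(axis_right)
    left_box = box_from_center(c_left, length, width, axis_left, EarSide.LEFT)
    right_box = box_from_center(c_right, length, width, axis_right, EarSide.RIGHT)
    half = length / 2.0 - 2.0
    refs = []
    for c, axis in ((c_left, axis_left), (c_right, axis_right)):
        u = unit_vector(axis)
        refs.append(ReferenceLine(p0=tuple(c - half * u), p1=tuple(c + half * u), width=5.0))
    return PigTruth(pig_id=pig_id, heading_deg=heading % 360.0, head_point=head,
                    left_box=left_box, right_box=right_box, true_temp=true_temp,
                    ear_peak_left=peaks[0], ear_peak_right=peaks[1],
                    body_temp=body_temp, ref_left=refs[0], ref_right=refs[1])


def _sample_params(cfg: SceneConfig, rng: np.random.Generator,
                   ear_distance: tuple[float, float] | None = None,
                   splay: tuple[float, float] | None = None) -> dict:
    d_lo, d_hi = ear_distance or cfg.ear_distance
    g_lo, g_hi = splay or cfg.splay_half_angle
    s = float(rng.uniform(d_lo, d_hi))
    gamma = float(rng.uniform(g_lo, g_hi))
    length = float(rng.uniform(*cfg.ear_length))
    width = float(rng.uniform(*cfg.ear_width))
    true_temp = float(rng.uniform(*cfg.ear_peak_temp))
    body = float(rng.uniform(*cfg.body_temp))
    if cfg.ear_noise_scale > 0:
        eps = rng.exponential(cfg.ear_noise_scale, size=2)
        ceiling = max(0.0, true_temp - body - 0.5)
        eps = np.minimum(eps, ceiling)
    else:
        eps = np.zeros(2)
    peaks = (true_temp - float(eps[0]), true_temp - float(eps[1]))
    return dict(s=s, gamma=gamma, length=length, width=width,
                true_temp=true_temp, peaks=peaks, body_temp=body)


def _inside_frame(pig: PigTruth, shape: tuple[int, int], margin: float = 2.0) -> bool:
    rows, cols = shape
    for box in (pig.left_box, pig.right_box):
        v = box.vertices
        if (v[:, 0] < margin).any() or (v[:, 0] > cols - margin).any():
            return False
        if (v[:, 1] < margin).any() or (v[:, 1] > rows - margin).any():
            return False
    return True


def _clipped_but_present(pig: PigTruth, shape: tuple[int, int]) -> bool:
    rows, cols = shape
    verts = np.vstack([pig.left_box.vertices, pig.right_box.vertices])
    outside = ((verts[:, 0] < 0) | (verts[:, 0] > cols) |
               (verts[:, 1] < 0) | (verts[:, 1] > rows)).any()
    present = (rasterize_mask(pig.left_box, shape).any()
               and rasterize_mask(pig.right_box, shape).any())
    return bool(outside and present)


def _well_separated(pig: PigTruth, others: list[PigTruth], min_dist: float) -> bool:
    for other in others:
        for a in (pig.left_box, pig.right_box):
            for b in (other.left_box, other.right_box):
                if np.linalg.norm(a.center - b.center) < min_dist:
                    return False
    return True


def generate_pig(cfg: SceneConfig, rng: np.random.Generator, pig_id: int = 0,
                 others: list[PigTruth] | None = None, clip_edge: bool = False,
                 max_tries: int = 500) -> PigTruth:
    """Sample and place one pig inside (or, for `clip_edge`, across) the frame.

    Non-adversarial multi-pig scenes keep cross-pig ear-center distances
    above the pairing window (plus margin) so the true pairing is
    unambiguous.
    """
    rows, cols = cfg.frame_shape
    others = others or []
    for _ in range(max_tries):
        params = _sample_params(cfg, rng)
        heading = float(rng.uniform(0.0, 360.0))
        if clip_edge:
            pad = 10.0
            head = np.array([rng.uniform(-pad, cols + pad), rng.uniform(-pad, rows + pad)])
        else:
            head = np.array([rng.uniform(0.1 * cols, 0.9 * cols),
                             rng.uniform(0.1 * rows, 0.9 * rows)])
        pig = _build_pig(pig_id, head, heading, **params)
        if clip_edge:
            if _clipped_but_present(pig, cfg.frame_shape):
                return pig
        elif _inside_frame(pig, cfg.frame_shape) and _well_separated(
                pig, others, cfg.ear_distance[1] + 10.0):
            return pig
    raise PlacementError(f"no feasible placement for pig {pig_id} after {max_tries} tries")


def _touching_heads_pigs(cfg: SceneConfig, rng: np.random.Generator,
                         max_tries: int = 500) -> list[PigTruth]:
    """Two pigs whose ear bands are adjacent so that rough pairing mispairs.

    Pig B is the point reflection of pig A through a point M behind A's
    ears; both cross-pig left/right ear distances then equal ``2 |M - E|``
    (E the midpoint of A's ear centers), which is sampled strictly below
    the same-pig distance and inside the pairing window.
    """
    rows, cols = cfg.frame_shape
    d_hi = min(135.0, cfg.ear_distance[1])
    d_lo = max(100.0, cfg.ear_distance[0])
    g_lo = max(30.0, cfg.splay_half_angle[0])
    for _ in range(max_tries):
        params = _sample_params(cfg, rng, ear_distance=(d_lo, d_hi),
                                splay=(g_lo, cfg.splay_half_angle[1]))
        cross = float(rng.uniform(80.0, params["s"] - 10.0))
        heading = float(rng.uniform(0.0, 360.0))
        head = np.array([rng.uniform(0.15 * cols, 0.85 * cols),
                         rng.uniform(0.15 * rows, 0.85 * rows)])
        pig_a = _build_pig(0, head, heading, **params)
        u = unit_vector(heading)
        ear_mid = 0.5 * (pig_a.left_box.center + pig_a.right_box.center)
        mirror = ear_mid - (cross / 2.0) * u
        params_b = _sample_params(cfg, rng, ear_distance=(d_lo, d_hi),
                                  splay=(g_lo, cfg.splay_half_angle[1]))
        # geometry is the exact reflection of pig A; only the temperatures differ
        pig_b = _build_pig(
            1, 2.0 * mirror - head, heading + 180.0,
            s=params["s"], gamma=params["gamma"], length=params["length"],
            width=params["width"], true_temp=params_b["true_temp"],
            peaks=params_b["peaks"], body_temp=params_b["body_temp"])
        if _inside_frame(pig_a, cfg.frame_shape) and _inside_frame(pig_b, cfg.frame_shape):
            return [pig_a, pig_b]
    raise PlacementError(f"no feasible touching-heads layout after {max_tries} tries")


def _render_frame(cfg: SceneConfig, pigs: list[PigTruth],
                  rng: np.random.Generator, frame_id: str) -> FrameRecord:
    """Composite the temperature field, add sensor noise, and quantize to 8 bits."""
    rows, cols = cfg.frame_shape
    field_t = rng.normal(cfg.background_temp[0], cfg.background_temp[1], (rows, cols))
    rr, cc = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij")
    for pig in pigs:
        u = unit_vector(pig.heading_deg)
        n = unit_vector(pig.heading_deg + 90.0)
        ear_mid = 0.5 * (pig.left_box.center + pig.right_box.center)
        body_c = ear_mid - 50.0 * u
        dx = cc - body_c[0]
        dy = rr - body_c[1]
        along = dx * u[0] + dy * u[1]
        across = dx * n[0] + dy * n[1]
        body_mask = (along / 75.0) ** 2 + (across / 42.0) ** 2 <= 1.0
        field_t[body_mask] = np.maximum(field_t[body_mask], pig.body_temp)
        for box, ref, peak in ((pig.left_box, pig.ref_left, pig.ear_peak_left),
                               (pig.right_box, pig.ref_right, pig.ear_peak_right)):
            box_mask = rasterize_mask(box, cfg.frame_shape)
            field_t[box_mask] = np.maximum(field_t[box_mask], peak - 1.2)
            line_mask = reference_line_mask(ref, cfg.frame_shape)
            field_t[line_mask] = np.maximum(field_t[line_mask], peak)
    if cfg.sensor_noise_sd > 0:
        step = (field_t.max() - field_t.min()) / 255.0
        field_t = field_t + rng.normal(0.0, cfg.sensor_noise_sd * step, field_t.shape)
    t_min = float(field_t.min())
    t_max = float(field_t.max())
    pixels = np.rint((field_t - t_min) / (t_max - t_min) * 255.0).astype(np.uint8)
    return FrameRecord(frame_id=frame_id, pixels=pixels, t_min=t_min, t_max=t_max)


def generate_scene(cfg: SceneConfig, frame_id: str = "scene") -> SyntheticScene:
    """Generate one scene (layout plus rendered frame), reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.adversarial == "touching_heads":
        pigs = _touching_heads_pigs(cfg, rng)
    else:
        # scene-level retries: an unlucky first pig can make the rest
        # unplaceable, so restart the whole layout rather than one pig
        for attempt in range(20):
            try:
                pigs = []
                for i in range(cfg.n_pigs):
                    clip = cfg.adversarial == "edge_clip" and i == 0
                    pigs.append(generate_pig(cfg, rng, i, others=pigs,
                                             clip_edge=clip, max_tries=200))
                break
            except PlacementError:
                if attempt == 19:
                    raise
    frame = _render_frame(cfg, pigs, rng, frame_id)
    boxes = [b for pig in pigs for b in (pig.left_box, pig.right_box)]
    return SyntheticScene(frame=frame, labels=LabelSet(frame_id=frame_id, boxes=boxes),
                          pigs=tuple(pigs), config=cfg)


def _manifest_row(frame_id: str, pig: PigTruth) -> dict:
    row = {
        "frame": frame_id,
        "pig": pig.pig_id,
        "heading_deg": pig.heading_deg,
        "true_temp": pig.true_temp,
        "ear_peak_left": pig.ear_peak_left,
        "ear_peak_right": pig.ear_peak_right,
        "body_temp": pig.body_temp,
    }
    for side, box in (("left", pig.left_box), ("right", pig.right_box)):
        for k, (x, y) in enumerate(box.vertices, start=1):
            row[f"{side}_x{k}"] = x
            row[f"{side}_y{k}"] = y
    for side, ref in (("left", pig.ref_left), ("right", pig.ref_right)):
        row[f"ref_{side}_x0"], row[f"ref_{side}_y0"] = ref.p0
        row[f"ref_{side}_x1"], row[f"ref_{side}_y1"] = ref.p1
        row[f"ref_{side}_width"] = ref.width
    return row


def generate_dataset(cfg: SceneConfig, n_frames: int, out_dir: str | Path,
                     dialect: str = "pixel") -> pd.DataFrame:
    """Write `n_frames` scenes (PNG + JSON sidecar + OBB TXT) and a truth manifest.

    Per-frame seeds are derived deterministically from ``cfg.seed``, so
    re-running with the same configuration reproduces identical files.
    Returns the manifest DataFrame (also written as ``manifest.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_frames):
        frame_seed = int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31))
        scene_cfg = replace(cfg, seed=frame_seed)
        frame_id = f"frame_{i:04d}"
        scene = generate_scene(scene_cfg, frame_id=frame_id)
        write_frame(scene.frame, out_dir / f"{frame_id}.png")
        write_obb_txt(scene.labels, out_dir / f"{frame_id}.txt", dialect=dialect,
                      frame_shape=cfg.frame_shape)
        rows.extend(_manifest_row(frame_id, pig) for pig in scene.pigs)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
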