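"""Per-frame processing pipeline: detections in, paired temperatures out.

For every frame the pipeline reads the detection file and the thermal
frame with its temperature sidecar, runs both pairing stages, extracts
the per-pig ear-root temperatures, and accumulates tabular results.
Detector inference is deliberately not embedded — detections are
consumed as files, keeping the pipeline detector-agnostic; any callable
returning a :class:`~pigtherm.io.LabelSet` can stand in as a detections
provider.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .io import FrameRecord, LabelSet, read_frame, read_obb_txt
from .pairing import EarPair, PairingConfig, pair_boxes
from .thermometry import NoMeasurementError, pig_temperature

__all__ = ["RunConfig", "run_pipeline", "pair_to_row"]

logger = logging.getLogger("pigtherm")


@dataclass(frozen=True)
class RunConfig:
    """Options of one pipeline run."""

    dialect: str = "normalized"
    pairing: PairingConfig = field(default_factory=PairingConfig)
    iou_threshold: float = 0.5
    display_precision: int = 1  # decimals for reported temperatures


def pair_to_row(frame_id: str, index: int, pair: EarPair) -> dict:
    """Flatten one pair (with its geometry) into a CSV row."""
    row = {
        "frame": frame_id,
        "pair": index,
        "stage": pair.stage.value,
        "consistent": pair.consistent,
        "center_dist": pair.center_dist,
        "theta": pair.geometry.theta if pair.geometry is not None else None,
    }
    for side, box in (("left", pair.left), ("right", pair.right)):
        for k, (x, y) in enumerate(box.vertices, start=1):
            row[f"{side}_x{k}"] = x
            row[f"{side}_y{k}"] = y
    return row


def _frame_inputs(input_dir: Path) -> list[Path]:
    images = sorted(input_dir.glob("*.png")) + sorted(input_dir.glob("*.tif")) \
        + sorted(input_dir.glob("*.tiff"))
    return images


def run_pipeline(input_dir: str | Path, out_dir: str | Path,
                 cfg: RunConfig | None = None,
                 detections_provider: Callable[[Path, FrameRecord], LabelSet] | None = None,
                 ) -> dict:
    """Process every frame in `input_dir` and write results to `out_dir`.

    Expects, per frame, ``<stem>.png`` (or ``.tif``), ``<stem>.json``
    (temperature sidecar) and ``<stem>.txt`` (detections).  Writes
    ``pairs.csv``, ``temperatures.csv`` and ``summary.json``; returns the
    summary dict.  Frames with missing or malformed inputs are skipped
    with a logged reason; a run where *every* frame fails raises.
    """
    cfg = cfg or RunConfig()
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = _frame_inputs(input_dir)
    if not images:
        raise FileNotFoundError(f"no frames found in {input_dir}")

    pair_rows: list[dict] = []
    temp_rows: list[dict] = []
    stage_counts: dict[str, int] = {}
    n_unpaired = 0
    n_frames_ok = 0
    skipped: list[dict] = []

    for image_path in images:
        stem = image_path.stem
        det_path = image_path.with_suffix(".txt")
        try:
            frame = read_frame(image_path)
            if detections_provider is not None:
                labels = detections_provider(image_path, frame)
            else:
                labels = read_obb_txt(det_path, dialect=cfg.dialect,
                                      frame_shape=frame.shape)
        except Exception as exc:
            logger.warning("skipping frame %s: %s", stem, exc)
            skipped.append({"frame": stem, "reason": str(exc)})
            continue
        result = pair_boxes(labels, cfg.pairing)
        n_unpaired += len(result.unpaired)
        for idx, pair in enumerate(result.pairs):
            stage_counts[pair.stage.value] = stage_counts.get(pair.stage.value, 0) + 1
            pair_rows.append(pair_to_row(stem, idx, pair))
            try:
                rec = pig_temperature(frame, pair, pair_index=idx)
            except NoMeasurementError as exc:
                logger.warning("frame %s pair %d: %s", stem, idx, exc)
                continue
            temp_rows.append({
                "frame": stem, "pair": idx, "stage": pair.stage.value,
                "consistent": pair.consistent, "degraded": rec.degraded,
                "t_left": rec.t_left, "t_right": rec.t_right, "t_pig": rec.t_pig,
            })
        n_frames_ok += 1

    if n_frames_ok == 0:
        raise RuntimeError("all frames failed; see log for reasons")

    pd.DataFrame(pair_rows).to_csv(out_dir / "pairs.csv", index=False)
    pd.DataFrame(temp_rows).to_csv(out_dir / "temperatures.csv", index=False)
    t_values = [row["t_pig"] for row in temp_rows]
    summary = {
        "n_frames": len(images),
        "n_frames_processed": n_frames_ok,
        "n_frames_skipped": len(skipped),
        "skipped": skipped,
        "n_pairs": len(pair_rows),
        "n_unpaired_boxes": n_unpaired,
        "pairs_by_stage": stage_counts,
        "n_temperature_records": len(temp_rows),
        "t_pig_mean": round(float(pd.Series(t_values).mean()), 3) if t_values else None,
        "t_pig_min": round(min(t_values), 3) if t_values else None,
        "t_pig_max": round(max(t_values), 3) if t_values else None,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
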