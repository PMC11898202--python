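"""Two-stage left/right ear-root pairing (TEPA).

Stage 1 — *rough pairing*: ear-root boxes are matched greedily by
minimum center distance.  Only pairs whose center distance falls inside
a fixed pixel window (default 80-160 px, the empirical same-pig range at
the nominal camera geometry) are candidates; by default one detector-left
box is matched with one detector-right box.

Stage 2 — *precise pairing*: each rough pair is re-classified from its
own geometry.  The two ear roots of a pig splay like the character "八",
narrow end toward the head, so the outer edge lines of the two boxes
intersect head-ward.  With that intersection as the origin of a polar
coordinate system, the polar angles of the two box centers determine
which box is anatomically left.  If the polar classification contradicts
the detector labels the rough pair is dissolved and its boxes are
re-paired with *other* nearby boxes.

Angle-difference rule
---------------------
With ``theta = (theta1 - theta2) mod 360`` (center angles of the boxes in
slots 1 and 2): if ``theta < 180`` the slot-2 box is the left ear, if
``theta > 180`` the slot-1 box is.  This is the smaller-angle-is-left /
larger-angle-is-left branch rule stated in terms of the modular
difference, which keeps it well-defined for either slot order and across
the 0/360 wrap of the angle scale.  ``theta`` exactly 0 or 180 is
geometrically ambiguous and is never silently classified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Literal, Sequence

import numpy as np

from .geometry import (
    EarSide,
    GeometryError,
    Line2D,
    OrientedBox,
    ParallelLinesError,
    PolarPoint,
    center_distance,
    extreme_vertices,
    line_intersection,
    line_through,
    nearest_vertex_pair,
    polar_angle,
)
from .io import LabelSet

__all__ = [
    "PairingConfig",
    "PairGeometry",
    "EarPair",
    "PairingStage",
    "AmbiguousAngleError",
    "NoHeadOriginError",
    "PrecisePairingResult",
    "classify_by_polar_angles",
    "polar_classify",
    "rough_pair",
    "precise_pair",
    "pair_boxes",
]


class AmbiguousAngleError(GeometryError):
    """Polar angle difference is exactly 0 or 180 degrees; left/right undecidable."""


class NoHeadOriginError(GeometryError):
    """Outermost lines are parallel or degenerate; no head origin exists."""


class PairingStage(str, Enum):
    ROUGH = "rough"
    PRECISE_CONFIRMED = "precise_confirmed"
    PRECISE_REPAIRED = "precise_repaired"
    FALLBACK = "fallback"


@dataclass(frozen=True)
class PairingConfig:
    """Tunable parameters of the pairing stages.

    d_min, d_max
        Center-distance window (pixels) inside which two boxes may belong
        to the same pig.
    class_constrained_rough
        Restrict rough candidates to one detector-left with one
        detector-right box.  The precise stage's consistency test
        presupposes one box of each class, so this is the default; the
        class-agnostic mode pairs any two boxes.
    parallel_fallback
        What to do with a rough pair whose outermost lines are parallel
        (no head origin): ``"keep_rough"`` keeps the pair with its
        detector labels, flagged as a fallback; ``"drop"`` dissolves it
        into the unpaired list.
    """

    d_min: float = 80.0
    d_max: float = 160.0
    class_constrained_rough: bool = True
    parallel_fallback: Literal["keep_rough", "drop"] = "keep_rough"

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError(f"need 0 < d_min < d_max, got ({self.d_min}, {self.d_max})")
        if self.parallel_fallback not in ("keep_rough", "drop"):
            raise ValueError(f"unknown parallel_fallback {self.parallel_fallback!r}")


@dataclass(frozen=True)
class PairGeometry:
    """Geometric quantities of the precise-pairing construction for one pair.

    Base points ``p1``/``p2`` are the nearest inter-box vertices; the
    extreme vertices of each box are taken relative to the *partner's*
    base point, and the line through them is the box's outermost line.
    ``origin`` is the head origin O (intersection of the outermost
    lines); ``c1``/``c2`` are the box centers in polar coordinates about
    O, and ``theta = (c1.angle - c2.angle) mod 360``.
    """

    p1: np.ndarray
    p2: np.ndarray
    p1_min: np.ndarray
    p1_max: np.ndarray
    p2_min: np.ndarray
    p2_max: np.ndarray
    line1: Line2D
    line2: Line2D
    origin: np.ndarray | None = None
    c1: PolarPoint | None = None
    c2: PolarPoint | None = None
    theta: float | None = None


@dataclass(frozen=True)
class EarPair:
    """A matched left/right ear-root pair for one pig."""

    left: OrientedBox
    right: OrientedBox
    center_dist: float
    stage: PairingStage = PairingStage.ROUGH
    consistent: bool | None = None
    geometry: PairGeometry | None = None

    @property
    def boxes(self) -> tuple[OrientedBox, OrientedBox]:
        return (self.left, self.right)


def classify_by_polar_angles(theta1: float, theta2: float) -> tuple[float, int]:
    """Apply the angle-difference rule to two polar angles (degrees).

    Returns ``(theta, left_slot)`` where ``theta = (theta1 - theta2) mod
    360`` and ``left_slot`` is 1 or 2, the slot classified as the left
    ear.  Raises :class:`AmbiguousAngleError` for theta exactly 0 or 180.
    """
    theta = (float(theta1) - float(theta2)) % 360.0
    if theta == 0.0 or theta == 180.0:
        raise AmbiguousAngleError(f"angle difference {theta} deg cannot be classified")
    return theta, (2 if theta < 180.0 else 1)


def polar_classify(box1: OrientedBox, box2: OrientedBox) -> tuple[PairGeometry, OrientedBox, OrientedBox]:
    """Classify the two boxes of a pair as left/right from their pairing geometry.

    Returns ``(geometry, left_box, right_box)`` where the assignment comes
    from the polar-coordinate rule, independent of the detector labels.

    Raises
    ------
    NoHeadOriginError
        If the outermost lines are parallel (or the construction is
        degenerate) so no head origin exists.
    AmbiguousAngleError
        If the angle difference is exactly 0 or 180 degrees.
    """
    p1, p2 = nearest_vertex_pair(box1, box2)
    p1_min, p1_max = extreme_vertices(box1, p2)
    p2_min, p2_max = extreme_vertices(box2, p1)
    try:
        line1 = line_through(p1_min, p1_max)
        line2 = line_through(p2_min, p2_max)
        origin = line_intersection(line1, line2)
        c1 = polar_angle(box1.center, origin)
        c2 = polar_angle(box2.center, origin)
    except AmbiguousAngleError:
        raise
    except ParallelLinesError as exc:
        raise NoHeadOriginError(str(exc)) from None
    except GeometryError as exc:
        raise NoHeadOriginError(f"degenerate pairing geometry: {exc}") from None
    theta, left_slot = classify_by_polar_angles(c1.angle, c2.angle)
    geom = PairGeometry(p1=p1, p2=p2, p1_min=p1_min, p1_max=p1_max,
                        p2_min=p2_min, p2_max=p2_max, line1=line1, line2=line2,
                        origin=origin, c1=c1, c2=c2, theta=theta)
    if left_slot == 1:
        return geom, box1, box2
    return geom, box2, box1


def _as_box_list(boxes: LabelSet | Iterable[OrientedBox]) -> list[OrientedBox]:
    if isinstance(boxes, LabelSet):
        return list(boxes.boxes)
    return list(boxes)


def _greedy_min_distance(boxes: Sequence[OrientedBox], cfg: PairingConfig,
                         class_of: dict[int, EarSide | None] | None = None,
                         forbidden: set[frozenset[int]] | None = None,
                         class_constrained: bool = True,
                         ) -> tuple[list[tuple[int, int, float]], list[int]]:
    """Greedy global-minimum matching on box indices.

    Returns matched index pairs ``(i, j, dist)`` with ``i``/``j`` ordered
    so the left-class box (when determinable) comes first, plus leftover
    indices.  Determinism: candidates are taken in (distance, i, j) order.
    """
    n = len(boxes)
    if class_of is None:
        class_of = {k: boxes[k].label for k in range(n)}
    forbidden = forbidden or set()
    candidates = []
    for i, j in itertools.combinations(range(n), 2):
        if frozenset((i, j)) in forbidden:
            continue
        ci, cj = class_of[i], class_of[j]
        if class_constrained:
            if {ci, cj} != {EarSide.LEFT, EarSide.RIGHT}:
                continue
        d = center_distance(boxes[i], boxes[j])
        if not (cfg.d_min <= d <= cfg.d_max):
            continue
        candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        if class_of[i] == EarSide.RIGHT and class_of[j] == EarSide.LEFT:
            i, j = j, i
        pairs.append((i, j, d))
    leftovers = [k for k in range(n) if k not in used]
    return pairs, leftovers


def rough_pair(boxes: LabelSet | Iterable[OrientedBox],
               cfg: PairingConfig | None = None,
               ) -> tuple[list[EarPair], list[OrientedBox]]:
    """Stage 1: greedy minimum-center-distance pairing within the distance window.

    Repeatedly selects the candidate pair with the globally smallest
    center distance inside ``[d_min, d_max]``, emits it, and removes both
    boxes; boxes left without a partner are returned as unpaired.
    """
    cfg = cfg or PairingConfig()
    box_list = _as_box_list(boxes)
    idx_pairs, leftovers = _greedy_min_distance(
        box_list, cfg, class_constrained=cfg.class_constrained_rough)
    pairs = [EarPair(left=box_list[i], right=box_list[j], center_dist=d,
                     stage=PairingStage.ROUGH)
             for i, j, d in idx_pairs]
    return pairs, [box_list[k] for k in leftovers]


@dataclass
class PrecisePairingResult:
    """Outcome of the precise stage, with repair bookkeeping."""

    pairs: list[EarPair]
    unpaired: list[OrientedBox]
    n_confirmed: int = 0
    n_dissolved: int = 0
    n_repaired: int = 0
    n_fallback: int = 0


def _validate_repaired(left: OrientedBox, right: OrientedBox, dist: float,
                       cfg: PairingConfig) -> EarPair:
    """Re-validate a re-formed pair once; survivors that still conflict are flagged."""
    labels_ok = left.label == EarSide.LEFT and right.label == EarSide.RIGHT
    try:
        geom, polar_left, _ = polar_classify(left, right)
    except (NoHeadOriginError, AmbiguousAngleError):
        return EarPair(left, right, dist, PairingStage.FALLBACK, consistent=False)
    if labels_ok and polar_left is left:
        return EarPair(left, right, dist, PairingStage.PRECISE_REPAIRED,
                       consistent=True, geometry=geom)
    return EarPair(left, right, dist, PairingStage.FALLBACK,
                   consistent=False, geometry=geom)


def precise_pair(rough_pairs: Sequence[EarPair], unpaired: Sequence[OrientedBox],
                 cfg: PairingConfig | None = None) -> PrecisePairingResult:
    """Stage 2: polar-coordinate validation and one round of re-pairing.

    Each rough pair is polar-classified.  Pairs whose polar left/right
    assignment agrees with the detector labels are confirmed.  Mismatched
    pairs are dissolved and their boxes pooled with the unpaired boxes;
    the pool is re-paired greedily by minimum center distance within the
    distance window, one polar-left with one polar-right (boxes that were
    never polar-classified keep their detector class), excluding the
    dissolved combinations so a failed pair cannot simply re-form.
    Re-formed pairs are re-validated once; survivors that still conflict
    are kept as flagged fallbacks rather than silently dropped.

    Every input box ends up in exactly one output pair or in the unpaired
    list.
    """
    cfg = cfg or PairingConfig()
    result_pairs: list[EarPair] = []
    pool: list[OrientedBox] = list(unpaired)
    pool_class: dict[int, EarSide | None] = {id(b): b.label for b in unpaired}
    dropped: list[OrientedBox] = []
    forbidden: set[frozenset[int]] = set()
    n_dissolved = 0
    n_confirmed = 0
    n_fallback = 0

    for pair in rough_pairs:
        try:
            geom, polar_left, polar_right = polar_classify(pair.left, pair.right)
        except AmbiguousAngleError:
            result_pairs.append(replace(pair, stage=PairingStage.FALLBACK, consistent=False))
            n_fallback += 1
            continue
        except NoHeadOriginError:
            if cfg.parallel_fallback == "keep_rough":
                result_pairs.append(replace(pair, stage=PairingStage.FALLBACK, consistent=False))
                n_fallback += 1
            else:
                # "drop": the pair's geometry is unusable, return its boxes
                # as unpaired rather than feeding them to the repair round
                dropped.extend(pair.boxes)
            continue
        if polar_left is pair.left:
            result_pairs.append(replace(pair, stage=PairingStage.PRECISE_CONFIRMED,
                                        consistent=True, geometry=geom))
            n_confirmed += 1
        else:
            # rough pairing error: dissolve, remember the polar classes and
            # forbid this combination in the re-pairing round
            n_dissolved += 1
            pool.extend(pair.boxes)
            pool_class[id(polar_left)] = EarSide.LEFT
            pool_class[id(polar_right)] = EarSide.RIGHT
            forbidden.add(frozenset((id(pair.left), id(pair.right))))

    class_by_index = {k: pool_class[id(b)] for k, b in enumerate(pool)}
    forbidden_idx = {
        frozenset((i, j))
        for i, j in itertools.combinations(range(len(pool)), 2)
        if frozenset((id(pool[i]), id(pool[j]))) in forbidden
    }
    idx_pairs, leftovers = _greedy_min_distance(
        pool, cfg, class_of=class_by_index, forbidden=forbidden_idx,
        class_constrained=True)

    n_repaired = 0
    for i, j, d in idx_pairs:
        a, b = pool[i], pool[j]
        # final slots follow the detector labels when they are one of each;
        # otherwise the re-pairing (polar) classes already ordered i, j
        if a.label == EarSide.RIGHT and b.label == EarSide.LEFT:
            a, b = b, a
        pair = _validate_repaired(a, b, d, cfg)
        if pair.stage == PairingStage.PRECISE_REPAIRED:
            n_repaired += 1
        else:
            n_fallback += 1
        result_pairs.append(pair)

    return PrecisePairingResult(
        pairs=result_pairs,
        unpaired=[pool[k] for k in leftovers] + dropped,
        n_confirmed=n_confirmed,
        n_dissolved=n_dissolved,
        n_repaired=n_repaired,
        n_fallback=n_fallback,
    )


def pair_boxes(boxes: LabelSet | Iterable[OrientedBox],
               cfg: PairingConfig | None = None) -> PrecisePairingResult:
    """Run both pairing stages on one frame's boxes."""
    cfg = cfg or PairingConfig()
    rough, unpaired = rough_pair(boxes, cfg)
    return precise_pair(rough, unpaired, cfg)
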