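"""Per-frame two-step tracking of tagged insects.

The tracker is a deterministic state machine over two per-frame detection
streams: *shape detections* (bounding box + confidence, from an object
detector) and *marker detections* (fiducial marker ID + center point, from
a matrix-code reader).  Each frame is processed in two consecutive steps:

1. **Association** — every confidence-filtered shape detection is compared
   against the boxes of the entities already in the system.  A detection
   with no positive box overlap becomes a new entity (reported ID −1); a
   detection overlapping one or more known boxes updates the position of
   the entity with the largest raw intersection area and marks it *seen*.
2. **Identity voting** — every detected marker whose center point falls
   inside an entity's box adds one vote for that marker ID to the entity's
   ordered vote ledger; when the center falls inside several boxes the
   entity whose box center lies closest to the marker wins.  An entity
   reports the marker ID with the highest vote count, so a missed or
   misread marker never revokes an established identity.

Entities that go undetected are retained at their last position for a
configurable number of frames (the *ghost threshold*) and deleted once
their run of consecutive misses exceeds it.  Every entity still in the
system at the end of a frame — seen or ghost-retained — emits one output
record.

Tie-breaking is deterministic throughout: equal overlap or equal marker
distance resolves to the lowest (oldest) entity key, and an exact vote tie
resolves to the earliest-inserted marker ID in the ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .geometry import BoundingBox, Point, box_overlap

__all__ = [
    "ShapeDetection",
    "MarkerDetection",
    "TrackedEntity",
    "TrackerConfig",
    "TrackerState",
    "TrackRecord",
    "filter_detections",
    "associate_frame",
    "assign_markers",
    "apply_ghosts",
    "step",
    "run_tracker",
    "records_to_frame",
    "TRACK_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Conditions understood by :meth:`TrackerConfig.for_condition`.
CONDITIONS = ("nest-ir", "forage-ir", "forage-vis")

#: Ghost-threshold presets per tracking condition (frames).  The nest is
#: tracked with a longer retention because ants move slower there and
#: missed detections are more often transient.
GHOST_PRESETS = {"nest-ir": 5, "forage-ir": 1, "forage-vis": 1}


@dataclass(frozen=True)
class ShapeDetection:
    """One detector hit: a candidate insect shape in a single frame."""

    frame: int
    bbox: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"negative frame index: {self.frame}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class MarkerDetection:
    """One decoded fiducial marker: its dictionary ID and center point."""

    frame: int
    marker_id: int
    center: Point

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"negative frame index: {self.frame}")
        if self.marker_id < 0:
            raise ValueError(f"marker_id must be non-negative, got {self.marker_id}")


@dataclass
class TrackedEntity:
    """The tracker's live hypothesis of one insect.

    ``marker_votes`` is an insertion-ordered mapping from marker ID to the
    number of times that marker was assigned to this entity; the reported
    identity is the argmax, with ties resolved in favour of the earliest
    inserted key.
    """

    entity_key: int
    bbox: BoundingBox
    unseen_count: int = 0
    marker_votes: dict[int, int] = field(default_factory=dict)
    seen_this_frame: bool = False

    def reported_id(self) -> int:
        """Current identity: −1 until any marker vote exists."""
        if not self.marker_votes:
            return -1
        best_id, best_count = -1, 0
        for marker_id, count in self.marker_votes.items():  # insertion order
            if count > best_count:
                best_id, best_count = marker_id, count
        return best_id

    def add_vote(self, marker_id: int) -> None:
        self.marker_votes[marker_id] = self.marker_votes.get(marker_id, 0) + 1


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable tracker parameters.

    confidence_threshold
        Shape detections must *exceed* this probability to enter the
        system (strict comparison).
    ghost_threshold
        Number of consecutive undetected frames an entity survives; with
        threshold g an entity is deleted on its (g+1)-th consecutive miss.
    fps
        Frame rate of the source video, used only for time conversions.
    """

    confidence_threshold: float = 0.5
    ghost_threshold: int = 1
    fps: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.ghost_threshold < 0:
            raise ValueError("ghost_threshold must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @classmethod
    def for_condition(cls, condition: str, **overrides) -> "TrackerConfig":
        """Preset for a named tracking condition (``nest-ir``, ``forage-ir``,
        ``forage-vis``), selecting the condition's ghost threshold."""
        if condition not in GHOST_PRESETS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        kwargs = {"ghost_threshold": GHOST_PRESETS[condition]}
        kwargs.update(overrides)
        return cls(**kwargs)

    def ghost_seconds(self) -> float:
        return self.ghost_threshold / self.fps


@dataclass
class TrackerState:
    """Mutable tracker state: the live entities and the frame cursor."""

    frame: int = 0
    entities: list[TrackedEntity] = field(default_factory=list)
    next_key: int = 0

    def new_entity(self, bbox: BoundingBox) -> TrackedEntity:
        ent = TrackedEntity(entity_key=self.next_key, bbox=bbox, seen_this_frame=True)
        self.next_key += 1
        self.entities.append(ent)
        logger.debug("frame %d: entity %d born", self.frame, ent.entity_key)
        return ent


@dataclass(frozen=True)
class TrackRecord:
    """One output row: the state of one live entity at one frame.

    ``seen`` is False for ghost-retained rows (the entity was not detected
    this frame and its last box was carried over).
    """

    frame: int
    entity_key: int
    reported_id: int
    bbox: BoundingBox
    center: Point
    seen: bool


def filter_detections(
    detections: Sequence[ShapeDetection], threshold: float
) -> list[ShapeDetection]:
    """Keep detections whose confidence strictly exceeds ``threshold``.

    Input order is preserved.  All detections must share one frame index.
    """
    frames = {d.frame for d in detections}
    if len(frames) > 1:
        raise ValueError(f"detections span multiple frames: {sorted(frames)}")
    return [d for d in detections if d.confidence > threshold]


def associate_frame(
    state: TrackerState, detections: Sequence[ShapeDetection]
) -> TrackerState:
    """Associate one frame's shape detections with the live entities.

    Detections are processed in list order.  A detection overlapping no
    *eligible* entity box (positive intersection area) is added as a new
    entity; otherwise the eligible entity with the largest intersection
    area has its box replaced by the detection's and is marked seen.
    Entities already seen this frame are ineligible, so a second detection
    falling on the same entity spills over to other entities or founds a
    new one.  Equal overlap resolves to the lowest entity key.
    """
    for det in detections:
        if det.frame != state.frame:
            raise ValueError(
                f"detection frame {det.frame} does not match state frame {state.frame}"
            )
        best: TrackedEntity | None = None
        best_overlap = 0.0
        for ent in state.entities:
            if ent.seen_this_frame:
                continue
            ov = box_overlap(det.bbox, ent.bbox)
            if ov > best_overlap:  # strict: ties keep the earlier (lower) key
                best, best_overlap = ent, ov
        if best is None:
            state.new_entity(det.bbox)
        else:
            best.bbox = det.bbox
            best.seen_this_frame = True
    return state


def assign_markers(
    state: TrackerState, markers: Sequence[MarkerDetection]
) -> TrackerState:
    """Assign one frame's marker detections to entity vote ledgers.

    Each marker whose center lies inside at least one live entity's box
    (boundary inclusive) adds one vote for its ID to exactly one entity:
    the containing entity whose box center is nearest to the marker
    center, with an exact distance tie resolving to the lowest entity
    key.  Markers inside no box are dropped.
    """
    for mk in markers:
        if mk.frame != state.frame:
            raise ValueError(
                f"marker frame {mk.frame} does not match state frame {state.frame}"
            )
        best: TrackedEntity | None = None
        best_dist = float("inf")
        for ent in state.entities:
            if not ent.bbox.contains(mk.center):
                continue
            d = ent.bbox.center().distance_to(mk.center)
            if d < best_dist:  # strict: ties keep the earlier (lower) key
                best, best_dist = ent, d
        if best is not None:
            best.add_vote(mk.marker_id)
    return state


def apply_ghosts(
    state: TrackerState, config: TrackerConfig
) -> tuple[TrackerState, list[TrackRecord]]:
    """Close out a frame: update miss counters, delete expired entities,
    emit one record per surviving entity.

    An entity missed this frame has its ``unseen_count`` incremented and
    is deleted — emitting nothing — once that count exceeds the ghost
    threshold; so an entity last seen at frame f is deleted at frame
    f + ghost_threshold + 1 exactly.  Seen entities reset their counter.
    """
    records: list[TrackRecord] = []
    survivors: list[TrackedEntity] = []
    for ent in state.entities:
        if ent.seen_this_frame:
            ent.unseen_count = 0
        else:
            ent.unseen_count += 1
            if ent.unseen_count > config.ghost_threshold:
                logger.debug(
                    "frame %d: entity %d deleted (unseen %d frames)",
                    state.frame,
                    ent.entity_key,
                    ent.unseen_count,
                )
                continue
        records.append(
            TrackRecord(
                frame=state.frame,
                entity_key=ent.entity_key,
                reported_id=ent.reported_id(),
                bbox=ent.bbox,
                center=ent.bbox.center(),
                seen=ent.seen_this_frame,
            )
        )
        survivors.append(ent)
    state.entities = survivors
    return state, records


def step(
    state: TrackerState,
    shape_detections: Sequence[ShapeDetection],
    marker_detections: Sequence[MarkerDetection],
    config: TrackerConfig,
) -> tuple[TrackerState, list[TrackRecord]]:
    """Process one frame: filter → associate → vote → ghost lifecycle.

    Inputs must carry the state's current frame index; the frame cursor
    advances by one.  Returns the frame's output records.
    """
    for ent in state.entities:
        ent.seen_this_frame = False
    kept = filter_detections(shape_detections, config.confidence_threshold)
    if kept and kept[0].frame != state.frame:
        raise ValueError(
            f"out-of-order input: detections for frame {kept[0].frame}, "
            f"state at frame {state.frame}"
        )
    associate_frame(state, kept)
    assign_markers(state, marker_detections)
    state, records = apply_ghosts(state, config)
    state.frame += 1
    return state, records


FramePacket = tuple[int, Sequence[ShapeDetection], Sequence[MarkerDetection]]

#: Column order of the trajectory table produced by :func:`run_tracker`.
TRACK_COLUMNS = [
    "frame",
    "entity_key",
    "id",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "cx",
    "cy",
    "seen",
]


def iter_track_records(
    stream: Iterable[FramePacket], config: TrackerConfig, state: TrackerState | None = None
) -> Iterator[TrackRecord]:
    """Run the tracker over a frame-indexed stream, yielding records as
    frames complete.  Memory use is constant in the number of frames.

    ``stream`` yields ``(frame, shape_detections, marker_detections)``
    tuples for contiguous frames starting at the state's frame cursor —
    this is the detector-adapter contract, satisfied by the CSV reader
    and by any live detector front-end.
    """
    for frame, shapes, markers in stream:
        if state is None:  # created lazily at the stream's first frame
            state = TrackerState(frame=frame)
        if frame != state.frame:
            raise ValueError(
                f"non-contiguous stream: expected frame {state.frame}, got {frame}"
            )
        state, records = step(state, shapes, markers, config)
        yield from records


def run_tracker(stream: Iterable[FramePacket], config: TrackerConfig) -> pd.DataFrame:
    """Track a whole stream and return the trajectory table.

    One row per live entity per frame, columns :data:`TRACK_COLUMNS`;
    ``id`` is the entity's reported marker identity (−1 when unknown) and
    ``seen`` is False for ghost-retained rows.
    """
    return records_to_frame(iter_track_records(stream, config))


def records_to_frame(records: Iterable[TrackRecord]) -> pd.DataFrame:
    rows = [
        (
            r.frame,
            r.entity_key,
            r.reported_id,
            r.bbox.x_min,
            r.bbox.y_min,
            r.bbox.x_max,
            r.bbox.y_max,
            r.center.x,
            r.center.y,
            r.seen,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    if df.empty:
        df = df.astype({"frame": int, "entity_key": int, "id": int, "seen": bool})
    return df
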