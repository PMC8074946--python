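"""Shared fixtures and the literal brute-force association oracle.

The oracle re-implements the per-frame association and marker-voting
rules as plain loops over dictionaries, independently of the package's
state machine, so the two can be compared on randomized frames.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from bach.geometry import BoundingBox, Point
from bach.trackcore import (
    MarkerDetection,
    ShapeDetection,
    TrackedEntity,
    TrackerState,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# --------------------------------------------------------------------------
# literal oracle: plain-loop transcription of the association rules
# --------------------------------------------------------------------------

def _overlap(a, b) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return w * h if (w > 0 and h > 0) else 0.0


def _center(box):
    return ((box[0] + box[2]) / 2.0, (box[1] + box[3]) / 2.0)


def oracle_associate(entities: list[dict], detections: list[tuple], next_key: int) -> int:
    """Apply the association rules literally.  ``entities`` is a list of
    dicts with keys ``key, box, seen, votes`` (votes: ordered list of
    ``[marker_id, count]``); mutated in place.  Returns the next key."""
    for det in detections:
        candidates = []
        for ent in entities:
            if ent["seen"]:
                continue
            ov = _overlap(det, ent["box"])
            if ov > 0.0:
                candidates.append((ov, ent))
        if not candidates:
            entities.append({"key": next_key, "box": det, "seen": True, "votes": []})
            next_key += 1
        else:
            # largest overlap; exact tie -> lowest (oldest) entity key
            best = sorted(candidates, key=lambda c: (-c[0], c[1]["key"]))[0][1]
            best["box"] = det
            best["seen"] = True
    return next_key


def oracle_assign_markers(entities: list[dict], markers: list[tuple]) -> None:
    """Apply the marker-voting rules literally.  ``markers`` is a list of
    ``(marker_id, (cx, cy))`` tuples."""
    for marker_id, (cx, cy) in markers:
        containing = [
            e
            for e in entities
            if e["box"][0] <= cx <= e["box"][2] and e["box"][1] <= cy <= e["box"][3]
        ]
        if not containing:
            continue

        def key_fn(e):
            ex, ey = _center(e["box"])
            return (math.hypot(ex - cx, ey - cy), e["key"])

        best = min(containing, key=key_fn)
        for pair in best["votes"]:
            if pair[0] == marker_id:
                pair[1] += 1
                break
        else:
            best["votes"].append([marker_id, 1])


def oracle_reported_id(votes: list[list[int]]) -> int:
    if not votes:
        return -1
    best_id, best_count = -1, 0
    for marker_id, count in votes:  # insertion order; strict > keeps earliest on tie
        if count > best_count:
            best_id, best_count = marker_id, count
    return best_id


# --------------------------------------------------------------------------
# randomized-frame construction shared by unit and acceptance tests
# --------------------------------------------------------------------------

def random_frame_case(rng: np.random.Generator, max_boxes: int = 6):
    """One randomized association scenario: a few pre-existing entities
    (some with votes), up to ``max_boxes`` detections and a handful of
    markers, on a 100×100 px canvas with deliberately heavy overlap."""
    n_entities = int(rng.integers(0, max_boxes + 1))
    n_dets = int(rng.integers(0, max_boxes + 1))
    n_markers = int(rng.integers(0, 5))

    def rand_box():
        x0 = float(rng.uniform(0, 80))
        y0 = float(rng.uniform(0, 80))
        return (x0, y0, x0 + float(rng.uniform(2, 25)), y0 + float(rng.uniform(2, 25)))

    entities = []
    for k in range(n_entities):
        votes = []
        for marker_id in rng.choice(6, size=int(rng.integers(0, 3)), replace=False):
            votes.append([int(marker_id), int(rng.integers(1, 4))])
        entities.append({"key": k, "box": rand_box(), "seen": False, "votes": votes})
    detections = [rand_box() for _ in range(n_dets)]
    markers = [
        (int(rng.integers(0, 6)), (float(rng.uniform(0, 105)), float(rng.uniform(0, 105))))
        for _ in range(n_markers)
    ]
    return entities, detections, markers


def state_from_oracle_entities(entities: list[dict], frame: int = 0) -> TrackerState:
    """Build the package's tracker state mirroring oracle entity dicts."""
    ents = []
    for e in entities:
        ent = TrackedEntity(
            entity_key=e["key"],
            bbox=BoundingBox(*e["box"]),
            marker_votes={int(m): int(c) for m, c in e["votes"]},
        )
        ents.append(ent)
    next_key = max((e["key"] for e in entities), default=-1) + 1
    return TrackerState(frame=frame, entities=ents, next_key=next_key)


def as_shape_detections(boxes, frame: int = 0):
    return [
        ShapeDetection(frame=frame, bbox=BoundingBox(*b), confidence=0.9) for b in boxes
    ]


def as_marker_detections(markers, frame: int = 0):
    return [
        MarkerDetection(frame=frame, marker_id=m, center=Point(*c)) for m, c in markers
    ]


def assert_state_matches_oracle(state: TrackerState, entities: list[dict]) -> None:
    """Entity-by-entity comparison of the package state with the oracle."""
    assert len(state.entities) == len(entities)
    impl = {e.entity_key: e for e in state.entities}
    for oe in entities:
        ie = impl[oe["key"]]
        assert tuple(
            (ie.bbox.x_min, ie.bbox.y_min, ie.bbox.x_max, ie.bbox.y_max)
        ) == pytest.approx(oe["box"])
        assert ie.seen_this_frame == oe["seen"]
        assert list(ie.marker_votes.items()) == [(m, c) for m, c in oe["votes"]]
        assert ie.reported_id() == oracle_reported_id(oe["votes"])


def run_oracle_equivalence_trial(rng: np.random.Generator) -> None:
    """One randomized frame: implementation vs literal oracle."""
    from bach.trackcore import assign_markers, associate_frame

    entities, detections, markers = random_frame_case(rng)
    state = state_from_oracle_entities(entities)
    next_key = state.next_key
    associate_frame(state, as_shape_detections(detections))
    assign_markers(state, as_marker_detections(markers))
    oracle_associate(entities, detections, next_key)
    oracle_assign_markers(entities, markers)
    assert_state_matches_oracle(state, entities)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
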