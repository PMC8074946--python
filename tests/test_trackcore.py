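"""Unit tests for the per-frame two-step tracking state machine."""

import numpy as np
import pytest

from conftest import (
    as_marker_detections,
    as_shape_detections,
    run_oracle_equivalence_trial,
)

from bach.geometry import BoundingBox, Point
from bach.trackcore import (
    MarkerDetection,
    ShapeDetection,
    TrackedEntity,
    TrackerConfig,
    TrackerState,
    apply_ghosts,
    assign_markers,
    associate_frame,
    filter_detections,
    run_tracker,
    step,
)


def det(box, conf=0.9, frame=0):
    return ShapeDetection(frame=frame, bbox=BoundingBox(*box), confidence=conf)


def marker(marker_id, center, frame=0):
    return MarkerDetection(frame=frame, marker_id=marker_id, center=Point(*center))


# --------------------------------------------------------------------------
# confidence filtering
# --------------------------------------------------------------------------

class TestFilterDetections:
    def test_strictly_greater_than_threshold(self):
        dets = [det((0, 0, 1, 1), 0.9), det((1, 1, 2, 2), 0.3), det((2, 2, 3, 3), 0.5)]
        kept = filter_detections(dets, 0.5)
        assert kept == [dets[0]]  # 0.5 itself does not "exceed" 0.5

    def test_zero_threshold_keeps_positive_confidences(self):
        dets = [det((0, 0, 1, 1), 0.0), det((1, 1, 2, 2), 0.01)]
        assert filter_detections(dets, 0.0) == [dets[1]]

    def test_matches_exhaustive_scan_on_random_confidences(self, rng):
        dets = [det((0, 0, 1, 1), float(c)) for c in rng.random(100)]
        for threshold in (0.0, 0.25, 0.5, 0.9):
            expected = [d for d in dets if d.confidence > threshold]
            assert filter_detections(dets, threshold) == expected

    def test_order_preserved(self, rng):
        confs = rng.random(50)
        dets = [det((0, 0, 1, 1), float(c)) for c in confs]
        kept = filter_detections(dets, 0.4)
        assert kept == sorted(kept, key=dets.index)

    def test_mixed_frames_rejected(self):
        with pytest.raises(ValueError, match="multiple frames"):
            filter_detections([det((0, 0, 1, 1)), det((0, 0, 1, 1), frame=1)], 0.5)


# --------------------------------------------------------------------------
# association
# --------------------------------------------------------------------------

class TestAssociateFrame:
    def test_cold_start_creates_unidentified_entity(self):
        state = TrackerState()
        associate_frame(state, [det((0, 0, 10, 10))])
        assert len(state.entities) == 1
        ent = state.entities[0]
        assert ent.reported_id() == -1
        assert ent.seen_this_frame and ent.unseen_count == 0

    def test_seen_entity_cannot_absorb_second_detection(self):
        # one entity, two overlapping detections: the first updates it,
        # the second must found a new entity even though it overlaps
        state = TrackerState()
        associate_frame(state, [det((0, 0, 10, 10))])
        state.entities[0].seen_this_frame = False
        state.frame = 1
        associate_frame(state, [det((8, 0, 18, 10), frame=1), det((0, 8, 10, 18), frame=1)])
        assert len(state.entities) == 2
        first, second = state.entities
        assert (first.bbox.x_min, first.bbox.x_max) == (8, 18)
        assert (second.bbox.y_min, second.bbox.y_max) == (8, 18)

    def test_largest_raw_overlap_wins(self):
        # detection overlaps A by 60 px² and B by 80 px² -> B is updated
        state = TrackerState()
        a = state.new_entity(BoundingBox(0, 0, 10, 10))
        b = state.new_entity(BoundingBox(6, 0, 16, 10))
        a.seen_this_frame = b.seen_this_frame = False
        associate_frame(state, [det((4, 0, 14, 10))])
        assert len(state.entities) == 2
        assert not a.seen_this_frame
        assert b.seen_this_frame
        assert (b.bbox.x_min, b.bbox.x_max) == (4, 14)

    def test_equal_overlap_tie_goes_to_oldest_entity(self):
        state = TrackerState()
        a = state.new_entity(BoundingBox(0, 0, 10, 10))
        b = state.new_entity(BoundingBox(0, 0, 10, 10))
        a.seen_this_frame = b.seen_this_frame = False
        associate_frame(state, [det((2, 2, 8, 8))])
        assert a.seen_this_frame and not b.seen_this_frame

    def test_no_positive_overlap_founds_new_entity(self):
        state = TrackerState()
        a = state.new_entity(BoundingBox(0, 0, 10, 10))
        a.seen_this_frame = False
        associate_frame(state, [det((10, 0, 20, 10))])  # touching edge: area 0
        assert len(state.entities) == 2
        assert not a.seen_this_frame


# --------------------------------------------------------------------------
# marker voting
# --------------------------------------------------------------------------

class TestAssignMarkers:
    def test_unique_container_gets_the_vote(self):
        state = TrackerState()
        ent = state.new_entity(BoundingBox(0, 0, 10, 10))
        assign_markers(state, [marker(3, (5, 5))])
        assert ent.marker_votes == {3: 1}
        assert ent.reported_id() == 3

    def test_nearest_entity_center_wins_in_intersection(self):
        state = TrackerState()
        far = state.new_entity(BoundingBox(0, 0, 14, 14))  # center (7, 7)
        near = state.new_entity(BoundingBox(0, 0, 6, 6))  # center (3, 3)
        assign_markers(state, [marker(5, (3, 3))])
        assert near.marker_votes == {5: 1}
        assert far.marker_votes == {}

    def test_exact_distance_tie_goes_to_lowest_key(self):
        state = TrackerState()
        a = state.new_entity(BoundingBox(0, 0, 10, 10))
        b = state.new_entity(BoundingBox(0, 0, 10, 10))
        assign_markers(state, [marker(2, (5, 5))])
        assert a.marker_votes == {2: 1} and b.marker_votes == {}

    def test_marker_outside_every_box_is_dropped(self):
        state = TrackerState()
        ent = state.new_entity(BoundingBox(0, 0, 10, 10))
        assign_markers(state, [marker(1, (50, 50))])
        assert ent.marker_votes == {}

    def test_boundary_point_counts_as_inside(self):
        state = TrackerState()
        ent = state.new_entity(BoundingBox(0, 0, 10, 10))
        assign_markers(state, [marker(4, (10, 10))])
        assert ent.marker_votes == {4: 1}

    def test_reported_id_follows_running_argmax(self):
        ent = TrackedEntity(entity_key=0, bbox=BoundingBox(0, 0, 1, 1))
        for m in [7, 7, 12]:
            ent.add_vote(m)
        assert ent.reported_id() == 7
        for m in [12, 12]:
            ent.add_vote(m)
        assert ent.reported_id() == 12

    def test_vote_tie_resolved_by_insertion_order(self):
        ent = TrackedEntity(entity_key=0, bbox=BoundingBox(0, 0, 1, 1))
        for m in [12, 7, 7, 12]:
            ent.add_vote(m)
        assert ent.reported_id() == 12  # 12 entered the ordered ledger first
        ent2 = TrackedEntity(entity_key=1, bbox=BoundingBox(0, 0, 1, 1))
        for m in [7, 12, 12, 7]:
            ent2.add_vote(m)
        assert ent2.reported_id() == 7


# --------------------------------------------------------------------------
# ghost lifecycle
# --------------------------------------------------------------------------

def run_miss_pattern(ghost_threshold, pattern):
    """Drive one entity through a hit/miss pattern; returns per-frame
    (alive_after_frame, record_emitted, record_seen_flag)."""
    config = TrackerConfig(ghost_threshold=ghost_threshold)
    state = TrackerState()
    out = []
    for f, hit in enumerate(pattern):
        dets = [det((0, 0, 10, 10), frame=f)] if hit else []
        state, records = step(state, dets, [], config)
        out.append((len(state.entities), len(records), records[0].seen if records else None))
    return out


class TestGhostLifecycle:
    @pytest.mark.parametrize("threshold", range(6))
    def test_deleted_exactly_when_misses_exceed_threshold(self, threshold):
        # hit, then all misses: survives exactly `threshold` missed frames
        pattern = [True] + [False] * (threshold + 2)
        out = run_miss_pattern(threshold, pattern)
        for i in range(1, threshold + 1):
            assert out[i] == (1, 1, False)  # ghost-retained and emitted
        assert out[threshold + 1] == (0, 0, None)  # deleted, nothing emitted

    @pytest.mark.parametrize("threshold", range(6))
    def test_redetection_resets_the_miss_counter(self, threshold):
        if threshold == 0:
            pattern = [True, True, False]
            out = run_miss_pattern(threshold, pattern)
            assert out[1] == (1, 1, True)
            assert out[2] == (0, 0, None)
            return
        pattern = [True] + [False] * threshold + [True] + [False] * threshold
        out = run_miss_pattern(threshold, pattern)
        assert all(alive == 1 for alive, _, _ in out[:-1])
        assert out[-1] == (1, 1, False)  # counter was reset by the re-detection

    def test_nest_preset_survives_five_missed_frames(self):
        out = run_miss_pattern(5, [True] + [False] * 6)
        assert [alive for alive, _, _ in out] == [1, 1, 1, 1, 1, 1, 0]

    def test_revival_keeps_entity_key_and_votes(self):
        config = TrackerConfig(ghost_threshold=5)
        state = TrackerState()
        state, _ = step(state, [det((0, 0, 10, 10))], [marker(3, (5, 5))], config)
        key = state.entities[0].entity_key
        for f in range(1, 4):  # three missed frames
            state, _ = step(state, [], [], config)
        state, records = step(state, [det((1, 0, 11, 10), frame=4)], [], config)
        assert state.entities[0].entity_key == key
        assert state.entities[0].marker_votes == {3: 1}
        assert records[0].reported_id == 3

    def test_ghost_rows_carry_last_box_and_seen_false(self):
        config = TrackerConfig(ghost_threshold=2)
        state = TrackerState()
        state, _ = step(state, [det((0, 0, 10, 10))], [], config)
        state, records = step(state, [], [], config)
        (rec,) = records
        assert not rec.seen
        assert (rec.bbox.x_min, rec.bbox.y_max) == (0, 10)


# --------------------------------------------------------------------------
# step composition and whole-stream behaviour
# --------------------------------------------------------------------------

class TestStep:
    def test_empty_frame_without_entities_emits_nothing(self):
        state, records = step(TrackerState(), [], [], TrackerConfig())
        assert records == [] and state.frame == 1

    def test_out_of_order_frame_rejected(self):
        state = TrackerState()
        with pytest.raises(ValueError, match="out-of-order"):
            step(state, [det((0, 0, 1, 1), frame=3)], [], TrackerConfig())

    def test_low_confidence_detections_never_enter_the_system(self):
        config = TrackerConfig(confidence_threshold=0.5)
        state, records = step(TrackerState(), [det((0, 0, 1, 1), conf=0.4)], [], config)
        assert state.entities == [] and records == []

    def test_replay_is_deterministic(self, rng):
        def play():
            state = TrackerState()
            config = TrackerConfig(ghost_threshold=1)
            out = []
            r = np.random.default_rng(7)
            for f in range(30):
                dets = [
                    det((x, x, x + 10, x + 12), conf=0.9, frame=f)
                    for x in r.uniform(0, 50, r.integers(0, 4))
                ]
                mks = [marker(int(r.integers(0, 5)), (float(r.uniform(0, 60)),) * 2, frame=f)]
                state, records = step(state, dets, mks, config)
                out.extend(records)
            return out

        assert play() == play()

    def test_entity_keys_never_reused(self):
        config = TrackerConfig(ghost_threshold=0)
        state = TrackerState()
        keys = set()
        for f in range(10):
            # alternate detections so entities die and new ones are born
            dets = [det((0, 0, 10, 10), frame=f)] if f % 2 == 0 else []
            state, records = step(state, dets, [], config)
            keys.update(r.entity_key for r in records)
        assert keys == {0, 1, 2, 3, 4}

    def test_identity_persists_while_shape_stays_detected(self):
        """Once any marker vote exists, a continuously detected entity
        keeps reporting an identity even when markers go unread."""
        config = TrackerConfig()
        state = TrackerState()
        reported = []
        for f in range(20):
            mks = [marker(9, (5, 5), frame=f)] if f == 2 else []
            state, records = step(state, [det((0, 0, 10, 10), frame=f)], mks, config)
            reported.append(records[0].reported_id)
        assert reported[:2] == [-1, -1]
        assert all(r == 9 for r in reported[2:])

    def test_vote_counts_monotonic_over_lifetime(self):
        config = TrackerConfig()
        state = TrackerState()
        prev = {}
        r = np.random.default_rng(11)
        for f in range(30):
            mks = [marker(int(r.integers(0, 3)), (5, 5), frame=f)]
            state, _ = step(state, [det((0, 0, 10, 10), frame=f)], mks, config)
            votes = dict(state.entities[0].marker_votes)
            assert all(votes.get(m, 0) >= c for m, c in prev.items())
            prev = votes


class TestRunTracker:
    def test_single_constant_detection_yields_one_entity(self):
        stream = [(f, [det((0, 0, 10, 10), frame=f)], []) for f in range(50)]
        tracks = run_tracker(stream, TrackerConfig())
        assert len(tracks) == 50
        assert tracks["entity_key"].nunique() == 1
        assert tracks["seen"].all()

    def test_non_contiguous_stream_rejected(self):
        stream = [(0, [], []), (2, [], [])]
        with pytest.raises(ValueError, match="non-contiguous"):
            run_tracker(stream, TrackerConfig())

    def test_empty_stream_gives_empty_table(self):
        tracks = run_tracker([], TrackerConfig())
        assert len(tracks) == 0
        assert list(tracks.columns)[:3] == ["frame", "entity_key", "id"]


class TestConfig:
    def test_condition_presets_match_stated_ghost_thresholds(self):
        assert TrackerConfig.for_condition("nest-ir").ghost_threshold == 5
        assert TrackerConfig.for_condition("forage-ir").ghost_threshold == 1
        assert TrackerConfig.for_condition("forage-vis").ghost_threshold == 1
        with pytest.raises(ValueError):
            TrackerConfig.for_condition("garden")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TrackerConfig(confidence_threshold=1.5)
        with pytest.raises(ValueError):
            TrackerConfig(ghost_threshold=-1)
        with pytest.raises(ValueError):
            TrackerConfig(fps=0)


# --------------------------------------------------------------------------
# oracle equivalence on randomized frames (small sample; the acceptance
# suite runs the full-size version)
# --------------------------------------------------------------------------

def test_association_matches_literal_oracle_on_random_frames():
    rng = np.random.default_rng(424242)
    for _ in range(200):
        run_oracle_equivalence_trial(rng)
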