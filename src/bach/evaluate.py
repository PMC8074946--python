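"""Scoring of tracker output against ground truth.

Mirrors a human-observer-style evaluation protocol: a subsample of
frames (by default one in ten, frames 60–240 of a 250-frame video) is
scored per ant instance for *detection* (the shape was found),
*identification* (a marker identity was reported) and *correct
identification* (the reported identity matches the true one).  Merged
("double") detections count as detecting one of the two ants involved,
and "double plus one" configurations — the merged box plus one partner
detected alone — as detecting both.

The module also provides the walking-speed proxy (displacement between
consecutive analysed frames, with sub-noise speeds floored to zero),
identity-exchange ("swap") episode extraction, and a closed-form
Pearson χ² test for count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchedInstance",
    "MetricsReport",
    "SpeedSeries",
    "SwapEpisode",
    "sample_frames",
    "match_records",
    "rates",
    "compute_speeds",
    "swap_episodes",
    "pearson_chi2",
    "SPEED_FLOOR_MM_S",
    "DEFAULT_BODY_LENGTH_MM",
]

#: Speeds below this value (mm s⁻¹) are artefacts of bounding-box jitter
#: and are rounded to exactly zero.
SPEED_FLOOR_MM_S = 0.75

#: Mean worker body length (mm); half of it is the default spatial gate
#: when matching track records to ground-truth positions.
DEFAULT_BODY_LENGTH_MM = 6.81


@dataclass(frozen=True)
class MatchedInstance:
    """Scoring outcome for one (frame, ant) ground-truth instance."""

    frame: int
    true_id: int
    entity_key: int | None
    detected: bool
    identified: bool
    correct: bool
    double_flag: str = "none"  # none | double | double_plus_one
    reported_id: int | None = None

    def __post_init__(self) -> None:
        if self.correct and not self.identified:
            raise ValueError("correct implies identified")
        if self.identified and not self.detected:
            raise ValueError("identified implies detected")


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate detection/identification performance over a set of
    scored instances."""

    n_instances: int
    n_detected: int
    n_identified: int
    n_correct: int
    n_double: int
    n_double_plus_one: int

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_instances if self.n_instances else float("nan")

    @property
    def identification_rate(self) -> float:
        return self.n_identified / self.n_instances if self.n_instances else float("nan")

    @property
    def correct_rate(self) -> float:
        return self.n_correct / self.n_instances if self.n_instances else float("nan")

    @property
    def correct_given_identified(self) -> float:
        return self.n_correct / self.n_identified if self.n_identified else float("nan")

    @property
    def incorrect_given_identified(self) -> float:
        return (
            (self.n_identified - self.n_correct) / self.n_identified
            if self.n_identified
            else float("nan")
        )

    def as_dict(self) -> dict:
        return {
            "n_instances": self.n_instances,
            "n_detected": self.n_detected,
            "n_identified": self.n_identified,
            "n_correct": self.n_correct,
            "n_double": self.n_double,
            "n_double_plus_one": self.n_double_plus_one,
            "detection_rate": self.detection_rate,
            "identification_rate": self.identification_rate,
            "correct_rate": self.correct_rate,
            "correct_given_identified": self.correct_given_identified,
        }


@dataclass(frozen=True)
class SpeedSeries:
    """Per-individual walking-speed proxy at analysed frames.

    The first analysed frame carries no speed (there is no preceding
    analysed frame to difference against), so ``frames`` starts at the
    second analysed frame.
    """

    ident: int
    stride: int
    frames: tuple[int, ...]
    speeds: tuple[float, ...]


@dataclass(frozen=True)
class SwapEpisode:
    """A maximal run of frames over which one entity reports another
    ant's identity."""

    entity_key: int
    start_frame: int
    end_frame: int
    true_id: int
    wrong_id: int
    duration: int
    onset_proximity_mm: float


def sample_frames(start: int, end: int, stride: int) -> list[int]:
    """Arithmetic frame subsample start, start+stride, … ≤ end."""
    if stride <= 0:
        raise ValueError("stride must be positive")
    if end < start:
        raise ValueError("end must be >= start")
    return list(range(start, end + 1, stride))


def _greedy_match(
    rec_xy: np.ndarray, truth_xy: np.ndarray, max_dist: float
) -> dict[int, int]:
    """Greedy nearest-pair one-to-one matching; returns truth_idx → rec_idx."""
    if len(rec_xy) == 0 or len(truth_xy) == 0:
        return {}
    d = np.linalg.norm(rec_xy[:, None, :] - truth_xy[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_r: set[int] = set()
    out: dict[int, int] = {}
    for ri, ti in order:
        ri, ti = int(ri), int(ti)
        if d[ri, ti] > max_dist:
            break
        if ri in used_r or ti in out:
            continue
        used_r.add(ri)
        out[ti] = ri
    return out


def match_records(
    tracks: pd.DataFrame,
    truth: pd.DataFrame,
    max_dist_mm: float | None = None,
    px_per_mm: float = 12.0,
    frames: Sequence[int] | None = None,
) -> list[MatchedInstance]:
    """Score tracker output against ground truth frame by frame.

    Seen track records are matched one-to-one to truth rows by greedy
    nearest-center assignment within ``max_dist_mm`` (default: half a
    body length); ghost-retained rows are excluded.  A matched truth row
    whose merge partner went unmatched is flagged ``double`` (one ant
    detected for the pair); if the partner was matched by a second
    record the pair is flagged ``double_plus_one`` (both detected).

    ``frames`` restricts scoring to the given frame subsample; by
    default every frame present in the truth table is scored.
    """
    if max_dist_mm is None:
        max_dist_mm = DEFAULT_BODY_LENGTH_MM / 2.0
    max_dist_px = max_dist_mm * px_per_mm
    if frames is None:
        frame_list = sorted(truth["frame"].unique())
    else:
        frame_list = list(frames)

    seen_tracks = tracks[tracks["seen"].astype(bool)] if len(tracks) else tracks
    tracks_by_frame = dict(tuple(seen_tracks.groupby("frame"))) if len(seen_tracks) else {}
    truth_by_frame = dict(tuple(truth.groupby("frame"))) if len(truth) else {}

    instances: list[MatchedInstance] = []
    for f in frame_list:
        tf = truth_by_frame.get(f)
        if tf is None or tf.empty:
            continue
        rf = tracks_by_frame.get(f)
        tf = tf.reset_index(drop=True)
        if rf is None or rf.empty:
            rec_xy = np.empty((0, 2))
            rec_ids = np.empty(0, dtype=int)
            rec_keys = np.empty(0, dtype=int)
        else:
            rf = rf.reset_index(drop=True)
            rec_xy = rf[["cx", "cy"]].to_numpy(float)
            rec_ids = rf["id"].to_numpy(int)
            rec_keys = rf["entity_key"].to_numpy(int)
        truth_xy = tf[["cx", "cy"]].to_numpy(float)
        match = _greedy_match(rec_xy, truth_xy, max_dist_px)

        true_ids = tf["true_id"].to_numpy(int)
        merged = (
            tf["merged_with"].to_numpy(int)
            if "merged_with" in tf.columns
            else np.full(len(tf), -1)
        )
        id_to_row = {int(t): k for k, t in enumerate(true_ids)}
        for k in range(len(tf)):
            detected = k in match
            flag = "none"
            partner = int(merged[k])
            if partner >= 0 and partner in id_to_row:
                pk = id_to_row[partner]
                if detected and pk in match:
                    flag = "double_plus_one"
                elif detected != (pk in match):
                    flag = "double"
            if detected:
                ri = match[k]
                rep = int(rec_ids[ri])
                identified = rep != -1
                correct = identified and rep == int(true_ids[k])
                instances.append(
                    MatchedInstance(
                        frame=int(f),
                        true_id=int(true_ids[k]),
                        entity_key=int(rec_keys[ri]),
                        detected=True,
                        identified=identified,
                        correct=correct,
                        double_flag=flag,
                        reported_id=rep,
                    )
                )
            else:
                instances.append(
                    MatchedInstance(
                        frame=int(f),
                        true_id=int(true_ids[k]),
                        entity_key=None,
                        detected=False,
                        identified=False,
                        correct=False,
                        double_flag=flag,
                    )
                )
    return instances


def rates(instances: Iterable[MatchedInstance]) -> MetricsReport:
    """Aggregate scored instances into detection/identification rates.

    ``n_double`` counts merged pairs scored as one detection;
    ``n_double_plus_one`` counts pairs where the merged box coexisted
    with a solo detection of one partner (pairs are counted once)."""
    inst = list(instances)
    n_double = sum(1 for i in inst if i.double_flag == "double" and i.detected)
    n_dp1 = sum(1 for i in inst if i.double_flag == "double_plus_one") // 2
    return MetricsReport(
        n_instances=len(inst),
        n_detected=sum(i.detected for i in inst),
        n_identified=sum(i.identified for i in inst),
        n_correct=sum(i.correct for i in inst),
        n_double=n_double,
        n_double_plus_one=n_dp1,
    )


def compute_speeds(
    table: pd.DataFrame,
    px_per_mm: float,
    stride: int = 10,
    fps: float = 10.0,
    frames: Sequence[int] | None = None,
    id_col: str | None = None,
) -> dict[int, SpeedSeries]:
    """Walking-speed proxy from positions at analysed frames.

    The speed attributed to analysed frame *f* is the Euclidean distance
    between the individual's positions at frames *f* and *f − stride*,
    converted to millimetres and divided by the elapsed time
    ``stride / fps`` seconds.  No speed exists for the first analysed
    frame.  Values below :data:`SPEED_FLOOR_MM_S` are rounded to exactly
    zero — sub-millimetre displacements are bounding-box jitter, not
    locomotion.

    ``table`` needs columns ``frame``, ``cx``, ``cy`` (pixels) and an
    identity column (``true_id`` for ground truth, else ``entity_key``).
    """
    if px_per_mm <= 0 or fps <= 0 or stride <= 0:
        raise ValueError("px_per_mm, fps and stride must be positive")
    if id_col is None:
        id_col = "true_id" if "true_id" in table.columns else "entity_key"
    if frames is None:
        present = sorted(int(f) for f in table["frame"].unique())
        analysed = (
            sample_frames(present[0], present[-1], stride) if present else []
        )
    else:
        analysed = sorted(int(f) for f in frames)
    dt = stride / fps

    out: dict[int, SpeedSeries] = {}
    for ident, grp in table.groupby(id_col):
        pos = {
            int(r.frame): (float(r.cx), float(r.cy))
            for r in grp.itertuples()
        }
        fs: list[int] = []
        vs: list[float] = []
        for prev, cur in zip(analysed[:-1], analysed[1:]):
            if cur - prev != stride:
                continue
            if prev not in pos or cur not in pos:
                continue
            dx = pos[cur][0] - pos[prev][0]
            dy = pos[cur][1] - pos[prev][1]
            v = float(np.hypot(dx, dy)) / px_per_mm / dt
            if v < SPEED_FLOOR_MM_S:
                v = 0.0
            fs.append(int(cur))
            vs.append(v)
        out[int(ident)] = SpeedSeries(
            ident=int(ident), stride=stride, frames=tuple(fs), speeds=tuple(vs)
        )
    return out


def swap_episodes(
    tracks: pd.DataFrame,
    truth: pd.DataFrame,
    max_dist_mm: float | None = None,
    px_per_mm: float = 12.0,
) -> list[SwapEpisode]:
    """Extract identity-exchange episodes.

    An episode is a maximal run of consecutive frames in which a matched
    track record reports an identity that belongs to a *different* ant.
    The onset proximity is the distance (mm) between the wronged ant and
    the ant whose identity it reports, at the episode's first frame.
    """
    instances = match_records(
        tracks, truth, max_dist_mm=max_dist_mm, px_per_mm=px_per_mm
    )
    truth_ids = set(int(t) for t in truth["true_id"].unique()) if len(truth) else set()
    pos_lookup = {
        (int(r.frame), int(r.true_id)): (float(r.cx), float(r.cy))
        for r in truth.itertuples()
    }

    by_entity: dict[int, list[MatchedInstance]] = {}
    for inst in instances:
        if inst.entity_key is None:
            continue
        by_entity.setdefault(inst.entity_key, []).append(inst)

    episodes: list[SwapEpisode] = []
    for key, insts in by_entity.items():
        insts.sort(key=lambda i: i.frame)
        run: list[tuple[MatchedInstance, int]] = []

        def close_run(run: list[tuple[MatchedInstance, int]]) -> None:
            if not run:
                return
            first, wrong_id = run[0]
            a = pos_lookup.get((first.frame, first.true_id))
            b = pos_lookup.get((first.frame, wrong_id))
            prox = float("nan")
            if a is not None and b is not None:
                prox = float(np.hypot(a[0] - b[0], a[1] - b[1])) / px_per_mm
            episodes.append(
                SwapEpisode(
                    entity_key=key,
                    start_frame=run[0][0].frame,
                    end_frame=run[-1][0].frame,
                    true_id=first.true_id,
                    wrong_id=wrong_id,
                    duration=len(run),
                    onset_proximity_mm=prox,
                )
            )

        prev_frame = None
        prev_wrong = None
        for inst in insts:
            wrong = (
                inst.reported_id
                if (
                    inst.identified
                    and inst.reported_id != inst.true_id
                    and inst.reported_id in truth_ids
                )
                else None
            )
            contiguous = prev_frame is not None and inst.frame == prev_frame + 1
            if wrong is not None and contiguous and wrong == prev_wrong:
                run.append((inst, wrong))
            else:
                close_run(run)
                run = [(inst, wrong)] if wrong is not None else []
            prev_frame, prev_wrong = inst.frame, wrong
        close_run(run)
    episodes.sort(key=lambda e: (e.start_frame, e.entity_key))
    return episodes


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson's χ² test of independence on an r×c count table.

    Expected counts come from the row/column margins; the statistic is
    Σ (observed − expected)² / expected with (r−1)(c−1) degrees of
    freedom and the p-value from the χ² survival function.  No
    continuity correction is applied.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2×2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("every row and column margin must be positive")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, df, p_value
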