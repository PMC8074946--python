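"""Synthetic tagged-colony simulator.

Generates per-frame shape-detection and marker-detection streams, with a
ground-truth table, for a group of individually tagged ants walking in a
2-D arena.  The generator emulates the noise structure observed when a
real-time detector tracks tagged *Camponotus* ants filmed at 10 frames
per second for 25 s (250 frames) in three lighting/arena conditions:

``nest-ir``
    nest area under infrared light — slow walking (marginal per-frame
    speed 1.19 ± 2.20 mm s⁻¹), sharp images.
``forage-ir``
    foraging area under infrared light — 2.44 ± 4.95 mm s⁻¹.
``forage-vis``
    foraging area under visible + UV light — stressed, fast walking
    (6.71 ± 9.43 mm s⁻¹), frequent motion blur.

Noise channels, each independently seeded so that changing one parameter
never perturbs the draws of another channel:

* **motion** — correlated random walk with per-frame speed redraw and
  reflective walls; occasional wall-climb episodes during which an ant is
  undetectable.
* **detection** — each ant's shape is emitted with probability
  ``p_detect_moving`` / ``p_detect_stationary``; pairs of ants in close
  proximity may instead be emitted as a single merged box ("double"
  detection), optionally with one partner also emitted alone ("double
  plus one").
* **marker** — the ant's fiducial marker is read with a probability that
  depends on its image blur class (sharp / blurry / very_blurry, driven
  by speed) and marker visibility class (horizontal / tilted /
  invisible); a read may return a wrong dictionary ID with probability
  ``p_misread``.  Invisible markers are never read.

Speed model.  ``speed_mean`` / ``speed_sd`` parameterise the *marginal*
per-frame speed distribution, zeros included: a frame is a pause (speed
exactly 0) with probability ``pause_prob``, otherwise speed is drawn
from a zero-truncated normal whose underlying location and scale are
calibrated numerically so that the marginal mean and standard deviation
equal the configured values.  This makes the condition presets reproduce
their stated speed summaries exactly in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import BoundingBox, Point
from .trackcore import FramePacket, MarkerDetection, ShapeDetection

__all__ = [
    "ArenaConfig",
    "ConditionParams",
    "AntState",
    "simulate",
    "frame_count",
    "ghost_seconds",
    "condition_preset",
    "noise_free_params",
    "CONDITION_PRESETS",
    "TRUTH_COLUMNS",
    "BLUR_CLASSES",
    "VISIBILITY_CLASSES",
]

#: Default video canvas, pixels (4K webcam frame).
CANVAS_PX = (4096, 2160)

BLUR_CLASSES = ("sharp", "blurry", "very_blurry")
VISIBILITY_CLASSES = ("horizontal", "tilted", "invisible")

TRUTH_COLUMNS = [
    "frame",
    "true_id",
    "cx",
    "cy",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "speed_mm_s",
    "blur",
    "visibility",
    "merged_with",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry, imaging calibration and run size.

    Defaults model a 17 × 12 cm arena filmed from above at 10 fps for
    25 s with ~20 tagged ants; ``px_per_mm`` maps arena millimetres to
    image pixels and must keep the arena inside the 4096 × 2160 canvas.
    """

    width_mm: float = 170.0
    height_mm: float = 120.0
    px_per_mm: float = 12.0
    fps: float = 10.0
    n_frames: int = 250
    n_ants: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_mm, self.height_mm, self.px_per_mm, self.fps) <= 0:
            raise ValueError("arena dimensions, calibration and fps must be positive")
        if self.n_frames < 0 or self.n_ants < 0:
            raise ValueError("n_frames and n_ants must be non-negative")
        if (
            self.width_mm * self.px_per_mm > CANVAS_PX[0]
            or self.height_mm * self.px_per_mm > CANVAS_PX[1]
        ):
            raise ValueError(
                f"arena at {self.px_per_mm} px/mm exceeds the {CANVAS_PX} canvas"
            )

    @property
    def width_px(self) -> float:
        return self.width_mm * self.px_per_mm

    @property
    def height_px(self) -> float:
        return self.height_mm * self.px_per_mm


def _default_read_table() -> dict[str, dict[str, float]]:
    # Marker read probability by (blur, visibility); invisible is always 0.
    return {
        "sharp": {"horizontal": 0.90, "tilted": 0.45, "invisible": 0.0},
        "blurry": {"horizontal": 0.55, "tilted": 0.25, "invisible": 0.0},
        "very_blurry": {"horizontal": 0.15, "tilted": 0.05, "invisible": 0.0},
    }


@dataclass
class ConditionParams:
    """Condition-specific noise and behaviour parameters.

    ``speed_mean`` and ``speed_sd`` are the *marginal* per-frame walking
    speed mean and standard deviation in mm s⁻¹ (zeros included); the
    underlying zero-truncated normal of the walking phase is calibrated
    at construction so the marginal moments match them exactly.
    """

    condition: str = "nest-ir"
    speed_mean: float = 1.19
    speed_sd: float = 2.20
    pause_prob: float = 0.60
    turn_sd: float = 0.4  # rad per frame of heading diffusion
    blur_cutpoints: tuple[float, float] = (2.0, 5.0)  # mm/s: sharp < c1 ≤ blurry ≤ c2 < very_blurry
    visibility_probs: tuple[float, float, float] = (0.60, 0.28, 0.12)
    groom_prob: float = 0.10  # fraction of paused frames spent grooming (marker hidden)
    p_detect_moving: float = 0.90
    p_detect_stationary: float = 0.80
    read_table: dict[str, dict[str, float]] = field(default_factory=_default_read_table)
    p_misread: float = 0.02
    merge_distance_mm: float = 7.46
    min_separation_mm: float = 3.5  # hard-core body exclusion (side-by-side contact)
    avoidance_distance_mm: float = 8.0  # antennation range: steer around neighbours
    contact_prob: float = 0.02  # per-frame chance of starting to seek contact
    contact_release: float = 0.15  # per-frame chance of breaking off a contact bout
    p_merge: float = 0.30
    p_double_plus_one: float = 0.15
    wall_climb_hazard: float = 0.0  # per-frame probability of starting a climb
    wall_climb_release: float = 0.10  # per-frame probability of ending one
    conf_range: tuple[float, float] = (0.5, 1.0)
    dictionary_size: int = 20
    body_length_mean_mm: float = 6.81
    body_length_sd_mm: float = 0.93
    body_width_ratio: float = 0.35

    # calibrated walking-phase truncated-normal parameters (set in __post_init__)
    _walk_loc: float = field(init=False, repr=False, default=0.0)
    _walk_scale: float = field(init=False, repr=False, default=1.0)

    def __post_init__(self) -> None:
        probs = [
            self.pause_prob,
            self.groom_prob,
            self.p_detect_moving,
            self.p_detect_stationary,
            self.p_misread,
            self.p_merge,
            self.p_double_plus_one,
            self.wall_climb_hazard,
            self.wall_climb_release,
            *self.visibility_probs,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.visibility_probs) - 1.0) > 1e-9:
            raise ValueError("visibility_probs must sum to 1")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speed moments must be non-negative")
        if self.speed_mean > 0:
            loc, scale = _calibrate_walking_speed(
                self.speed_mean, self.speed_sd, self.pause_prob
            )
            self._walk_loc, self._walk_scale = loc, scale

    def p_read(self, blur: str, visibility: str) -> float:
        return self.read_table[blur][visibility]

    def blur_class(self, speed: float) -> str:
        c1, c2 = self.blur_cutpoints
        if speed < c1:
            return "sharp"
        if speed <= c2:
            return "blurry"
        return "very_blurry"


def _walking_moments(mean: float, sd: float, pause_prob: float) -> tuple[float, float]:
    """Moments the walking (non-zero) phase must have so that the
    zero-inflated marginal attains (mean, sd)."""
    q = 1.0 - pause_prob
    if q <= 0.0:
        raise ValueError("pause_prob must be < 1 for a non-zero mean speed")
    m = mean / q
    second = (sd**2 + mean**2) / q
    var = second - m**2
    if var <= 0.0:
        raise ValueError(
            "infeasible speed target: marginal sd too small for this pause_prob"
        )
    return m, float(np.sqrt(var))


def _calibrate_walking_speed(
    mean: float, sd: float, pause_prob: float
) -> tuple[float, float]:
    """Location/scale of the zero-truncated normal whose truncated moments
    equal the required walking-phase moments.

    A zero-truncated normal has coefficient of variation strictly below 1,
    so targets implying a walking CV ≥ 1 are rejected; condition presets
    pick pause probabilities that keep the walking CV near 0.9.
    """
    m, s = _walking_moments(mean, sd, pause_prob)
    cv = s / m
    if cv >= 0.98:
        raise ValueError(
            f"infeasible walking-phase CV {cv:.3f} (≥ 1 unreachable for a "
            "zero-truncated normal); increase pause_prob"
        )

    def residual(x: np.ndarray) -> np.ndarray:
        loc, log_scale = x
        scale = np.exp(log_scale)
        a = (0.0 - loc) / scale
        tm, tv = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        return np.array([tm - m, np.sqrt(tv) - s])

    for guess in ([m, np.log(s)], [m - 2 * s, np.log(1.5 * s)], [-m, np.log(2 * s)]):
        sol = optimize.root(residual, np.asarray(guess, dtype=float), method="hybr")
        if sol.success and np.max(np.abs(sol.fun)) < 1e-8 * max(m, 1.0):
            return float(sol.x[0]), float(np.exp(sol.x[1]))
    raise RuntimeError(
        f"walking-speed calibration failed for mean={mean}, sd={sd}, pause={pause_prob}"
    )


#: Condition presets.  Speed summaries are the marginal per-frame targets
#: for each condition; pause probabilities are chosen per condition to keep
#: the walking-phase distribution reachable (see module docstring) and to
#: reflect that ants in visible light pause least.
CONDITION_PRESETS: dict[str, dict] = {
    "nest-ir": dict(
        condition="nest-ir",
        speed_mean=1.19,
        speed_sd=2.20,
        pause_prob=0.60,
        visibility_probs=(0.60, 0.28, 0.12),
        wall_climb_hazard=0.0,
    ),
    "forage-ir": dict(
        condition="forage-ir",
        speed_mean=2.44,
        speed_sd=4.95,
        pause_prob=0.65,
        visibility_probs=(0.55, 0.30, 0.15),
        wall_climb_hazard=0.002,
    ),
    "forage-vis": dict(
        condition="forage-vis",
        speed_mean=6.71,
        speed_sd=9.43,
        pause_prob=0.40,
        visibility_probs=(0.55, 0.30, 0.15),
        wall_climb_hazard=0.002,
    ),
}


def condition_preset(condition: str, **overrides) -> ConditionParams:
    """Build the :class:`ConditionParams` preset for a named condition."""
    if condition not in CONDITION_PRESETS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {tuple(CONDITION_PRESETS)}"
        )
    kwargs = dict(CONDITION_PRESETS[condition])
    kwargs.update(overrides)
    return ConditionParams(**kwargs)


def noise_free_params(condition: str = "nest-ir", **overrides) -> ConditionParams:
    """Preset with every noise channel switched off: perfect detection,
    perfect marker reads, no merges, no misreads, no climbs, markers
    always horizontal."""
    perfect_read = {b: {"horizontal": 1.0, "tilted": 1.0, "invisible": 0.0} for b in BLUR_CLASSES}
    kwargs = dict(
        p_detect_moving=1.0,
        p_detect_stationary=1.0,
        read_table=perfect_read,
        p_misread=0.0,
        p_merge=0.0,
        p_double_plus_one=0.0,
        wall_climb_hazard=0.0,
        groom_prob=0.0,
        contact_prob=0.0,
        visibility_probs=(1.0, 0.0, 0.0),
        conf_range=(1.0, 1.0),
    )
    kwargs.update(overrides)
    return condition_preset(condition, **kwargs)


@dataclass
class AntState:
    """Snapshot of one simulated ant (exposed mainly for introspection)."""

    true_id: int
    position_mm: Point
    heading: float
    current_speed: float
    body_length_mm: float
    behaviour: str  # walking | paused | wall-climb | grooming


def frame_count(fps: float, duration_s: float) -> int:
    """Number of frames in a recording: fps × duration, labelled 0..n−1."""
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration must be positive")
    return int(round(fps * duration_s))


def ghost_seconds(frames: int, fps: float) -> float:
    """Convert a ghost threshold in frames to seconds."""
    if frames < 0:
        raise ValueError("frames must be non-negative")
    if fps <= 0:
        raise ValueError("fps must be positive")
    return frames / fps


def _sample_walking_speeds(
    n: int, params: ConditionParams, rng: np.random.Generator
) -> np.ndarray:
    if params.speed_mean == 0.0 or n == 0:
        return np.zeros(n)
    loc, scale = params._walk_loc, params._walk_scale
    a = (0.0 - loc) / scale
    return np.asarray(
        stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=n, random_state=rng)
    )


def _avoidance_steering(
    pos: np.ndarray,
    heading: np.ndarray,
    step_len: np.ndarray,
    avoid_dist: float,
    min_sep: float,
    ignore: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Antennation-range collision avoidance.

    An ant heading towards any neighbour within its look-ahead range —
    ``avoid_dist`` mm, extended for fast steps — turns to slide
    tangentially around the most obstructing one (choosing the tangent
    nearer its current heading) instead of walking into it, re-checking
    a few times in case the dodge aims it at somebody else.  An ant
    hemmed in on all sides turns straight back, and if even that path is
    blocked it freezes for the frame (``blocked`` True in the returned
    mask).  Ants flagged in ``ignore`` are contact-seekers and keep
    their heading.  Deterministic — consumes no random draws.

    Returns ``(headings, blocked)``.
    """
    n = len(pos)
    blocked = np.zeros(n, dtype=bool)
    if n < 2 or avoid_dist <= 0:
        return heading, blocked
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = j − i
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    toward = np.arctan2(diff[..., 1], diff[..., 0])
    new_heading = heading.copy()
    for i in range(n):
        if step_len[i] <= 0.0 or (ignore is not None and ignore[i]):
            continue
        # perception range plus this step's length: any step that could
        # end within antennation range of a neighbour triggers steering
        look = avoid_dist + step_len[i]

        def obstructor(h: float) -> int | None:
            cos_t = np.cos(h - toward[i])
            mask = (dist[i] < look) & (cos_t > 0.0)
            if not mask.any():
                return None
            score = np.where(mask, cos_t / np.maximum(dist[i], 1e-9), -np.inf)
            return int(np.argmax(score))

        for _ in range(3):
            j = obstructor(new_heading[i])
            if j is None:
                break
            t1, t2 = toward[i, j] + np.pi / 2.0, toward[i, j] - np.pi / 2.0
            d1 = abs(float(np.angle(np.exp(1j * (new_heading[i] - t1)))))
            d2 = abs(float(np.angle(np.exp(1j * (new_heading[i] - t2)))))
            new_heading[i] = t1 if d1 <= d2 else t2
        j = obstructor(new_heading[i])
        if j is not None:  # surrounded: turn straight back, else freeze
            back = toward[i, j] + np.pi
            if obstructor(back) is None:
                new_heading[i] = back
            else:
                new_heading[i] = heading[i]
                blocked[i] = True
    return np.mod(new_heading, 2.0 * np.pi), blocked


def _truncate_steps_at_contact(
    pos: np.ndarray, disp: np.ndarray, min_sep: float
) -> np.ndarray:
    """Scale each ant's displacement so it stops at body contact
    (``min_sep`` mm) with any neighbour's pre-move position, instead of
    walking over it.  Returns the per-ant scale factors in [0, 1]."""
    n = len(pos)
    scale = np.ones(n)
    if n < 2 or min_sep <= 0:
        return scale
    for i in range(n):
        d = disp[i]
        d2 = float(d @ d)
        if d2 <= 0.0:
            continue
        t_max = 1.0
        for j in range(n):
            if j == i:
                continue
            rel = pos[i] - pos[j]
            c = float(rel @ rel) - min_sep**2
            if c <= 0.0:  # already in contact: let the exclusion push resolve it
                continue
            b = 2.0 * float(rel @ d)
            discr = b * b - 4.0 * d2 * c
            if discr <= 0.0:
                continue
            t0 = (-b - np.sqrt(discr)) / (2.0 * d2)
            if 0.0 <= t0 < t_max:
                t_max = t0
        scale[i] = t_max
    return scale


def _resolve_collisions(
    pos: np.ndarray, min_sep: float, bounds: tuple[float, float], max_iter: int = 8
) -> np.ndarray:
    """Hard-core body exclusion: push apart any two ants closer than
    ``min_sep`` mm (ants are solid — they walk around, not through, each
    other).  Symmetric pairwise separation along the center line,
    iterated to convergence, positions kept inside the arena."""
    n = len(pos)
    if n < 2 or min_sep <= 0:
        return pos
    for _ in range(max_iter):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        iu = np.triu_indices(n, k=1)
        close = dist[iu] < min_sep
        if not close.any():
            break
        for i, j in zip(iu[0][close], iu[1][close]):
            d = dist[i, j]
            if d < 1e-9:  # coincident centers: separate along x
                direction = np.array([1.0, 0.0])
            else:
                direction = diff[i, j] / d
            push = (min_sep - d) / 2.0
            pos[i] = pos[i] + direction * push
            pos[j] = pos[j] - direction * push
        pos = np.clip(pos, [0.0, 0.0], list(bounds))
    return pos


def _greedy_proximity_pairs(
    pos: np.ndarray, eligible: np.ndarray, max_dist: float
) -> list[tuple[int, int, float]]:
    """Closest-first pairing of eligible ants within ``max_dist`` mm; each
    ant joins at most one pair."""
    idx = np.flatnonzero(eligible)
    if idx.size < 2:
        return []
    cand: list[tuple[float, int, int]] = []
    for ai in range(idx.size):
        for bi in range(ai + 1, idx.size):
            i, j = int(idx[ai]), int(idx[bi])
            d = float(np.hypot(*(pos[i] - pos[j])))
            if d < max_dist:
                cand.append((d, i, j))
    cand.sort()
    used: set[int] = set()
    pairs = []
    for d, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((i, j, d))
    return pairs


def simulate(
    arena: ArenaConfig, params: ConditionParams
) -> tuple[list[FramePacket], pd.DataFrame]:
    """Generate one synthetic video's detection stream and ground truth.

    Returns ``(stream, truth)`` where ``stream`` is a list of
    ``(frame, shape_detections, marker_detections)`` packets for frames
    0..n_frames−1 (the detector-adapter contract consumed by the
    tracker) and ``truth`` is a table with one row per ant per frame,
    columns :data:`TRUTH_COLUMNS`.  Positions are in pixels; speeds in
    mm s⁻¹; ``merged_with`` is the partner's true ID or −1.

    Fully reproducible from ``arena.seed``: motion, detection, marker and
    merge noise use four independently spawned generator streams, so e.g.
    raising ``p_detect_moving`` flips individual misses to hits without
    re-randomising anything else.
    """
    n = arena.n_ants
    n_frames = arena.n_frames
    ss = np.random.SeedSequence(arena.seed)
    rng_motion, rng_detect, rng_marker, rng_merge = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    stream: list[FramePacket] = []
    truth_rows: list[tuple] = []
    if n == 0 or n_frames == 0:
        stream = [(f, [], []) for f in range(n_frames)]
        return stream, pd.DataFrame(columns=TRUTH_COLUMNS)

    body_len = np.clip(
        rng_motion.normal(params.body_length_mean_mm, params.body_length_sd_mm, n),
        params.body_length_mean_mm - 3.0 * params.body_length_sd_mm,
        params.body_length_mean_mm + 3.0 * params.body_length_sd_mm,
    )
    body_w = body_len * params.body_width_ratio
    margin = body_len.max() / 2.0
    # spread the colony out at start: nestmates begin at least an
    # antennation range apart (dart-throwing with relaxation fallback)
    init_sep = max(params.min_separation_mm, params.avoidance_distance_mm)
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        cand = np.array(
            [
                rng_motion.uniform(margin, arena.width_mm - margin),
                rng_motion.uniform(margin, arena.height_mm - margin),
            ]
        )
        attempts += 1
        if placed == 0 or (
            np.linalg.norm(pos[:placed] - cand, axis=1).min() >= init_sep
        ) or attempts > 50 * n:
            pos[placed] = cand
            placed += 1
    pos = _resolve_collisions(pos, init_sep, (arena.width_mm, arena.height_mm))
    heading = rng_motion.uniform(0.0, 2.0 * np.pi, n)
    climbing = np.zeros(n, dtype=bool)
    seeking = np.zeros(n, dtype=bool)  # contact-seeking behavioural state
    ppm = arena.px_per_mm
    clipped_any = False
    dict_size = max(params.dictionary_size, n)

    for f in range(n_frames):
        # --- motion update (fixed draw counts per frame) -------------------
        turn = rng_motion.normal(0.0, params.turn_sd, n)
        pause_u = rng_motion.random(n)
        walk = _sample_walking_speeds(n, params, rng_motion)
        speed = np.where(pause_u < params.pause_prob, 0.0, walk)
        groom_u = rng_motion.random(n)
        climb_u = rng_motion.random(n)
        vis_u = rng_motion.random(n)
        contact_u = rng_motion.random(n)
        # ants turn while walking; a paused ant keeps its orientation
        heading = np.mod(heading + np.where(speed > 0.0, turn, 0.0), 2 * np.pi)
        # contact-seeking bouts: a seeker walks at its nearest nestmate
        # (antennation/trophallaxis approach) instead of avoiding it
        seeking = np.where(
            seeking, contact_u >= params.contact_release, contact_u < params.contact_prob
        ) & (n > 1)
        if seeking.any():
            dvec = pos[None, :, :] - pos[:, None, :]
            dmat = np.linalg.norm(dvec, axis=2)
            np.fill_diagonal(dmat, np.inf)
            nearest = np.argmin(dmat, axis=1)
            for i in np.flatnonzero(seeking):
                j = nearest[i]
                heading[i] = np.arctan2(dvec[i, j, 1], dvec[i, j, 0])
        step_len = speed / arena.fps
        heading, blocked = _avoidance_steering(
            pos,
            heading,
            step_len,
            params.avoidance_distance_mm,
            params.min_separation_mm,
            ignore=seeking,
        )
        speed = np.where(blocked, 0.0, speed)  # hemmed-in ants freeze this frame
        step_len = speed / arena.fps

        climbing = np.where(
            climbing, climb_u >= params.wall_climb_release, climb_u < params.wall_climb_hazard
        )
        grooming = (speed == 0.0) & (groom_u < params.groom_prob) & ~climbing

        # the recorded speed is the behavioural gait speed; an ant bumping
        # into a nestmate stops early, shortening its realised displacement
        disp = step_len[:, None] * np.column_stack([np.cos(heading), np.sin(heading)])
        scale = _truncate_steps_at_contact(pos, disp, params.min_separation_mm)
        pos = pos + disp * scale[:, None]
        # reflective walls: fold position back in and mirror the heading
        for axis, dim in ((0, arena.width_mm), (1, arena.height_mm)):
            low = pos[:, axis] < 0.0
            high = pos[:, axis] > dim
            pos[low, axis] = -pos[low, axis]
            pos[high, axis] = 2.0 * dim - pos[high, axis]
            out = low | high
            if axis == 0:
                heading[out] = np.pi - heading[out]
            else:
                heading[out] = -heading[out]
        pos = np.clip(pos, [0.0, 0.0], [arena.width_mm, arena.height_mm])
        pos = _resolve_collisions(
            pos, params.min_separation_mm, (arena.width_mm, arena.height_mm)
        )

        # --- appearance classes -------------------------------------------
        blur = [params.blur_class(s) for s in speed]
        pv = np.cumsum(params.visibility_probs)
        vis_idx = np.searchsorted(pv, vis_u, side="right").clip(0, 2)
        visibility = [VISIBILITY_CLASSES[i] for i in vis_idx]
        for i in range(n):
            if climbing[i] or grooming[i]:
                visibility[i] = "invisible"

        # --- true bounding boxes (pixel space, clipped to canvas) ---------
        c, s_ = np.abs(np.cos(heading)), np.abs(np.sin(heading))
        hx = (c * body_len + s_ * body_w) / 2.0
        hy = (s_ * body_len + c * body_w) / 2.0
        x_min = (pos[:, 0] - hx) * ppm
        x_max = (pos[:, 0] + hx) * ppm
        y_min = (pos[:, 1] - hy) * ppm
        y_max = (pos[:, 1] + hy) * ppm
        if (
            (x_min < 0).any()
            or (y_min < 0).any()
            or (x_max > arena.width_px).any()
            or (y_max > arena.height_px).any()
        ):
            clipped_any = True
        x_min = np.clip(x_min, 0.0, None)
        y_min = np.clip(y_min, 0.0, None)
        x_max = np.clip(x_max, None, arena.width_px)
        y_max = np.clip(y_max, None, arena.height_px)
        boxes = [
            BoundingBox(float(x_min[i]), float(y_min[i]), float(x_max[i]), float(y_max[i]))
            for i in range(n)
        ]

        # --- merged ("double") detections ---------------------------------
        merged_with = np.full(n, -1, dtype=int)
        merged_boxes: list[ShapeDetection] = []
        solo_extra: list[int] = []  # "double plus one" partners
        if params.p_merge > 0.0:
            for i, j, _d in _greedy_proximity_pairs(
                pos, ~climbing, params.merge_distance_mm
            ):
                if rng_merge.random() >= params.p_merge:
                    continue
                merged_with[i], merged_with[j] = j, i
                conf = rng_merge.uniform(*params.conf_range)
                merged_boxes.append(
                    ShapeDetection(frame=f, bbox=boxes[i].union(boxes[j]), confidence=conf)
                )
                if rng_merge.random() < params.p_double_plus_one:
                    solo_extra.append(i if rng_merge.random() < 0.5 else j)

        # --- individual shape detections ----------------------------------
        u_det = rng_detect.random(n)
        conf = params.conf_range[0] + rng_detect.random(n) * (
            params.conf_range[1] - params.conf_range[0]
        )
        shapes: list[ShapeDetection] = []
        for i in range(n):
            if climbing[i]:
                continue
            if merged_with[i] >= 0:
                if i in solo_extra:
                    shapes.append(
                        ShapeDetection(frame=f, bbox=boxes[i], confidence=float(conf[i]))
                    )
                continue
            p = params.p_detect_moving if speed[i] > 0 else params.p_detect_stationary
            if u_det[i] < p:
                shapes.append(
                    ShapeDetection(frame=f, bbox=boxes[i], confidence=float(conf[i]))
                )
        shapes.extend(merged_boxes)

        # --- marker detections ---------------------------------------------
        u_read = rng_marker.random(n)
        u_mis = rng_marker.random(n)
        wrong = rng_marker.integers(0, max(dict_size - 1, 1), n)
        markers: list[MarkerDetection] = []
        for i in range(n):
            if climbing[i] or visibility[i] == "invisible":
                continue
            if u_read[i] >= params.p_read(blur[i], visibility[i]):
                continue
            marker_id = i
            if params.p_misread > 0.0 and u_mis[i] < params.p_misread:
                w = int(wrong[i])
                marker_id = w if w < i else w + 1  # uniform over the other IDs
            markers.append(
                MarkerDetection(frame=f, marker_id=marker_id, center=boxes[i].center())
            )

        stream.append((f, shapes, markers))
        for i in range(n):
            truth_rows.append(
                (
                    f,
                    i,
                    pos[i, 0] * ppm,
                    pos[i, 1] * ppm,
                    boxes[i].x_min,
                    boxes[i].y_min,
                    boxes[i].x_max,
                    boxes[i].y_max,
                    float(speed[i]),
                    blur[i],
                    visibility[i],
                    int(merged_with[i]),
                )
            )

    if clipped_any:
        warnings.warn(
            "some bounding boxes extended beyond the canvas and were clipped",
            stacklevel=2,
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return stream, truth
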