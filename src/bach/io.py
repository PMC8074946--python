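"""CSV formats, configuration files and the detector-adapter contract.

Three fixed-schema CSV files tie the pipeline together:

* detection stream — ``frame,kind,x_min,y_min,x_max,y_max,confidence,marker_id,cx,cy``
  with ``kind`` ∈ {shape, marker} and the unused fields left empty;
* trajectory (tracker output) — ``frame,entity_key,id,x_min,y_min,x_max,y_max,cx,cy,seen``;
* ground truth — ``frame,true_id,cx,cy,x_min,y_min,x_max,y_max,speed_mm_s,blur,visibility,merged_with``.

Headers are validated byte-exactly and malformed rows are reported with
file and line number.  Floats are serialised with 3 decimal places —
sub-pixel precision beyond sensor noise carries no information.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml

from .geometry import BoundingBox, Point
from .simulator import ArenaConfig, TRUTH_COLUMNS
from .trackcore import (
    FramePacket,
    MarkerDetection,
    ShapeDetection,
    TRACK_COLUMNS,
    TrackerConfig,
    TrackRecord,
)

__all__ = [
    "DETECTION_HEADER",
    "TRAJECTORY_HEADER",
    "TRUTH_HEADER",
    "RunConfig",
    "write_detection_csv",
    "read_detection_csv",
    "detection_stream",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_truth_csv",
    "read_truth_csv",
]

DETECTION_HEADER = "frame,kind,x_min,y_min,x_max,y_max,confidence,marker_id,cx,cy"
TRAJECTORY_HEADER = "frame,entity_key,id,x_min,y_min,x_max,y_max,cx,cy,seen"
TRUTH_HEADER = ",".join(TRUTH_COLUMNS)

_F = "{:.3f}".format  # float serialisation: 3 decimals


class CsvFormatError(ValueError):
    """Raised for a malformed CSV file, pointing at file and line."""


def _fail(path, line_no: int, message: str):
    raise CsvFormatError(f"{path}:{line_no}: {message}")


def _check_header(path, got: str, expected: str) -> None:
    if got != expected:
        _fail(path, 1, f"bad header: expected {expected!r}, got {got!r}")


def write_detection_csv(stream: Iterable[FramePacket], path) -> None:
    """Serialise a detection stream; shape rows first, then marker rows,
    per frame, in stream order."""
    with open(path, "w", newline="") as fh:
        fh.write(DETECTION_HEADER + "\n")
        w = csv.writer(fh)
        for frame, shapes, markers in stream:
            for d in shapes:
                w.writerow(
                    [
                        frame,
                        "shape",
                        _F(d.bbox.x_min),
                        _F(d.bbox.y_min),
                        _F(d.bbox.x_max),
                        _F(d.bbox.y_max),
                        _F(d.confidence),
                        "",
                        "",
                        "",
                    ]
                )
            for m in markers:
                w.writerow(
                    [frame, "marker", "", "", "", "", "", m.marker_id, _F(m.center.x), _F(m.center.y)]
                )


def _parse_float(path, line_no: int, field: str, value: str) -> float:
    try:
        return float(value)
    except ValueError:
        _fail(path, line_no, f"non-numeric value {value!r} in field {field!r}")


def _parse_int(path, line_no: int, field: str, value: str) -> int:
    try:
        return int(value)
    except ValueError:
        _fail(path, line_no, f"non-integer value {value!r} in field {field!r}")


def read_detection_csv(path) -> dict[int, tuple[list[ShapeDetection], list[MarkerDetection]]]:
    """Parse a detection CSV into per-frame shape/marker lists, keyed by
    frame in ascending order.  Row order within a frame is preserved even
    if frames appear shuffled in the file."""
    frames: dict[int, tuple[list[ShapeDetection], list[MarkerDetection]]] = {}
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        _check_header(path, header, DETECTION_HEADER)
        for line_no, row in enumerate(csv.reader(fh), start=2):
            if not row:
                continue
            if len(row) != 10:
                _fail(path, line_no, f"expected 10 fields, got {len(row)}")
            frame = _parse_int(path, line_no, "frame", row[0])
            if frame < 0:
                _fail(path, line_no, f"negative frame index {frame}")
            kind = row[1]
            shapes, markers = frames.setdefault(frame, ([], []))
            if kind == "shape":
                bbox = BoundingBox(
                    _parse_float(path, line_no, "x_min", row[2]),
                    _parse_float(path, line_no, "y_min", row[3]),
                    _parse_float(path, line_no, "x_max", row[4]),
                    _parse_float(path, line_no, "y_max", row[5]),
                )
                conf = _parse_float(path, line_no, "confidence", row[6])
                shapes.append(ShapeDetection(frame=frame, bbox=bbox, confidence=conf))
            elif kind == "marker":
                markers.append(
                    MarkerDetection(
                        frame=frame,
                        marker_id=_parse_int(path, line_no, "marker_id", row[7]),
                        center=Point(
                            _parse_float(path, line_no, "cx", row[8]),
                            _parse_float(path, line_no, "cy", row[9]),
                        ),
                    )
                )
            else:
                _fail(path, line_no, f"unknown kind {kind!r} (expected 'shape' or 'marker')")
    return dict(sorted(frames.items()))


def detection_stream(path, start_frame: int = 0) -> Iterator[FramePacket]:
    """Detector adapter over a detection CSV: yields one
    ``(frame, shapes, markers)`` packet per frame from ``start_frame``
    through the last frame present, empty packets for gaps."""
    frames = read_detection_csv(path)
    if not frames:
        return
    last = max(frames)
    for f in range(start_frame, last + 1):
        shapes, markers = frames.get(f, ([], []))
        yield f, shapes, markers


def write_tracks_csv(records: Iterable[TrackRecord] | pd.DataFrame, path) -> None:
    """Write a trajectory table (or an iterable of records) to CSV."""
    if not isinstance(records, pd.DataFrame):
        from .trackcore import records_to_frame

        records = records_to_frame(records)
    with open(path, "w", newline="") as fh:
        fh.write(TRAJECTORY_HEADER + "\n")
        w = csv.writer(fh)
        for r in records.itertuples(index=False):
            w.writerow(
                [
                    int(r.frame),
                    int(r.entity_key),
                    int(r.id),
                    _F(r.x_min),
                    _F(r.y_min),
                    _F(r.x_max),
                    _F(r.y_max),
                    _F(r.cx),
                    _F(r.cy),
                    "true" if r.seen else "false",
                ]
            )


def read_tracks_csv(path) -> pd.DataFrame:
    rows = []
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        _check_header(path, header, TRAJECTORY_HEADER)
        for line_no, row in enumerate(csv.reader(fh), start=2):
            if not row:
                continue
            if len(row) != 10:
                _fail(path, line_no, f"expected 10 fields, got {len(row)}")
            if row[9] not in ("true", "false"):
                _fail(path, line_no, f"seen must be 'true' or 'false', got {row[9]!r}")
            rows.append(
                (
                    _parse_int(path, line_no, "frame", row[0]),
                    _parse_int(path, line_no, "entity_key", row[1]),
                    _parse_int(path, line_no, "id", row[2]),
                    *[
                        _parse_float(path, line_no, f, v)
                        for f, v in zip(TRACK_COLUMNS[3:9], row[3:9])
                    ],
                    row[9] == "true",
                )
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    if df.empty:
        df = df.astype({"frame": int, "entity_key": int, "id": int, "seen": bool})
    return df


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(TRUTH_HEADER + "\n")
        w = csv.writer(fh)
        for r in truth.itertuples(index=False):
            mw = int(r.merged_with)
            w.writerow(
                [
                    int(r.frame),
                    int(r.true_id),
                    _F(r.cx),
                    _F(r.cy),
                    _F(r.x_min),
                    _F(r.y_min),
                    _F(r.x_max),
                    _F(r.y_max),
                    _F(r.speed_mm_s),
                    r.blur,
                    r.visibility,
                    "" if mw < 0 else mw,
                ]
            )


def read_truth_csv(path) -> pd.DataFrame:
    rows = []
    blur_ok = {"sharp", "blurry", "very_blurry"}
    vis_ok = {"horizontal", "tilted", "invisible"}
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n")
        _check_header(path, header, TRUTH_HEADER)
        for line_no, row in enumerate(csv.reader(fh), start=2):
            if not row:
                continue
            if len(row) != 12:
                _fail(path, line_no, f"expected 12 fields, got {len(row)}")
            if row[9] not in blur_ok:
                _fail(path, line_no, f"unknown blur class {row[9]!r}")
            if row[10] not in vis_ok:
                _fail(path, line_no, f"unknown visibility class {row[10]!r}")
            rows.append(
                (
                    _parse_int(path, line_no, "frame", row[0]),
                    _parse_int(path, line_no, "true_id", row[1]),
                    *[
                        _parse_float(path, line_no, f, v)
                        for f, v in zip(TRUTH_COLUMNS[2:9], row[2:9])
                    ],
                    row[9],
                    row[10],
                    -1 if row[11] == "" else _parse_int(path, line_no, "merged_with", row[11]),
                )
            )
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if df.empty:
        df = df.astype({"frame": int, "true_id": int, "merged_with": int})
    return df


@dataclass(frozen=True)
class RunConfig:
    """Structured run configuration, round-trippable through YAML.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    condition: str = "nest-ir"
    seed: int = 0
    n_ants: int = 20
    n_frames: int = 250
    px_per_mm: float = 12.0
    fps: float = 10.0
    confidence_threshold: float = 0.5
    ghost_threshold: int | None = None  # None → condition preset
    detections: str | None = None
    truth: str | None = None
    tracks: str | None = None
    report: str | None = None

    def tracker_config(self) -> TrackerConfig:
        overrides: dict = {"confidence_threshold": self.confidence_threshold, "fps": self.fps}
        if self.ghost_threshold is not None:
            overrides["ghost_threshold"] = self.ghost_threshold
        return TrackerConfig.for_condition(self.condition, **overrides)

    def arena_config(self) -> ArenaConfig:
        return ArenaConfig(
            px_per_mm=self.px_per_mm,
            fps=self.fps,
            n_frames=self.n_frames,
            n_ants=self.n_ants,
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
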