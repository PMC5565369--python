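"""Reading, writing and pairing of tracked base/tip point data.

Two on-disk formats are supported:

* MTrackJ data files (``.mdf``): text records ``MTrackJ`` / ``Assembly`` /
  ``Cluster`` / ``Track`` / ``Point``.  Within each cluster, track #1 is the
  filopodium base and track #2 the tip.
* A flat CSV dialect with header
  ``filopodium_id,role,frame,x_um,y_um,group_label`` (role is ``base`` or
  ``tip``), UTF-8, LF line endings, ``.`` decimal separator.

Frames are 1-based as stored in the files; internal time is
``t = (frame - 1) * frame_interval`` in minutes, so downstream velocities are
µm/min.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .errors import (
    TrackParseError,
    TrackTooShortError,
    TrackValidationError,
)

logger = logging.getLogger(__name__)

CSV_HEADER = ["filopodium_id", "role", "frame", "x_um", "y_um", "group_label"]

BASE_TRACK_NO = 1
TIP_TRACK_NO = 2


@dataclass(frozen=True)
class TrackPoint:
    """One tracked point: 1-based frame index, time (min) and position (µm)."""

    frame: int
    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise TrackValidationError(f"frame must be >= 1, got {self.frame}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise TrackValidationError(
                f"non-finite coordinate at frame {self.frame}: ({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata: frame interval, recording window and calibration.

    ``coordinates_in_pixels`` marks files whose coordinates were exported
    uncalibrated; they are multiplied by ``pixel_size_um`` on read.  The
    default assumes coordinates are already in µm.
    """

    frame_interval_min: float = 2.0
    window_min: float = 30.0
    pixel_size_um: float = 1.0
    region_width_um: float = 49.0
    region_height_um: float = 76.0
    coordinates_in_pixels: bool = False

    def __post_init__(self) -> None:
        for name in (
            "frame_interval_min",
            "window_min",
            "pixel_size_um",
            "region_width_um",
            "region_height_um",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise TrackValidationError(f"{name} must be strictly positive, got {value}")

    @property
    def window_start_frame(self) -> int:
        return 1

    @property
    def window_end_frame(self) -> int:
        return int(round(self.window_min / self.frame_interval_min)) + 1

    def time_of_frame(self, frame: int) -> float:
        return (frame - 1) * self.frame_interval_min


@dataclass
class FilopodiumTrack:
    """Paired base (track #1) and tip (track #2) series for one filopodium."""

    filopodium_id: int
    base: list[TrackPoint]
    tip: list[TrackPoint]
    frame_interval: float
    window_start_frame: int
    window_end_frame: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be > 0")
        for role, points in (("base", self.base), ("tip", self.tip)):
            frames = [p.frame for p in points]
            for a, b in zip(frames, frames[1:]):
                if b <= a:
                    raise TrackValidationError(
                        f"filopodium {self.filopodium_id}: {role} track frames "
                        f"not strictly increasing ({a} then {b})"
                    )
            for f in frames:
                if not (self.window_start_frame <= f <= self.window_end_frame):
                    raise TrackValidationError(
                        f"filopodium {self.filopodium_id}: {role} frame {f} outside "
                        f"window [{self.window_start_frame}, {self.window_end_frame}]"
                    )


@dataclass(frozen=True)
class RejectedCluster:
    cluster_id: int
    reason: str


@dataclass
class ReadReport:
    """Point-record accounting so that nothing is dropped silently.

    ``point_records == accepted_points + rejected_cluster_points +
    excluded_points + extra_track_points + out_of_window_points`` always
    holds.
    """

    point_records: int = 0
    accepted_points: int = 0
    rejected_cluster_points: int = 0
    excluded_points: int = 0
    extra_track_points: int = 0
    out_of_window_points: int = 0

    def balanced(self) -> bool:
        return self.point_records == (
            self.accepted_points
            + self.rejected_cluster_points
            + self.excluded_points
            + self.extra_track_points
            + self.out_of_window_points
        )


class TrackReadResult(NamedTuple):
    tracks: list[FilopodiumTrack]
    rejected: list[RejectedCluster]
    report: ReadReport


class PairedFrame(NamedTuple):
    t: float
    base: TrackPoint
    tip: TrackPoint


def _assemble_cluster(
    cluster_id: int,
    tracks: dict[int, list[TrackPoint]],
    meta: AcquisitionMeta,
    group_label: str,
) -> FilopodiumTrack:
    for role, track_no in (("base", BASE_TRACK_NO), ("tip", TIP_TRACK_NO)):
        frames = [p.frame for p in tracks[track_no]]
        dupes = {f for f in frames if frames.count(f) > 1}
        if dupes:
            raise TrackValidationError(
                f"filopodium {cluster_id}: duplicate frame(s) {sorted(dupes)} in {role} track"
            )
    base = sorted(tracks[BASE_TRACK_NO], key=lambda p: p.frame)
    tip = sorted(tracks[TIP_TRACK_NO], key=lambda p: p.frame)
    return FilopodiumTrack(
        filopodium_id=cluster_id,
        base=base,
        tip=tip,
        frame_interval=meta.frame_interval_min,
        window_start_frame=meta.window_start_frame,
        window_end_frame=meta.window_end_frame,
        group_label=group_label,
    )


def _finish_clusters(
    clusters: dict[int, dict[int, list[tuple[float, float, int]]]],
    meta: AcquisitionMeta,
    group_label: str,
    exclude_ids: frozenset[int],
    report: ReadReport,
) -> tuple[list[FilopodiumTrack], list[RejectedCluster]]:
    scale = meta.pixel_size_um if meta.coordinates_in_pixels else 1.0
    accepted: list[FilopodiumTrack] = []
    rejected: list[RejectedCluster] = []
    for cluster_id in sorted(clusters):
        raw = clusters[cluster_id]
        n_points = sum(len(v) for v in raw.values())
        if cluster_id in exclude_ids:
            report.excluded_points += n_points
            rejected.append(RejectedCluster(cluster_id, "excluded by configuration"))
            continue
        if BASE_TRACK_NO not in raw:
            report.rejected_cluster_points += n_points
            rejected.append(RejectedCluster(cluster_id, "missing base track"))
            continue
        if TIP_TRACK_NO not in raw:
            report.rejected_cluster_points += n_points
            rejected.append(RejectedCluster(cluster_id, "missing tip track"))
            continue
        extra = sum(len(v) for no, v in raw.items() if no not in (BASE_TRACK_NO, TIP_TRACK_NO))
        if extra:
            logger.warning(
                "filopodium %d: ignoring %d point(s) on tracks other than 1/2",
                cluster_id,
                extra,
            )
        report.extra_track_points += extra
        kept: dict[int, list[TrackPoint]] = {BASE_TRACK_NO: [], TIP_TRACK_NO: []}
        for track_no in (BASE_TRACK_NO, TIP_TRACK_NO):
            for x, y, frame in raw[track_no]:
                if not (meta.window_start_frame <= frame <= meta.window_end_frame):
                    report.out_of_window_points += 1
                    logger.info(
                        "filopodium %d: dropping frame %d outside recording window",
                        cluster_id,
                        frame,
                    )
                    continue
                kept[track_no].append(
                    TrackPoint(
                        frame=frame,
                        t=meta.time_of_frame(frame),
                        x=x * scale,
                        y=y * scale,
                    )
                )
        track = _assemble_cluster(cluster_id, kept, meta, group_label)
        report.accepted_points += len(track.base) + len(track.tip)
        accepted.append(track)
    return accepted, rejected


def read_mdf(
    path: str | Path,
    meta: AcquisitionMeta,
    group_label: str = "",
    exclude_ids: Iterable[int] = (),
) -> TrackReadResult:
    """Read an MTrackJ data file into per-filopodium paired tracks.

    One :class:`FilopodiumTrack` is produced per cluster holding both track 1
    (base) and track 2 (tip); clusters missing either, or listed in
    ``exclude_ids`` (the non-filopodium sidecar list), land in ``rejected``
    with a reason.  z and channel fields of Point records are parsed and
    discarded.
    """
    path = Path(path)
    exclude = frozenset(int(i) for i in exclude_ids)
    clusters: dict[int, dict[int, list[tuple[float, float, int]]]] = {}
    report = ReadReport()
    current_cluster: int | None = None
    current_track: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("MTrackJ"):
            raise TrackParseError(f"{path}: line 1: not an MTrackJ data file")
        for lineno, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            kind = tokens[0]
            try:
                if kind == "Cluster":
                    current_cluster = int(float(tokens[1]))
                    current_track = None
                    clusters.setdefault(current_cluster, {})
                elif kind == "Track":
                    if current_cluster is None:
                        raise TrackParseError(f"{path}: line {lineno}: Track before Cluster")
                    current_track = int(float(tokens[1]))
                    clusters[current_cluster].setdefault(current_track, [])
                elif kind == "Point":
                    if current_cluster is None or current_track is None:
                        raise TrackParseError(f"{path}: line {lineno}: Point before Track")
                    # Point <id> <x> <y> <z> <t> <c>; z and c are discarded.
                    _pid, x, y, _z, t = (float(v) for v in tokens[1:6])
                    frame = int(round(t))
                    clusters[current_cluster][current_track].append((x, y, frame))
                    report.point_records += 1
                elif kind in ("Assembly", "Displaying", "Offset", "Origin", "Space", "Time", "End"):
                    continue
                else:
                    raise TrackParseError(f"{path}: line {lineno}: unknown record '{kind}'")
            except TrackParseError:
                raise
            except (IndexError, ValueError) as exc:
                raise TrackParseError(f"{path}: line {lineno}: malformed {kind} record") from exc
    accepted, rejected = _finish_clusters(clusters, meta, group_label, exclude, report)
    logger.info(
        "%s: %d track(s) accepted, %d cluster(s) rejected", path.name, len(accepted), len(rejected)
    )
    return TrackReadResult(accepted, rejected, report)


def read_csv_tracks(
    path: str | Path,
    meta: AcquisitionMeta | None = None,
    exclude_ids: Iterable[int] = (),
) -> TrackReadResult:
    """Read the flat CSV track dialect; assembly/validation as in read_mdf."""
    path = Path(path)
    meta = meta or AcquisitionMeta()
    exclude = frozenset(int(i) for i in exclude_ids)
    role_to_no = {"base": BASE_TRACK_NO, "tip": TIP_TRACK_NO}
    clusters: dict[int, dict[int, list[tuple[float, float, int]]]] = {}
    group_labels: dict[int, str] = {}
    report = ReadReport()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrackParseError(f"{path}: empty file") from None
        if header != CSV_HEADER:
            raise TrackParseError(
                f"{path}: line 1: expected header {','.join(CSV_HEADER)!r}, got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise TrackParseError(f"{path}: line {lineno}: expected {len(CSV_HEADER)} fields")
            fid_s, role, frame_s, x_s, y_s, group = row
            if role not in role_to_no:
                raise TrackValidationError(
                    f"{path}: line {lineno}: unknown role {role!r} (expected base or tip)"
                )
            try:
                fid = int(fid_s)
                frame = int(frame_s)
                x = float(x_s)
                y = float(y_s)
            except ValueError as exc:
                raise TrackParseError(f"{path}: line {lineno}: non-numeric field") from exc
            clusters.setdefault(fid, {}).setdefault(role_to_no[role], []).append((x, y, frame))
            group_labels.setdefault(fid, group)
            report.point_records += 1
    accepted_all: list[FilopodiumTrack] = []
    rejected_all: list[RejectedCluster] = []
    for cluster_id in sorted(clusters):
        sub_report = ReadReport()
        accepted, rejected = _finish_clusters(
            {cluster_id: clusters[cluster_id]},
            replace(meta, coordinates_in_pixels=False),  # CSV stores µm by definition
            group_labels.get(cluster_id, ""),
            exclude,
            sub_report,
        )
        accepted_all.extend(accepted)
        rejected_all.extend(rejected)
        report.accepted_points += sub_report.accepted_points
        report.rejected_cluster_points += sub_report.rejected_cluster_points
        report.excluded_points += sub_report.excluded_points
        report.extra_track_points += sub_report.extra_track_points
        report.out_of_window_points += sub_report.out_of_window_points
    return TrackReadResult(accepted_all, rejected_all, report)


def _fmt(value: float) -> str:
    """Shortest decimal that round-trips; integers without trailing zeros."""
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(value)


def write_csv_tracks(tracks: Sequence[FilopodiumTrack], path: str | Path) -> None:
    """Write tracks in the CSV dialect, rows sorted by (id, role, frame).

    Output bytes are deterministic for identical input and independent of the
    order tracks or points were supplied in.
    """
    path = Path(path)
    rows: list[tuple[int, str, int, float, float, str]] = []
    for track in tracks:
        for role, points in (("base", track.base), ("tip", track.tip)):
            for p in points:
                rows.append((track.filopodium_id, role, p.frame, p.x, p.y, track.group_label))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(CSV_HEADER) + "\n")
        for fid, role, frame, x, y, group in rows:
            fh.write(f"{fid},{role},{frame},{_fmt(x)},{_fmt(y)},{group}\n")


def pair_frames(track: FilopodiumTrack) -> list[PairedFrame]:
    """Return time-ordered (t, base, tip) tuples for frames in BOTH tracks."""
    base_by_frame = {p.frame: p for p in track.base}
    tip_by_frame = {p.frame: p for p in track.tip}
    common = sorted(set(base_by_frame) & set(tip_by_frame))
    dropped = (len(base_by_frame) - len(common)) + (len(tip_by_frame) - len(common))
    if dropped:
        logger.info(
            "filopodium %d: %d unpaired point(s) dropped", track.filopodium_id, dropped
        )
    if len(common) < 2:
        raise TrackTooShortError(
            f"filopodium {track.filopodium_id}: track too short "
            f"({len(common)} paired frame(s), need >= 2)"
        )
    return [PairedFrame(base_by_frame[f].t, base_by_frame[f], tip_by_frame[f]) for f in common]
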