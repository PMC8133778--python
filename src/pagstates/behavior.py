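"""Behavior classification and spatial scores from pose coordinates.

All detectors follow fixed kinematic rules:

* freeze      — head AND tailbase speed below 0.25 cm/s for at least 0.33 s;
* approach    — moving toward the rat faster than 3 cm/s (escape: away);
* rat movement— rat speed above its session 99.5th percentile, events within
                5.33 s of a kept event dropped, annotated with the movement
                angle relative to the mouse (0 deg = toward the mouse);
* head dip    — nose past the lateral edge of an open arm while the body is
                inside that arm, for at least 0.2 s.

Spatial scores: the EPM location index |x| - |y| on normalized maze
coordinates, and the per-frame avoidance/approach score combining
(min-max normalized) distance-to-safety, movement direction, freezing and
head dips.

Speeds are median-filtered over ~0.33 s before thresholding: the median
suppresses tracker jitter like a moving average but keeps onsets sharp,
so planted bouts are recovered to the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .core import (
    AssayGeometry,
    AssayKind,
    BehaviorIntervals,
    PoseTrack,
    runs_to_intervals,
)

__all__ = [
    "KinematicSeries",
    "ZoneLabels",
    "ScoreSeries",
    "compute_kinematics",
    "detect_freeze",
    "detect_approach_escape",
    "detect_rat_movements",
    "detect_head_dips",
    "detect_all_behaviors",
    "assign_zones",
    "epm_location_index",
    "distance_to_safety",
    "movement_direction",
    "avoidance_approach_score",
    "assemble_behavior_variables",
]

FREEZE_SPEED_CMS = 0.25
FREEZE_MIN_S = 0.33
APPROACH_SPEED_CMS = 3.0
RAT_MOVE_PERCENTILE = 99.5
RAT_MOVE_MERGE_S = 5.33
HEAD_DIP_MIN_S = 0.2
HEAD_DIP_MULTIPLIER = 1.11
EPM_SCORE_RANGE = 0.9
DIRECTION_DEADBAND_CM = 0.1


def _smooth(x: np.ndarray, fps: float, window_s: float = 0.33) -> np.ndarray:
    k = int(round(window_s * fps))
    if k % 2 == 0:
        k -= 1
    if k < 3:
        return np.asarray(x, dtype=float)
    return median_filter(np.asarray(x, dtype=float), size=k, mode="nearest")


def _speed(xy: np.ndarray, fps: float) -> np.ndarray:
    d = np.gradient(xy, axis=0)
    return np.hypot(d[:, 0], d[:, 1]) * fps


@dataclass
class KinematicSeries:
    """Per-frame kinematics derived from a pose track (all filtered)."""

    fps: float
    assay: AssayKind
    speed_head: np.ndarray  # cm/s
    speed_tailbase: np.ndarray  # cm/s
    speed_body: np.ndarray  # cm/s, centroid
    dist_to_rat: np.ndarray | None = None  # cm
    radial_velocity: np.ndarray | None = None  # cm/s, >0 means away from rat
    head_to_rat_angle: np.ndarray | None = None  # degrees in [0, 360)
    rat_speed: np.ndarray | None = None  # cm/s
    rat_xy: np.ndarray | None = None
    mouse_xy: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.speed_body)


def compute_kinematics(pose: PoseTrack, smooth_window_s: float = 0.33) -> KinematicSeries:
    """Speeds, and (rat assays) distance / radial velocity / angle to the rat."""
    if pose.n_frames < 2:
        raise ValueError("kinematics need at least 2 frames")
    fps = pose.fps
    centroid = pose.centroid()
    head = pose.head_center()
    tail = pose.keypoints["tailbase"]
    kin = KinematicSeries(
        fps=fps,
        assay=pose.geometry.assay_kind,
        speed_head=_smooth(_speed(head, fps), fps, smooth_window_s),
        speed_tailbase=_smooth(_speed(tail, fps), fps, smooth_window_s),
        speed_body=_smooth(_speed(centroid, fps), fps, smooth_window_s),
        mouse_xy=centroid,
    )
    if pose.has_rat:
        rat = pose.keypoints["rat"]
        delta = rat - centroid
        dist = np.hypot(delta[:, 0], delta[:, 1])
        kin.dist_to_rat = dist
        kin.radial_velocity = _smooth(np.gradient(dist) * fps, fps, smooth_window_s)
        heading = pose.keypoints["nose"] - tail
        ang_head = np.arctan2(heading[:, 1], heading[:, 0])
        ang_rat = np.arctan2(delta[:, 1], delta[:, 0])
        kin.head_to_rat_angle = np.degrees(ang_rat - ang_head) % 360.0
        kin.rat_speed = _smooth(_speed(rat, fps), fps, smooth_window_s)
        kin.rat_xy = rat
    return kin


# ---------------------------------------------------------------------------
# detectors


def detect_freeze(kin: KinematicSeries) -> BehaviorIntervals:
    """Freezing: head and tailbase speeds jointly below 0.25 cm/s >= 0.33 s."""
    mask = (kin.speed_head < FREEZE_SPEED_CMS) & (kin.speed_tailbase < FREEZE_SPEED_CMS)
    runs = runs_to_intervals(mask, kin.fps, FREEZE_MIN_S)
    return BehaviorIntervals.from_records([("freeze", a, b) for a, b in runs])


def detect_approach_escape(kin: KinematicSeries, min_bout_s: float = 0.33) -> BehaviorIntervals:
    """Approach/escape: >3 cm/s toward / away from the rat (rat assays only)."""
    if kin.radial_velocity is None:
        raise ValueError("approach/escape detection needs rat keypoints (rat assay)")
    fast = kin.speed_body > APPROACH_SPEED_CMS
    approach = runs_to_intervals(fast & (kin.radial_velocity < 0), kin.fps, min_bout_s)
    escape = runs_to_intervals(fast & (kin.radial_velocity > 0), kin.fps, min_bout_s)
    recs = [("approach", a, b) for a, b in approach] + [("escape", a, b) for a, b in escape]
    return BehaviorIntervals.from_records(sorted(recs, key=lambda r: r[1]))


def detect_rat_movements(kin: KinematicSeries) -> BehaviorIntervals:
    """Prominent rat movements: speed above the session 99.5th percentile.

    Multiple threshold crossings within 5.33 s of a kept event are dropped
    (only the first is used).  Each event carries the movement direction
    angle relative to the mouse position at onset: 0 deg is a movement
    straight at the mouse, 180 deg straight away.
    """
    if kin.rat_speed is None:
        raise ValueError("rat-movement detection needs rat keypoints")
    speed = kin.rat_speed
    thr = np.percentile(speed, RAT_MOVE_PERCENTILE)
    above = speed > thr
    if not above.any():
        return BehaviorIntervals()
    onsets = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    kept: list[int] = []
    for t in onsets:
        if not kept or (t - kept[-1]) / kin.fps > RAT_MOVE_MERGE_S:
            kept.append(int(t))
    records = []
    for t in kept:
        stop = t
        while stop < len(above) and above[stop]:
            stop += 1
        # movement direction over the first few frames of the event
        horizon = min(stop, t + max(int(0.2 * kin.fps), 2))
        move = kin.rat_xy[horizon - 1] - kin.rat_xy[t]
        to_mouse = kin.mouse_xy[t] - kin.rat_xy[t]
        ang = np.degrees(np.arctan2(move[1], move[0]) - np.arctan2(to_mouse[1], to_mouse[0])) % 360.0
        records.append(("rat_movement", t / kin.fps, stop / kin.fps, {"angle_deg": float(ang)}))
    return BehaviorIntervals.from_records(records)


def detect_head_dips(pose: PoseTrack, zones: "ZoneLabels") -> BehaviorIntervals:
    """Head dips: nose beyond the lateral open-arm edge, body in the arm.

    The maze frame puts open arms along x, so the lateral coordinate of an
    open arm is y; a dip is |y_nose| exceeding the arm half-width while the
    centroid is inside an open arm, sustained >= 0.2 s.
    """
    if not pose.geometry.is_epm:
        raise ValueError("head dips are defined on the EPM only")
    hw = pose.geometry.half_width
    in_open = zones.is_open
    nose = pose.keypoints["nose"]
    mask = in_open & (np.abs(nose[:, 1]) > hw)
    runs = runs_to_intervals(mask, pose.fps, HEAD_DIP_MIN_S)
    return BehaviorIntervals.from_records([("head_dip", a, b) for a, b in runs])


def detect_all_behaviors(pose: PoseTrack, kin: KinematicSeries | None = None,
                         zones: "ZoneLabels | None" = None) -> BehaviorIntervals:
    """Run every detector applicable to the assay and concatenate."""
    kin = kin or compute_kinematics(pose)
    out = detect_freeze(kin)
    if pose.geometry.is_epm:
        zones = zones if zones is not None else assign_zones(pose, pose.geometry)
        out = out + detect_head_dips(pose, zones)
    elif pose.has_rat:
        out = out + detect_approach_escape(kin)
        out = out + detect_rat_movements(kin)
    return out


# ---------------------------------------------------------------------------
# zones


@dataclass
class ZoneLabels:
    """Exactly one zone label per frame."""

    labels: np.ndarray  # array of strings
    assay: AssayKind

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def is_open(self) -> np.ndarray:
        return np.isin(self.labels, ["open1", "open2"])

    @property
    def is_closed(self) -> np.ndarray:
        return np.isin(self.labels, ["closed1", "closed2"])

    @property
    def is_center(self) -> np.ndarray:
        return self.labels == "center"


def assign_zones(pose: PoseTrack, geometry: AssayGeometry,
                 tolerance_cm: float = 5.0) -> ZoneLabels:
    """Per-frame zone labels from the body centroid.

    EPM: open1/open2 (along +x/-x), closed1/closed2 (along +y/-y), center.
    Rat arena: safe (leftmost 20% of the arena), threatening (within 14 cm
    of the rat, inclusive), else middle.
    """
    xy = pose.centroid()
    if geometry.is_epm:
        ext = geometry.epm_half_extent
        if (np.abs(xy) > ext + tolerance_cm).any():
            raise ValueError("centroid outside the maze beyond tolerance")
        hw = geometry.half_width
        ax, ay = np.abs(xy[:, 0]), np.abs(xy[:, 1])
        labels = np.full(len(xy), "center", dtype="<U8")
        on_x = ax > np.maximum(ay, hw)
        on_y = ay > np.maximum(ax, hw)
        labels[on_x & (xy[:, 0] > 0)] = "open1"
        labels[on_x & (xy[:, 0] < 0)] = "open2"
        labels[on_y & (xy[:, 1] > 0)] = "closed1"
        labels[on_y & (xy[:, 1] < 0)] = "closed2"
        return ZoneLabels(labels, geometry.assay_kind)
    L, W = geometry.arena_length, geometry.arena_width
    if ((xy[:, 0] < -tolerance_cm) | (xy[:, 0] > L + tolerance_cm)
            | (xy[:, 1] < -tolerance_cm) | (xy[:, 1] > W + tolerance_cm)).any():
        raise ValueError("centroid outside the arena beyond tolerance")
    rat = pose.keypoints["rat"] if pose.has_rat else np.tile(geometry.rat_tether_xy, (len(xy), 1))
    dist = np.hypot(*(rat - xy).T)
    labels = np.full(len(xy), "middle", dtype="<U11")
    labels[dist <= geometry.threat_distance_cm] = "threatening"
    labels[xy[:, 0] <= geometry.safe_zone_max_x] = "safe"
    return ZoneLabels(labels, geometry.assay_kind)


# ---------------------------------------------------------------------------
# spatial scores


def epm_location_index(pose: PoseTrack, geometry: AssayGeometry) -> np.ndarray:
    """|x| - |y| on maze coordinates normalized so arm ends map to +/-1.

    +1 at the end of an open arm, 0 at the maze center, -1 at the end of a
    closed arm.
    """
    if not geometry.is_epm:
        raise ValueError("the location index is defined on the EPM only")
    xy = pose.centroid()
    ext = geometry.epm_half_extent
    xn = np.clip(xy[:, 0] / ext, -1, 1)
    yn = np.clip(xy[:, 1] / ext, -1, 1)
    return np.abs(xn) - np.abs(yn)


def _raw_distance_to_safety(xy: np.ndarray, geometry: AssayGeometry) -> np.ndarray:
    """Unnormalized distance from safety in cm.

    Rat arena: distance from the safe wall (x).  EPM: geodesic distance from
    the nearest closed-arm end along the arm axes through the center, so a
    mouse deep in an open arm is far from safety even though the closed arm
    may be close in a straight line.
    """
    if geometry.assay_kind is AssayKind.EPM:
        ext = geometry.epm_half_extent
        return (ext - np.abs(xy[:, 1])) + np.abs(xy[:, 0])
    return xy[:, 0].copy()


def distance_to_safety(pose: PoseTrack, geometry: AssayGeometry,
                       norm_range: tuple[float, float] | None = None) -> np.ndarray:
    """Min-max normalized distance from safety: [0, 1] in the rat arena,
    [0, 0.9] in the EPM.  ``norm_range`` overrides the observed (min, max)
    when the session does not span the full arena."""
    raw = _raw_distance_to_safety(pose.centroid(), geometry)
    lo, hi = norm_range if norm_range is not None else (raw.min(), raw.max())
    span = hi - lo
    scaled = np.zeros_like(raw) if span <= 0 else np.clip((raw - lo) / span, 0, 1)
    top = EPM_SCORE_RANGE if geometry.is_epm else 1.0
    return top * scaled


def movement_direction(pose: PoseTrack, geometry: AssayGeometry,
                       window_s: float = 0.33) -> np.ndarray:
    """Per-frame +1 (toward threat) / -1 (away) from the signed displacement
    of raw distance-to-safety over a trailing 0.33 s window; displacements
    under 0.1 cm hold the previous direction."""
    raw = _raw_distance_to_safety(pose.centroid(), geometry)
    w = max(int(round(window_s * pose.fps)), 1)
    disp = np.empty_like(raw)
    disp[:w] = raw[:w] - raw[0]
    disp[w:] = raw[w:] - raw[:-w]
    sign = np.where(disp > DIRECTION_DEADBAND_CM, 1.0,
                    np.where(disp < -DIRECTION_DEADBAND_CM, -1.0, 0.0))
    # forward-fill zeros with the previous defined direction
    idx = np.arange(len(sign))
    defined = sign != 0
    if not defined.any():
        return np.full_like(sign, -1.0)
    last = np.maximum.accumulate(np.where(defined, idx, -1))
    out = np.where(last >= 0, sign[np.clip(last, 0, None)], sign[np.argmax(defined)])
    first = sign[defined][0]
    out[last < 0] = first
    return out


@dataclass
class ScoreSeries:
    """Per-frame spatial scores for one session."""

    fps: float
    assay: AssayKind
    score: np.ndarray  # avoidance/approach score in [-1, 1]
    dist_to_safety: np.ndarray  # normalized
    direction: np.ndarray  # +1 toward threat, -1 away
    location_index: np.ndarray | None = None  # EPM only
    norm_abs_x: np.ndarray | None = None  # EPM only, [0, 1]
    norm_abs_y: np.ndarray | None = None


def avoidance_approach_score(pose: PoseTrack, intervals: BehaviorIntervals,
                             geometry: AssayGeometry,
                             norm_range: tuple[float, float] | None = None) -> ScoreSeries:
    """Continuous avoidance/approach score per frame.

    While moving toward threat the score is distance-to-safety x (+1); while
    moving away it is (1 - distance-to-safety) x (-1).  Freezing forces the
    minimum of -1 anywhere; EPM head-dip frames are multiplied by 1.11 so a
    dip at the end of an open arm reaches the maximum of +1.  Output is
    clipped to [-1, 1].
    """
    n = pose.n_frames
    d = distance_to_safety(pose, geometry, norm_range)
    direction = movement_direction(pose, geometry)
    score = np.where(direction > 0, d * direction, (1.0 - d) * direction)
    loc = xn = yn = None
    if geometry.is_epm:
        dips = intervals.mask("head_dip", n, pose.fps)
        score = np.where(dips, score * HEAD_DIP_MULTIPLIER, score)
        loc = epm_location_index(pose, geometry)
        xy = pose.centroid()
        ext = geometry.epm_half_extent
        xn = np.abs(np.clip(xy[:, 0] / ext, -1, 1))
        yn = np.abs(np.clip(xy[:, 1] / ext, -1, 1))
    score[intervals.mask("freeze", n, pose.fps)] = -1.0
    score = np.clip(score, -1.0, 1.0)
    return ScoreSeries(pose.fps, geometry.assay_kind, score, d, direction, loc, xn, yn)


# ---------------------------------------------------------------------------
# behavioral variable tables (decoding / GLM / CoCA inputs)


def assemble_behavior_variables(pose: PoseTrack, kin: KinematicSeries,
                                intervals: BehaviorIntervals,
                                scores: ScoreSeries) -> tuple[dict[str, np.ndarray], list[str]]:
    """Named per-frame behavioral channels for the assay.

    EPM (6): normalized |x|, |y|, speed, head-dip, freeze, location index.
    Rat (9): distance to rat, mouse speed, rat speed, head-to-rat angle,
    approach, escape, freeze, rat movement, distance from the safe wall.
    Returns the channel dict and the list of binary channel names.
    """
    n = pose.n_frames
    fps = pose.fps
    if pose.geometry.is_epm:
        channels = {
            "abs_x": scores.norm_abs_x,
            "abs_y": scores.norm_abs_y,
            "speed": kin.speed_body,
            "head_dip": intervals.mask("head_dip", n, fps).astype(float),
            "freeze": intervals.mask("freeze", n, fps).astype(float),
            "location_index": scores.location_index,
        }
        binary = ["head_dip", "freeze"]
    else:
        channels = {
            "dist_to_rat": kin.dist_to_rat,
            "speed": kin.speed_body,
            "rat_speed": kin.rat_speed,
            "head_to_rat_angle": kin.head_to_rat_angle,
            "approach": intervals.mask("approach", n, fps).astype(float),
            "escape": intervals.mask("escape", n, fps).astype(float),
            "freeze": intervals.mask("freeze", n, fps).astype(float),
            "rat_movement": intervals.mask("rat_movement", n, fps).astype(float),
            "dist_from_safe_wall": pose.centroid()[:, 0],
        }
        binary = ["approach", "escape", "freeze", "rat_movement"]
    return channels, binary
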