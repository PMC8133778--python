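"""Synthetic session generator with planted ground truth.

Generates elevated-plus-maze (EPM), rat-exposure (RAT) and toy-rat (TOY)
sessions: a pose track at the behavior frame rate, a planted behavior-event
table, a per-frame approach/avoid/neutral state sequence, and a calcium
trace matrix at the (slower) neural rate whose cells are tuned to the
planted states.  Everything is a deterministic function of the seed, so the
whole pipeline is testable without any recorded data.

The trajectory model is deliberately simple: a waypoint-biased random walk
(reflective at the walls) whose wander speed is kept strictly inside the
band (0.8, 2.8) cm/s, so the only epochs that cross the freeze (0.25 cm/s)
or approach/escape (3 cm/s) thresholds are the planted ones.  Planted
events are scripted segments spliced into the walk:

* freeze       — the mouse holds position (speed 0) for the bout;
* approach     — straight run toward the rat at 5 cm/s (RAT/TOY);
* escape       — straight run away from the rat at 8 cm/s (RAT/TOY);
* head dip     — body parked in an open arm, nose displaced past the
                 lateral arm edge (EPM);
* rat movement — the rat, otherwise nearly stationary, runs at ~10 cm/s
                 for the bout so that these frames form the top tail of
                 the session's rat-speed distribution.

Calcium traces: cell rate = baseline + tuning x (state indicator), passed
through a single-exponential calcium kernel (GCaMP6s-like, tau default
2 s), plus i.i.d. Gaussian noise with SD = tuning/snr, plus an optional
multiplicative bleaching ramp shared across cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AssayGeometry,
    AssayKind,
    BehaviorIntervals,
    CoregistrationMap,
    PoseTrack,
    TraceMatrix,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Session",
    "Cohort",
    "STATE_NEUTRAL",
    "STATE_APPROACH",
    "STATE_AVOID",
    "simulate_behavior_session",
    "simulate_population_activity",
    "simulate_session",
    "simulate_cohort",
    "write_fixture_bundle",
    "load_ground_truth",
]

# per-frame state codes
STATE_NEUTRAL = 0
STATE_APPROACH = 1
STATE_AVOID = -1
STATE_NAMES = {STATE_NEUTRAL: "neutral", STATE_APPROACH: "approach", STATE_AVOID: "avoid"}

_EVENT_DEFAULT_COUNTS = {
    "freeze": 8,
    "approach": 6,
    "escape": 6,
    "head_dip": 5,
    "rat_movement": 4,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator.  The defaults are the study conditions:
    20 min sessions, 30 frames/s behavior video, 7.5 Hz neural sampling,
    a quarter of cells tuned to each arm type, and ~44% of cells
    co-registered across assays."""

    n_cells: int = 60
    frac_open: float = 0.25
    frac_closed: float = 0.25
    frac_neither: float = 0.5
    snr: float = 5.0
    calcium_decay_tau: float = 2.0
    session_length: float = 1200.0
    behavior_fps: float = 30.0
    neural_hz: float = 7.5
    seed: int = 0
    coregistration_frac: float = 0.44
    artifact_amplitude: float = 0.0
    tuning_amplitude: float = 1.0
    baseline: float = 0.1
    n_freezes: int = 8
    n_approaches: int = 6
    n_escapes: int = 6
    n_head_dips: int = 5
    n_rat_movements: int = 4
    freeze_duration_s: float = 1.0
    approach_duration_s: float = 1.5
    escape_duration_s: float = 1.2
    head_dip_duration_s: float = 0.6
    rat_movement_duration_s: float = 2.0

    def __post_init__(self) -> None:
        total = self.frac_open + self.frac_closed + self.frac_neither
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cell-category fractions must sum to 1")
        ratio = self.behavior_fps / self.neural_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("behavior_fps must be an integer multiple of neural_hz")
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")

    @property
    def downsample_ratio(self) -> int:
        return int(round(self.behavior_fps / self.neural_hz))

    def category_counts(self) -> tuple[int, int, int]:
        n_open = int(round(self.frac_open * self.n_cells))
        n_closed = int(round(self.frac_closed * self.n_cells))
        return n_open, n_closed, self.n_cells - n_open - n_closed


@dataclass
class GroundTruth:
    """Planted structure of one synthetic session."""

    assay_kind: AssayKind
    cell_category: dict[str, str]  # cell id -> open / closed / neither
    state_sequence: np.ndarray  # int8 per behavior frame (see STATE_*)
    events: BehaviorIntervals  # planted event table
    fps: float

    def state_mask(self, state: int) -> np.ndarray:
        return np.asarray(self.state_sequence) == state


@dataclass
class Session:
    """A simulated recording: pose + planted truth + calcium traces."""

    geometry: AssayGeometry
    config: SimulationConfig
    pose: PoseTrack
    truth: GroundTruth
    traces: TraceMatrix


@dataclass
class Cohort:
    """Matched EPM / RAT / TOY sessions from one simulated mouse, with the
    cell co-registration map between the EPM and rat-arena sessions."""

    epm: Session
    rat: Session
    toy: Session
    coreg: CoregistrationMap


# ---------------------------------------------------------------------------
# event scheduling


def _schedule_events(kinds: list[str], durations: dict[str, float], config: SimulationConfig,
                     rng: np.random.Generator, lead_s: float) -> list[tuple[int, int, str]]:
    """Place events in evenly spaced jittered slots; error when they can't fit."""
    if not kinds:
        return []
    T = config.session_length
    fps = config.behavior_fps
    margin = 12.0
    max_dur = max(durations[k] for k in kinds)
    slot = (T - 2 * margin) / len(kinds)
    if slot < max_dur + lead_s + 2.0 or T < 2 * margin + max_dur:
        raise ValueError(
            f"session of {T:.0f} s is too short for {len(kinds)} planted events"
        )
    kinds = list(kinds)
    rng.shuffle(kinds)
    out = []
    for i, kind in enumerate(kinds):
        dur = durations[kind]
        lo = margin + i * slot + lead_s
        hi = margin + (i + 1) * slot - dur - 1.0
        onset_s = rng.uniform(lo, min(hi, lo + slot / 3))
        onset = int(round(onset_s * fps))
        offset = onset + int(round(dur * fps))
        out.append((onset, offset, kind))
    return sorted(out)


# ---------------------------------------------------------------------------
# trajectory generation


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(*v))
    return v / n if n > 1e-12 else np.array([1.0, 0.0])


def _simulate_epm_track(geometry, config, rng, events):
    """Corridor walk on the plus-maze skeleton with closed-arm dwell bias."""
    fps = config.behavior_fps
    dt = 1.0 / fps
    n = int(round(config.session_length * fps))
    hw = geometry.half_width
    ext = geometry.epm_half_extent
    lead_frames = int(round(14.0 * fps))

    # corridor 0: open arms along x; corridor 1: closed arms along y
    corridor, s, lat, dirn, v = 1, 0.5 * ext, 0.0, 1.0, 1.5
    xy = np.zeros((n, 2))
    dip_nose = np.full(n, np.nan)  # lateral nose excursion during head dips

    ev_at = {}
    for onset, offset, kind in events:
        for t in range(onset, min(offset, n)):
            ev_at[t] = kind
        if kind == "head_dip":
            for t in range(max(onset - lead_frames, 0), onset):
                ev_at.setdefault(t, "lead_dip")

    frozen = None
    for t in range(n):
        mode = ev_at.get(t, "wander")
        if mode == "freeze":
            if frozen is None:
                frozen = (corridor, s, lat)
            corridor, s, lat = frozen
        elif mode == "lead_dip":
            frozen = None
            # steer into an open arm (corridor 0), away from the center
            if corridor == 1:
                step = min(2.6 * dt, abs(s))
                s -= np.sign(s) * step if abs(s) > 1e-9 else 0.0
                if abs(s) < hw - 1.0:
                    corridor, s, lat = 0, lat, s
            else:
                target = np.sign(s) if abs(s) > hw else 1.0
                goal = target * (hw + 0.6 * geometry.arm_length)
                if abs(s - goal) > 0.4:
                    s += np.sign(goal - s) * 2.6 * dt
                else:
                    s = goal + 0.3 * np.sin(0.12 * t)  # idle wobble, no parking
        elif mode == "head_dip":
            if frozen is None:
                frozen = (corridor, s, lat)
            # body wobbles slightly during the dip (a dipping mouse is not
            # frozen; keeps the freeze detector quiet)
            corridor = frozen[0]
            s = frozen[1] + 0.2 * np.cos(0.1 * t)
            lat = float(np.clip(frozen[2] + 0.2 * np.sin(0.1 * t), -0.7, 0.7))
            dip_nose[t] = hw + 1.0
        else:
            frozen = None
            v = float(np.clip(v + 0.6 * (1.9 - v) * dt + 1.2 * np.sqrt(dt) * rng.standard_normal(),
                              0.8, 2.8))
            if rng.random() < 0.004:
                dirn = -dirn
            # retreat bias out of open arms
            if corridor == 0 and abs(s) > hw and rng.random() < 0.006:
                dirn = -np.sign(s)
            s += dirn * v * dt
            lim = ext - 1.0
            if abs(s) > lim:
                s = np.sign(s) * (2 * lim - abs(s))
                dirn = -dirn
            lat = float(np.clip(lat + 0.25 * np.sqrt(dt) * rng.standard_normal(), -0.5, 0.5))
            if abs(s) < hw - 1.0 and rng.random() < 0.02:
                new_corr = 1 if rng.random() < 0.62 else 0
                if new_corr != corridor:
                    corridor, s, lat = new_corr, lat, s
                dirn = 1.0 if rng.random() < 0.5 else -1.0
        xy[t] = (s, lat) if corridor == 0 else (lat, s)
    return xy, dip_nose


def _simulate_rat_track(geometry, config, rng, events):
    """Waypoint random walk in the rat arena with a safe-side bias, plus the
    rat's own track (slow jitter + planted high-speed movements)."""
    fps = config.behavior_fps
    dt = 1.0 / fps
    n = int(round(config.session_length * fps))
    L, W = geometry.arena_length, geometry.arena_width
    rat_home = np.array([L - 4.0, W / 2.0])
    lead_frames = int(round(8.0 * fps))

    ev_at = {}
    rat_bursts = []
    for onset, offset, kind in events:
        if kind == "rat_movement":
            rat_bursts.append((onset, min(offset, n)))
            continue
        for t in range(onset, min(offset, n)):
            ev_at[t] = kind
        for t in range(max(onset - lead_frames, 0), onset):
            ev_at.setdefault(t, "lead_" + kind)

    xy = np.zeros((n, 2))
    pos = np.array([0.3 * L, W / 2.0])
    vel = np.array([1.5, 0.0])
    waypoint = pos.copy()
    next_wp = 0
    frozen = None
    for t in range(n):
        mode = ev_at.get(t, "wander")
        if mode == "freeze":
            if frozen is None:
                frozen = pos.copy()
            pos = frozen.copy()
        elif mode == "approach":
            frozen = None
            d = rat_home - pos
            if np.hypot(*d) > 3.0:
                pos = pos + 5.0 * dt * _unit(d)
            else:
                pos = pos + 1.2 * dt * _unit(np.array([-d[1], d[0]]))  # skirt the rat
        elif mode == "escape":
            frozen = None
            pos = pos + 8.0 * dt * _unit(pos - rat_home)
        elif mode in ("lead_approach", "lead_escape"):
            frozen = None
            goal = np.array([(0.3 if mode == "lead_approach" else 0.55) * L, W / 2.0])
            if np.hypot(*(goal - pos)) > 1.0:
                pos = pos + 2.6 * dt * _unit(goal - pos)
            else:
                # chase a slowly orbiting point instead of parking (parking
                # would read as a freeze); capped step, never a teleport
                target = goal + 0.4 * np.array([np.cos(0.1 * t), np.sin(0.1 * t)])
                gap = float(np.hypot(*(target - pos)))
                pos = pos + min(2.6 * dt, gap) * _unit(target - pos)
        else:
            frozen = None
            if t >= next_wp:
                # safe-side bias, but with regular excursions toward the rat
                u = rng.random()
                if u < 0.45:
                    waypoint = np.array([rng.uniform(2.0, geometry.safe_zone_max_x),
                                         rng.uniform(2, W - 2)])
                elif u < 0.7:
                    waypoint = np.array([rng.uniform(geometry.safe_zone_max_x, 0.65 * L),
                                         rng.uniform(2, W - 2)])
                else:
                    # risk-assessment excursion into the rat's vicinity
                    waypoint = np.array([rng.uniform(0.78 * L, L - 3.0),
                                         rat_home[1] + rng.uniform(-5, 5)])
                next_wp = t + int(rng.uniform(12, 25) * fps)
            if np.hypot(*(waypoint - pos)) < 2.0:
                next_wp = t  # arrived early: resample next frame, keep moving
            vel = 0.9 * vel + 0.1 * 2.2 * _unit(waypoint - pos)
            vel += 0.3 * np.sqrt(dt) * rng.standard_normal(2)
            speed = float(np.hypot(*vel))
            target = float(np.clip(speed, 0.85, 2.75))
            vel = vel * (target / max(speed, 1e-9))
            pos = pos + vel * dt
        clipped = np.array([np.clip(pos[0], 1.0, L - 1.0), np.clip(pos[1], 1.0, W - 1.0)])
        if mode == "wander" and not np.allclose(clipped, pos):
            next_wp = t  # hit a wall chasing the waypoint: pick a new one
        pos = clipped
        xy[t] = pos

    if geometry.assay_kind is AssayKind.TOY:
        # an inanimate toy rat does not move at all
        return xy, np.tile(rat_home, (n, 1))
    # rat track: slow smooth jitter around the tether + deterministic bursts
    theta = np.cumsum(rng.normal(0, 0.05, n))
    rat = rat_home + 1.5 * np.column_stack([np.cos(theta * 0.2), np.sin(theta * 0.2)])
    # small smooth wobble keeps baseline rat speed ~0.2-0.5 cm/s
    for onset, offset in rat_bursts:
        direction = _unit(rng.standard_normal(2))
        p = rat[max(onset - 1, 0)].copy()
        for k, t in enumerate(range(onset, offset)):
            step = (10.0 - 0.01 * k) * dt  # strictly decreasing ramp
            p = p + step * direction
            if not (1.0 < p[0] < L - 1.0) or not (1.0 < p[1] < W - 1.0):
                direction = -direction
                p = p + 2 * step * direction
            rat[t] = p
        # glide back toward the tether afterwards
        back = min(offset + int(2 * fps), n)
        if back > offset:
            ramp = np.linspace(0, 1, back - offset)[:, None]
            rat[offset:back] = rat[offset - 1] * (1 - ramp) + rat_home * ramp
    rat[:, 0] = np.clip(rat[:, 0], 1.0, L - 1.0)
    rat[:, 1] = np.clip(rat[:, 1], 1.0, W - 1.0)
    return xy, rat


def _keypoints_from_centroid(xy: np.ndarray, dip_nose: np.ndarray | None, geometry,
                             events: BehaviorIntervals | None = None) -> dict[str, np.ndarray]:
    """Place nose/ears/tailbase around the centroid along the heading."""
    n = len(xy)
    disp = np.vstack([[0.0, 0.0], np.diff(xy, axis=0)])
    heading = np.zeros((n, 2))
    h = np.array([1.0, 0.0])
    for t in range(n):
        d = disp[t]
        if np.hypot(*d) > 1e-6:
            h = 0.75 * h + 0.25 * _unit(d)
            h = _unit(h)
        heading[t] = h
    perp = np.column_stack([-heading[:, 1], heading[:, 0]])
    nose = xy + 2.5 * heading
    # offsets sum to zero so the 4-keypoint centroid equals the walk position
    # exactly and heading rotation adds no spurious body speed
    kp = {
        "nose": nose,
        "ear_l": xy + 1.0 * heading + 1.0 * perp,
        "ear_r": xy + 1.0 * heading - 1.0 * perp,
        "tailbase": xy - 4.5 * heading,
    }
    if dip_nose is not None:
        dip = np.isfinite(dip_nose)
        if dip.any():
            # nose pushed past the lateral edge of the open arm (open arms run
            # along x, so the lateral coordinate is y)
            kp["nose"] = kp["nose"].copy()
            kp["nose"][dip, 0] = xy[dip, 0]
            kp["nose"][dip, 1] = np.sign(xy[dip, 1] + 1e-9) * dip_nose[dip]
    return kp


# ---------------------------------------------------------------------------
# public generator API


def simulate_behavior_session(geometry: AssayGeometry, config: SimulationConfig
                              ) -> tuple[PoseTrack, GroundTruth]:
    """Generate a pose track plus ground truth for one session.

    Deterministic for a given (geometry.assay_kind, config.seed).
    """
    assay = geometry.assay_kind
    rng = np.random.default_rng([config.seed, {"EPM": 0, "RAT": 1, "TOY": 2}[assay.value]])
    fps = config.behavior_fps
    n = int(round(config.session_length * fps))

    durations = {
        "freeze": config.freeze_duration_s,
        "approach": config.approach_duration_s,
        "escape": config.escape_duration_s,
        "head_dip": config.head_dip_duration_s,
        "rat_movement": config.rat_movement_duration_s,
    }
    if assay is AssayKind.EPM:
        kinds = ["freeze"] * config.n_freezes + ["head_dip"] * config.n_head_dips
        lead = 14.0
    else:
        # rat movements share the slot sequence with mouse events so the
        # rat's own motion never perturbs a planted approach/escape bout
        kinds = (["freeze"] * config.n_freezes + ["approach"] * config.n_approaches
                 + ["escape"] * config.n_escapes)
        if assay is AssayKind.RAT:
            kinds += ["rat_movement"] * config.n_rat_movements
        lead = 8.0
    events = _schedule_events(kinds, durations, config, rng, lead)
    mouse_events = [e for e in events if e[2] != "rat_movement"]
    rat_events = [e for e in events if e[2] == "rat_movement"]

    if assay is AssayKind.EPM:
        xy, dip_nose = _simulate_epm_track(geometry, config, rng, mouse_events)
        kp = _keypoints_from_centroid(xy, dip_nose, geometry)
    else:
        xy, rat_xy = _simulate_rat_track(geometry, config, rng, mouse_events + rat_events)
        kp = _keypoints_from_centroid(xy, None, geometry)
        kp["rat"] = rat_xy
    pose = PoseTrack(kp, fps, geometry)

    records = [(kind, onset / fps, offset / fps) for onset, offset, kind in
               sorted(mouse_events + rat_events)]
    events = BehaviorIntervals.from_records(records)

    state = _planted_state_sequence(assay, geometry, xy, events, n, fps)
    categories = _assign_categories(config, rng_master=np.random.default_rng([config.seed, 99]))
    truth = GroundTruth(assay, categories, state, events, fps)
    return pose, truth


def _assign_categories(config: SimulationConfig, rng_master) -> dict[str, str]:
    n_open, n_closed, n_neither = config.category_counts()
    labels = ["open"] * n_open + ["closed"] * n_closed + ["neither"] * n_neither
    rng_master.shuffle(labels)
    return {f"c{i:04d}": lab for i, lab in enumerate(labels)}


def _planted_state_sequence(assay, geometry, xy, events: BehaviorIntervals,
                            n: int, fps: float) -> np.ndarray:
    """Per-frame approach/avoid/neutral codes.  In the EPM, approach maps to
    open-arm occupancy and head dips, avoid to closed arms and freezes; in
    the rat arena, approach maps to approach bouts and the threat zone,
    avoid to escapes, freezes and the safe zone.  TOY sessions carry no
    state at all (negative control)."""
    state = np.zeros(n, dtype=np.int8)
    if assay is AssayKind.TOY:
        return state
    if assay is AssayKind.EPM:
        hw = geometry.half_width
        open_mask = (np.abs(xy[:, 0]) > hw) & (np.abs(xy[:, 1]) <= hw)
        closed_mask = (np.abs(xy[:, 1]) > hw) & (np.abs(xy[:, 0]) <= hw)
        state[open_mask] = STATE_APPROACH
        state[closed_mask] = STATE_AVOID
        state[events.mask("head_dip", n, fps)] = STATE_APPROACH
    else:
        rat_ref = np.array(geometry.rat_tether_xy)
        dist = np.hypot(*(xy - rat_ref).T)
        state[dist <= geometry.threat_distance_cm] = STATE_APPROACH
        state[xy[:, 0] <= geometry.safe_zone_max_x] = STATE_AVOID
        state[events.mask("approach", n, fps)] = STATE_APPROACH
        state[events.mask("escape", n, fps)] = STATE_AVOID
    state[events.mask("freeze", n, fps)] = STATE_AVOID
    return state


def simulate_population_activity(truth: GroundTruth, config: SimulationConfig) -> TraceMatrix:
    """Calcium traces tuned to the planted state sequence.

    Open cells follow the approach state, closed cells the avoid state,
    neither cells carry baseline only; TOY sessions get no tuning at all.
    """
    if not config.snr > 0:
        raise ValueError("snr must be positive (np.inf allowed for noiseless traces)")
    rng = np.random.default_rng([config.seed, 7, {"EPM": 0, "RAT": 1, "TOY": 2}[truth.assay_kind.value]])
    ratio = config.downsample_ratio
    n_frames = len(truth.state_sequence)
    n_neural = n_frames // ratio
    state = np.asarray(truth.state_sequence[: n_neural * ratio])
    blocks = state.reshape(n_neural, ratio)
    frac_approach = (blocks == STATE_APPROACH).mean(axis=1)
    frac_avoid = (blocks == STATE_AVOID).mean(axis=1)

    amp = config.tuning_amplitude
    cells = list(truth.cell_category)[: config.n_cells]
    drive = np.zeros((len(cells), n_neural))
    for i, cid in enumerate(cells):
        cat = truth.cell_category[cid]
        if truth.assay_kind is AssayKind.TOY:
            tuning = np.zeros(n_neural)
        elif cat == "open":
            tuning = frac_approach
        elif cat == "closed":
            tuning = frac_avoid
        else:
            tuning = np.zeros(n_neural)
        drive[i] = config.baseline + amp * tuning

    # single-exponential calcium kernel as a unit-gain AR(1) filter
    a = float(np.exp(-1.0 / (config.neural_hz * config.calcium_decay_tau)))
    from scipy.signal import lfilter

    sig = lfilter([1 - a], [1, -a], drive, axis=1)
    if np.isfinite(config.snr):
        sig = sig + rng.normal(0.0, amp / config.snr, sig.shape)
    if config.artifact_amplitude > 0:
        t = np.arange(n_neural) / config.neural_hz
        ramp = 1.0 + config.artifact_amplitude * np.exp(-t / (config.session_length / 3.0))
        sig = sig * ramp[None, :]
    return TraceMatrix(sig, config.neural_hz, cells)


def simulate_session(geometry: AssayGeometry, config: SimulationConfig) -> Session:
    pose, truth = simulate_behavior_session(geometry, config)
    traces = simulate_population_activity(truth, config)
    return Session(geometry, config, pose, truth, traces)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """One simulated mouse run through all three assays.

    Cell identities are shared across sessions; the co-registration map
    pairs a seeded random subset of ``coregistration_frac`` of the cells
    between the EPM and rat-arena sessions.  Co-registered cells keep their
    planted category in both assays (the cross-assay shared code that CoCA
    and centroid transfer are meant to find).
    """
    epm = simulate_session(AssayGeometry.epm(), config)
    rat = simulate_session(AssayGeometry.rat(), config)
    toy = simulate_session(AssayGeometry.toy(), config)
    rng = np.random.default_rng([config.seed, 13])
    k = int(round(config.coregistration_frac * config.n_cells))
    ids = np.array(epm.traces.cell_ids)
    chosen = np.sort(rng.choice(len(ids), size=k, replace=False))
    pairs = pd.DataFrame({"cell_id_assay1": ids[chosen], "cell_id_assay2": ids[chosen]})
    return Cohort(epm, rat, toy, CoregistrationMap(pairs))


# ---------------------------------------------------------------------------
# fixture writing / round-trips


def _write_traces_h5(traces: TraceMatrix, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=traces.values)
        d.attrs["fs_hz"] = traces.fs
        f.create_dataset("cell_ids", data=np.array(traces.cell_ids, dtype="S"))


def _write_traces_csv(traces: TraceMatrix, path: Path) -> None:
    df = pd.DataFrame(traces.values, index=pd.Index(traces.cell_ids, name="cell_id"))
    df.insert(0, "fs_hz", traces.fs)
    df.to_csv(path)


def _write_pose_csv(pose: PoseTrack, path: Path) -> None:
    """DeepLabCut-dialect CSV: three header rows (scorer/bodyparts/coords)."""
    cols, data = [], []
    for name, xy in pose.keypoints.items():
        lik = pose.likelihood.get(name, np.ones(pose.n_frames))
        for coord, arr in (("x", xy[:, 0]), ("y", xy[:, 1]), ("likelihood", lik)):
            cols.append(("synth", name, coord))
            data.append(arr)
    df = pd.DataFrame(np.column_stack(data),
                      columns=pd.MultiIndex.from_tuples(cols, names=["scorer", "bodyparts", "coords"]))
    df.index.name = None
    df.to_csv(path, index=True)


def write_fixture_bundle(sessions: dict[str, Session], out_dir,
                         coreg: CoregistrationMap | None = None,
                         trace_format: str = "h5") -> dict[str, dict[str, Path]]:
    """Write a session set to disk in the pipeline's input formats.

    Per session: ``<name>_traces.h5`` (dataset ``traces`` with ``fs_hz``
    attribute) or ``<name>_traces.csv``; ``<name>_pose.csv`` (DeepLabCut
    dialect); ``<name>_truth.json``.  Plus ``coreg.csv`` when a
    co-registration map is given.  Loading these back through
    :mod:`pagstates.preprocess` round-trips within float precision.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    paths: dict[str, dict[str, Path]] = {}
    for name, sess in sessions.items():
        p: dict[str, Path] = {}
        if trace_format == "h5":
            p["traces"] = out_dir / f"{name}_traces.h5"
            _write_traces_h5(sess.traces, p["traces"])
        elif trace_format == "csv":
            p["traces"] = out_dir / f"{name}_traces.csv"
            _write_traces_csv(sess.traces, p["traces"])
        else:
            raise ValueError(f"unknown trace format {trace_format!r}")
        p["pose"] = out_dir / f"{name}_pose.csv"
        _write_pose_csv(sess.pose, p["pose"])
        p["truth"] = out_dir / f"{name}_truth.json"
        truth = sess.truth
        payload = {
            "assay_kind": truth.assay_kind.value,
            "cell_category": truth.cell_category,
            "fps": truth.fps,
            "state_sequence": np.asarray(truth.state_sequence, dtype=int).tolist(),
            "events": truth.events.table.assign(
                meta=truth.events.table["meta"].apply(json.dumps)
            ).to_dict(orient="records"),
        }
        p["truth"].write_text(json.dumps(payload))
        paths[name] = p
    if coreg is not None:
        cpath = out_dir / "coreg.csv"
        coreg.to_csv(cpath)
        paths["coreg"] = {"coreg": cpath}
    return paths


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    events = pd.DataFrame(payload["events"])
    if len(events):
        events["meta"] = events["meta"].apply(json.loads)
    return GroundTruth(
        AssayKind(payload["assay_kind"]),
        payload["cell_category"],
        np.asarray(payload["state_sequence"], dtype=np.int8),
        BehaviorIntervals(events),
        payload["fps"],
    )
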