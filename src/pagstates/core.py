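"""Core data containers shared by every pipeline stage.

The pipeline operates on four kinds of objects: calcium trace matrices
(:class:`TraceMatrix`), pose tracks from a keypoint tracker
(:class:`PoseTrack`), labeled behavior event tables
(:class:`BehaviorIntervals`) and assay geometry descriptions
(:class:`AssayGeometry`).  Everything downstream (zone labels, scores,
decoders, state models) is derived from these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "AssayKind",
    "AssayGeometry",
    "TraceMatrix",
    "PoseTrack",
    "BehaviorIntervals",
    "CoregistrationMap",
    "runs_to_intervals",
    "intervals_to_mask",
]

MOUSE_KEYPOINTS = ("nose", "ear_l", "ear_r", "tailbase")


class AssayKind(str, Enum):
    """Which arena the session was recorded in.

    ``EPM``  elevated plus maze (two open, two closed arms, center square).
    ``RAT``  rectangular arena with a tethered live rat at one end.
    ``TOY``  same arena with an inanimate toy rat (no-threat control).
    """

    EPM = "EPM"
    RAT = "RAT"
    TOY = "TOY"


@dataclass(frozen=True)
class AssayGeometry:
    """Physical dimensions of an assay arena, in cm.

    The EPM is modeled in a frame centered on the maze center with the open
    arms along x and the closed arms along y.  The rat arena is modeled with
    x in [0, arena_length], y in [0, arena_width]; the safe wall is at x = 0
    and the rat is tethered near x = arena_length.
    """

    assay_kind: AssayKind
    arm_length: float = 30.0
    arm_width: float = 7.0
    arena_length: float = 70.0
    arena_width: float = 26.0
    safe_zone_fraction: float = 0.2
    threat_distance_cm: float = 14.0

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        if isinstance(self.assay_kind, str) and not isinstance(self.assay_kind, AssayKind):
            object.__setattr__(self, "assay_kind", AssayKind(self.assay_kind))
        for name in ("arm_length", "arm_width", "arena_length", "arena_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.safe_zone_fraction < 1:
            raise ValueError("safe_zone_fraction must lie in (0, 1)")

    # -- EPM helpers ------------------------------------------------------
    @property
    def half_width(self) -> float:
        return self.arm_width / 2.0

    @property
    def epm_half_extent(self) -> float:
        """Distance from maze center to the far end of an arm."""
        return self.arm_length + self.half_width

    @property
    def is_epm(self) -> bool:
        return self.assay_kind is AssayKind.EPM

    # -- rat-arena helpers ------------------------------------------------
    @property
    def safe_zone_max_x(self) -> float:
        return self.safe_zone_fraction * self.arena_length

    @property
    def rat_tether_xy(self) -> tuple[float, float]:
        return (self.arena_length, self.arena_width / 2.0)

    @classmethod
    def epm(cls, **kw) -> "AssayGeometry":
        return cls(AssayKind.EPM, **kw)

    @classmethod
    def rat(cls, **kw) -> "AssayGeometry":
        return cls(AssayKind.RAT, **kw)

    @classmethod
    def toy(cls, **kw) -> "AssayGeometry":
        return cls(AssayKind.TOY, **kw)


@dataclass
class TraceMatrix:
    """Cells x timepoints calcium activity (dF/F or z-scored).

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_timepoints)
    fs : float
        Sampling rate in Hz.
    cell_ids : sequence of str
        Unique cell identifiers, one per row.
    is_zscored : bool
        Set once :func:`pagstates.preprocess.zscore_traces` has run; guards
        against accidental double normalization.
    """

    values: np.ndarray
    fs: float
    cell_ids: list[str] = field(default_factory=list)
    is_zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x timepoints matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.cell_ids:
            self.cell_ids = [f"c{i:04d}" for i in range(self.n_cells)]
        if len(self.cell_ids) != self.n_cells:
            raise ValueError("cell_ids length does not match number of rows")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_timepoints / self.fs

    def select_cells(self, ids: list[str]) -> "TraceMatrix":
        """Return a new matrix restricted to ``ids``, in the given order."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        rows = [index[c] for c in ids]
        return TraceMatrix(self.values[rows].copy(), self.fs, list(ids), self.is_zscored)

    def copy(self) -> "TraceMatrix":
        return TraceMatrix(self.values.copy(), self.fs, list(self.cell_ids), self.is_zscored)


@dataclass
class PoseTrack:
    """Per-frame keypoint coordinates for one session.

    ``keypoints`` maps a bodypart name to an (n_frames, 2) array of x/y in
    cm.  Mouse keypoints are nose, ear_l, ear_r, tailbase; rat-assay sessions
    additionally carry a ``rat`` keypoint (rat body center).  ``likelihood``
    optionally carries the tracker's per-frame confidence per keypoint.
    """

    keypoints: dict[str, np.ndarray]
    fps: float
    geometry: AssayGeometry
    likelihood: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = None
        for name, xy in self.keypoints.items():
            xy = np.asarray(xy, dtype=float)
            if xy.ndim != 2 or xy.shape[1] != 2:
                raise ValueError(f"keypoint {name!r} must be (n_frames, 2)")
            self.keypoints[name] = xy
            if n is None:
                n = len(xy)
            elif len(xy) != n:
                raise ValueError("keypoints disagree on frame count")
        missing = [k for k in MOUSE_KEYPOINTS if k not in self.keypoints]
        if missing:
            raise ValueError(f"missing keypoints: {missing}")

    @property
    def n_frames(self) -> int:
        return len(self.keypoints["nose"])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def has_rat(self) -> bool:
        return "rat" in self.keypoints

    def centroid(self) -> np.ndarray:
        """Body centroid: mean of the four mouse keypoints, (n, 2)."""
        stack = np.stack([self.keypoints[k] for k in MOUSE_KEYPOINTS])
        return stack.mean(axis=0)

    def head_center(self) -> np.ndarray:
        """Head position: mean of nose and both ears, (n, 2)."""
        stack = np.stack([self.keypoints[k] for k in ("nose", "ear_l", "ear_r")])
        return stack.mean(axis=0)

    def translated(self, dx: float, dy: float) -> "PoseTrack":
        shifted = {k: v + np.array([dx, dy]) for k, v in self.keypoints.items()}
        return PoseTrack(shifted, self.fps, self.geometry, dict(self.likelihood))


class BehaviorIntervals:
    """Labeled behavior event table: (label, onset_s, offset_s, metadata).

    Thin wrapper over a pandas DataFrame that enforces onset < offset and
    forbids overlapping intervals of the same label.
    """

    COLUMNS = ("label", "onset_s", "offset_s", "meta")

    def __init__(self, table: pd.DataFrame | None = None):
        if table is None:
            table = pd.DataFrame({c: [] for c in self.COLUMNS})
        table = table.reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in table.columns:
                table[col] = [{} for _ in range(len(table))] if col == "meta" else np.nan
        self.table = table[list(self.COLUMNS)]
        self._validate()

    def _validate(self) -> None:
        t = self.table
        if len(t) == 0:
            return
        if not (t["onset_s"] < t["offset_s"]).all():
            raise ValueError("every interval needs onset < offset")
        for label, grp in t.groupby("label"):
            g = grp.sort_values("onset_s")
            if (g["onset_s"].to_numpy()[1:] < g["offset_s"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping {label!r} intervals")

    @classmethod
    def from_records(cls, records: list[tuple]) -> "BehaviorIntervals":
        rows = []
        for rec in records:
            label, onset, offset = rec[:3]
            meta = rec[3] if len(rec) > 3 else {}
            rows.append({"label": label, "onset_s": onset, "offset_s": offset, "meta": meta})
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def of(self, label: str) -> pd.DataFrame:
        return self.table[self.table["label"] == label].reset_index(drop=True)

    def labels(self) -> set[str]:
        return set(self.table["label"])

    def __len__(self) -> int:
        return len(self.table)

    def __add__(self, other: "BehaviorIntervals") -> "BehaviorIntervals":
        return BehaviorIntervals(
            pd.concat([self.table, other.table], ignore_index=True).sort_values(
                "onset_s", ignore_index=True
            )
        )

    def mask(self, label: str, n_samples: int, fs: float) -> np.ndarray:
        """Boolean per-sample mask at rate ``fs`` for intervals of ``label``."""
        return intervals_to_mask(self.of(label), n_samples, fs)

    def to_tsv(self, path) -> None:
        import json

        out = self.table.copy()
        out["meta"] = out["meta"].apply(json.dumps)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "BehaviorIntervals":
        import json

        t = pd.read_csv(path, sep="\t")
        if len(t):
            t["meta"] = t["meta"].apply(json.loads)
        return cls(t)


@dataclass
class CoregistrationMap:
    """One-to-one pairing of cell ids across two sessions."""

    pairs: pd.DataFrame  # columns: cell_id_assay1, cell_id_assay2

    def __post_init__(self) -> None:
        cols = ["cell_id_assay1", "cell_id_assay2"]
        if list(self.pairs.columns[:2]) != cols:
            self.pairs = self.pairs.iloc[:, :2].set_axis(cols, axis=1)
        for col in cols:
            if self.pairs[col].duplicated().any():
                raise ValueError(f"co-registration map has duplicate ids in {col}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ids_assay1(self) -> list[str]:
        return list(self.pairs["cell_id_assay1"])

    @property
    def ids_assay2(self) -> list[str]:
        return list(self.pairs["cell_id_assay2"])

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CoregistrationMap":
        return cls(pd.read_csv(path, dtype=str))


# ---------------------------------------------------------------------------
# run-length helpers used by every detector


def runs_to_intervals(mask: np.ndarray, fs: float, min_duration_s: float = 0.0):
    """Maximal True runs of ``mask`` as (onset_s, offset_s) pairs.

    A run of n samples at rate fs has duration n / fs; runs shorter than
    ``min_duration_s`` are dropped.  Offsets are exclusive (first sample
    after the run), so onset/offset are multiples of 1/fs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    out = []
    for a, b in zip(starts, stops):
        if (b - a) / fs >= min_duration_s - 1e-12:
            out.append((a / fs, b / fs))
    return out


def intervals_to_mask(table: pd.DataFrame, n_samples: int, fs: float) -> np.ndarray:
    """Per-sample boolean mask for a (onset_s, offset_s) interval table."""
    mask = np.zeros(n_samples, dtype=bool)
    for _, row in table.iterrows():
        a = int(np.round(row["onset_s"] * fs))
        b = int(np.round(row["offset_s"] * fs))
        mask[max(a, 0) : min(b, n_samples)] = True
    return mask
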