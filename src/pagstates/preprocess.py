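"""Session loading and trace conditioning.

The conditioning chain is fixed: PCA artifact suppression (optional per
session) -> variance thresholding against a reference cell -> z-scoring,
applied exactly once over the whole session.  Time-base alignment maps the
30 frames/s behavior clock onto the 7.5 Hz neural clock by block averaging
(continuous channels) or any-within-block (binary labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AssayGeometry, AssayKind, PoseTrack, TraceMatrix, MOUSE_KEYPOINTS

__all__ = [
    "load_traces",
    "load_pose",
    "load_session",
    "suppress_artifact_components",
    "variance_filter",
    "zscore_traces",
    "align_timebases",
    "downsample_series",
    "ArtifactReport",
    "VarianceReport",
]


# ---------------------------------------------------------------------------
# loading


def load_traces(path) -> TraceMatrix:
    """Read a trace matrix from HDF5 (dataset ``traces``, attr ``fs_hz``)
    or wide CSV (index column ``cell_id``, first column ``fs_hz``)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            values = np.asarray(f["traces"], dtype=float)
            fs = float(f["traces"].attrs["fs_hz"])
            if "cell_ids" in f:
                ids = [c.decode() for c in f["cell_ids"][()]]
            else:
                ids = []
        return TraceMatrix(values, fs, ids)
    df = pd.read_csv(path, index_col=0)
    if "fs_hz" not in df.columns:
        raise ValueError(f"{path}: wide trace CSV must carry an fs_hz column")
    fs = float(df["fs_hz"].iloc[0])
    values = df.drop(columns="fs_hz").to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-numeric or missing trace values")
    return TraceMatrix(values, fs, [str(i) for i in df.index])


def load_pose(path, geometry: AssayGeometry, fps: float = 30.0,
              likelihood_threshold: float = 0.9, max_gap_frames: int = 10) -> PoseTrack:
    """Read a DeepLabCut-dialect pose CSV (scorer/bodyparts/coords header).

    Frames whose likelihood falls below ``likelihood_threshold`` are treated
    as tracker gaps and linearly interpolated, up to ``max_gap_frames``
    consecutive frames; longer gaps raise.
    """
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = df.columns.get_level_values("bodyparts")
    keypoints: dict[str, np.ndarray] = {}
    likelihood: dict[str, np.ndarray] = {}
    for part in dict.fromkeys(bodyparts):
        sub = df.xs(part, axis=1, level="bodyparts")
        sub.columns = sub.columns.get_level_values("coords")
        if "x" not in sub.columns or "y" not in sub.columns:
            raise ValueError(f"{path}: keypoint {part!r} lacks x/y columns")
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        lik = sub["likelihood"].to_numpy(dtype=float) if "likelihood" in sub.columns else np.ones(len(xy))
        bad = (lik < likelihood_threshold) | ~np.isfinite(xy).all(axis=1)
        if bad.any():
            xy = _interpolate_gaps(xy, bad, max_gap_frames, part)
        keypoints[part] = xy
        likelihood[part] = lik
    missing = [k for k in MOUSE_KEYPOINTS if k not in keypoints]
    if missing:
        raise ValueError(f"{path}: missing keypoints {missing}")
    return PoseTrack(keypoints, fps, geometry, likelihood)


def _interpolate_gaps(xy: np.ndarray, bad: np.ndarray, max_gap: int, part: str) -> np.ndarray:
    idx = np.arange(len(xy))
    runs = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    for a, b in zip(runs[::2], runs[1::2]):
        if b - a > max_gap:
            raise ValueError(f"tracker gap of {b - a} frames in keypoint {part!r} "
                             f"exceeds the {max_gap}-frame interpolation limit")
    out = xy.copy()
    good = ~bad
    if good.sum() < 2:
        raise ValueError(f"keypoint {part!r} has too few tracked frames")
    for col in range(2):
        out[bad, col] = np.interp(idx[bad], idx[good], xy[good, col])
    return out


def load_session(trace_path, pose_path, geometry: AssayGeometry,
                 fps: float = 30.0) -> tuple[TraceMatrix, PoseTrack]:
    """Load and validate one session's traces and pose."""
    return load_traces(trace_path), load_pose(pose_path, geometry, fps)


# ---------------------------------------------------------------------------
# artifact suppression


@dataclass
class ArtifactReport:
    variance_ratios: np.ndarray
    candidate_pcs: list[int]
    removed_pcs: list[int]
    removed_variance: float


def suppress_artifact_components(traces: TraceMatrix, flagged_pcs: list[int] | None = None,
                                 variance_threshold: float = 0.05,
                                 slow_band_hz: float = 0.01,
                                 slow_power_fraction: float = 0.6,
                                 ) -> tuple[TraceMatrix, ArtifactReport]:
    """Remove large-variance artifact principal components.

    PCA is computed over cells (cells are the variables, timepoints the
    samples).  Candidate PCs are those carrying at least
    ``variance_threshold`` (5%) of total variance.  When ``flagged_pcs`` is
    given it is used verbatim (after checking the indices are candidates);
    otherwise a candidate is auto-flagged when more than
    ``slow_power_fraction`` of its projected-signal power lies below
    ``slow_band_hz`` — a reproducible surrogate for visually spotting slow
    shared bleaching.  Flagged PCs are excluded from the reconstruction.
    """
    if traces.is_zscored:
        raise ValueError("artifact suppression must run before z-scoring")
    X = traces.values  # cells x time
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    # SVD of the centered matrix: rows of Vt are time courses, cols of U loadings
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    ratios = var / var.sum() if var.sum() > 0 else var
    candidates = [int(i) for i in np.flatnonzero(ratios >= variance_threshold)]

    if flagged_pcs is not None:
        for i in flagged_pcs:
            if not 0 <= i < len(s):
                raise IndexError(f"flagged PC index {i} out of range")
        removed = sorted(int(i) for i in flagged_pcs)
    else:
        removed = []
        for i in candidates:
            proj = s[i] * Vt[i]
            power = np.abs(np.fft.rfft(proj)) ** 2
            freqs = np.fft.rfftfreq(proj.size, d=1.0 / traces.fs)
            total = power.sum()
            if total > 0 and power[freqs <= slow_band_hz].sum() / total > slow_power_fraction:
                removed.append(i)

    if not removed:
        out = traces.copy()
    else:
        keep = np.ones(len(s), dtype=bool)
        keep[removed] = False
        if not keep.any():
            warnings.warn("all principal components removed; traces reduced to their means")
        recon = (U[:, keep] * s[keep]) @ Vt[keep] + mean
        out = TraceMatrix(recon, traces.fs, list(traces.cell_ids), traces.is_zscored)
    report = ArtifactReport(ratios, candidates, removed, float(ratios[removed].sum()) if removed else 0.0)
    return out, report


# ---------------------------------------------------------------------------
# variance thresholding


@dataclass
class VarianceReport:
    reference_cell: str
    reference_variance: float
    discarded_cells: list[str]
    elbow_index: int | None


def find_elbow(sorted_values: np.ndarray, min_relative_depth: float = 0.02) -> int | None:
    """Elbow of a descending curve: the point of maximum perpendicular
    distance to the chord joining the first and last points, computed on
    axes normalized to [0, 1] (so index and variance scales weigh equally).
    Returns None when the curve is flat or too straight (no obvious elbow).
    """
    y = np.asarray(sorted_values, dtype=float)
    n = len(y)
    if n < 3:
        return None
    yrange = y[0] - y[-1]
    if yrange <= 1e-9 * max(abs(y[0]), 1.0):
        return None  # flat curve
    xn = np.linspace(0.0, 1.0, n)
    yn = (y - y[-1]) / yrange
    # chord runs from (0, 1) to (1, 0); perpendicular distance of (xn, yn)
    d = np.abs(xn + yn - 1.0) / np.sqrt(2.0)
    if d.max() < min_relative_depth:
        return None
    return int(np.argmax(d))


def variance_filter(traces: TraceMatrix, ratio_threshold: float = 0.1
                    ) -> tuple[TraceMatrix, VarianceReport]:
    """Discard low-variance cells relative to a reference cell.

    Cell variances are sorted in decreasing order; the reference cell sits at
    the elbow of that curve (falling back to the highest-variance cell when
    no clear elbow exists).  Cells with variance below ``ratio_threshold``
    (10%) of the reference variance are removed.  The reference cell itself
    always survives.
    """
    if traces.n_cells < 3:
        raise ValueError("variance filtering needs at least 3 cells")
    var = traces.values.var(axis=1, ddof=0)
    order = np.argsort(var)[::-1]
    sorted_var = var[order]
    elbow = find_elbow(sorted_var)
    ref_pos = elbow if elbow is not None else 0
    ref_idx = int(order[ref_pos])
    ref_var = float(var[ref_idx])
    keep = (var >= ratio_threshold * ref_var) | (np.arange(traces.n_cells) == ref_idx)
    if not keep.any():
        raise ValueError("variance filter removed every cell")
    discarded = [traces.cell_ids[i] for i in np.flatnonzero(~keep)]
    kept_ids = [traces.cell_ids[i] for i in np.flatnonzero(keep)]
    out = TraceMatrix(traces.values[keep].copy(), traces.fs, kept_ids, traces.is_zscored)
    return out, VarianceReport(traces.cell_ids[ref_idx], ref_var, discarded, elbow)


# ---------------------------------------------------------------------------
# z-scoring


def zscore_traces(traces: TraceMatrix) -> TraceMatrix:
    """z = (x - mu) / sigma per cell over the whole session (population SD).

    Applied exactly once: re-running on already z-scored traces raises
    instead of silently renormalizing.
    """
    if traces.is_zscored:
        raise ValueError("traces are already z-scored; refusing to z-score twice")
    mu = traces.values.mean(axis=1, keepdims=True)
    sd = traces.values.std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"cell {traces.cell_ids[zero[0]]!r} has zero variance; "
                         "run variance_filter first")
    return TraceMatrix((traces.values - mu) / sd, traces.fs, list(traces.cell_ids), True)


# ---------------------------------------------------------------------------
# time-base alignment


def downsample_series(series: np.ndarray, ratio: int, binary: bool = False) -> np.ndarray:
    """Downsample a behavior-clock series onto the neural clock.

    Continuous channels are block-averaged; binary labels use any-within-
    block.  The trailing partial block is dropped.
    """
    series = np.asarray(series)
    n_blocks = series.shape[0] // ratio
    trimmed = series[: n_blocks * ratio]
    blocks = trimmed.reshape(n_blocks, ratio, *series.shape[1:])
    if binary:
        return blocks.astype(bool).any(axis=1)
    return blocks.mean(axis=1)


def align_timebases(traces: TraceMatrix, pose: PoseTrack) -> tuple[TraceMatrix, dict[str, np.ndarray], int]:
    """Align traces and pose onto the neural clock.

    Returns the (possibly trimmed) traces, the block-averaged keypoint
    coordinates, and the integer downsampling ratio.
    """
    ratio_f = pose.fps / traces.fs
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-9:
        raise ValueError(f"behavior fps {pose.fps} is not an integer multiple of "
                         f"neural rate {traces.fs}")
    down = {k: downsample_series(v, ratio) for k, v in pose.keypoints.items()}
    n = min(traces.n_timepoints, next(iter(down.values())).shape[0])
    down = {k: v[:n] for k, v in down.items()}
    trimmed = TraceMatrix(traces.values[:, :n].copy(), traces.fs, list(traces.cell_ids),
                          traces.is_zscored)
    return trimmed, down, ratio
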