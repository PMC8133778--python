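"""Arm-preferring ensemble analysis.

Cells are categorized as open-, closed- or neither-arm-preferring by
one-sided Wilcoxon rank-sum tests of per-frame activity in each individual
arm against the pooled opposite arm type.  Arm preference is also scored
continuously as 2*AUC - 1 (the ROC area from thresholding single-cell
activity), and as the EPM score (A - B)/(A + B) contrasting between- and
within-arm-type activity differences.  Peri-event aligned traces and
activity changes (delta dF/F) quantify behavior coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import ZoneLabels
from .core import BehaviorIntervals, TraceMatrix

__all__ = [
    "EnsembleLabels",
    "ArmScores",
    "PeriEventResult",
    "categorization_split",
    "categorize_arm_cells",
    "open_arm_preference_score",
    "epm_score",
    "compute_arm_scores",
    "peri_event_analysis",
    "activity_correlations",
    "spatial_activity_map",
    "downsample_zone_labels",
]

ARMS = ("open1", "open2", "closed1", "closed2")


def downsample_zone_labels(zones: ZoneLabels, ratio: int) -> ZoneLabels:
    """Zone labels on the neural clock by per-block majority vote."""
    labels = zones.labels
    n = len(labels) // ratio
    blocks = labels[: n * ratio].reshape(n, ratio)
    out = np.empty(n, dtype=labels.dtype)
    for i, row in enumerate(blocks):
        vals, counts = np.unique(row, return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return ZoneLabels(out, zones.assay)


def categorization_split(n_timepoints: int, fs: float, train_frac: float = 0.4,
                         gap_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """First 40% of the session for categorization, the last 60% (after a
    10 s separation) withheld for activity/correlation estimates."""
    split = int(round(train_frac * n_timepoints))
    gap = int(round(gap_s * fs))
    cat = np.zeros(n_timepoints, dtype=bool)
    cat[:split] = True
    held = np.zeros(n_timepoints, dtype=bool)
    held[min(split + gap, n_timepoints):] = True
    return cat, held


@dataclass
class EnsembleLabels:
    """Per-cell open/closed/neither category with the per-arm p-values."""

    table: pd.DataFrame  # index cell_id; columns category, p_open1, ...
    split: str = "full"

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def cells(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    def counts(self) -> dict[str, int]:
        return self.table["category"].value_counts().to_dict()


def categorize_arm_cells(traces: TraceMatrix, zones: ZoneLabels,
                         split: str | np.ndarray | None = None,
                         alpha: float = 0.05) -> EnsembleLabels:
    """Open/closed/neither categorization by one-sided rank-sum tests.

    A cell is open-arm-preferring iff its activity in *each individual* open
    arm is significantly greater (one-sided Wilcoxon rank sum, p < alpha)
    than its pooled closed-arm activity; closed cells by the mirrored rule;
    everything else is neither.  Center frames are excluded.  ``split`` may
    be None (whole session), "40/60" (categorize on the first 40% only) or a
    boolean mask of usable timepoints.
    """
    if len(zones) != traces.n_timepoints:
        raise ValueError("zone labels and traces must share the neural clock")
    usable = np.ones(traces.n_timepoints, dtype=bool)
    split_name = "full"
    if isinstance(split, str):
        if split not in {"40/60"}:
            raise ValueError(f"unknown split spec {split!r}")
        usable, _ = categorization_split(traces.n_timepoints, traces.fs)
        split_name = split
    elif split is not None:
        usable = np.asarray(split, dtype=bool)
        split_name = "mask"

    masks = {arm: (zones.labels == arm) & usable for arm in ARMS}
    missing = [arm for arm, m in masks.items() if not m.any()]
    if missing:
        warnings.warn(f"arm(s) never visited: {missing}; all cells labeled neither")
    pooled_open = masks["open1"] | masks["open2"]
    pooled_closed = masks["closed1"] | masks["closed2"]

    rows = []
    for i, cid in enumerate(traces.cell_ids):
        x = traces.values[i]
        pvals = {}
        for arm in ARMS:
            other = pooled_closed if arm.startswith("open") else pooled_open
            if missing or not masks[arm].any() or not other.any():
                pvals[f"p_{arm}"] = np.nan
                continue
            pvals[f"p_{arm}"] = stats.mannwhitneyu(
                x[masks[arm]], x[other], alternative="greater"
            ).pvalue
        if missing:
            cat = "neither"
        elif pvals["p_open1"] < alpha and pvals["p_open2"] < alpha:
            cat = "open"
        elif pvals["p_closed1"] < alpha and pvals["p_closed2"] < alpha:
            cat = "closed"
        else:
            cat = "neither"
        rows.append({"cell_id": cid, "category": cat, **pvals})
    table = pd.DataFrame(rows).set_index("cell_id")
    return EnsembleLabels(table, split_name)


# ---------------------------------------------------------------------------
# scores


def open_arm_preference_score(activity: np.ndarray, open_mask: np.ndarray,
                              closed_mask: np.ndarray) -> tuple[float, float]:
    """(score, AUC) for one cell: score = 2*AUC - 1.

    AUC is the area under the ROC curve from predicting open-arm occupancy
    by thresholding cell activity at every observed value; with ties handled
    it equals the Mann-Whitney U statistic normalized by n+ * n-.
    """
    from sklearn.metrics import roc_auc_score

    if not open_mask.any() or not closed_mask.any():
        raise ValueError("preference score needs samples from both arm types")
    mask = open_mask | closed_mask
    labels = open_mask[mask].astype(int)
    auc = float(roc_auc_score(labels, activity[mask]))
    return 2.0 * auc - 1.0, auc


def epm_score(f_o1, f_o2, f_c1, f_c2):
    """EPM score (A - B)/(A + B) from the four per-arm mean activities.

    A is the mean absolute activity difference between arms of different
    types, B between arms of the same type.  1.0 means identical activity
    within each arm type but different across types; negative values mean
    the cell distinguishes same-type arms more than arm types.  The
    degenerate A = B = 0 case (all four means equal) is defined as 0.
    """
    f_o1, f_o2, f_c1, f_c2 = map(np.asarray, (f_o1, f_o2, f_c1, f_c2))
    A = 0.25 * (np.abs(f_c1 - f_o1) + np.abs(f_c1 - f_o2)
                + np.abs(f_c2 - f_o1) + np.abs(f_c2 - f_o2))
    B = 0.5 * (np.abs(f_c1 - f_c2) + np.abs(f_o1 - f_o2))
    denom = A + B
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (A - B) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ArmScores:
    """Per-cell arm preference and EPM scores with the intermediates."""

    table: pd.DataFrame  # index cell_id; preference_score, auc, epm_score, F_O1..F_C2

    @property
    def preference(self) -> pd.Series:
        return self.table["preference_score"]


def compute_arm_scores(traces: TraceMatrix, zones: ZoneLabels,
                       mask: np.ndarray | None = None) -> ArmScores:
    """Preference score, AUC, per-arm means and EPM score for every cell."""
    usable = np.ones(traces.n_timepoints, dtype=bool) if mask is None else np.asarray(mask, bool)
    arm_masks = {arm: (zones.labels == arm) & usable for arm in ARMS}
    open_mask = arm_masks["open1"] | arm_masks["open2"]
    closed_mask = arm_masks["closed1"] | arm_masks["closed2"]
    rows = []
    for i, cid in enumerate(traces.cell_ids):
        x = traces.values[i]
        score, auc = open_arm_preference_score(x, open_mask, closed_mask)
        means = {f"F_{arm[0].upper()}{arm[-1]}": float(x[m].mean()) if m.any() else np.nan
                 for arm, m in arm_masks.items()}
        rows.append({
            "cell_id": cid, "preference_score": score, "auc": auc,
            "epm_score": epm_score(means["F_O1"], means["F_O2"], means["F_C1"], means["F_C2"]),
            **means,
        })
    return ArmScores(pd.DataFrame(rows).set_index("cell_id"))


# ---------------------------------------------------------------------------
# peri-event analysis


@dataclass
class PeriEventResult:
    label: str
    time_s: np.ndarray  # window time axis relative to onset
    aligned: np.ndarray  # cells x window, mean over events
    delta: np.ndarray  # per-cell after-minus-before mean activity
    n_events: int
    ensemble_mean: np.ndarray | None = None
    ensemble_sem: np.ndarray | None = None


def _exclude_following(events: pd.DataFrame, others: pd.DataFrame, within_s: float) -> pd.DataFrame:
    """Drop events whose onset falls within ``within_s`` after any other-type
    event onset (slow indicator decay would confound them)."""
    if len(others) == 0:
        return events
    keep = []
    for _, row in events.iterrows():
        dt = row["onset_s"] - others["onset_s"]
        keep.append(not ((dt > 0) & (dt <= within_s)).any())
    return events[np.asarray(keep, bool)]


def peri_event_analysis(traces: TraceMatrix, intervals: BehaviorIntervals, label: str,
                        trace_window_s: tuple[float, float] = (-5.0, 5.0),
                        before_s: tuple[float, float] | None = None,
                        after_s: tuple[float, float] = (0.0, 2.5),
                        exclude_after: str | None = None,
                        exclude_within_s: float = 10.0) -> PeriEventResult:
    """Onset-aligned mean traces and delta dF/F for one behavior.

    delta dF/F is mean activity in ``after_s`` minus mean in ``before_s``
    ([0, 2.5] vs [-2.5, 0] by default; head dips use [-5, -2.5] before).
    Events too close to the session edges for the full window are dropped;
    with ``exclude_after`` set, events starting within 10 s after an event
    of that label are excluded too.
    """
    if before_s is None:
        before_s = (-5.0, -2.5) if label == "head_dip" else (-2.5, 0.0)
    events = intervals.of(label)
    if exclude_after is not None:
        events = _exclude_following(events, intervals.of(exclude_after), exclude_within_s)
    fs = traces.fs
    lo = int(round(trace_window_s[0] * fs))
    hi = int(round(trace_window_s[1] * fs))
    b0, b1 = (int(round(s * fs)) for s in before_s)
    a0, a1 = (int(round(s * fs)) for s in after_s)
    need_lo = min(lo, b0)
    need_hi = max(hi, a1)

    snippets, deltas = [], []
    for _, row in events.iterrows():
        onset = int(round(row["onset_s"] * fs))
        if onset + need_lo < 0 or onset + need_hi > traces.n_timepoints:
            continue
        snippets.append(traces.values[:, onset + lo: onset + hi])
        before = traces.values[:, onset + b0: onset + b1].mean(axis=1)
        after = traces.values[:, onset + a0: onset + a1].mean(axis=1)
        deltas.append(after - before)
    if not snippets:
        raise ValueError(f"no usable {label!r} events for peri-event analysis")
    aligned = np.mean(snippets, axis=0)
    delta = np.mean(deltas, axis=0)
    time_s = np.arange(lo, hi) / fs
    res = PeriEventResult(label, time_s, aligned, delta, len(snippets))
    res.ensemble_mean = aligned.mean(axis=0)
    res.ensemble_sem = aligned.std(axis=0, ddof=1) / np.sqrt(max(aligned.shape[0], 1)) \
        if aligned.shape[0] > 1 else np.zeros_like(res.ensemble_mean)
    return res


# ---------------------------------------------------------------------------
# correlations and maps


def activity_correlations(traces: TraceMatrix, zones: ZoneLabels | None = None,
                          speed: np.ndarray | None = None,
                          location_index: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell Pearson correlations with speed and location index, plus the
    across-cell correlations of per-arm mean activity (open1 vs open2, open
    vs closed).  Zero-variance regressors yield NaN."""
    rows = {}
    def _corr(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(stats.pearsonr(x, y)[0])

    per_cell = pd.DataFrame(index=pd.Index(traces.cell_ids, name="cell_id"))
    if speed is not None:
        per_cell["r_speed"] = [_corr(traces.values[i], speed) for i in range(traces.n_cells)]
    if location_index is not None:
        per_cell["r_location_index"] = [
            _corr(traces.values[i], location_index) for i in range(traces.n_cells)
        ]
    if zones is not None:
        means = {arm: traces.values[:, zones.labels == arm].mean(axis=1)
                 if (zones.labels == arm).any() else np.full(traces.n_cells, np.nan)
                 for arm in ARMS}
        per_cell.attrs["r_open1_open2"] = _corr(means["open1"], means["open2"])
        open_mean = np.nanmean([means["open1"], means["open2"]], axis=0)
        closed_mean = np.nanmean([means["closed1"], means["closed2"]], axis=0)
        per_cell.attrs["r_open_closed"] = _corr(open_mean, closed_mean)
        for arm, m in means.items():
            per_cell[f"mean_{arm}"] = m
    return per_cell


def spatial_activity_map(traces: TraceMatrix, xy: np.ndarray, bin_cm: float = 4.0,
                         min_occupancy: int = 3,
                         extent: tuple[float, float, float, float] | None = None):
    """Occupancy-normalized spatial activity maps.

    Returns (maps, x_edges, y_edges) where ``maps`` is a masked array of
    shape (n_cells, nx, ny) holding the mean z-scored activity per spatial
    bin; bins visited fewer than ``min_occupancy`` samples are masked.
    """
    from scipy.stats import binned_statistic_2d

    if extent is None:
        extent = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())
    x_edges = np.arange(extent[0], extent[1] + bin_cm, bin_cm)
    y_edges = np.arange(extent[2], extent[3] + bin_cm, bin_cm)
    occupancy, _, _, _ = binned_statistic_2d(
        xy[:, 0], xy[:, 1], None, statistic="count", bins=[x_edges, y_edges])
    maps = []
    for i in range(traces.n_cells):
        m, _, _, _ = binned_statistic_2d(
            xy[:, 0], xy[:, 1], traces.values[i], statistic="mean", bins=[x_edges, y_edges])
        maps.append(m)
    maps = np.ma.masked_invalid(np.stack(maps))
    maps = np.ma.masked_where(np.broadcast_to(occupancy < min_occupancy, maps.shape), maps)
    return maps, x_edges, y_edges
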