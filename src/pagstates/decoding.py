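"""Decoding mouse position from population activity.

Train/test data are interleaved in time — alternating 60 s blocks with 10 s
excluded gaps between them — so that slow calcium dynamics cannot leak
across the split.  Arm type (open vs closed) is decoded with a linear
maximum-margin classifier (balanced class weights) and scored with the
Matthews correlation coefficient on test timepoints, against a null of 100
refits with shuffled training labels.  The continuous EPM location index is
predicted by ordinary least squares with outputs clipped to [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import ZoneLabels
from .core import TraceMatrix

__all__ = [
    "InterleavedSplit",
    "make_interleaved_split",
    "matthews_corrcoef",
    "ArmDecoder",
    "ArmDecoderResults",
    "LocationIndexModel",
    "LocationIndexResults",
]

TRAIN_BLOCK_S = 60.0
GAP_S = 10.0


@dataclass
class InterleavedSplit:
    """Per-timepoint role assignment: train (0), excluded gap (-1), test (1)."""

    roles: np.ndarray  # int8 per timepoint
    fs: float

    @property
    def train(self) -> np.ndarray:
        return self.roles == 0

    @property
    def test(self) -> np.ndarray:
        return self.roles == 1

    @property
    def excluded(self) -> np.ndarray:
        return self.roles == -1


def make_interleaved_split(n_timepoints: int, fs: float,
                           block_s: float = TRAIN_BLOCK_S,
                           gap_s: float = GAP_S) -> InterleavedSplit:
    """[60 s train, 10 s gap, 60 s test, 10 s gap, 60 s train, ...].

    The pattern starts with a training block; a trailing partial block keeps
    the role the pattern assigns it.  Sessions shorter than one training
    block plus one gap cannot be split.
    """
    if n_timepoints / fs < block_s + gap_s:
        raise ValueError(f"session shorter than {block_s + gap_s:.0f} s cannot be "
                         "interleaved into train/test blocks")
    block = int(round(block_s * fs))
    gap = int(round(gap_s * fs))
    pattern = np.concatenate([
        np.zeros(block, dtype=np.int8),
        np.full(gap, -1, dtype=np.int8),
        np.ones(block, dtype=np.int8),
        np.full(gap, -1, dtype=np.int8),
    ])
    reps = int(np.ceil(n_timepoints / len(pattern)))
    roles = np.tile(pattern, reps)[:n_timepoints]
    return InterleavedSplit(roles, fs)


def matthews_corrcoef(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC from the 2x2 confusion matrix; 0 when a denominator vanishes."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = np.sum(y_true & y_pred)
    tn = np.sum(~y_true & ~y_pred)
    fp = np.sum(~y_true & y_pred)
    fn = np.sum(y_true & ~y_pred)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


# ---------------------------------------------------------------------------
# arm-type decoding


class ArmDecoder:
    """Linear SVM decoding open vs closed arm occupancy from traces.

    Parameters
    ----------
    traces : TraceMatrix
        z-scored activity on the neural clock.
    zones : ZoneLabels
        Per-timepoint arm labels on the same clock; center frames are
        excluded from both train and test (they carry no arm label).
    split : InterleavedSplit, optional
        Defaults to the standard 60 s / 10 s interleave.
    C : float
        SVM regularization strength.
    """

    def __init__(self, traces: TraceMatrix, zones: ZoneLabels,
                 split: InterleavedSplit | None = None, C: float = 1.0):
        if len(zones) != traces.n_timepoints:
            raise ValueError("zones and traces must share the neural clock")
        self.traces = traces
        self.zones = zones
        self.split = split or make_interleaved_split(traces.n_timepoints, traces.fs)
        self.C = C
        self._X = traces.values.T  # timepoints x cells
        self._y = zones.is_open  # True = open
        self._labeled = zones.is_open | zones.is_closed

    def _fit_svm(self, train_mask: np.ndarray, y_train: np.ndarray):
        from sklearn.svm import SVC

        clf = SVC(kernel="linear", C=self.C, class_weight="balanced")
        clf.fit(self._X[train_mask], y_train)
        return clf

    def fit(self, n_permutations: int = 100, seed: int = 0) -> "ArmDecoderResults":
        train = self.split.train & self._labeled
        test = self.split.test & self._labeled
        for name, mask in (("train", train), ("test", test)):
            if np.unique(self._y[mask]).size < 2:
                raise ValueError(f"{name} set contains a single arm-type class")
        clf = self._fit_svm(train, self._y[train])
        decision = np.full(self.traces.n_timepoints, np.nan)
        decision[self._labeled] = clf.decision_function(self._X[self._labeled])
        pred_test = clf.predict(self._X[test])
        mcc = matthews_corrcoef(self._y[test], pred_test)

        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        y_train = self._y[train]
        for i in range(n_permutations):
            shuffled = rng.permutation(y_train)
            if np.unique(shuffled).size < 2:  # cannot happen unless degenerate
                null[i] = 0.0
                continue
            clf_i = self._fit_svm(train, shuffled)
            null[i] = matthews_corrcoef(self._y[test], clf_i.predict(self._X[test]))
        p = (1 + np.sum(null >= mcc)) / (1 + n_permutations)
        return ArmDecoderResults(self, mcc, float(p), null, decision, clf)


@dataclass
class ArmDecoderResults:
    model: ArmDecoder
    mcc: float
    p_perm: float
    null_mcc: np.ndarray
    decision_values: np.ndarray  # per timepoint, NaN in center frames
    classifier: object

    def summary(self) -> str:
        lines = [
            "Arm-type decoding (linear SVM, balanced class weights)",
            f"  cells: {self.model.traces.n_cells}   "
            f"test timepoints: {int((self.model.split.test & self.model._labeled).sum())}",
            f"  test MCC: {self.mcc:.3f}",
            f"  permutation p ({len(self.null_mcc)} shuffles): {self.p_perm:.4f}",
            f"  null MCC mean +/- sd: {self.null_mcc.mean():.3f} +/- {self.null_mcc.std():.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# location-index regression


class LocationIndexModel:
    """Linear prediction of the continuous EPM location index.

    Ordinary least squares on interleaved training timepoints; predictions
    are clipped to [-1, 1]; reported as the Pearson r between prediction and
    truth on test timepoints.
    """

    def __init__(self, traces: TraceMatrix, index: np.ndarray,
                 split: InterleavedSplit | None = None):
        index = np.asarray(index, dtype=float)
        if index.shape[0] != traces.n_timepoints:
            raise ValueError("index series and traces must share the neural clock")
        self.traces = traces
        self.index = index
        self.split = split or make_interleaved_split(traces.n_timepoints, traces.fs)

    def fit(self, ridge_eps: float = 1e-8) -> "LocationIndexResults":
        X = self.traces.values.T
        design = np.column_stack([X, np.ones(len(X))])
        train, test = self.split.train, self.split.test
        A, y = design[train], self.index[train]
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            warnings.warn("rank-deficient design; falling back to ridge regression")
            AtA = A.T @ A + ridge_eps * np.trace(A.T @ A) / A.shape[1] * np.eye(A.shape[1])
            beta = np.linalg.solve(AtA, A.T @ y)
        else:
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
        pred = np.clip(design @ beta, -1.0, 1.0)
        r_train = _pearson(pred[train], self.index[train])
        r_test = _pearson(pred[test], self.index[test])
        return LocationIndexResults(self, beta, pred, r_train, r_test)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class LocationIndexResults:
    model: LocationIndexModel
    params: np.ndarray  # cell weights + intercept
    predicted: np.ndarray  # clipped, full session
    r_train: float
    r_test: float

    def summary(self) -> str:
        return "\n".join([
            "EPM location-index prediction (OLS, outputs clipped to [-1, 1])",
            f"  cells: {self.model.traces.n_cells}",
            f"  train r: {self.r_train:.3f}   test r: {self.r_test:.3f}",
        ])
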