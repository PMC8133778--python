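"""Per-cell encoding model: behaviors -> calcium activity.

Each cell's z-scored activity is modeled as a linear combination of
behavioral channels convolved with a log-time raised-cosine basis,

    f_j(x) = 1/2 [cos(pi * x - phi_j) + 1]   on  phi_j/pi - 1 < x <= phi_j/pi + 1,
    x      = log(t + b + eps),
    phi_j  = log(b + eps) + (j - 1) * pi / 2,

so early lags are sampled densely and late lags coarsely, which suits the
slow calcium indicator.  Binary behavior channels use mirrored (acausal)
copies of the basis covering 5 s before onset to 5 s after offset; kinematic
channels use the causal half only (responses within 5 s after onset).  The
weights minimize mean-square reconstruction error (Gaussian-identity GLM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BehaviorIntervals, TraceMatrix
from .decoding import InterleavedSplit

__all__ = [
    "BasisConfig",
    "raised_cosine_basis",
    "DesignMatrix",
    "build_design_matrix",
    "EncodingGLM",
    "EncodingGLMResults",
]


@dataclass(frozen=True)
class BasisConfig:
    """Raised-cosine basis parameters.

    ``n_bases`` bumps are spaced pi/2 apart in the log-time phase, so with
    the defaults (J=5, b=0.25 s) the peaks fall near 0.4, 0.8, 1.5, 2.7 and
    4.5 s; the kernels are truncated at the 5 s window.
    """

    n_bases: int = 5
    b: float = 0.25  # s, log-time warp offset
    eps: float = 1e-3  # s
    pre_window_s: float = 5.0
    post_window_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_bases < 1:
            raise ValueError("need at least one basis function")
        if self.b + self.eps <= 0:
            raise ValueError("b + eps must be positive")
        if self.pre_window_s <= 0 or self.post_window_s <= 0:
            raise ValueError("windows must be positive")

    def phi(self, j: int) -> float:
        """Phase offset of basis j (1-based)."""
        return float(np.log(self.b + self.eps) + 0.5 * (j - 1) * np.pi)


def raised_cosine_basis(config: BasisConfig, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the J basis kernels on a non-negative time grid.

    Returns an array of shape (len(t_grid), J); each column is f_j(x(t)),
    zero outside its support, peaking at exactly 1 where x = phi_j / pi.
    Raises when a requested basis has no support inside the grid.
    """
    t = np.asarray(t_grid, dtype=float)
    if (t < 0).any():
        raise ValueError("t_grid must be non-negative")
    x = np.log(t + config.b + config.eps)
    cols = []
    for j in range(1, config.n_bases + 1):
        phi = config.phi(j)
        center = phi / np.pi
        # analytic support in t: (exp(center-1) - b - eps, exp(center+1) - b - eps]
        t_lo = np.exp(center - 1.0) - config.b - config.eps
        if t_lo > config.post_window_s:
            raise ValueError(f"basis {j} has no support within the {config.post_window_s} s "
                             "window; reduce n_bases or widen the window")
        inside = (x > center - 1.0) & (x <= center + 1.0)
        f = np.zeros_like(x)
        f[inside] = 0.5 * (np.cos(np.pi * x[inside] - phi) + 1.0)
        cols.append(f)
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Convolved predictor matrix with a trailing intercept column."""

    matrix: np.ndarray  # timepoints x (n_channels * J + 1)
    columns: list[tuple[str, int]]  # (channel, basis index); intercept = ("intercept", 0)
    fs: float
    config: BasisConfig

    @property
    def n_predictors(self) -> int:
        return self.matrix.shape[1] - 1

    def channel_columns(self, channel: str) -> list[int]:
        return [i for i, (c, _) in enumerate(self.columns) if c == channel]

    @property
    def channels(self) -> list[str]:
        seen = dict.fromkeys(c for c, _ in self.columns if c != "intercept")
        return list(seen)


def _convolve_with_kernels(series: np.ndarray, kernels: np.ndarray, n_pre: int) -> np.ndarray:
    """y_j[t] = sum_tau K_j(tau) series[t - tau], tau in [-n_pre, n_post]."""
    n = len(series)
    out = np.empty((n, kernels.shape[1]))
    for j in range(kernels.shape[1]):
        full = np.convolve(series, kernels[:, j])
        out[:, j] = full[n_pre: n_pre + n]
    return out


def build_design_matrix(behaviors: BehaviorIntervals | None,
                        kinematics: dict[str, np.ndarray] | None,
                        n_timepoints: int, fs: float,
                        config: BasisConfig | None = None,
                        behavior_labels: list[str] | None = None,
                        zscore_kinematics: bool = True) -> DesignMatrix:
    """Assemble the convolved design matrix on the neural clock.

    ``behaviors`` supplies binary channels (one per label); ``kinematics``
    supplies continuous channels.  Binary channels are convolved with the
    mirrored two-sided basis; kinematic channels with the causal half only.
    """
    config = config or BasisConfig()
    n_post = int(round(config.post_window_s * fs))
    n_pre = int(round(config.pre_window_s * fs))
    t_post = np.arange(n_post + 1) / fs
    causal = raised_cosine_basis(config, t_post)
    # two-sided kernel: mirrored copy on negative lags, causal copy on positive
    two_sided = np.vstack([causal[1: n_pre + 1][::-1], causal])

    cols, names = [], []
    if behaviors is not None:
        labels = behavior_labels if behavior_labels is not None else sorted(behaviors.labels())
        for label in labels:
            ind = behaviors.mask(label, n_timepoints, fs).astype(float)
            if not ind.any():
                warnings.warn(f"behavior channel {label!r} has no events; columns will be zero")
            conv = _convolve_with_kernels(ind, two_sided, n_pre)
            cols.append(conv)
            names += [(label, j) for j in range(1, config.n_bases + 1)]
    if kinematics is not None:
        for name, series in kinematics.items():
            series = np.asarray(series, dtype=float)
            if len(series) != n_timepoints:
                raise ValueError(f"kinematic channel {name!r} has wrong length")
            if zscore_kinematics:
                sd = series.std()
                if sd == 0:
                    warnings.warn(f"kinematic channel {name!r} is constant; left as zeros")
                    series = np.zeros_like(series)
                else:
                    series = (series - series.mean()) / sd
            conv = _convolve_with_kernels(series, causal, 0)
            cols.append(conv)
            names += [(name, j) for j in range(1, config.n_bases + 1)]
    if not cols:
        raise ValueError("design matrix needs at least one channel")
    matrix = np.column_stack(cols + [np.ones(n_timepoints)])
    names.append(("intercept", 0))
    return DesignMatrix(matrix, names, fs, config)


# ---------------------------------------------------------------------------
# fitting


class EncodingGLM:
    """Least-squares encoding model for every cell at once.

    Parameters
    ----------
    traces : TraceMatrix
        z-scored activity, neural clock.
    design : DesignMatrix
        Output of :func:`build_design_matrix` on the same clock.
    split : InterleavedSplit, optional
        When given, weights are fit on training rows and R^2 is also
        reported on test rows.
    """

    def __init__(self, traces: TraceMatrix, design: DesignMatrix,
                 split: InterleavedSplit | None = None):
        if design.matrix.shape[0] != traces.n_timepoints:
            raise ValueError("design and traces must share the neural clock")
        self.traces = traces
        self.design = design
        self.split = split

    def fit(self, ridge_scale: float = 1e-6) -> "EncodingGLMResults":
        A_full = self.design.matrix
        Y_full = self.traces.values.T
        train = self.split.train if self.split is not None else np.ones(len(A_full), bool)
        A, Y = A_full[train], Y_full[train]
        m = A.shape[1]
        rank = np.linalg.matrix_rank(A)
        if A.shape[0] <= m or rank < m:
            warnings.warn("singular or underdetermined design; using ridge fallback")
            AtA = A.T @ A
            beta = np.linalg.solve(AtA + ridge_scale * np.trace(AtA) / m * np.eye(m), A.T @ Y)
        else:
            beta = np.linalg.lstsq(A, Y, rcond=None)[0]
        pred = A_full @ beta

        def _r2(mask):
            resid = Y_full[mask] - pred[mask]
            ss_res = (resid**2).sum(axis=0)
            centered = Y_full[mask] - Y_full[mask].mean(axis=0)
            ss_tot = (centered**2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(ss_tot > 0, 1 - ss_res / np.where(ss_tot > 0, ss_tot, 1), np.nan)

        r2_train = _r2(train)
        r2_test = _r2(self.split.test) if self.split is not None else None
        return EncodingGLMResults(self, beta, pred, r2_train, r2_test)


@dataclass
class EncodingGLMResults:
    model: EncodingGLM
    params: np.ndarray  # (n_predictors + 1) x n_cells; last row = intercept
    fitted: np.ndarray  # timepoints x n_cells
    r2_train: np.ndarray
    r2_test: np.ndarray | None

    @property
    def intercepts(self) -> np.ndarray:
        return self.params[-1]

    def params_table(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.model.design.columns,
                                        names=["channel", "basis"])
        return pd.DataFrame(self.params, index=idx, columns=self.model.traces.cell_ids)

    def channel_weights(self) -> pd.DataFrame:
        """Per-behavior summary weight: mean of the channel's J basis
        coefficients, per cell."""
        table = self.params_table()
        rows = {ch: table.loc[ch].mean(axis=0) for ch in self.model.design.channels}
        return pd.DataFrame(rows)

    def ensemble_channel_weights(self, categories: pd.Series) -> pd.DataFrame:
        """Mean summary weight per channel within each cell category."""
        w = self.channel_weights()
        w["category"] = categories.reindex(w.index)
        return w.groupby("category").mean()

    def summary(self) -> str:
        w = self.channel_weights()
        lines = ["Encoding GLM (least squares, raised-cosine basis)",
                 f"  cells: {self.model.traces.n_cells}   "
                 f"predictors: {self.model.design.n_predictors}",
                 f"  mean train R^2: {np.nanmean(self.r2_train):.3f}"]
        if self.r2_test is not None:
            lines.append(f"  mean test R^2: {np.nanmean(self.r2_test):.3f}")
        lines.append("  mean |summary weight| per channel:")
        for ch in w.columns:
            lines.append(f"    {ch:<20s} {np.abs(w[ch]).mean():.4f}")
        return "\n".join(lines)
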