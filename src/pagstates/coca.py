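"""Constrained Correlation Analysis (CoCA).

Finds a single shared neural projection per mouse (weights over that
mouse's co-registered cells, identical across assays) and a single
behavioral projection per assay (weights over that assay's behavioral
variables, identical across mice) maximizing the summed Pearson
correlations

    max  sum_i sum_j  corr( n_i' X_{i,j} ,  b_j' Y_{i,j} )

over training timepoints.  The constraint structure — neural weights tied
across assays, behavioral weights tied across mice — is what distinguishes
this from per-session canonical correlation: a high test correlation means
the *same* cell weighting tracks threat-related behavior in both assays.

Optimization is plain gradient ascent with Adam on the analytic gradient of
the summed correlations; correlations are scale-invariant so the weights
are reported unit-norm.  Significance is assessed on test timepoints
against correlations of 1000 random unit-norm neural projections with the
fitted behavioral projection (one-tailed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "normalize_behavior_matrix",
    "CoCAEntry",
    "CoCADataset",
    "CoCA",
    "CoCAResults",
]

EPM_MINMAX_CHANNELS = ("abs_x", "abs_y")


def normalize_behavior_matrix(channels: dict[str, np.ndarray], assay: str,
                              minmax_channels: tuple[str, ...] = EPM_MINMAX_CHANNELS
                              ) -> tuple[np.ndarray, list[str]]:
    """Stack behavioral channels into a p x T matrix, normalized.

    Every channel is z-scored to zero mean and unit variance, except the
    EPM's normalized |x| and |y| positions which are min-max scaled to
    [0, 1].  A constant channel cannot be normalized and raises, naming the
    channel.
    """
    names = list(channels)
    rows = []
    for name in names:
        v = np.asarray(channels[name], dtype=float)
        if str(assay).upper() == "EPM" and name in minmax_channels:
            span = v.max() - v.min()
            if span == 0:
                raise ValueError(f"behavioral channel {name!r} is constant")
            rows.append((v - v.min()) / span)
        else:
            sd = v.std()
            if sd == 0:
                raise ValueError(f"behavioral channel {name!r} is constant")
            rows.append((v - v.mean()) / sd)
    return np.vstack(rows), names


@dataclass
class CoCAEntry:
    """One (mouse, assay) session: neural k x T, behavioral p x T, masks."""

    mouse: str
    assay: str
    X: np.ndarray
    Y: np.ndarray
    train: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[1] != self.Y.shape[1]:
            raise ValueError("neural and behavioral data must share timepoints")
        self.train = np.asarray(self.train, dtype=bool)
        self.test = np.asarray(self.test, dtype=bool)
        if len(self.train) != self.X.shape[1]:
            raise ValueError("mask length mismatch")
        if not self.train.any():
            raise ValueError("empty training mask")


class CoCADataset:
    """Collection of CoCAEntry objects with consistency checks."""

    def __init__(self, entries: list[CoCAEntry]):
        if not entries:
            raise ValueError("CoCA needs at least one session")
        self.entries = entries
        self.mice = list(dict.fromkeys(e.mouse for e in entries))
        self.assays = list(dict.fromkeys(e.assay for e in entries))
        for mouse in self.mice:
            ks = {e.X.shape[0] for e in entries if e.mouse == mouse}
            if len(ks) > 1:
                raise ValueError(f"mouse {mouse!r} has differing cell counts across assays")
        for assay in self.assays:
            ps = {e.Y.shape[0] for e in entries if e.assay == assay}
            if len(ps) > 1:
                raise ValueError(f"assay {assay!r} has differing variable counts across mice")

    def __iter__(self):
        return iter(self.entries)


def _center(M: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sub = M[:, mask]
    return sub - sub.mean(axis=1, keepdims=True)


def _proj_corr(w: np.ndarray, M: np.ndarray, v: np.ndarray, eps: float = 1e-12) -> float:
    u = M.T @ w
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < eps or nv < eps:
        return 0.0
    return float(u @ v / (nu * nv))


class CoCA:
    """Fit the shared neural / behavioral projections on a CoCADataset."""

    def __init__(self, dataset: CoCADataset):
        self.dataset = dataset
        # train-centered views used by both objective and gradient
        self._Xc = {id(e): _center(e.X, e.train) for e in dataset}
        self._Yc = {id(e): _center(e.Y, e.train) for e in dataset}

    # -- objective and gradient -------------------------------------------
    def _objective_and_grads(self, n_w: dict, b_w: dict):
        obj = 0.0
        g_n = {m: np.zeros_like(v) for m, v in n_w.items()}
        g_b = {a: np.zeros_like(v) for a, v in b_w.items()}
        eps = 1e-12
        for e in self.dataset:
            Xc, Yc = self._Xc[id(e)], self._Yc[id(e)]
            n, b = n_w[e.mouse], b_w[e.assay]
            u, v = Xc.T @ n, Yc.T @ b
            nu = np.linalg.norm(u) + eps
            nv = np.linalg.norm(v) + eps
            r = float(u @ v / (nu * nv))
            obj += r
            g_n[e.mouse] += Xc @ (v / (nu * nv) - r * u / nu**2)
            g_b[e.assay] += Yc @ (u / (nu * nv) - r * v / nv**2)
        return obj, g_n, g_b

    def fit(self, lr: float = 0.01, beta1: float = 0.9, beta2: float = 0.999,
            max_iter: int = 10000, tol: float = 1e-7, patience: int = 50,
            restarts: int = 5, seed: int = 0) -> "CoCAResults":
        """Adam ascent from ``restarts`` seeded random initializations; the
        run with the best training objective is kept.  Convergence: relative
        objective change below ``tol`` over ``patience`` iterations."""
        best = None
        for r in range(restarts):
            rng = np.random.default_rng([seed, r])
            n_w = {m: rng.standard_normal(self._k(m)) for m in self.dataset.mice}
            b_w = {a: rng.standard_normal(self._p(a)) for a in self.dataset.assays}
            n_w, b_w, trace = self._adam(n_w, b_w, lr, beta1, beta2, max_iter, tol, patience)
            if best is None or trace[-1] > best[2][-1]:
                best = (n_w, b_w, trace)
        n_w, b_w, trace = best
        self._fix_signs(n_w, b_w)
        for m in n_w:
            n_w[m] = n_w[m] / (np.linalg.norm(n_w[m]) + 1e-12)
        for a in b_w:
            b_w[a] = b_w[a] / (np.linalg.norm(b_w[a]) + 1e-12)
        return CoCAResults(self, n_w, b_w, np.asarray(trace))

    def _adam(self, n_w, b_w, lr, beta1, beta2, max_iter, tol, patience):
        m_n = {k: np.zeros_like(v) for k, v in n_w.items()}
        v_n = {k: np.zeros_like(v) for k, v in n_w.items()}
        m_b = {k: np.zeros_like(v) for k, v in b_w.items()}
        v_b = {k: np.zeros_like(v) for k, v in b_w.items()}
        trace = []
        eps = 1e-8
        for t in range(1, max_iter + 1):
            obj, g_n, g_b = self._objective_and_grads(n_w, b_w)
            if not np.isfinite(obj):
                raise FloatingPointError(
                    f"CoCA objective diverged at iteration {t}; last finite value "
                    f"{trace[-1] if trace else float('nan')}")
            trace.append(obj)
            if len(trace) > patience:
                prev = trace[-patience - 1]
                if abs(trace[-1] - prev) < tol * max(abs(prev), 1.0):
                    break
            bc1, bc2 = 1 - beta1**t, 1 - beta2**t
            for store, grads, m_s, v_s in ((n_w, g_n, m_n, v_n), (b_w, g_b, m_b, v_b)):
                for key, g in grads.items():
                    m_s[key] = beta1 * m_s[key] + (1 - beta1) * g
                    v_s[key] = beta2 * v_s[key] + (1 - beta2) * g**2
                    store[key] = store[key] + lr * (m_s[key] / bc1) / (np.sqrt(v_s[key] / bc2) + eps)
        return n_w, b_w, trace

    def _fix_signs(self, n_w, b_w) -> None:
        """Resolve sign indeterminacy: flip weight vectors so that per-mouse
        and per-assay summed training correlations are non-negative."""
        for _ in range(2):
            for m in self.dataset.mice:
                s = sum(self._train_corr(e, n_w, b_w) for e in self.dataset if e.mouse == m)
                if s < 0:
                    n_w[m] = -n_w[m]
            for a in self.dataset.assays:
                s = sum(self._train_corr(e, n_w, b_w) for e in self.dataset if e.assay == a)
                if s < 0:
                    b_w[a] = -b_w[a]

    def _train_corr(self, e: CoCAEntry, n_w, b_w) -> float:
        return _proj_corr(n_w[e.mouse], self._Xc[id(e)], self._Yc[id(e)].T @ b_w[e.assay])

    def _k(self, mouse: str) -> int:
        return next(e.X.shape[0] for e in self.dataset if e.mouse == mouse)

    def _p(self, assay: str) -> int:
        return next(e.Y.shape[0] for e in self.dataset if e.assay == assay)


@dataclass
class CoCAResults:
    model: CoCA
    neural_weights: dict[str, np.ndarray]  # per mouse, unit norm
    behavioral_weights: dict[str, np.ndarray]  # per assay, unit norm
    objective_trace: np.ndarray

    def _corr(self, entry: CoCAEntry, mask: np.ndarray) -> float:
        Xc = _center(entry.X, mask)
        Yc = _center(entry.Y, mask)
        return _proj_corr(self.neural_weights[entry.mouse], Xc,
                          Yc.T @ self.behavioral_weights[entry.assay])

    def correlations(self) -> dict[tuple[str, str], dict[str, float]]:
        out = {}
        for e in self.model.dataset:
            out[(e.mouse, e.assay)] = {
                "train": self._corr(e, e.train),
                "test": self._corr(e, e.test) if e.test.any() else np.nan,
            }
        return out

    def significance(self, n_trials: int = 1000, seed: int = 0
                     ) -> dict[tuple[str, str], dict[str, float]]:
        """One-tailed empirical p per session: the test-set correlation of the
        fitted projections against a null of ``n_trials`` random unit-norm
        neural projections correlated with the fitted behavioral projection."""
        rng = np.random.default_rng(seed)
        out = {}
        for e in self.model.dataset:
            if not e.test.any():
                raise ValueError("significance testing needs a test mask")
            Xc = _center(e.X, e.test)
            v = _center(e.Y, e.test).T @ self.behavioral_weights[e.assay]
            obs = _proj_corr(self.neural_weights[e.mouse], Xc, v)
            null = np.empty(n_trials)
            for t in range(n_trials):
                w = rng.standard_normal(e.X.shape[0])
                w /= np.linalg.norm(w) + 1e-12
                null[t] = _proj_corr(w, Xc, v)
            p = (1 + np.sum(null >= obs)) / (1 + n_trials)
            out[(e.mouse, e.assay)] = {"r_test": obs, "p": float(p),
                                       "null_mean": float(null.mean()),
                                       "null_sd": float(null.std())}
        return out

    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def summary(self) -> str:
        lines = ["Constrained Correlation Analysis",
                 f"  mice: {len(self.neural_weights)}   assays: {list(self.behavioral_weights)}",
                 f"  iterations: {len(self.objective_trace)}   "
                 f"final objective: {self.objective():.4f}"]
        for (mouse, assay), c in self.correlations().items():
            lines.append(f"  {mouse}/{assay}: train r = {c['train']:.3f}, "
                         f"test r = {c['test']:.3f}")
        return "\n".join(lines)
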