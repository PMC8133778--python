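"""Unsupervised approach/avoidance state discovery.

Population vectors (timepoints as samples, cells as dimensions) are
clustered with k-means; the number of clusters is selected by an AIC that
treats clusters as identity-covariance Gaussians,

    AIC(K) = RSS_min(K) + 2 M K,

with M the dimensionality (number of cells) and RSS the within-cluster sum
of squared distances of the best of 10 seeded initializations.  Clusters
are then labeled post hoc: the cluster with the lowest mean
avoidance/approach score is the avoidance cluster, the highest the approach
cluster, and the labeling is tested against a null of 100 score-label
permutations.  Centroids trained in one assay can be transferred to the
co-registered cells of the other assay by nearest-centroid assignment.  A
Gaussian-emission HMM (4 states, on the top principal components carrying
at least 60% of the variance) provides a sequence-aware alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CoregistrationMap, TraceMatrix

__all__ = [
    "aic_kmeans",
    "StateKMeans",
    "ClusterModelResults",
    "StateNull",
    "TransferResult",
    "transfer_clusters",
    "StateHMM",
    "HMMStateResults",
]


def aic_kmeans(rss: float, m: int, k: int) -> float:
    """AIC for k-means under identity-covariance Gaussian clusters."""
    return float(rss) + 2.0 * m * k


class StateKMeans:
    """k-means state model with AIC model selection.

    Parameters
    ----------
    traces : TraceMatrix
        z-scored activity; timepoints are the samples to cluster.
    k_range : iterable of int
        Candidate cluster counts (default 1-10).
    n_init : int
        Randomized initializations per K; the best by within-cluster sum of
        squared distances is kept.
    """

    def __init__(self, traces: TraceMatrix, k_range=range(1, 11), n_init: int = 10):
        self.traces = traces
        self.k_range = list(k_range)
        self.n_init = n_init
        if max(self.k_range) > traces.n_timepoints:
            raise ValueError("more clusters requested than timepoints")

    def fit(self, seed: int = 0, force_k: int | None = None) -> "ClusterModelResults":
        """Fit every candidate K and select the AIC minimizer (or ``force_k``)."""
        from sklearn.cluster import KMeans

        X = self.traces.values.T  # timepoints x cells
        m = self.traces.n_cells
        aic_table = {}
        fits = {}
        for k in self.k_range:
            km = KMeans(n_clusters=k, n_init=self.n_init, random_state=seed)
            labels = km.fit_predict(X)
            aic_table[k] = aic_kmeans(km.inertia_, m, k)
            fits[k] = (km.cluster_centers_, labels, km.inertia_)
        chosen = force_k if force_k is not None else min(aic_table, key=aic_table.get)
        if chosen not in fits:
            raise ValueError(f"force_k={chosen} outside the fitted range")
        centroids, labels, rss = fits[chosen]
        return ClusterModelResults(self, chosen, centroids, labels, rss, aic_table)


@dataclass
class ClusterModelResults:
    model: StateKMeans
    k: int
    centroids: np.ndarray  # K x n_cells
    assignments: np.ndarray  # per timepoint
    rss: float
    aic_table: dict[int, float]
    avoidance_cluster: int | None = None
    approach_cluster: int | None = None
    cluster_scores: np.ndarray | None = None

    def label_states(self, score_series: np.ndarray) -> "ClusterModelResults":
        """Label clusters by their mean avoidance/approach score: minimum =
        avoidance, maximum = approach; ties break to the lower index."""
        score_series = np.asarray(score_series, dtype=float)
        if len(score_series) != len(self.assignments):
            raise ValueError("score series must be on the neural clock")
        means = np.array([score_series[self.assignments == c].mean()
                          if (self.assignments == c).any() else np.nan
                          for c in range(self.k)])
        if np.isnan(means).any():
            raise ValueError("empty cluster; re-fit with a different seed or K")
        self.cluster_scores = means
        self.avoidance_cluster = int(np.nanargmin(means))
        self.approach_cluster = int(np.nanargmax(means))
        if self.k > 1 and self.avoidance_cluster == self.approach_cluster:
            warnings.warn("tied cluster scores; avoidance/approach broke ties by index")
            self.approach_cluster = int(np.nanargmax(means[::-1]))
        return self

    def permutation_null(self, score_series: np.ndarray, n_perm: int = 100,
                         seed: int = 0) -> "StateNull":
        """Null distribution of extreme cluster score means under random
        permutation of the score labels over timepoints."""
        if n_perm < 20:
            warnings.warn("fewer than 20 permutations gives unstable percentiles")
        score_series = np.asarray(score_series, dtype=float)
        rng = np.random.default_rng(seed)
        null_min = np.empty(n_perm)
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(score_series)
            means = np.array([perm[self.assignments == c].mean() for c in range(self.k)])
            null_min[i] = means.min()
            null_max[i] = means.max()
        if self.cluster_scores is None:
            self.label_states(score_series)
        obs_min = self.cluster_scores[self.avoidance_cluster]
        obs_max = self.cluster_scores[self.approach_cluster]
        return StateNull(
            null_min, null_max, obs_min, obs_max,
            avoidance_significant=bool(obs_min < np.percentile(null_min, 5)),
            approach_significant=bool(obs_max > np.percentile(null_max, 95)),
        )

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment for new timepoints x cells data."""
        d = ((X[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def summary(self) -> str:
        lines = [f"k-means state model: K = {self.k} (AIC-selected from "
                 f"{self.model.k_range[0]}-{self.model.k_range[-1]})",
                 f"  RSS: {self.rss:.1f}   AIC: {self.aic_table[self.k]:.1f}"]
        if self.cluster_scores is not None:
            lines.append(f"  cluster mean scores: "
                         + ", ".join(f"{s:+.3f}" for s in self.cluster_scores))
            lines.append(f"  avoidance cluster: {self.avoidance_cluster}   "
                         f"approach cluster: {self.approach_cluster}")
        return "\n".join(lines)


@dataclass
class StateNull:
    null_min: np.ndarray
    null_max: np.ndarray
    observed_min: float
    observed_max: float
    avoidance_significant: bool
    approach_significant: bool


# ---------------------------------------------------------------------------
# cross-assay transfer


@dataclass
class TransferResult:
    assignments: np.ndarray
    approach_mean_score: float
    avoidance_mean_score: float
    p_ranksum: float


def transfer_clusters(results: ClusterModelResults, traces_test: TraceMatrix,
                      coreg: CoregistrationMap | None, scores_test: np.ndarray
                      ) -> TransferResult:
    """Apply centroids trained in one assay to the withheld assay.

    ``traces_test`` is restricted to the co-registered cells, in the
    training model's cell order, then each test timepoint is assigned to the
    nearest training centroid.  Reported: the mean avoidance/approach score
    of the transferred approach and avoidance clusters and a two-sided
    rank-sum test of their difference.
    """
    from scipy.stats import ranksums

    if results.avoidance_cluster is None:
        raise ValueError("label the training clusters before transfer")
    if coreg is not None:
        if len(coreg) == 0:
            raise ValueError("empty co-registration map")
        test = traces_test.select_cells(coreg.ids_assay2)
    else:
        test = traces_test
    if test.n_cells != results.centroids.shape[1]:
        raise ValueError("test traces do not match the training model's cells")
    assignments = results.assign(test.values.T)
    scores_test = np.asarray(scores_test, dtype=float)[: len(assignments)]
    app = scores_test[assignments == results.approach_cluster]
    avd = scores_test[assignments == results.avoidance_cluster]
    if len(app) == 0 or len(avd) == 0:
        p = np.nan
    else:
        p = float(ranksums(app, avd).pvalue)
    return TransferResult(
        assignments,
        float(app.mean()) if len(app) else np.nan,
        float(avd.mean()) if len(avd) else np.nan,
        p,
    )


# ---------------------------------------------------------------------------
# HMM alternative


class StateHMM:
    """Gaussian-emission HMM on the top principal components.

    PCs are retained until cumulative explained variance reaches
    ``var_target`` (60%); the HMM (diagonal covariance, ``n_states``
    states) is fit by EM with seeded restarts, keeping the best
    log-likelihood.
    """

    def __init__(self, traces: TraceMatrix, n_states: int = 4, var_target: float = 0.6,
                 n_restarts: int = 10, max_iter: int = 500, tol: float = 1e-6):
        self.traces = traces
        self.n_states = n_states
        self.var_target = var_target
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, seed: int = 0) -> "HMMStateResults":
        from hmmlearn.hmm import GaussianHMM
        from sklearn.decomposition import PCA

        X = self.traces.values.T
        pca = PCA()
        Z = pca.fit_transform(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pc = int(np.searchsorted(cum, self.var_target) + 1)
        Z = Z[:, :n_pc]
        if len(np.unique(Z.round(12), axis=0)) < self.n_states:
            raise ValueError("fewer distinct observations than states")

        best = None
        for r in range(self.n_restarts):
            hmm = GaussianHMM(n_components=self.n_states, covariance_type="diag",
                              n_iter=self.max_iter, tol=self.tol,
                              random_state=int(np.random.default_rng([seed, r]).integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    hmm.fit(Z)
                except ValueError:
                    continue
            ll = hmm.score(Z)
            if best is None or ll > best[1]:
                best = (hmm, ll)
        if best is None:
            raise RuntimeError("every HMM restart failed")
        hmm, ll = best
        if not hmm.monitor_.converged:
            warnings.warn("EM did not converge; keeping the best log-likelihood fit")
        states = hmm.predict(Z)
        return HMMStateResults(self, hmm, states, float(ll), n_pc,
                               float(cum[n_pc - 1]))


@dataclass
class HMMStateResults:
    model: StateHMM
    hmm: object
    state_sequence: np.ndarray
    log_likelihood: float
    n_components_pca: int
    variance_explained: float
    avoidance_state: int | None = None
    approach_state: int | None = None
    state_scores: np.ndarray | None = None

    @property
    def transition_matrix(self) -> np.ndarray:
        return self.hmm.transmat_

    def label_states(self, score_series: np.ndarray) -> "HMMStateResults":
        """Avoidance = state with minimum mean score, approach = maximum."""
        score_series = np.asarray(score_series, dtype=float)
        means = np.array([
            score_series[self.state_sequence == s].mean()
            if (self.state_sequence == s).any() else np.nan
            for s in range(self.model.n_states)
        ])
        self.state_scores = means
        self.avoidance_state = int(np.nanargmin(means))
        self.approach_state = int(np.nanargmax(means))
        return self

    def summary(self) -> str:
        lines = [f"Gaussian HMM: {self.model.n_states} states on {self.n_components_pca} PCs "
                 f"({self.variance_explained:.0%} variance)",
                 f"  log-likelihood: {self.log_likelihood:.1f}"]
        if self.state_scores is not None:
            lines.append("  state mean scores: "
                         + ", ".join(f"{s:+.3f}" for s in self.state_scores))
        return "\n".join(lines)
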