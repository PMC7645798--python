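"""Consensus sNMF clustering with permutation-calibrated cluster-number selection.

Because sNMF depends on its random initialization, the factorization is
repeated (default 50 restarts) and summarized by a consensus matrix C whose
(i, j) entry is the fraction of runs in which patients i and j received the
same hard label. Final labels come from average-linkage hierarchical
clustering of the distance 1 − C. Stability of a candidate cluster number k
is scored by three criteria:

* PAC — proportion of off-diagonal consensus entries strictly inside
  (0.1, 0.9); lower is more stable;
* silhouette index on the distance 1 − C with the final labels;
* cophenetic correlation between 1 − C and the dendrogram's cophenetic
  distances.

A permutation null (independently shuffling every burden column, which
destroys patient structure while preserving marginals) calibrates silhouette
and cophenetic correlation. The selected k is the smallest k attaining the
minimum PAC among candidates whose silhouette AND cophenetic correlation
exceed the 95th percentile of their null distributions; if no candidate
passes, no cluster structure is declared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .nmf import FactorizationResult, snmf

__all__ = [
    "ConsensusResult",
    "ConsensusClustering",
    "consensus_cluster",
    "cluster_metrics",
    "permutation_null",
    "select_k",
    "top_mechanisms",
]


@dataclass
class ConsensusResult:
    """Consensus matrix, final labels, stability metrics and the best run."""

    C: np.ndarray
    labels: np.ndarray  # 1-based cluster ids from the dendrogram cut
    k: int
    n_runs: int
    metrics: dict[str, float]  # pac, silhouette, cophenetic
    best_run: FactorizationResult


def cluster_metrics(C: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """PAC, silhouette (on 1−C) and cophenetic correlation of a consensus matrix."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    iu = np.triu_indices(n, k=1)
    off = C[iu]
    pac = float(np.mean((off > 0.1) & (off < 0.9))) if off.size else 0.0
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = average(condensed)
    coph_d = cophenet(Z)
    if np.std(coph_d) == 0 or np.std(condensed) == 0:
        cophenetic = 1.0 if np.allclose(coph_d, condensed) else 0.0
    else:
        cophenetic = float(np.corrcoef(condensed, coph_d)[0, 1])
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        sil = float("nan")
    else:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return {"pac": pac, "silhouette": sil, "cophenetic": cophenetic}


def consensus_cluster(
    X,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    sparsity: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Repeat sNMF over random restarts and cluster the consensus matrix.

    Restart r uses seed ``seed + r``. Final labels cut the average-linkage
    dendrogram of 1 − C at k groups.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    counts = np.zeros((n, n))
    best: FactorizationResult | None = None
    for r in range(n_runs):
        res = snmf(X, k, sparsity=sparsity, seed=seed + r, max_iter=max_iter, tol=tol)
        lab = res.labels
        counts += (lab[:, None] == lab[None, :]).astype(float)
        if best is None or res.objective < best.objective:
            best = res
    C = counts / n_runs
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust")
    metrics = cluster_metrics(C, labels)
    return ConsensusResult(C=C, labels=labels, k=k, n_runs=n_runs, metrics=metrics, best_run=best)


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """Consensus sNMF clustering as an sklearn-style estimator.

    Fitted attributes: ``labels_``, ``consensus_``, ``pac_``, ``silhouette_``,
    ``cophenetic_`` and ``best_run_`` (the lowest-objective factorization,
    whose loading matrix S feeds :func:`top_mechanisms`).
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_runs: int = 50,
        sparsity: float = 0.01,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.sparsity = sparsity
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        res = consensus_cluster(
            np.asarray(X, dtype=float),
            k=self.n_clusters,
            n_runs=self.n_runs,
            seed=self.random_state,
            sparsity=self.sparsity,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.labels_ = res.labels
        self.consensus_ = res.C
        self.pac_ = res.metrics["pac"]
        self.silhouette_ = res.metrics["silhouette"]
        self.cophenetic_ = res.metrics["cophenetic"]
        self.best_run_ = res.best_run
        self.result_ = res
        return self


def permutation_null(
    X,
    k_grid,
    n_perm: int = 20,
    n_runs: int = 50,
    seed: int = 0,
    sparsity: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> dict[int, list[dict[str, float]]]:
    """Stability metrics of column-shuffled data, per candidate k.

    Each permutation shuffles every column of X independently (patient
    structure destroyed, per-mechanism marginals preserved), then repeats the
    full consensus procedure. Returns {k: [metric dict per permutation]}.
    """
    X = np.asarray(X, dtype=float)
    nulls: dict[int, list[dict[str, float]]] = {int(k): [] for k in k_grid}
    for p in range(n_perm):
        rng = np.random.default_rng([seed, 1000 + p])
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        for k in k_grid:
            res = consensus_cluster(
                Xp, int(k), n_runs=n_runs, seed=seed + 500_000 + p, sparsity=sparsity,
                max_iter=max_iter, tol=tol,
            )
            nulls[int(k)].append(res.metrics)
    return nulls


def select_k(
    results: dict[int, dict[str, float]],
    nulls: dict[int, list[dict[str, float]]],
    percentile: float = 95.0,
) -> int | None:
    """Pick the cluster number: minimal PAC among permutation-significant k.

    A candidate passes when its silhouette AND cophenetic correlation both
    exceed the given percentile of their permutation null. Among passing
    candidates the minimum PAC wins; PAC ties go to the smallest k. Returns
    None when no candidate is significant.
    """
    if not results:
        raise ValueError("empty k grid")
    passing = []
    for k, met in results.items():
        null = nulls.get(k, [])
        if not null:
            continue
        sil_cut = np.percentile([m["silhouette"] for m in null], percentile)
        coph_cut = np.percentile([m["cophenetic"] for m in null], percentile)
        if np.isnan(met["silhouette"]):
            continue
        if met["silhouette"] > sil_cut and met["cophenetic"] > coph_cut:
            passing.append((met["pac"], k))
    if not passing:
        return None
    min_pac = min(p for p, _ in passing)
    return min(k for p, k in passing if p == min_pac)


def top_mechanisms(
    S: np.ndarray,
    threshold: float = 0.5,
    mechanism_names: list[str] | None = None,
) -> list[list[tuple[str, float]]]:
    """Per-cluster mechanisms ranked by loading, kept above threshold·row-max.

    Returns, for each cluster row of S, (mechanism, loading) pairs sorted by
    decreasing loading. An all-zero row yields an empty list with a warning.
    """
    import warnings

    S = np.asarray(S, dtype=float)
    k, m = S.shape
    names = mechanism_names or [f"M{j + 1}" for j in range(m)]
    out: list[list[tuple[str, float]]] = []
    for c in range(k):
        row = S[c]
        top = row.max()
        if top <= 0:
            warnings.warn(f"cluster {c}: all-zero loading row", stacklevel=2)
            out.append([])
            continue
        keep = [(names[j], float(row[j])) for j in range(m) if row[j] >= threshold * top]
        keep.sort(key=lambda t: (-t[1], t[0]))
        out.append(keep)
    return out
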