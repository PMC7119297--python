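"""Fold-change-weighted spectral clustering of the tissue network.

Standard normalized spectral clustering partitions a graph via the
eigenvectors of L = D^{-1/2}(D - S)D^{-1/2}, where S holds 0/1
connectivities and D the node degrees. Here the affinity S' holds signed
Pearson correlations (r_aa = 1 on the diagonal) and the degree matrix D'
holds each gene's tumor-vs-normal log fold change FC_a, so the embedding
mixes local co-expression with a global dysregulation signal. To keep the
degree identity d_a = sum_k S_ak, S' is row-rescaled to
S''_ab = r_ab * FC_a / sum_k r_ak, giving L_raw = D' - S'' and
L_norm = D'^{-1/2} L_raw D'^{-1/2}.

In the limit FC_a = sum_k S'_ak with binary correlations, S'' = S' and
L_raw collapses to the ordinary graph Laplacian D - A exactly (the unit
diagonal cancels), so the construction is a strict generalisation.

The number of clusters K is chosen by Hartigan's rule: increase k while
H(k) = (W_k / W_{k+1} - 1)(n - k - 1) exceeds 10, and stop at the first
k where it does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .network import IntegratedNetwork

logger = logging.getLogger(__name__)

DEFAULT_HARTIGAN_THRESHOLD = 10.0
MAX_EIGENVECTORS = 40


@dataclass
class SpectralMatrices:
    """The matrices of the fold-change-weighted Laplacian construction."""

    genes: list[str]
    S_prime: np.ndarray   # signed correlations, unit diagonal, 0 off-skeleton
    D_prime: np.ndarray   # node-weight vector FC_a
    S_dprime: np.ndarray  # row-normalised influence matrix
    L_raw: np.ndarray     # diag(FC) - S''
    L_norm: np.ndarray    # D'^{-1/2} L_raw D'^{-1/2}
    max_asymmetry: float = 0.0  # diagnostic: max |L_norm - L_norm^T| before symmetrisation


@dataclass
class HartiganTrace:
    """Per-k record of within-cluster sum of squares and Hartigan's number."""

    rows: list[tuple[int, float, float]] = field(default_factory=list)  # (k, W_k, H_k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["k", "within_ss", "hartigan"])


@dataclass
class ClusterAssignment:
    """Gene → cluster map plus the spectral embedding it came from."""

    assignment: dict[str, int]
    K: int
    embedding: np.ndarray     # n × m eigenvector matrix
    eigenvalues: np.ndarray   # the m selected eigenvalues
    hartigan_trace: HartiganTrace | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        used = set(self.assignment.values())
        if used != set(range(self.K)):
            raise ValueError("cluster ids must be exactly 0..K-1 with no empty cluster")

    def members(self, cluster_id: int) -> list[str]:
        return sorted(g for g, c in self.assignment.items() if c == cluster_id)


def build_matrices_arrays(S_prime: np.ndarray, fc: np.ndarray,
                          eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core matrix construction on raw arrays; returns (S'', L_raw, L_norm)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    S_prime = np.asarray(S_prime, dtype=float)
    fc = np.asarray(fc, dtype=float)
    n = S_prime.shape[0]
    if S_prime.shape != (n, n):
        raise ValueError("S_prime must be square")
    if fc.shape != (n,):
        raise ValueError("fc must be a length-n vector")
    if np.any(fc <= 0):
        bad = np.nonzero(fc <= 0)[0]
        raise ValueError(f"non-positive node weight at index {bad[0]} "
                         "(weighted Laplacian undefined)")
    row_sums = S_prime.sum(axis=1)
    degenerate = np.abs(row_sums) < eps
    if degenerate.any():
        logger.warning("build_matrices: %d rows with |sum r| < eps zeroed",
                       int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, row_sums)
    S_dprime = S_prime * (fc / safe)[:, None]
    S_dprime[degenerate, :] = 0.0
    L_raw = np.diag(fc) - S_dprime
    d_floor = np.maximum(fc, eps)
    inv_sqrt = 1.0 / np.sqrt(d_floor)
    L_norm = inv_sqrt[:, None] * L_raw * inv_sqrt[None, :]
    return S_dprime, L_raw, L_norm


def build_matrices(net: IntegratedNetwork, eps: float = 1e-8) -> SpectralMatrices:
    """Assemble S', D', S'', L_raw and L_norm from an integrated network.

    Requires strictly positive node weights (the tissue context: log fold
    changes of over-expressed genes). The affinity has r_aa = 1 on the
    diagonal and its row sums include that diagonal term.
    """
    genes = list(net.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    S = np.zeros((n, n))
    np.fill_diagonal(S, 1.0)
    for (a, b), w in net.edge_weight.items():
        S[idx[a], idx[b]] = w
        S[idx[b], idx[a]] = w
    fc = np.array([net.node_weight[g] for g in genes], dtype=float)
    S_dp, L_raw, L_norm = build_matrices_arrays(S, fc, eps=eps)
    asym = float(np.max(np.abs(L_norm - L_norm.T))) if n > 1 else 0.0
    return SpectralMatrices(genes=genes, S_prime=S, D_prime=fc, S_dprime=S_dp,
                            L_raw=L_raw, L_norm=L_norm, max_asymmetry=asym)


def eigendecompose(mats: SpectralMatrices, m: int,
                   order: str = "smallest") -> tuple[np.ndarray, np.ndarray]:
    """m eigenpairs of the symmetrised L_norm, eigenvalues ascending.

    With heterogeneous fold changes L_norm is not exactly symmetric under
    row normalisation, so (L + L^T)/2 is decomposed; the asymmetry is kept
    as a diagnostic on the matrices object. Eigenvector signs are fixed by
    forcing each vector's largest-magnitude entry positive. ``order``
    selects the smallest (standard) or largest eigenvalues.
    """
    n = len(mats.genes)
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}]")
    if mats.max_asymmetry > 1e-10:
        logger.info("eigendecompose: symmetrising L_norm (max asymmetry %.3g)",
                    mats.max_asymmetry)
    sym = (mats.L_norm + mats.L_norm.T) / 2.0
    vals, vecs = eigh(sym)  # ascending
    if order == "largest":
        sel = np.arange(n - m, n)
    elif order == "smallest":
        sel = np.arange(m)
    else:
        raise ValueError(f"unknown eigen order {order!r}")
    vals, vecs = vals[sel], vecs[:, sel]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def _within_ss(embedding: np.ndarray, k: int, restarts: int, seed: int) -> float:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    km.fit(embedding)
    return float(km.inertia_)


def choose_k_hartigan(embedding: np.ndarray, k_max: int,
                      threshold: float = DEFAULT_HARTIGAN_THRESHOLD,
                      restarts: int = 10, seed: int = 0
                      ) -> tuple[int, HartiganTrace]:
    """Smallest k whose Hartigan number falls below the threshold.

    H(k) = (W_k / W_{k+1} - 1)(n - k - 1), with W_k the best-of-restarts
    K-means within-cluster sum of squares. H(k) > threshold means k+1
    clusters are worthwhile; the first k with H(k) < threshold is
    returned. If none qualifies, k_max is returned with a warning.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k_max > n - 2:
        k_max = max(1, n - 2)
        logger.warning("choose_k_hartigan: k_max clamped to %d", k_max)
    W = {k: _within_ss(embedding, k, restarts, seed) for k in range(1, k_max + 2)}
    trace = HartiganTrace()
    chosen: int | None = None
    for k in range(1, k_max + 1):
        if W[k] <= 0.0:
            h = 0.0
        elif W[k + 1] <= 0.0:
            h = np.inf
        else:
            h = (W[k] / W[k + 1] - 1.0) * (n - k - 1)
        trace.rows.append((k, W[k], float(h)))
        if chosen is None and h < threshold:
            chosen = k
    if chosen is None:
        logger.warning("choose_k_hartigan: no k <= %d passed threshold %.3g; "
                       "returning k_max", k_max, threshold)
        chosen = k_max
    return chosen, trace


def spectral_cluster(net: IntegratedNetwork, m: int | None = None,
                     k: int | None = None, seed: int = 0,
                     k_max: int | None = None,
                     hartigan_threshold: float = DEFAULT_HARTIGAN_THRESHOLD,
                     restarts: int = 10, eps: float = 1e-8,
                     eigen_order: str = "smallest") -> ClusterAssignment:
    """Cluster the tissue network in its weighted-Laplacian embedding.

    ``k`` is selected by Hartigan's rule when not given; ``m`` (eigenvector
    count) defaults to min(k, 40). K-means runs with k-means++ and
    ``restarts`` initialisations under the fixed seed.
    """
    mats = build_matrices(net, eps=eps)
    n = len(mats.genes)
    trace = None
    if k is None:
        if k_max is None:
            k_max = min(10, max(1, n - 2))
        # The Hartigan scan needs an embedding whose dimension roughly matches
        # the structure; noise eigenvectors (orthonormal, ~1 SS each) would
        # otherwise swamp the within-SS ratios. The eigengap heuristic picks
        # that dimension; Hartigan's rule then decides K inside it.
        m_cap = min(max(k_max + 1, 2), MAX_EIGENVECTORS, n)
        vals_cap, _ = eigendecompose(mats, m_cap, order=eigen_order)
        if m_cap > 1:
            m_sel = int(np.argmax(np.diff(vals_cap))) + 1
        else:
            m_sel = 1
        m_sel = max(m_sel, 2) if n > 2 else m_sel
        logger.info("spectral_cluster: eigengap selection embedding m=%d", m_sel)
        _, emb_sel = eigendecompose(mats, m_sel, order=eigen_order)
        k, trace = choose_k_hartigan(emb_sel, k_max=k_max,
                                     threshold=hartigan_threshold,
                                     restarts=restarts, seed=seed)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if m is None:
        m = min(k, MAX_EIGENVECTORS)
    vals, vecs = eigendecompose(mats, m, order=eigen_order)
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(vecs)
    # compact labels so cluster ids are 0..K-1 with no gaps
    used = np.unique(labels)
    remap = {int(c): i for i, c in enumerate(used)}
    if len(used) < k:
        logger.warning("spectral_cluster: %d requested clusters, %d non-empty",
                       k, len(used))
    assignment = {g: remap[int(c)] for g, c in zip(mats.genes, labels)}
    return ClusterAssignment(assignment=assignment, K=len(used), embedding=vecs,
                             eigenvalues=vals, hartigan_trace=trace, seed=seed)


class NetworkSpectralClustering(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator for the weighted spectral clustering.

    Parameters
    ----------
    n_clusters : int or "auto"
        Cluster count; "auto" selects K by Hartigan's rule.
    n_components : int or None
        Eigenvector count for the embedding (default min(K, 40)).
    k_max : int or None
        Search ceiling for auto-K.
    hartigan_threshold : float
        Stopping threshold for Hartigan's number.
    n_restarts : int
        K-means restarts.
    eps : float
        Guard for degenerate row sums / the D'^{-1/2} power.
    random_state : int
        Seed for K-means.

    ``fit`` takes the precomputed affinity X (n × n signed correlations,
    unit diagonal, zeros off the skeleton) and a ``node_weights`` fit
    parameter (strictly positive vector). Fitted attributes: ``labels_``,
    ``embedding_``, ``eigenvalues_``, ``n_clusters_``, ``hartigan_trace_``.
    """

    def __init__(self, n_clusters: int | str = "auto",
                 n_components: int | None = None, k_max: int | None = None,
                 hartigan_threshold: float = DEFAULT_HARTIGAN_THRESHOLD,
                 n_restarts: int = 10, eps: float = 1e-8,
                 eigen_order: str = "smallest", random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.k_max = k_max
        self.hartigan_threshold = hartigan_threshold
        self.n_restarts = n_restarts
        self.eps = eps
        self.eigen_order = eigen_order
        self.random_state = random_state

    def fit(self, X, y=None, node_weights=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if X.shape != (n, n) or not np.allclose(X, X.T, atol=1e-9):
            raise ValueError("X must be a symmetric n x n affinity matrix")
        if node_weights is None:
            node_weights = np.ones(n)
        width = len(str(max(n - 1, 0)))
        genes = [f"g{i:0{width}d}" for i in range(n)]
        net = _network_from_arrays(genes, X, np.asarray(node_weights, dtype=float))
        k = None if self.n_clusters == "auto" else int(self.n_clusters)
        res = spectral_cluster(net, m=self.n_components, k=k,
                               seed=self.random_state, k_max=self.k_max,
                               hartigan_threshold=self.hartigan_threshold,
                               restarts=self.n_restarts, eps=self.eps,
                               eigen_order=self.eigen_order)
        self.labels_ = np.array([res.assignment[g] for g in genes], dtype=int)
        self.embedding_ = res.embedding
        self.eigenvalues_ = res.eigenvalues
        self.n_clusters_ = res.K
        self.hartigan_trace_ = res.hartigan_trace
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_


def _network_from_arrays(genes: list[str], S: np.ndarray,
                         fc: np.ndarray) -> IntegratedNetwork:
    n = len(genes)
    ew: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if S[i, j] != 0.0:
                ew[(genes[i], genes[j])] = float(S[i, j])
    nw = {g: float(w) for g, w in zip(genes, fc)}
    return IntegratedNetwork(nodes=genes, node_weight=nw, edge_weight=ew,
                             context="tissue")
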