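"""kNN affinity graphs and closed-form graph label propagation.

Both labeled and unlabeled training points are embedded in a symmetric
kNN graph with Gaussian edge weights

    W_ij = exp(-||x_i - x_j||^2 / sigma^2)   if i, j are neighbors,

an edge being kept when either endpoint lists the other among its t
nearest neighbors.  Label mass then spreads over the graph by minimizing
a quadratic objective balancing fidelity to the observed one-hot labels
against smoothness under the symmetric normalized affinity
S = D^{-1/2} W D^{-1/2}:

    L(F) = 1/2 ||F - Y||_F^2 + (lambda/2) * sum_{i<j} W_ij ||f_i/sqrt(D_ii) - f_j/sqrt(D_jj)||^2

whose unique minimizer has the closed form

    F* = ((1 + lambda) I - lambda S)^{-1} Y.

Pseudo-labels for the unlabeled block are the row-argmaxes of F*.  The
system matrix is symmetric positive definite for any lambda > 0 because
the spectrum of S lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.neighbors import NearestNeighbors

from .datasets import PartiallyLabeledDataset, label_matrix

#: above this many points the linear system is solved by conjugate gradients
_DENSE_SOLVE_LIMIT = 4000


@dataclass
class AffinityGraph:
    """Symmetrized kNN graph with Gaussian weights over all l+u points."""

    weights: sp.csr_matrix  # symmetric, zero diagonal
    degrees: np.ndarray  # row sums of weights
    n_neighbors: int
    bandwidth: float

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def normalized_affinity(self) -> sp.csr_matrix:
        """S = D^{-1/2} W D^{-1/2}, with D^{-1/2} := 0 on isolated nodes."""
        with np.errstate(divide="ignore"):
            dinv = np.where(self.degrees > 0, 1.0 / np.sqrt(self.degrees), 0.0)
        Dinv = sp.diags(dinv)
        return (Dinv @ self.weights @ Dinv).tocsr()

    def edge_list(self) -> np.ndarray:
        """Upper-triangular edges as an (m, 3) array of (i, j, weight)."""
        coo = sp.triu(self.weights, k=1).tocoo()
        return np.column_stack([coo.row, coo.col, coo.data])


@dataclass
class PropagationResult:
    """Optimal score matrix F* and the pseudo-labels derived from it."""

    scores: np.ndarray  # (l+u, K)
    pseudo_labels_unlabeled: np.ndarray  # (u,)
    regularization: float
    unlabeled_indices: np.ndarray  # rows of `scores` that were unlabeled

    def to_frame(self):
        import pandas as pd

        n, K = self.scores.shape
        frame = pd.DataFrame(self.scores, columns=[f"score_{k}" for k in range(K)])
        frame.insert(0, "instance", np.arange(n))
        pseudo = np.full(n, -1)
        pseudo[self.unlabeled_indices] = self.pseudo_labels_unlabeled
        frame["pseudo_label"] = pseudo
        return frame


def build_affinity_graph(
    dataset: PartiallyLabeledDataset | np.ndarray,
    n_neighbors: int = 10,
    sigma: float | str = "auto",
) -> AffinityGraph:
    """Build the symmetrized kNN Gaussian affinity graph.

    Parameters
    ----------
    dataset
        A :class:`PartiallyLabeledDataset` (labeled block stacked above
        unlabeled) or a plain (n, d) feature matrix.
    n_neighbors
        Neighbor count t; each point contributes edges to its t nearest
        neighbors and the edge set is symmetrized by union.
    sigma
        Gaussian bandwidth.  ``"auto"`` uses the median heuristic: the
        median of all retained directed neighbor distances.
    """
    X = dataset.all_features() if isinstance(dataset, PartiallyLabeledDataset) else np.asarray(dataset, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("graph construction needs at least 2 points")
    if n_neighbors < 1 or n_neighbors >= n:
        raise ValueError(f"need 1 <= t < n; got t={n_neighbors}, n={n}")

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop one occurrence of self per row (ties/duplicates permitting, it
    # may not sit in the first column)
    rows = []
    cols = []
    dists = []
    for i in range(n):
        neigh = idx[i]
        d = dist[i]
        self_pos = np.nonzero(neigh == i)[0]
        keep = np.ones(neigh.size, dtype=bool)
        keep[self_pos[0] if self_pos.size else neigh.size - 1] = False
        rows.append(np.full(n_neighbors, i))
        cols.append(neigh[keep][:n_neighbors])
        dists.append(d[keep][:n_neighbors])
    row = np.concatenate(rows)
    col = np.concatenate(cols)
    d = np.concatenate(dists)

    if sigma == "auto":
        med = float(np.median(d))
        sigma_val = med if med > 0 else 1.0
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")

    w = np.exp(-(d ** 2) / sigma_val ** 2)
    A = sp.coo_matrix((w, (row, col)), shape=(n, n)).tocsr()
    W = A.maximum(A.T)  # union symmetrization; weights from identical distances
    W.setdiag(0.0)
    W.eliminate_zeros()
    degrees = np.asarray(W.sum(axis=1)).ravel()
    return AffinityGraph(weights=W.tocsr(), degrees=degrees, n_neighbors=n_neighbors, bandwidth=sigma_val)


def _system_matrix(graph: AffinityGraph, lam: float) -> sp.csr_matrix:
    n = graph.n_nodes
    S = graph.normalized_affinity()
    return ((1.0 + lam) * sp.identity(n, format="csr") - lam * S).tocsr()


def propagate_labels(
    graph: AffinityGraph,
    labels: np.ndarray,
    lam: float = 99.0,
) -> PropagationResult:
    """Solve the closed-form propagation and derive pseudo-labels.

    ``labels`` is the (l+u, K) one-hot label matrix (zero rows mark
    unlabeled instances).  Returns the full score matrix F* and the
    row-argmax pseudo-labels of the unlabeled rows (ties resolved to the
    lowest class index).
    """
    Y = np.asarray(labels, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != graph.n_nodes:
        raise ValueError("label matrix shape does not match the graph")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    M = _system_matrix(graph, lam)
    n = graph.n_nodes
    if n <= _DENSE_SOLVE_LIMIT:
        F = scipy.linalg.solve(M.toarray(), Y, assume_a="pos")
    else:
        F = np.empty_like(Y)
        for k in range(Y.shape[1]):
            x, info = spla.cg(M, Y[:, k], rtol=1e-10, atol=0.0)
            if info != 0:
                raise RuntimeError(f"conjugate gradient failed (info={info})")
            F[:, k] = x
    unlabeled = np.nonzero(Y.sum(axis=1) == 0)[0]
    pseudo = F[unlabeled].argmax(axis=1) if unlabeled.size else np.empty(0, dtype=int)
    return PropagationResult(
        scores=F,
        pseudo_labels_unlabeled=pseudo.astype(int),
        regularization=float(lam),
        unlabeled_indices=unlabeled,
    )


def propagate_dataset(
    dataset: PartiallyLabeledDataset,
    n_neighbors: int = 10,
    sigma: float | str = "auto",
    lam: float = 99.0,
) -> PropagationResult:
    """Convenience wrapper: build the graph and propagate in one call."""
    graph = build_affinity_graph(dataset, n_neighbors=n_neighbors, sigma=sigma)
    return propagate_labels(graph, label_matrix(dataset), lam=lam)


def propagation_objective(
    scores: np.ndarray,
    labels: np.ndarray,
    graph: AffinityGraph,
    lam: float,
) -> float:
    """Quadratic propagation loss evaluated at an arbitrary score matrix.

    Each unordered pair contributes once to the smoothness term;
    isolated nodes contribute no smoothness (their D^{-1/2} is taken as
    zero, matching the solver's convention).
    """
    F = np.asarray(scores, dtype=float)
    Y = np.asarray(labels, dtype=float)
    if F.shape != Y.shape or F.shape[0] != graph.n_nodes:
        raise ValueError("dimension mismatch")
    with np.errstate(divide="ignore"):
        dinv = np.where(graph.degrees > 0, 1.0 / np.sqrt(graph.degrees), 0.0)
    Fn = F * dinv[:, None]
    coo = graph.weights.tocoo()
    diff = Fn[coo.row] - Fn[coo.col]
    # coo stores each unordered pair twice, hence the extra factor 1/2
    smooth = 0.5 * float(np.sum(coo.data * np.sum(diff * diff, axis=1)))
    fit = float(np.sum((F - Y) ** 2))
    return 0.5 * fit + 0.5 * lam * smooth


def propagation_gradient(
    scores: np.ndarray,
    labels: np.ndarray,
    graph: AffinityGraph,
    lam: float,
) -> np.ndarray:
    """Analytic gradient of :func:`propagation_objective` in ``scores``."""
    F = np.asarray(scores, dtype=float)
    Y = np.asarray(labels, dtype=float)
    S = graph.normalized_affinity()
    connected = (graph.degrees > 0).astype(float)[:, None]
    return (F - Y) + lam * (connected * F - S @ F)


def iterative_propagation(
    graph: AffinityGraph,
    labels: np.ndarray,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Fixed-point iteration equivalent of the closed-form solution.

    Iterates ``F <- alpha S F + (1 - alpha) Y`` with
    ``alpha = lambda / (1 + lambda)`` from ``F = Y`` until the relative
    change drops below ``tol``.  Serves as an independent cross-check of
    :func:`propagate_labels`; the fixed point satisfies the same linear
    system.
    """
    Y = np.asarray(labels, dtype=float)
    alpha = lam / (1.0 + lam)
    S = graph.normalized_affinity()
    F = Y.copy()
    for _ in range(max_iter):
        F_next = alpha * (S @ F) + (1.0 - alpha) * Y
        denom = max(np.abs(F).max(), 1e-300)
        change = np.abs(F_next - F).max() / denom
        F = F_next
        if change < tol:
            break
    return F
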