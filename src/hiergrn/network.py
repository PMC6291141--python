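"""Mutual-information association network with DPI pruning.

Edges are weighted by Gaussian-copula mutual information: each profile is
rank-transformed to normal scores, and MI = -1/2 ln(1 - rho^2) nats where
rho is the correlation of the scores. With only ~24 arrays per profile this
estimator is far better behaved than binned MI (which is provided as an
alternative), is invariant to monotone per-gene transforms, and reduces the
whole matrix to one correlation computation. Edges are kept when their
permutation p-value beats a threshold, then the data-processing inequality
(DPI) prunes the weakest edge of every fully connected triplet: for a
Markov chain X -> Y -> Z, MI(X,Z) <= min(MI(X,Y), MI(Y,Z)), so an edge that
is more than a tolerance factor below both sides of an indirect path is
likely indirect.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .expression import ExpressionMatrix
from .rankprod import DEGSet

__all__ = [
    "gaussian_copula_mi",
    "binned_mi",
    "mi_matrix",
    "edge_significance",
    "apply_dpi",
    "build_network",
]

logger = logging.getLogger(__name__)

#: |rho| is clamped below 1 so identical profiles get a large finite MI.
RHO_CLAMP = 1.0 - 1e-9

#: MI value assigned to a perfectly correlated pair (the clamp ceiling).
MI_CEILING = -0.5 * math.log1p(-(RHO_CLAMP**2))


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Ranks mapped to standard-normal quantiles, r/(n+1) convention."""
    r = stats.rankdata(x, method="average")
    return ndtri(r / (x.size + 1.0))


def _mi_from_rho(rho: np.ndarray | float) -> np.ndarray | float:
    rho = np.clip(rho, -RHO_CLAMP, RHO_CLAMP)
    return -0.5 * np.log1p(-np.square(rho))


def gaussian_copula_mi(x: Sequence[float], y: Sequence[float]) -> float:
    """Copula-MI (nats) between two profiles; symmetric and >= 0.

    Constant profiles have no rank structure; their correlation is defined
    as 0 and the function returns 0 with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    sx, sy = _normal_scores(x), _normal_scores(y)
    if np.ptp(sx) == 0.0 or np.ptp(sy) == 0.0:
        logger.warning("constant profile in MI estimation; returning 0")
        return 0.0
    rho = float(np.corrcoef(sx, sy)[0, 1])
    return float(_mi_from_rho(rho))


def binned_mi(x: Sequence[float], y: Sequence[float], bins: int | None = None) -> float:
    """Equal-frequency binned MI with Miller-Madow bias correction (nats).

    Alternative estimator (ceil(sqrt(n)) bins by default); noticeably biased
    at small n, provided for cross-checking only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if bins is None:
        bins = int(math.ceil(math.sqrt(n)))
    qx = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    qy = np.quantile(y, np.linspace(0, 1, bins + 1)[1:-1])
    ix = np.searchsorted(qx, x, side="right")
    iy = np.searchsorted(qy, y, side="right")
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ix, iy), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    # Miller-Madow: + (cells - 1) correction difference of the three entropies
    k_joint = int(nz.sum())
    k_x = int((px > 0).sum())
    k_y = int((py > 0).sum())
    mi += (k_x - 1) / (2 * n) + (k_y - 1) / (2 * n) - (k_joint - 1) / (2 * n)
    return max(mi, 0.0)


def _score_matrix(values: np.ndarray) -> np.ndarray:
    scores = np.empty_like(values, dtype=float)
    ranks = stats.rankdata(values, method="average", axis=1)
    scores = ndtri(ranks / (values.shape[1] + 1.0))
    return scores


def mi_matrix(
    expr: ExpressionMatrix, genes: Iterable[str] | None = None, *,
    estimator: str = "gaussian_copula",
) -> pd.DataFrame:
    """Pairwise MI over all unordered gene pairs (diagonal set to 0).

    All arrays (both conditions, every timepoint) form the sample dimension.
    """
    genes = list(genes) if genes is not None else expr.gene_ids
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"unknown gene ids: {missing[:5]}")
    values = expr.data.loc[genes].to_numpy()
    if estimator == "gaussian_copula":
        constant = np.ptp(values, axis=1) == 0.0
        scores = _score_matrix(values)
        scores[constant] = 0.0
        sd = scores.std(axis=1)
        safe = sd > 0
        if not safe.all():
            logger.warning("%d constant profile(s) in MI matrix; their MI is 0",
                           int((~safe).sum()))
        corr = np.zeros((len(genes), len(genes)))
        if safe.any():
            sub = np.corrcoef(scores[safe])
            corr[np.ix_(safe, safe)] = np.atleast_2d(sub)
        mi = _mi_from_rho(corr)
    elif estimator == "binned":
        n = len(genes)
        mi = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mi[i, j] = mi[j, i] = binned_mi(values[i], values[j])
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=genes, columns=genes)


def edge_significance(
    expr: ExpressionMatrix, pair: tuple[str, str], B: int, seed: int
) -> float:
    """Permutation p-value of one edge: shuffle one profile B times and
    recompute MI; p = (1 + #{null >= observed}) / (1 + B)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    a, b = pair
    x = expr.data.loc[a].to_numpy()
    y = expr.data.loc[b].to_numpy()
    observed = gaussian_copula_mi(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        null = gaussian_copula_mi(x, rng.permutation(y))
        if null >= observed:
            count += 1
    return (1.0 + count) / (1.0 + B)


def _null_mi_distribution(n_samples: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted permutation null of the copula-MI statistic.

    For tie-free profiles every gene's normal-score vector is the same
    multiset, so the null obtained by shuffling one profile against another
    is identical for all pairs and can be computed once.
    """
    base = ndtri(np.arange(1, n_samples + 1) / (n_samples + 1.0))
    base = (base - base.mean()) / base.std()
    null = np.empty(B)
    for b in range(B):
        perm = base[rng.permutation(n_samples)]
        null[b] = abs(float(np.dot(base, perm)) / n_samples)
    null = _mi_from_rho(null)
    null.sort()
    return null


def _dpi_removal_mask(W: np.ndarray, eps: float) -> np.ndarray:
    """Boolean mask of edges to delete under DPI.

    For every connected triplet, edge (x, z) is marked when
    w(x, z) < (1 - eps) * min(w(x, y), w(y, z)), evaluated on the original
    weights; deletion is simultaneous. Strict inequality keeps exact ties.
    """
    present = W > 0
    remove = np.zeros_like(present)
    n = W.shape[0]
    for y in range(n):
        nb = np.flatnonzero(present[y])
        if nb.size < 2:
            continue
        w = W[y, nb]
        bound = (1.0 - eps) * np.minimum.outer(w, w)
        sub = W[np.ix_(nb, nb)]
        mask = (sub > 0) & (sub < bound)
        if mask.any():
            remove[np.ix_(nb, nb)] |= mask
    return remove


def _dpi_removal_mask_fast(W: np.ndarray, eps: float) -> np.ndarray:
    """Edge-centric DPI identical to :func:`_dpi_removal_mask` but scanning
    each edge's candidate intermediates in descending weight order with
    early exit, compiled with numba when available. On the dense graphs a
    correlated time course produces this is orders of magnitude faster than
    the node-centric scan."""
    try:
        kernel = _get_dpi_kernel()
    except ImportError:  # pragma: no cover - numba is normally present
        return _dpi_removal_mask(W, eps)
    n = W.shape[0]
    # CSR adjacency with per-row neighbors sorted by descending weight
    counts = (W > 0).sum(axis=1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.empty(int(indptr[-1]), dtype=np.int64)
    for x in range(n):
        nb = np.flatnonzero(W[x] > 0)
        order = np.argsort(-W[x, nb], kind="stable")
        indices[indptr[x] : indptr[x + 1]] = nb[order]
    remove = np.zeros((n, n), dtype=np.bool_)
    kernel(np.ascontiguousarray(W, dtype=np.float64), indptr, indices,
           float(eps), remove)
    return remove


_DPI_KERNEL = None


def _get_dpi_kernel():
    global _DPI_KERNEL
    if _DPI_KERNEL is None:
        from numba import njit

        @njit(cache=False)
        def kernel(W, indptr, indices, eps, remove):  # pragma: no cover
            n = W.shape[0]
            f = 1.0 - eps
            for x in range(n):
                for e in range(indptr[x], indptr[x + 1]):
                    z = indices[e]
                    if z <= x:
                        continue
                    wxz = W[x, z]
                    for e2 in range(indptr[x], indptr[x + 1]):
                        y = indices[e2]
                        wxy = W[x, y]
                        if f * wxy <= wxz:
                            break  # sorted descending: no later y qualifies
                        if y != z and f * W[y, z] > wxz:
                            remove[x, z] = True
                            remove[z, x] = True
                            break
            return remove

        _DPI_KERNEL = kernel
    return _DPI_KERNEL


def apply_dpi(net: nx.Graph, eps: float) -> nx.Graph:
    """DPI-prune a weighted graph (edge attribute ``mi``); returns a copy
    whose edge set is a subset of the input's."""
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must lie in [0, 1)")
    nodes = list(net.nodes)
    W = nx.to_numpy_array(net, nodelist=nodes, weight="mi")
    remove = _dpi_removal_mask(W, eps)
    out = net.copy()
    idx = {g: i for i, g in enumerate(nodes)}
    out.remove_edges_from(
        [(u, v) for u, v in net.edges if remove[idx[u], idx[v]]]
    )
    out.graph["dpi_eps"] = eps
    return out


def build_network(
    expr: ExpressionMatrix,
    deg_set: DEGSet | Iterable[str],
    *,
    edge_alpha: float = 0.05,
    B: int = 1000,
    eps: float = 0.25,
    estimator: str = "gaussian_copula",
    seed: int = 0,
) -> nx.Graph:
    """MI network over the DEG union: significance filter then DPI.

    Nodes are every called gene (isolated nodes kept so coverage fractions
    are well defined); an edge survives when its permutation p (shared null,
    see :func:`_null_mi_distribution`) is below ``edge_alpha`` and it is not
    pruned by DPI at tolerance ``eps``. Provenance (estimator, thresholds,
    pre-DPI edge count) is stored in ``G.graph``.
    """
    genes = sorted(deg_set.union() if isinstance(deg_set, DEGSet) else set(deg_set))
    if not genes:
        raise ValueError("empty DEG set: no genes to build a network on")
    if not 0.0 < edge_alpha <= 1.0:
        raise ValueError("edge_alpha must be in (0, 1]")
    mi = mi_matrix(expr, genes, estimator=estimator).to_numpy()
    rng = np.random.default_rng(seed)
    n_samples = expr.n_arrays
    null = _null_mi_distribution(n_samples, B, rng)

    # p(edge) = (1 + #{null >= mi}) / (1 + B) < edge_alpha is equivalent to
    # clearing the matching upper order statistic of the null
    c_max = int(math.ceil(edge_alpha * (1.0 + B) - 1.0)) - 1
    if c_max < 0:
        keep = np.zeros_like(mi, dtype=bool)
    else:
        keep = mi > null[B - 1 - c_max]
    np.fill_diagonal(keep, False)
    W = np.where(keep, mi, 0.0)
    del mi
    n_pre = int(keep.sum() // 2)
    remove = _dpi_removal_mask_fast(W, eps)
    W[remove] = 0.0

    G = nx.Graph()
    G.add_nodes_from(genes)
    iu, ju = np.nonzero(np.triu(W, k=1))
    w_edges = W[iu, ju]
    p_edges = (1.0 + (null.size - np.searchsorted(null, w_edges, side="left"))) / (
        1.0 + null.size
    )
    G.add_edges_from(
        (genes[i], genes[j], {"mi": float(w), "p": float(p)})
        for i, j, w, p in zip(iu.tolist(), ju.tolist(), w_edges, p_edges)
    )
    G.graph.update(
        estimator=estimator,
        edge_alpha=edge_alpha,
        dpi_eps=eps,
        n_permutations=B,
        n_samples=n_samples,
        n_edges_pre_dpi=n_pre,
    )
    logger.info(
        "network: %d nodes, %d edges pre-DPI, %d edges post-DPI",
        G.number_of_nodes(), n_pre, G.number_of_edges(),
    )
    return G
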