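"""Two-class rank-product differential expression with permutation p-values.

For each timepoint the stress and control replicates form all n1 x n2
pairwise log2 fold-changes (K comparison columns). Within each column genes
are ranked (rank 1 = most up- or most down-regulated, ties get average
ranks) and the rank product RP_g = (prod_k r_gk)^(1/K) summarizes how
consistently extreme a gene is. Significance comes from the permutation
null: shuffling gene labels independently within each column makes the null
rank columns independent uniform permutations, so B shuffled datasets yield
a pooled null of B*G rank products against which every observed RP is
scored, with a +1 pseudocount so p-values are never zero. Benjamini-Hochberg
step-up adjustment is applied per timepoint and direction; a gene is called
at a timepoint when its better direction survives the adjusted threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, MissingContrastError

__all__ = [
    "pairwise_log2fc",
    "rank_product",
    "permutation_pvalues",
    "exact_permutation_pvalues",
    "bh_adjust",
    "call_degs",
    "DEGSet",
]

DIRECTIONS = ("up", "down")


def pairwise_log2fc(expr: ExpressionMatrix, timepoint_h: int) -> pd.DataFrame:
    """All stress-vs-control replicate pairings at one timepoint.

    Returns a genes x K frame (K = n_stress * n_control) where column
    ``i*n_control + j`` is stress replicate i minus control replicate j
    (values are log2, so differences are log2 fold-changes).
    """
    design = expr.design
    s = expr.replicate_values(design.stress, timepoint_h)
    c = expr.replicate_values(design.control, timepoint_h)
    n1, n2 = s.shape[1], c.shape[1]
    fc = (s[:, :, None] - c[:, None, :]).reshape(s.shape[0], n1 * n2)
    cols = [f"s{i + 1}c{j + 1}" for i in range(n1) for j in range(n2)]
    return pd.DataFrame(fc, index=expr.gene_ids, columns=cols)


def _rank_columns(fc: np.ndarray, direction: str) -> np.ndarray:
    """Per-column ranks; rank 1 = largest FC for 'up', smallest for 'down';
    ties get average ranks. Invariant to monotone transforms of columns."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    signed = -fc if direction == "up" else fc
    return stats.rankdata(signed, method="average", axis=0)


def rank_product(fc: pd.DataFrame | np.ndarray, direction: str = "up") -> np.ndarray:
    """Geometric mean of a gene's per-comparison ranks (RP >= 1)."""
    values = np.asarray(fc, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("rank product needs a 2-D matrix with >= 2 genes")
    ranks = _rank_columns(values, direction)
    return np.exp(np.log(ranks).mean(axis=1))


def _null_log_rp_pool(
    n_genes: int, n_cols: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Sorted pooled null of B*G log rank products.

    Each permuted dataset re-ranks label-shuffled columns; since shuffling a
    column uniformly permutes its ranks, the null is the geometric mean of
    K independent uniformly permuted rank columns.
    """
    log_ranks = np.log(np.arange(1, n_genes + 1, dtype=float))
    pool = np.empty((n_perm, n_genes))
    for b in range(n_perm):
        acc = log_ranks[rng.permutation(n_genes)].copy()
        for _ in range(n_cols - 1):
            acc += log_ranks[rng.permutation(n_genes)]
        pool[b] = acc / n_cols
    out = pool.ravel()
    out.sort()
    return out


def _pool_pvalues(observed_log_rp: np.ndarray, sorted_pool: np.ndarray) -> np.ndarray:
    count_le = np.searchsorted(sorted_pool, observed_log_rp, side="right")
    return (1.0 + count_le) / (1.0 + sorted_pool.size)


def permutation_pvalues(
    fc: pd.DataFrame | np.ndarray, B: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values (p_up, p_down) from a pooled null of B*G RPs.

    p_g = (1 + #{null RP <= observed RP_g}) / (1 + B*G); monotone
    non-increasing in RP and never zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    values = np.asarray(fc, dtype=float)
    rng = np.random.default_rng(seed)
    pool = _null_log_rp_pool(values.shape[0], values.shape[1], B, rng)
    out = []
    for direction in DIRECTIONS:
        ranks = _rank_columns(values, direction)
        obs = np.log(ranks).mean(axis=1)
        out.append(_pool_pvalues(obs, pool))
    return out[0], out[1]


def exact_permutation_pvalues(
    fc: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive-permutation p-values for small instances.

    Enumerating all (G!)^K tuples of within-column label shuffles, each
    K-tuple of rank values appears ((G-1)!)^K times per gene, so the pooled
    null reduces to the G^K cross product of the per-column rank values:
    p_g = #{null rank product <= RP_g} / G^K. Feasible for G^K up to a few
    million.
    """
    values = np.asarray(fc, dtype=float)
    G, K = values.shape
    if G**K > 20_000_000:
        raise ValueError("exhaustive enumeration infeasible for this G, K")
    out = []
    for direction in DIRECTIONS:
        ranks = _rank_columns(values, direction)
        obs_prod = ranks.prod(axis=1)
        null = reduce(np.multiply.outer, [ranks[:, k] for k in range(K)])
        null = null.ravel().copy()
        null.sort()
        out.append(np.searchsorted(null, obs_prod, side="right") / float(G**K))
    return out[0], out[1]


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr.copy()
    return stats.false_discovery_control(arr, method="bh")


@dataclass
class DEGSet:
    """Per-timepoint rank-product calls.

    ``table`` has one row per gene x timepoint with columns gene_id,
    timepoint_h, log2fc, rp_up, rp_down, p_up, p_down, padj, direction
    (direction is 'none' for uncalled rows).
    """

    table: pd.DataFrame
    alpha: float

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "none"]

    def union(self) -> frozenset[str]:
        """Genes called in at least one timepoint."""
        return frozenset(self.called["gene_id"])

    def genes_at(self, timepoint_h: int, direction: str | None = None) -> frozenset[str]:
        sub = self.called[self.called["timepoint_h"] == int(timepoint_h)]
        if direction is not None:
            sub = sub[sub["direction"] == direction]
        return frozenset(sub["gene_id"])

    def counts(self) -> pd.DataFrame:
        """Per-timepoint up/down/total table (the Table-1 layout)."""
        rows = []
        for tp in sorted(self.table["timepoint_h"].unique()):
            up = len(self.genes_at(tp, "up"))
            down = len(self.genes_at(tp, "down"))
            rows.append({"timepoint_h": int(tp), "up": up, "down": down,
                         "total": up + down})
        return pd.DataFrame(rows).set_index("timepoint_h")

    def log2fc_at(self, timepoint_h: int, genes=None) -> pd.Series:
        sub = self.table[self.table["timepoint_h"] == int(timepoint_h)]
        series = sub.set_index("gene_id")["log2fc"]
        if genes is not None:
            series = series.loc[[g for g in genes if g in series.index]]
        return series


def call_degs(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    *,
    timepoints: list[int] | None = None,
    include_time0: bool = False,
) -> DEGSet:
    """Call differentially expressed genes per timepoint.

    A gene is called up at a timepoint if its BH-adjusted up-direction
    permutation p is below ``alpha`` (analogously down); when both
    directions pass, the smaller adjusted p wins with ties going to 'up'.
    The 0 h timepoint (matched-control contrast that is null by design) is
    excluded unless ``include_time0``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    design = expr.design
    if timepoints is None:
        timepoints = [
            t
            for t in design.timepoints_h
            if (include_time0 or t != 0) and not (design.shared_time0 and t == design.timepoints_h[0])
        ]
    if not timepoints:
        raise ValueError("no timepoints to test")

    rng = np.random.default_rng(seed)
    pool_cache: dict[tuple[int, int], np.ndarray] = {}
    frames = []
    for tp in timepoints:
        fc = pairwise_log2fc(expr, tp)
        values = fc.to_numpy()
        G, K = values.shape
        if (G, K) not in pool_cache:
            pool_cache[(G, K)] = _null_log_rp_pool(G, K, B, rng)
        pool = pool_cache[(G, K)]
        rp = {}
        padj = {}
        p = {}
        for direction in DIRECTIONS:
            ranks = _rank_columns(values, direction)
            log_rp = np.log(ranks).mean(axis=1)
            rp[direction] = np.exp(log_rp)
            p[direction] = _pool_pvalues(log_rp, pool)
            padj[direction] = bh_adjust(p[direction])
        up_hit = padj["up"] < alpha
        down_hit = padj["down"] < alpha
        direction = np.full(G, "none", dtype=object)
        direction[up_hit] = "up"
        direction[down_hit & ~up_hit] = "down"
        both = up_hit & down_hit
        direction[both & (padj["down"] < padj["up"])] = "down"
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": fc.index,
                    "timepoint_h": int(tp),
                    "log2fc": values.mean(axis=1),
                    "rp_up": rp["up"],
                    "rp_down": rp["down"],
                    "p_up": p["up"],
                    "p_down": p["down"],
                    "padj": np.minimum(padj["up"], padj["down"]),
                    "direction": direction,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return DEGSet(table=table, alpha=alpha)
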