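"""Functional-category enrichment statistics.

Two complementary tests over a flat gene -> category annotation (no
ontology-graph roll-up; categories are plain sets, so the code is
annotation-agnostic):

* SEA-style over-representation: one exact hypergeometric upper-tail test
  per category on a fixed query set against a background, BH-adjusted, with
  a stringent default FDR of 0.001.
* PageMan-style per-timepoint enrichment: a two-sided Wilcoxon rank-sum
  test of the in-category log2 fold-changes against all remaining genes,
  BH-adjusted across categories, then mapped to signed z-scores where
  adjusted p > 0.05 becomes exactly 0 and |z| is capped at 4 (the heatmap
  display scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .rankprod import bh_adjust

__all__ = [
    "AnnotationMap",
    "hypergeom_over",
    "sea_enrichment",
    "pageman_enrichment",
    "p_to_z",
]

logger = logging.getLogger(__name__)

#: Display cap for signed enrichment z-scores.
Z_CAP = 4.0

#: Above this population size the exact integer sum switches to scipy's
#: hypergeometric survival function (the exact sum is kept where the
#: 1e-12-level agreement matters and big-integer work stays cheap).
_EXACT_N_LIMIT = 2000


@dataclass
class AnnotationMap:
    """Flat gene -> categories mapping plus category display names."""

    gene_to_cats: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_to_cats = {
            g: frozenset(cats) for g, cats in self.gene_to_cats.items() if cats
        }
        members: dict[str, set[str]] = {}
        for g, cats in self.gene_to_cats.items():
            for c in cats:
                members.setdefault(c, set()).add(g)
        self._members = {c: frozenset(gs) for c, gs in members.items()}

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AnnotationMap":
        """Build from a tidy (gene_id, category_id[, category_name]) frame."""
        g2c: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in table.itertuples(index=False):
            g2c.setdefault(str(row.gene_id), set()).add(str(row.category_id))
            if hasattr(row, "category_name"):
                names[str(row.category_id)] = str(row.category_name)
        return cls({g: frozenset(c) for g, c in g2c.items()}, names)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(self._members)

    def members(self, category: str) -> frozenset[str]:
        return self._members.get(category, frozenset())

    def name(self, category: str) -> str:
        return self.names.get(category, category)


def hypergeom_over(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members in a size-``n`` draw without replacement from
    a population of ``N`` genes of which ``K`` are in the category.
    Computed as an exact integer sum for moderate N.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    if k <= max(0, n + K - N):
        return 1.0
    if N <= _EXACT_N_LIMIT:
        num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
        return float(Fraction(num, comb(N, n)))
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def p_to_z(padj: float, direction: str, *, alpha: float = 0.05, cap: float = Z_CAP) -> float:
    """Signed display z-score for an adjusted p-value.

    Adjusted p above ``alpha`` maps to exactly 0; otherwise
    z = Phi^-1(1 - padj/2), positive for over- and negative for
    under-representation, capped at +-``cap``.
    """
    if not 0.0 <= padj <= 1.0:
        raise ValueError("padj must lie in [0, 1]")
    if padj > alpha:
        return 0.0
    z = float(ndtri(1.0 - padj / 2.0))
    z = min(z, cap)
    if direction == "under":
        return -z
    if direction == "over":
        return z
    return 0.0


def sea_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    ann: AnnotationMap,
    fdr: float = 0.001,
) -> pd.DataFrame:
    """Singular enrichment analysis: hypergeometric over-representation of
    every category with at least one query hit, BH-adjusted.

    Returns a frame with columns category, name, k, K, n, N, p, padj,
    direction, z, significant; sorted by adjusted p. The query must be a
    subset of the background.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query is not a subset of the background, e.g. {extra}")
    N, n = len(background), len(query)
    rows = []
    for cat in sorted(ann.categories):
        members_bg = ann.members(cat) & background
        k = len(members_bg & query)
        if k == 0:
            continue
        K = len(members_bg)
        p = hypergeom_over(k, K, n, N)
        rows.append({"category": cat, "name": ann.name(cat), "k": k, "K": K,
                     "n": n, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(
            columns=["category", "name", "k", "K", "n", "N", "p", "padj",
                     "direction", "z", "significant"]
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = "over"
    out["z"] = [p_to_z(q, "over") for q in out["padj"]]
    out["significant"] = out["padj"] < fdr
    return out.sort_values(["padj", "category"], kind="stable").reset_index(drop=True)


def pageman_enrichment(
    log2fc: pd.Series,
    ann: AnnotationMap,
    *,
    min_size: int = 5,
    z_cap: float = Z_CAP,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-category Wilcoxon rank-sum enrichment of fold-change values.

    ``log2fc`` maps gene id -> log2 fold-change for one timepoint. Each
    category with at least ``min_size`` members among the input genes is
    tested two-sided against all remaining genes (normal approximation with
    tie and continuity correction); smaller categories are skipped with a
    log entry. Direction is 'over' when the in-category median exceeds the
    rest. Returns category, name, n_in, n_out, median_in, median_out, p,
    padj, direction, z.
    """
    if len(log2fc) < 2:
        raise ValueError("need at least two genes")
    values = log2fc.astype(float)
    genes = set(values.index)
    rows = []
    for cat in sorted(ann.categories):
        members = ann.members(cat) & genes
        if len(members) < min_size:
            logger.debug("category %s below min_size (%d < %d); skipped",
                         cat, len(members), min_size)
            continue
        rest = genes - members
        if not rest:
            continue
        x = values.loc[sorted(members)].to_numpy()
        y = values.loc[sorted(rest)].to_numpy()
        # exact enumeration is feasible only for small categories; categories
        # are typically in the hundreds, where the tie- and continuity-
        # corrected normal approximation is accurate
        how = method
        if method == "auto":
            how = "exact" if min(len(x), len(y)) <= 25 and len(x) + len(y) <= 60 else "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", use_continuity=True, method=how
        )
        med_in, med_out = float(np.median(x)), float(np.median(y))
        rows.append({
            "category": cat,
            "name": ann.name(cat),
            "n_in": len(members),
            "n_out": len(rest),
            "median_in": med_in,
            "median_out": med_out,
            "p": min(float(res.pvalue), 1.0),
            "direction": "over" if med_in > med_out else "under",
        })
    if not rows:
        return pd.DataFrame(
            columns=["category", "name", "n_in", "n_out", "median_in",
                     "median_out", "p", "padj", "direction", "z"]
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["z"] = [
        p_to_z(q, d, cap=z_cap) for q, d in zip(out["padj"], out["direction"])
    ]
    return out.sort_values(["padj", "category"], kind="stable").reset_index(drop=True)


def pageman_z_matrix(
    fc_by_timepoint: Mapping[int, pd.Series],
    ann: AnnotationMap,
    *,
    min_size: int = 5,
    z_cap: float = Z_CAP,
) -> pd.DataFrame:
    """Categories x timepoints matrix of signed z-scores (the numeric
    content of a PageMan heatmap); untested cells are 0."""
    cols = {}
    for tp in sorted(fc_by_timepoint):
        res = pageman_enrichment(
            fc_by_timepoint[tp], ann, min_size=min_size, z_cap=z_cap
        )
        cols[int(tp)] = res.set_index("category")["z"] if len(res) else pd.Series(dtype=float)
    out = pd.DataFrame(cols).fillna(0.0)
    out.index.name = "category"
    return out.sort_index()
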