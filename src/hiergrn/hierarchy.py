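"""Three-tier decomposition of the pruned MI network.

The top tier ("superhubs") are differentially expressed transcription
factors adjacent to between 3 and 15 hub genes; hubs are the high-degree
nodes of the DPI-pruned network (top 1% by degree, ties included, by
default, since no operational hub definition is fixed by convention); the
third tier ("terminals") are the remaining neighbors of hubs that are
themselves neither superhub nor hub. Tier labels take precedence in that
order, so the tiers are disjoint layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "identify_hubs",
    "identify_superhubs",
    "assign_tiers",
    "extract_subnetwork",
    "TierAssignment",
]


@dataclass(frozen=True)
class TierAssignment:
    """Disjoint superhub / hub / terminal partition with adjacency lists.

    ``coverage`` is the fraction of network genes (the DEG union) assigned
    to any tier; ``superhub_links`` maps each superhub to its adjacent kept
    hubs, ``hub_links`` each kept hub to its terminal neighbors.
    """

    superhubs: frozenset[str]
    hubs: frozenset[str]
    terminals: frozenset[str]
    superhub_links: Mapping[str, tuple[str, ...]]
    hub_links: Mapping[str, tuple[str, ...]]
    coverage: float

    def __post_init__(self) -> None:
        self.validate()

    @property
    def assigned(self) -> frozenset[str]:
        return self.superhubs | self.hubs | self.terminals

    def tier_of(self, gene: str) -> str:
        if gene in self.superhubs:
            return "superhub"
        if gene in self.hubs:
            return "hub"
        if gene in self.terminals:
            return "terminal"
        return "unassigned"

    def validate(self) -> None:
        if (
            self.superhubs & self.hubs
            or self.superhubs & self.terminals
            or self.hubs & self.terminals
        ):
            raise ValueError("tier sets must be pairwise disjoint")
        for s in self.superhubs:
            if s not in self.superhub_links:
                raise ValueError(f"superhub {s!r} has no hub links")
        hub_parents: set[str] = set()
        for s, hs in self.superhub_links.items():
            hub_parents.update(hs)
        for h in self.hubs:
            if h not in hub_parents:
                raise ValueError(f"hub {h!r} is adjacent to no superhub")
        term_parents: set[str] = set()
        for h, ts in self.hub_links.items():
            term_parents.update(ts)
        for t in self.terminals:
            if t not in term_parents:
                raise ValueError(f"terminal {t!r} is adjacent to no hub")


def identify_hubs(
    net: nx.Graph,
    *,
    degree_min: int | None = None,
    top_fraction: float = 0.01,
) -> frozenset[str]:
    """Hub candidates by degree on the DPI-pruned network.

    Either an absolute degree floor (``degree_min``) or the top
    ``top_fraction`` of nodes by degree with ties included (default 1%).
    Isolated nodes are never hubs; an empty network gives an empty set.
    """
    degrees = dict(net.degree())
    if not degrees:
        return frozenset()
    if degree_min is not None:
        if degree_min < 1:
            raise ValueError("degree_min must be >= 1")
        return frozenset(n for n, d in degrees.items() if d >= degree_min)
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    positive = sorted((d for d in degrees.values() if d > 0), reverse=True)
    if not positive:
        return frozenset()
    k = max(1, math.ceil(top_fraction * net.number_of_nodes()))
    threshold = positive[min(k, len(positive)) - 1]
    return frozenset(n for n, d in degrees.items() if d >= threshold and d > 0)


def identify_superhubs(
    net: nx.Graph,
    tf_ids: Iterable[str],
    hubs: Iterable[str],
    k_min: int = 3,
    k_max: int = 15,
) -> frozenset[str]:
    """TFs adjacent to between ``k_min`` and ``k_max`` hub candidates.

    The search runs over the TF list only; a gene that qualifies is a
    superhub and must afterwards be removed from the hub set by the caller
    (see :func:`assign_tiers`, which does this).
    """
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    hubs = set(hubs)
    out = set()
    for tf in set(tf_ids):
        if tf not in net:
            continue
        n_hub_neighbors = sum(1 for nb in net[tf] if nb in hubs)
        if k_min <= n_hub_neighbors <= k_max:
            out.add(tf)
    return frozenset(out)


def assign_tiers(
    net: nx.Graph,
    superhubs: Iterable[str],
    hubs: Iterable[str],
) -> TierAssignment:
    """Partition network genes into the three tiers.

    Precedence superhub > hub > terminal: superhubs are removed from the
    hub set; hubs are kept only when adjacent to at least one superhub;
    terminals are neighbors of kept hubs that are neither superhubs nor hub
    candidates (a dropped hub candidate stays unassigned rather than
    becoming a terminal). Coverage is measured against all network nodes,
    i.e. the DEG union the network was built on.
    """
    superhubs = frozenset(s for s in superhubs if s in net)
    hub_candidates = set(hubs) - superhubs
    kept = {h for h in hub_candidates if h in net and any(nb in superhubs for nb in net[h])}
    superhub_links = {
        s: tuple(sorted(set(net[s]) & kept)) for s in sorted(superhubs)
    }
    excluded = superhubs | hub_candidates
    hub_links = {
        h: tuple(sorted(nb for nb in net[h] if nb not in excluded))
        for h in sorted(kept)
    }
    terminals = frozenset(t for ts in hub_links.values() for t in ts)
    n_nodes = net.number_of_nodes()
    assigned = len(superhubs) + len(kept) + len(terminals)
    coverage = assigned / n_nodes if n_nodes else 0.0
    return TierAssignment(
        superhubs=superhubs,
        hubs=frozenset(kept),
        terminals=terminals,
        superhub_links=superhub_links,
        hub_links=hub_links,
        coverage=coverage,
    )


def extract_subnetwork(
    tiers: TierAssignment,
    superhub_id: str,
    net: nx.Graph | None = None,
) -> nx.Graph:
    """Superhub-centered subnetwork: the superhub, its hubs, and those
    hubs' terminals, with a ``tier`` node attribute.

    When the source network is supplied its edge attributes (MI weight,
    p-value) are copied onto the subnetwork edges.
    """
    if superhub_id not in tiers.superhubs:
        raise KeyError(f"unknown superhub {superhub_id!r}")
    hubs = tiers.superhub_links[superhub_id]
    if not hubs:
        raise ValueError(f"superhub {superhub_id!r} has an empty hub list")
    sub = nx.Graph()
    sub.add_node(superhub_id, tier="superhub")
    for h in hubs:
        sub.add_node(h, tier="hub")
        sub.add_edge(superhub_id, h)
        for t in tiers.hub_links.get(h, ()):
            sub.add_node(t, tier="terminal")
            sub.add_edge(h, t)
    if net is not None:
        for u, v in sub.edges:
            if net.has_edge(u, v):
                sub.edges[u, v].update(net.edges[u, v])
    sub.graph["superhub"] = superhub_id
    return sub
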