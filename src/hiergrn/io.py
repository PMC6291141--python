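"""Readers and writers for the pipeline's interchange formats.

Plain-text formats throughout: expression matrices as TSV with a
``condition:timepoint:replicate`` header, gene lists as one id per line,
annotations as tidy TSV, networks as SIF (and GraphML with weight/p/tier
attributes), configuration and planted truths as YAML. All writers are
deterministic (lexicographic ordering, fixed float formatting) so repeated
runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .hierarchy import TierAssignment
from .simulate import Effect, PlantedTruth

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_list",
    "write_gene_list",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "write_sif",
    "read_sif",
    "write_graphml",
    "write_tiers_tsv",
    "write_truth_yaml",
    "read_truth_yaml",
]

FLOAT_FORMAT = "%.6g"


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    """Expression TSV: first column ``gene_id``, then one column per array
    headed ``condition:timepoint:replicate``."""
    headers = [f"{c}:{int(t)}:{int(r)}" for c, t, r in expr.data.columns]
    frame = expr.data.copy()
    frame.columns = headers
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read and validate an expression TSV (see :func:`write_expression_tsv`).

    Raises on duplicate gene ids, NA or non-numeric cells (with a row/column
    report) and on array headers that do not parse or do not cover a full
    design grid.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    arrays = []
    for col in frame.columns:
        parts = str(col).split(":")
        if len(parts) != 3:
            raise ValueError(
                f"malformed array header {col!r}: expected condition:timepoint:replicate"
            )
        cond, tp, rep = parts
        try:
            arrays.append((cond, int(tp), int(rep)))
        except ValueError as err:
            raise ValueError(f"malformed array header {col!r}: {err}") from None
    values = frame.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"missing or non-numeric cell at gene {frame.index[i]!r}, "
            f"array {frame.columns[j]!r}"
        )
    return ExpressionMatrix.from_arrays(list(frame.index), arrays, values.to_numpy())


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> tuple[str, ...]:
    lines = Path(path).read_text().splitlines()
    return tuple(g.strip() for g in lines if g.strip())


def write_annotation_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "category_id"}
    if not required <= set(table.columns):
        raise ValueError(
            f"annotation table needs columns {sorted(required)}, got {list(table.columns)}"
        )
    return table


def _sorted_edges(net: nx.Graph) -> list[tuple[str, str]]:
    return sorted((min(u, v), max(u, v)) for u, v in net.edges)


def write_sif(net: nx.Graph, path: str | Path, relation: str = "mi") -> None:
    """SIF export: ``idA <TAB> mi <TAB> idB``, one undirected edge once,
    lexicographically ordered for determinism."""
    with open(path, "w") as fh:
        for u, v in _sorted_edges(net):
            fh.write(f"{u}\t{relation}\t{v}\n")


def read_sif(path: str | Path) -> nx.Graph:
    G = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed SIF line: {line!r}")
        G.add_edge(parts[0], parts[2])
    return G


def write_graphml(
    net: nx.Graph, path: str | Path, tiers: TierAssignment | None = None
) -> None:
    """GraphML export with ``mi``/``p`` edge attributes and, when a tier
    assignment is given, a ``tier`` node attribute."""
    G = net.copy()
    G.graph.clear()  # provenance dicts are not GraphML-serializable
    if tiers is not None:
        for node in G.nodes:
            G.nodes[node]["tier"] = tiers.tier_of(node)
    nx.write_graphml(G, path, named_key_ids=True)


def write_tiers_tsv(tiers: TierAssignment, path: str | Path) -> None:
    """Tier table: gene_id, tier, parents (comma-joined, sorted)."""
    parent_map: dict[str, set[str]] = {}
    for s, hs in tiers.superhub_links.items():
        for h in hs:
            parent_map.setdefault(h, set()).add(s)
    for h, ts in tiers.hub_links.items():
        for t in ts:
            parent_map.setdefault(t, set()).add(h)
    with open(path, "w") as fh:
        fh.write("gene_id\ttier\tparents\n")
        for tier in ("superhub", "hub", "terminal"):
            members = {
                "superhub": tiers.superhubs,
                "hub": tiers.hubs,
                "terminal": tiers.terminals,
            }[tier]
            for g in sorted(members):
                parents = ",".join(sorted(parent_map.get(g, ())))
                fh.write(f"{g}\t{tier}\t{parents}\n")


def write_truth_yaml(truth: PlantedTruth, path: str | Path) -> None:
    """Planted-truth YAML: tier memberships, edges, effects and noise level.

    The per-timepoint delta table is stored inline so a reloaded truth
    supports exact fidelity checks.
    """
    doc = {
        "superhub_ids": list(truth.superhub_ids),
        "hub_ids": list(truth.hub_ids),
        "terminal_ids": list(truth.terminal_ids),
        "independent_ids": list(truth.independent_ids),
        "background_ids": list(truth.background_ids),
        "edges": [[p, c] for p, c in truth.edges],
        "weights": [[p, c, float(w)] for (p, c), w in sorted(truth.weights.items())],
        "noise_sd": truth.noise_sd,
        "hubs_per_super_range": list(truth.hubs_per_super_range),
        "effect": {
            g: {"size": e.size, "timepoints_h": list(e.timepoints_h), "sign": e.sign}
            for g, e in truth.effect.items()
        },
        "delta": {
            "timepoints_h": [int(c) for c in truth.delta.columns],
            "genes": {
                g: [float(x) for x in truth.delta.loc[g]]
                for g in truth.delta.index
            },
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth_yaml(path: str | Path) -> PlantedTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    delta = pd.DataFrame.from_dict(
        doc["delta"]["genes"], orient="index", columns=doc["delta"]["timepoints_h"]
    )
    affected = (
        list(doc["superhub_ids"]) + list(doc["hub_ids"])
        + list(doc["terminal_ids"]) + list(doc["independent_ids"])
    )
    delta = delta.reindex(affected)
    return PlantedTruth(
        superhub_ids=tuple(doc["superhub_ids"]),
        hub_ids=tuple(doc["hub_ids"]),
        terminal_ids=tuple(doc["terminal_ids"]),
        independent_ids=tuple(doc["independent_ids"]),
        background_ids=tuple(doc["background_ids"]),
        edges=tuple((p, c) for p, c in doc["edges"]),
        effect={
            g: Effect(size=e["size"], timepoints_h=tuple(e["timepoints_h"]),
                      sign=e["sign"])
            for g, e in doc["effect"].items()
        },
        delta=delta,
        noise_sd=doc["noise_sd"],
        weights={(p, c): float(w) for p, c, w in doc.get("weights", [])},
        hubs_per_super_range=tuple(doc["hubs_per_super_range"]),
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
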