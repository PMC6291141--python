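"""End-to-end pipeline: simulate -> DEG -> network -> tiers -> enrichment.

A single :class:`PipelineConfig` houses every numeric threshold (DEG alpha,
permutation counts, edge alpha, DPI tolerance, hub rule, superhub degree
range 3..15, SEA FDR 0.001, PageMan minimum category size and z cap). The
runner executes the stages in order, writes every interchange file, and
produces a manifest (seeds, thresholds, per-stage counts in the
per-timepoint up/down layout, file hashes) that is byte-identical across
runs with the same config and seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import AnnotationMap, pageman_z_matrix, sea_enrichment
from .expression import ExpressionMatrix, StudyDesign
from .hierarchy import assign_tiers, identify_hubs, identify_superhubs
from .io import (
    FLOAT_FORMAT,
    write_annotation_tsv,
    write_expression_tsv,
    write_gene_list,
    write_graphml,
    write_json,
    write_sif,
    write_tiers_tsv,
    write_truth_yaml,
)
from .network import build_network
from .rankprod import call_degs
from .simulate import (
    STUDY_SCALE,
    PlantedTruth,
    generate_annotations,
    generate_planted_network,
    select_tf_ids,
    simulate_expression,
)

__all__ = ["SimulationConfig", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Scale and noise of the synthetic study (defaults: published scale)."""

    n_super: int = STUDY_SCALE["n_super"]
    hubs_per_super: tuple[int, int] = STUDY_SCALE["hubs_per_super"]
    terminals_per_hub: tuple[int, int] = STUDY_SCALE["terminals_per_hub"]
    n_background: int = STUDY_SCALE["n_background"]
    n_hubs: int | None = STUDY_SCALE["n_hubs"]
    n_independent: int = STUDY_SCALE["n_independent"]
    noise_sd: float = 0.3
    n_decoy_tfs_independent: int = 100
    n_decoy_tfs_background: int = 50
    shared_time0: bool = False

    @classmethod
    def small(cls, **overrides) -> "SimulationConfig":
        """A miniature layout for quick runs and tests."""
        base = dict(
            n_super=3,
            hubs_per_super=(3, 4),
            terminals_per_hub=(20, 30),
            n_background=600,
            n_hubs=7,
            n_independent=80,
            n_decoy_tfs_independent=10,
            n_decoy_tfs_background=5,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the five analysis stages."""

    alpha_deg: float = 0.05
    perms_deg: int = 1000
    edge_alpha: float = 0.05
    perms_edge: int = 1000
    dpi_eps: float = 0.25
    hub_top_fraction: float = 0.01
    hub_degree_min: int | None = None
    k_min: int = 3
    k_max: int = 15
    fdr_sea: float = 0.001
    pageman_min_size: int = 5
    z_cap: float = 4.0
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_deg <= 1.0:
            raise ValueError("alpha_deg must be in [0, 1]")
        if not 0.0 < self.edge_alpha <= 1.0:
            raise ValueError("edge_alpha must be in (0, 1]")
        if not 0.0 <= self.dpi_eps < 1.0:
            raise ValueError("dpi_eps must be in [0, 1)")
        if self.perms_deg < 1 or self.perms_edge < 1:
            raise ValueError("permutation counts must be >= 1")
        if self.k_min > self.k_max or self.k_min < 1:
            raise ValueError("need 1 <= k_min <= k_max")
        if not 0.0 < self.fdr_sea <= 1.0:
            raise ValueError("fdr_sea must be in (0, 1]")

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["simulation"] = asdict(self.simulation)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        sim = doc.pop("simulation", {})
        if isinstance(sim, SimulationConfig):
            sim_cfg = sim
        else:
            sim = dict(sim)
            for key in ("hubs_per_super", "terminals_per_hub"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            sim_cfg = SimulationConfig(**sim)
        return cls(simulation=sim_cfg, **doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds derived from the master seed (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    *,
    expr: ExpressionMatrix | None = None,
    tf_ids: tuple[str, ...] | None = None,
    annotation: pd.DataFrame | None = None,
    truth: PlantedTruth | None = None,
) -> dict:
    """Run all stages and write outputs plus a deterministic manifest.

    Without an ``expr`` argument the synthetic stage generates the inputs
    (planted truth, expression matrix, TF list, annotation table) from
    ``config.simulation``. Supplied inputs skip simulation; a TF list is
    then required. Returns the manifest dict (also written as
    ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ("truth", "expression", "tfs", "annotation", "deg", "network"),
        _spawn_seeds(config.seed, 6),
    ))
    manifest: dict = {
        "hiergrn_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "stages": {},
        "files": {},
    }

    # -- stage 1: inputs ---------------------------------------------------
    sim = config.simulation
    if expr is None:
        logger.info("stage simulate: generating planted truth and expression")
        try:
            if truth is None:
                truth = generate_planted_network(
                    sim.n_super,
                    sim.hubs_per_super,
                    sim.terminals_per_hub,
                    sim.n_background,
                    seeds["truth"],
                    n_hubs=sim.n_hubs,
                    n_independent=sim.n_independent,
                    noise_sd=sim.noise_sd,
                )
            design = StudyDesign(shared_time0=sim.shared_time0)
            expr = simulate_expression(truth, design, seeds["expression"])
            if tf_ids is None:
                tf_ids = select_tf_ids(
                    truth,
                    seeds["tfs"],
                    n_decoy_independent=sim.n_decoy_tfs_independent,
                    n_decoy_background=sim.n_decoy_tfs_background,
                )
            if annotation is None:
                annotation = generate_annotations(truth, seeds["annotation"])
            write_truth_yaml(truth, out / "truth.yaml")
            write_expression_tsv(expr, out / "expression.tsv")
        except Exception as err:
            raise RuntimeError(f"stage simulate failed: {err}") from err
    if tf_ids is None:
        raise ValueError("a TF list is required when expression data is supplied")
    write_gene_list(tf_ids, out / "tfs.txt")
    if annotation is not None:
        write_annotation_tsv(annotation, out / "annotation.tsv")
    manifest["stages"]["input"] = {
        "n_genes": expr.n_genes,
        "n_arrays": expr.n_arrays,
        "n_tfs": len(tf_ids),
        "simulated": truth is not None,
    }

    # -- stage 2: rank-product DEG calling ---------------------------------
    try:
        logger.info("stage deg: rank product at alpha=%g, B=%d",
                    config.alpha_deg, config.perms_deg)
        degs = call_degs(
            expr, alpha=config.alpha_deg, B=config.perms_deg, seed=seeds["deg"]
        )
    except Exception as err:
        raise RuntimeError(f"stage deg failed: {err}") from err
    degs.table.to_csv(out / "deg.tsv", sep="\t", index=False,
                      float_format=FLOAT_FORMAT)
    counts = degs.counts()
    counts.to_csv(out / "deg_counts.tsv", sep="\t")
    manifest["stages"]["deg"] = {
        "n_called_union": len(degs.union()),
        "per_timepoint": {
            str(tp): {"up": int(row["up"]), "down": int(row["down"]),
                      "total": int(row["total"])}
            for tp, row in counts.iterrows()
        },
    }
    logger.info("stage deg: %d genes called at >=1 timepoint", len(degs.union()))

    # -- stage 3: MI network ----------------------------------------------
    try:
        net = build_network(
            expr,
            degs,
            edge_alpha=config.edge_alpha,
            B=config.perms_edge,
            eps=config.dpi_eps,
            seed=seeds["network"],
        )
    except Exception as err:
        raise RuntimeError(f"stage network failed: {err}") from err
    write_sif(net, out / "network.sif")
    manifest["stages"]["network"] = {
        "n_nodes": net.number_of_nodes(),
        "n_edges_pre_dpi": net.graph["n_edges_pre_dpi"],
        "n_edges": net.number_of_edges(),
    }

    # -- stage 4: tier decomposition ---------------------------------------
    try:
        hubs = identify_hubs(
            net,
            degree_min=config.hub_degree_min,
            top_fraction=config.hub_top_fraction,
        )
        superhubs = identify_superhubs(
            net, tf_ids, hubs, k_min=config.k_min, k_max=config.k_max
        )
        tiers = assign_tiers(net, superhubs, hubs)
    except Exception as err:
        raise RuntimeError(f"stage tiers failed: {err}") from err
    write_tiers_tsv(tiers, out / "tiers.tsv")
    write_graphml(net, out / "network.graphml", tiers)
    manifest["stages"]["tiers"] = {
        "n_hub_candidates": len(hubs),
        "n_superhubs": len(tiers.superhubs),
        "n_hubs": len(tiers.hubs),
        "n_terminals": len(tiers.terminals),
        "coverage": round(tiers.coverage, 6),
    }
    logger.info(
        "stage tiers: %d superhubs / %d hubs / %d terminals (coverage %.3f)",
        len(tiers.superhubs), len(tiers.hubs), len(tiers.terminals),
        tiers.coverage,
    )

    # -- stage 5: enrichment ----------------------------------------------
    manifest["stages"]["enrichment"] = {}
    if annotation is not None:
        try:
            ann = AnnotationMap.from_table(annotation)
            background = set(expr.gene_ids)
            sea = sea_enrichment(
                set(degs.union()), background, ann, fdr=config.fdr_sea
            )
            sea.to_csv(out / "sea.tsv", sep="\t", index=False,
                       float_format=FLOAT_FORMAT)
            called_tps = sorted(degs.table["timepoint_h"].unique())
            fc_by_tp = {
                int(tp): degs.log2fc_at(tp, genes=degs.genes_at(tp))
                for tp in called_tps
            }
            fc_by_tp = {tp: s for tp, s in fc_by_tp.items() if len(s) >= 2}
            zmat = pageman_z_matrix(
                fc_by_tp, ann, min_size=config.pageman_min_size,
                z_cap=config.z_cap,
            )
            zmat.to_csv(out / "pageman_z.tsv", sep="\t",
                        float_format=FLOAT_FORMAT)
        except Exception as err:
            raise RuntimeError(f"stage enrich failed: {err}") from err
        manifest["stages"]["enrichment"] = {
            "n_sea_tested": int(len(sea)),
            "n_sea_significant": int(sea["significant"].sum()) if len(sea) else 0,
            "n_pageman_categories": int(zmat.shape[0]),
            "n_pageman_nonzero": int((zmat.to_numpy() != 0).sum()),
        }

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["files"][path.name] = _sha256(path)
    write_json(manifest, out / "manifest.json")
    return manifest
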