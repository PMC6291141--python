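"""Benchmark harness: scoring the pipeline against planted ground truth.

These functions regenerate study-scale synthetic data, run the analysis
stages with the package defaults, and measure recovery and calibration
quantities (superhub precision/recall, tier coverage, null false-call rate,
MI estimator error, DPI behavior, Wilcoxon type-I rate). They are used by
the acceptance script and the acceptance tests; all randomness is seeded.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationMap, pageman_enrichment
from .expression import ExpressionMatrix, StudyDesign
from .hierarchy import assign_tiers, identify_hubs, identify_superhubs
from .network import apply_dpi, build_network, gaussian_copula_mi
from .pipeline import PipelineConfig
from .rankprod import call_degs
from .simulate import study_scale_truth, select_tf_ids, simulate_expression

__all__ = [
    "study_scale_recovery",
    "null_false_call_rate",
    "mi_closed_form_error",
    "dpi_markov_removal_rate",
    "dpi_oracle_agreement",
    "wilcoxon_null_type1",
]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def study_scale_recovery(seed: int, config: PipelineConfig | None = None) -> dict:
    """Full recovery benchmark at the published study's scale.

    Generates a planted 9-superhub / 18-hub / ~3,000-terminal truth over a
    50,000-gene background (noise sd 0.3 log2), runs DEG calling, network
    inference and tier decomposition with the default thresholds, and scores
    the recovered top tier and coverage against the truth.
    """
    cfg = config or PipelineConfig()
    s_truth, s_expr, s_deg, s_net, s_tfs = _seeds(seed, 5)
    truth = study_scale_truth(seed=s_truth)
    expr = simulate_expression(truth, StudyDesign(), s_expr)
    degs = call_degs(expr, alpha=cfg.alpha_deg, B=cfg.perms_deg, seed=s_deg)
    called = degs.union()
    net = build_network(
        expr, degs, edge_alpha=cfg.edge_alpha, B=cfg.perms_edge,
        eps=cfg.dpi_eps, seed=s_net,
    )
    tf_ids = select_tf_ids(truth, s_tfs)
    hubs = identify_hubs(
        net, degree_min=cfg.hub_degree_min, top_fraction=cfg.hub_top_fraction
    )
    superhubs = identify_superhubs(net, tf_ids, hubs, cfg.k_min, cfg.k_max)
    tiers = assign_tiers(net, superhubs, hubs)
    true_supers = set(truth.superhub_ids)
    tp = len(superhubs & true_supers)
    return {
        "n_called_degs": len(called),
        "terminal_call_rate": len(set(truth.terminal_ids) & called)
        / len(truth.terminal_ids),
        "n_superhubs_found": len(superhubs),
        "superhub_precision": tp / len(superhubs) if superhubs else 0.0,
        "superhub_recall": tp / len(true_supers),
        "hub_candidate_recall": len(hubs & set(truth.hub_ids))
        / len(truth.hub_ids),
        "n_hubs_kept": len(tiers.hubs),
        "n_terminals": len(tiers.terminals),
        "tier_coverage": tiers.coverage,
    }


def null_false_call_rate(
    seed: int, n_sims: int = 200, n_genes: int = 2000, B: int = 250,
    alpha: float = 0.05,
) -> float:
    """Mean fraction of gene x timepoint tests called on pure-noise data.

    Each simulation draws a no-effect matrix under the default design
    (2 conditions x 6 timepoints x 2 replicates, baseline N(8, 1.5), noise
    sd 0.3) and runs the full rank-product caller at BH level ``alpha``.
    """
    design = StudyDesign()
    arrays = list(design.arrays())
    fractions = []
    for s in _seeds(seed, n_sims):
        rng = np.random.default_rng(s)
        values = (
            rng.normal(8.0, 1.5, size=(n_genes, 1))
            + rng.normal(0.0, 0.3, size=(n_genes, len(arrays)))
        )
        expr = ExpressionMatrix.from_arrays(
            [f"g{i}" for i in range(n_genes)], arrays, values
        )
        degs = call_degs(expr, alpha=alpha, B=B, seed=s)
        n_tests = n_genes * len(degs.table["timepoint_h"].unique())
        fractions.append(len(degs.called) / n_tests)
    return float(np.mean(fractions))


def mi_closed_form_error(
    seed: int, rhos: tuple[float, ...] = (0.0, 0.5, 0.8),
    n_samples: int = 500, n_seeds: int = 50,
) -> dict[float, float]:
    """|mean estimated MI - (-1/2)ln(1-rho^2)| per rho, over seeded draws."""
    out = {}
    for rho in rhos:
        vals = []
        for s in _seeds(seed + int(rho * 1000), n_seeds):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(n_samples)
            y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n_samples)
            vals.append(gaussian_copula_mi(x, y))
        closed = -0.5 * math.log1p(-(rho**2))
        out[rho] = abs(float(np.mean(vals)) - closed)
    return out


def dpi_markov_removal_rate(
    seed: int, n_runs: int = 100, n_samples: int = 1000, eps: float = 0.10
) -> float:
    """Fraction of simulated linear Markov chains X -> Y -> Z whose X-Z
    shortcut edge is removed by DPI."""
    removed = 0
    for s in _seeds(seed, n_runs):
        rng = np.random.default_rng(s)
        x = rng.standard_normal(n_samples)
        y = x + 0.75 * rng.standard_normal(n_samples)
        z = y + 0.75 * rng.standard_normal(n_samples)
        G = nx.Graph()
        G.add_edge("X", "Y", mi=gaussian_copula_mi(x, y))
        G.add_edge("Y", "Z", mi=gaussian_copula_mi(y, z))
        G.add_edge("X", "Z", mi=gaussian_copula_mi(x, z))
        removed += not apply_dpi(G, eps).has_edge("X", "Z")
    return removed / n_runs


def dpi_oracle_agreement(seed: int, n_graphs: int = 20) -> float:
    """Fraction of random 8-node graphs where DPI equals an explicit
    triple-loop oracle (expected 1.0)."""
    import itertools

    agree = 0
    for s in _seeds(seed, n_graphs):
        rng = np.random.default_rng(s)
        G = nx.gnp_random_graph(8, 0.5, seed=int(s % 2**16))
        for u, v in G.edges:
            G.edges[u, v]["mi"] = float(rng.uniform(0.05, 1.0))
        eps = float(rng.choice([0.0, 0.1, 0.25]))
        got = apply_dpi(G, eps)
        keep = set(map(frozenset, G.edges))
        for x, y, z in itertools.permutations(G.nodes, 3):
            if (G.has_edge(x, y) and G.has_edge(y, z) and G.has_edge(x, z)
                    and G.edges[x, z]["mi"]
                    < (1 - eps) * min(G.edges[x, y]["mi"], G.edges[y, z]["mi"])):
                keep.discard(frozenset((x, z)))
        agree += set(map(frozenset, got.edges)) == keep
    return agree / n_graphs


def wilcoxon_null_type1(
    seed: int, n_reps: int = 500, n_in: int = 150, n_genes: int = 1500,
    level: float = 0.05,
) -> float:
    """Type-I error of the per-category Wilcoxon test on null data
    (category size in the hundreds, the regime the asymptotic test targets)."""
    ann = AnnotationMap(
        gene_to_cats={f"g{i}": frozenset({"C"}) for i in range(n_in)}
    )
    rejected = 0
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        values = pd.Series(
            rng.standard_normal(n_genes),
            index=[f"g{i}" for i in range(n_genes)],
        )
        res = pageman_enrichment(values, ann)
        rejected += bool(res.iloc[0]["p"] < level)
    return rejected / n_reps
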