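"""Copula-MI estimation and DPI pruning against closed forms and oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from hiergrn import (
    apply_dpi,
    build_network,
    edge_significance,
    gaussian_copula_mi,
    mi_matrix,
)
from hiergrn.network import (
    MI_CEILING,
    _dpi_removal_mask,
    _dpi_removal_mask_fast,
    binned_mi,
)
from hiergrn.expression import ExpressionMatrix, StudyDesign


def _expr_from_profiles(profiles):
    design = StudyDesign(timepoints_h=(0, 6, 24), n_replicates=2)
    values = np.asarray(profiles, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix.from_arrays(genes, list(design.arrays()), values)


def brute_force_dpi(graph, eps):
    """Independent triplet scan: check every node triple explicitly."""
    nodes = list(graph.nodes)
    to_remove = set()
    for x, y, z in itertools.permutations(nodes, 3):
        if graph.has_edge(x, y) and graph.has_edge(y, z) and graph.has_edge(x, z):
            wxy = graph.edges[x, y]["mi"]
            wyz = graph.edges[y, z]["mi"]
            wxz = graph.edges[x, z]["mi"]
            if wxz < (1 - eps) * min(wxy, wyz):
                to_remove.add(frozenset((x, z)))
    out = graph.copy()
    out.remove_edges_from([tuple(e) for e in to_remove])
    return out


# ------------------------------------------------------------------- MI

def test_identical_profiles_hit_the_clamp_ceiling(rng):
    x = rng.normal(size=50)
    assert gaussian_copula_mi(x, x) == pytest.approx(MI_CEILING)


def test_constant_profile_gives_zero():
    x = np.ones(10)
    y = np.arange(10.0)
    assert gaussian_copula_mi(x, y) == 0.0


def test_mi_symmetry_and_nonnegativity(rng):
    for _ in range(10):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert gaussian_copula_mi(x, y) == pytest.approx(gaussian_copula_mi(y, x))
        assert gaussian_copula_mi(x, y) >= 0


def test_mi_monotone_transform_invariance(rng):
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    assert gaussian_copula_mi(x, y) == pytest.approx(
        gaussian_copula_mi(np.exp(x), y**3 + 2 * y)
    )


def test_mi_matches_closed_form_at_rho_08():
    vals = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        x = r.standard_normal(500)
        y = 0.8 * x + math.sqrt(1 - 0.64) * r.standard_normal(500)
        vals.append(gaussian_copula_mi(x, y))
    assert np.mean(vals) == pytest.approx(-0.5 * math.log(1 - 0.64), abs=0.05)


def test_binned_mi_detects_dependence(rng):
    x = rng.normal(size=400)
    y = x + 0.3 * rng.normal(size=400)
    z = rng.normal(size=400)
    assert binned_mi(x, y) > binned_mi(x, z)
    assert binned_mi(x, z) >= 0.0


def test_mi_matrix_construction():
    r = np.random.default_rng(1)
    g1 = r.normal(size=12)
    g3 = r.normal(size=12)
    expr = _expr_from_profiles([g1, g1, g3])
    m = mi_matrix(expr)
    assert m.loc["g0", "g1"] == pytest.approx(MI_CEILING)
    assert m.loc["g0", "g2"] < 0.5
    assert np.allclose(m.to_numpy(), m.to_numpy().T)
    assert (np.diag(m.to_numpy()) == 0).all()


def test_mi_matrix_unknown_gene_raises(tiny_expr):
    with pytest.raises(KeyError):
        mi_matrix(tiny_expr, ["nope"])


# ------------------------------------------------------------ significance

def test_edge_significance_identical_profiles():
    r = np.random.default_rng(3)
    g = r.normal(size=12)
    expr = _expr_from_profiles([g, g])
    assert edge_significance(expr, ("g0", "g1"), B=100, seed=0) == pytest.approx(1 / 101)


def test_edge_significance_reproducible_and_null_uniformish():
    r = np.random.default_rng(4)
    expr = _expr_from_profiles([r.normal(size=12), r.normal(size=12)])
    p1 = edge_significance(expr, ("g0", "g1"), B=50, seed=9)
    p2 = edge_significance(expr, ("g0", "g1"), B=50, seed=9)
    assert p1 == p2
    ps = [edge_significance(expr, ("g0", "g1"), B=20, seed=s) for s in range(30)]
    assert 0.05 < np.mean(ps) < 0.95


# -------------------------------------------------------------------- DPI

def test_dpi_removes_forced_weak_edge():
    G = nx.Graph()
    G.add_edge("A", "B", mi=0.9)
    G.add_edge("B", "C", mi=0.8)
    G.add_edge("A", "C", mi=0.3)
    out = apply_dpi(G, eps=0.0)
    assert not out.has_edge("A", "C")
    assert out.has_edge("A", "B") and out.has_edge("B", "C")


@pytest.mark.parametrize("eps", [0.0, 0.2, 0.5])
def test_dpi_keeps_equilateral_triangle(eps):
    G = nx.Graph()
    for u, v in [("A", "B"), ("B", "C"), ("A", "C")]:
        G.add_edge(u, v, mi=0.5)
    assert apply_dpi(G, eps).number_of_edges() == 3


def test_dpi_eps_out_of_range():
    with pytest.raises(ValueError):
        apply_dpi(nx.Graph(), eps=1.0)
    with pytest.raises(ValueError):
        apply_dpi(nx.Graph(), eps=-0.1)


@pytest.mark.parametrize("seed", range(10))
def test_dpi_matches_brute_force_on_random_graphs(seed):
    r = np.random.default_rng(seed)
    G = nx.gnp_random_graph(8, 0.55, seed=int(seed))
    for u, v in G.edges:
        G.edges[u, v]["mi"] = float(r.uniform(0.05, 1.0))
    eps = float(r.choice([0.0, 0.1, 0.3]))
    got = apply_dpi(G, eps)
    want = brute_force_dpi(G, eps)
    assert set(map(frozenset, got.edges)) == set(map(frozenset, want.edges))
    assert set(map(frozenset, got.edges)) <= set(map(frozenset, G.edges))


@pytest.mark.parametrize("seed", range(5))
def test_fast_dpi_kernel_equals_numpy_scan(seed):
    r = np.random.default_rng(100 + seed)
    n = 30
    W = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = r.random(iu[0].size) < 0.4
    w = np.where(mask, r.uniform(0.05, 1.0, iu[0].size), 0.0)
    W[iu] = w
    W = W + W.T
    for eps in (0.0, 0.15, 0.35):
        assert np.array_equal(_dpi_removal_mask(W, eps),
                              _dpi_removal_mask_fast(W, eps))


# ---------------------------------------------------------- build_network

def test_build_network_empty_deg_set_raises(tiny_expr):
    with pytest.raises(ValueError):
        build_network(tiny_expr, [])


def test_build_network_markov_chain_prunes_shortcut():
    """X -> Y -> Z linear chain: the X-Z shortcut goes away."""
    removed = 0
    n_runs = 20
    for seed in range(n_runs):
        r = np.random.default_rng(seed)
        x = r.standard_normal(1000)
        y = x + 0.75 * r.standard_normal(1000)
        z = y + 0.75 * r.standard_normal(1000)
        mis = {
            ("X", "Y"): gaussian_copula_mi(x, y),
            ("Y", "Z"): gaussian_copula_mi(y, z),
            ("X", "Z"): gaussian_copula_mi(x, z),
        }
        G = nx.Graph()
        for (u, v), w in mis.items():
            G.add_edge(u, v, mi=w)
        out = apply_dpi(G, eps=0.10)
        removed += not out.has_edge("X", "Z")
        assert out.has_edge("X", "Y") and out.has_edge("Y", "Z")
    assert removed >= 0.95 * n_runs


def test_build_network_recovers_planted_edges(small_truth, small_expr):
    genes = list(small_truth.affected_ids)
    net = build_network(small_expr, genes, B=300, seed=5)
    assert net.number_of_nodes() == len(genes)
    present = sum(
        net.has_edge(h, t)
        for h, t in small_truth.edges
        if h in small_truth.hub_ids
    )
    n_spokes = sum(1 for h, t in small_truth.edges if h in small_truth.hub_ids)
    assert present / n_spokes > 0.6
    assert net.graph["dpi_eps"] == 0.25
    for _, _, d in net.edges(data=True):
        assert d["mi"] > 0 and 0 < d["p"] < 0.05
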