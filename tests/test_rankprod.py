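"""Rank-product calling against brute-force oracles and its invariants."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hiergrn import (
    MissingContrastError,
    bh_adjust,
    call_degs,
    exact_permutation_pvalues,
    generate_planted_network,
    pairwise_log2fc,
    permutation_pvalues,
    rank_product,
    simulate_expression,
)
from hiergrn.expression import ExpressionMatrix, StudyDesign


def _expr_from_values(values, timepoints=(0, 6)):
    design = StudyDesign(timepoints_h=tuple(timepoints))
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix.from_arrays(genes, list(design.arrays()), values)


# ---------------------------------------------------------------- oracles

def brute_force_rank_product(fc, direction):
    """Per-column ranks by explicit sorting, geometric mean by explicit loop."""
    G, K = fc.shape
    out = []
    for g in range(G):
        prod = 1.0
        for k in range(K):
            col = list(fc[:, k])
            key = (lambda v: -v) if direction == "up" else (lambda v: v)
            ordered = sorted(range(G), key=lambda i: key(col[i]))
            # average ranks over ties
            ranks = [0.0] * G
            i = 0
            while i < G:
                j = i
                while j + 1 < G and col[ordered[j + 1]] == col[ordered[i]]:
                    j += 1
                avg = (i + j) / 2.0 + 1.0
                for m in range(i, j + 1):
                    ranks[ordered[m]] = avg
                i = j + 1
            prod *= ranks[g]
        out.append(prod ** (1.0 / K))
    return np.array(out)


def brute_force_exact_pvalues(fc, direction):
    """Literal enumeration of all (G!)^K within-column label shuffles."""
    G, K = fc.shape
    rank_cols = []
    for k in range(K):
        r = stats.rankdata(-fc[:, k] if direction == "up" else fc[:, k])
        rank_cols.append(r)
    obs = np.prod([rank_cols[k] for k in range(K)], axis=0)
    null = []
    perms = list(itertools.permutations(range(G)))
    for combo in itertools.product(perms, repeat=K):
        prods = np.ones(G)
        for k, sigma in enumerate(combo):
            prods = prods * rank_cols[k][list(sigma)]
        null.extend(prods.tolist())
    null = np.sort(np.array(null))
    counts = np.searchsorted(null, obs, side="right")
    return counts / float(null.size)


# ------------------------------------------------------------- pairwise FC

def test_pairwise_fc_constant_case():
    vals = np.array([[8.0, 8.0, 9.0, 9.0], [1.0, 1.0, 1.0, 1.0]])
    fc = pairwise_log2fc(_expr_from_values(vals, (0,)), 0)
    assert fc.shape == (2, 4)
    assert np.allclose(fc.loc["g0"], 1.0)
    assert np.allclose(fc.loc["g1"], 0.0)


def test_pairwise_fc_arithmetic():
    vals = np.array([[8.0, 6.0, 9.0, 7.0], [0, 0, 0, 0.0]])
    fc = pairwise_log2fc(_expr_from_values(vals, (0,)), 0)
    assert list(fc.loc["g0"]) == [1.0, 3.0, -1.0, 1.0]


def test_pairwise_fc_k_equals_four_for_default_design(tiny_expr):
    assert pairwise_log2fc(tiny_expr, 6).shape[1] == 4


def test_missing_contrast_raises():
    vals = np.random.default_rng(0).normal(size=(3, 4))
    expr = _expr_from_values(vals, (0,))
    with pytest.raises(MissingContrastError):
        pairwise_log2fc(expr, 6)


# ------------------------------------------------------------ rank product

def test_rank_product_minimum_is_one():
    fc = np.array([[9.0, 9.0], [1.0, 2.0], [0.0, 1.0]])
    assert rank_product(fc, "up")[0] == 1.0


def test_rank_product_sqrt6_example():
    # gene 0 ranked 2nd and 3rd over K=2 comparisons
    fc = np.array([[5.0, 3.0], [9.0, 5.0], [1.0, 4.0], [0.0, 1.0]])
    rp = rank_product(fc, "up")
    assert rp[0] == pytest.approx(math.sqrt(6), rel=1e-12)


@pytest.mark.parametrize("direction", ["up", "down"])
@pytest.mark.parametrize("seed", range(4))
def test_rank_product_matches_brute_force(direction, seed):
    rng = np.random.default_rng(seed)
    fc = rng.normal(size=(5, 4))
    got = rank_product(fc, direction)
    want = brute_force_rank_product(fc, direction)
    assert np.allclose(got, want, rtol=1e-12)


def test_rank_product_monotone_transform_invariance(rng):
    fc = rng.normal(size=(8, 3))
    transformed = np.exp(fc) * 3.0 + 1.0  # strictly increasing per column
    assert np.allclose(rank_product(fc, "up"), rank_product(transformed, "up"))


# ---------------------------------------------------------- permutation p

@pytest.mark.parametrize("seed", range(3))
def test_exact_pvalues_match_literal_enumeration(seed):
    rng = np.random.default_rng(seed)
    fc = rng.normal(size=(3, 2))
    pu, pdn = exact_permutation_pvalues(fc)
    assert np.allclose(pu, brute_force_exact_pvalues(fc, "up"), atol=0)
    assert np.allclose(pdn, brute_force_exact_pvalues(fc, "down"), atol=0)


def test_monte_carlo_pvalues_bounds_and_determinism(rng):
    fc = rng.normal(size=(30, 4))
    p1u, p1d = permutation_pvalues(fc, B=200, seed=5)
    p2u, p2d = permutation_pvalues(fc, B=200, seed=5)
    assert np.array_equal(p1u, p2u) and np.array_equal(p1d, p2d)
    assert (p1u > 0).all() and (p1u <= 1).all()
    # monotone non-increasing in RP
    rp = rank_product(fc, "up")
    order = np.argsort(rp)
    assert (np.diff(p1u[order]) >= 0).all()
    # worst gene close to 1
    assert p1u[np.argmax(rp)] > 0.9


# ------------------------------------------------------------ BH adjustment

def test_bh_step_up_formula():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert np.allclose(bh_adjust([0.3]), [0.3])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


# --------------------------------------------------------------- call_degs

def test_alpha_zero_calls_nothing(small_expr):
    degs = call_degs(small_expr, alpha=0.0, B=50, seed=0, timepoints=[6])
    assert len(degs.union()) == 0


def test_direction_symmetry(design):
    truth = generate_planted_network(1, (3, 3), (8, 8), 150, seed=21,
                                     noise_sd=0.3)
    expr = simulate_expression(truth, design, seed=22)
    neg = ExpressionMatrix(-expr.data)
    a = call_degs(expr, alpha=0.05, B=200, seed=3, timepoints=[6, 24])
    b = call_degs(neg, alpha=0.05, B=200, seed=3, timepoints=[6, 24])
    for tp in (6, 24):
        assert a.genes_at(tp, "up") == b.genes_at(tp, "down")
        assert a.genes_at(tp, "down") == b.genes_at(tp, "up")


def test_calls_invariant_under_monotone_transform(small_expr):
    # cube-root-ish strictly increasing transform of log2 values
    transformed = ExpressionMatrix(small_expr.data * 3.0 + 2.0)
    a = call_degs(small_expr, alpha=0.05, B=100, seed=7, timepoints=[24])
    b = call_degs(transformed, alpha=0.05, B=100, seed=7, timepoints=[24])
    assert a.genes_at(24, "up") == b.genes_at(24, "up")
    assert a.genes_at(24, "down") == b.genes_at(24, "down")


def test_strong_planted_effects_are_called(design):
    truth = generate_planted_network(
        1, (3, 3), (10, 10), 800, seed=31, noise_sd=0.3,
        effect_size=(2.0, 2.5), terminal_peak=(2.0, 2.5), n_independent=40,
        independent_effect_size=(2.0, 2.5),
    )
    expr = simulate_expression(truth, design, seed=32)
    degs = call_degs(expr, alpha=0.05, B=300, seed=33)
    called = degs.union()
    # independents carry pure measurement noise (sd 0.3): at ~2 log2 peak
    # effects every one of them is called at its affected timepoints
    independents = set(truth.independent_ids)
    for g in independents:
        tp = truth.effect[g].timepoints_h[
            int(np.argmax(np.abs(truth.delta.loc[g, list(truth.effect[g].timepoints_h)])))
        ]
        direction = "up" if truth.effect[g].sign > 0 else "down"
        assert g in degs.genes_at(tp, direction), g
    # hierarchy members inherit their regulators' noise (larger effective
    # spread), so a small miss rate is expected
    affected = set(truth.affected_ids)
    assert len(called & affected) / len(affected) > 0.9


def test_counts_table_shape(small_expr):
    degs = call_degs(small_expr, alpha=0.05, B=100, seed=0)
    counts = degs.counts()
    assert list(counts.index) == [6, 24, 48, 96, 504]
    assert (counts["up"] + counts["down"] == counts["total"]).all()
    # union equals genes called at >= 1 timepoint
    union = set()
    for tp in counts.index:
        union |= degs.genes_at(tp)
    assert union == set(degs.union())
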