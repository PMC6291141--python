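"""Generator invariants: seeded determinism, tier wiring, effect injection."""

import numpy as np
import pandas as pd
import pytest

from hiergrn import (
    StudyDesign,
    generate_annotations,
    generate_planted_network,
    pairwise_log2fc,
    select_tf_ids,
    simulate_expression,
)


def test_tiny_truth_counts(tiny_truth):
    assert len(tiny_truth.superhub_ids) == 1
    assert len(tiny_truth.hub_ids) == 3
    assert len(tiny_truth.terminal_ids) == 15
    assert len(tiny_truth.background_ids) == 0
    # each terminal has exactly one hub parent
    for t in tiny_truth.terminal_ids:
        parents = tiny_truth.parents_of(t)
        assert len(parents) == 1 and parents[0] in tiny_truth.hub_ids


def test_seeded_determinism_of_truth():
    a = generate_planted_network(2, (3, 3), (4, 6), 50, seed=5, n_independent=10)
    b = generate_planted_network(2, (3, 3), (4, 6), 50, seed=5, n_independent=10)
    assert a.edges == b.edges
    assert a.weights == b.weights
    pd.testing.assert_frame_equal(a.delta, b.delta)
    c = generate_planted_network(2, (3, 3), (4, 6), 50, seed=6, n_independent=10)
    assert a.edges != c.edges or not a.delta.equals(c.delta)


def test_truth_invariants_hold(small_truth):
    small_truth.validate()
    tiers = [set(small_truth.superhub_ids), set(small_truth.hub_ids),
             set(small_truth.terminal_ids), set(small_truth.independent_ids),
             set(small_truth.background_ids)]
    for i, a in enumerate(tiers):
        for b in tiers[i + 1:]:
            assert not a & b
    lo, hi = small_truth.hubs_per_super_range
    for s in small_truth.superhub_ids:
        k = len(set(small_truth.children_of(s)) & set(small_truth.hub_ids))
        assert lo <= k <= hi


@pytest.mark.parametrize("bad_kwargs", [
    dict(n_super=0),
    dict(hubs_per_super=(4, 2)),
    dict(terminals_per_hub=(5, 3)),
    dict(hubs_per_super=(0, 2)),
    dict(n_background=-1),
])
def test_infeasible_arguments_raise(bad_kwargs):
    kwargs = dict(n_super=2, hubs_per_super=(2, 3), terminals_per_hub=(3, 5),
                  n_background=10)
    kwargs.update(bad_kwargs)
    with pytest.raises(ValueError):
        generate_planted_network(kwargs.pop("n_super"),
                                 kwargs.pop("hubs_per_super"),
                                 kwargs.pop("terminals_per_hub"),
                                 kwargs.pop("n_background"), seed=0, **kwargs)


def test_hub_pool_infeasible_when_too_large():
    with pytest.raises(ValueError):
        generate_planted_network(2, (2, 3), (3, 4), 0, seed=0, n_hubs=10)


def test_default_design_is_the_study_layout(design):
    assert design.timepoints_h == (0, 6, 24, 48, 96, 504)
    assert design.n_replicates == 2
    assert design.n_arrays == 24


def test_shared_time0_design_drops_stress_baseline():
    d = StudyDesign(shared_time0=True)
    assert d.n_arrays == 22
    assert ("stress", 0, 1) not in list(d.arrays())


def test_simulated_matrix_covers_design(tiny_expr, design):
    assert tiny_expr.n_arrays == 24
    assert tiny_expr.design == design


def test_effect_injection_exact_without_noise(tiny_truth, tiny_expr):
    """With zero noise the realized log2FC equals the planted effect exactly."""
    for tp in (6, 24, 48, 96, 504):
        fc = pairwise_log2fc(tiny_expr, tp)
        for g in tiny_expr.gene_ids:
            want = tiny_truth.delta.loc[g, tp] if g in tiny_truth.delta.index else 0.0
            assert np.allclose(fc.loc[g], want, atol=1e-9), (g, tp)


def test_no_effect_truth_gives_near_zero_mean_fc(design):
    truth = generate_planted_network(1, (3, 3), (0, 0), 400, seed=3, noise_sd=0.3)
    # wipe the planted responses: background-dominated null matrix
    truth.delta.iloc[:, :] = 0.0
    expr = simulate_expression(truth, design, seed=4)
    for tp in (6, 504):
        fc = pairwise_log2fc(expr, tp).to_numpy()
        assert abs(fc.mean()) < 0.05  # Monte-Carlo error at ~400 genes x 4 FCs


def test_seeded_determinism_of_expression(tiny_truth, design):
    a = simulate_expression(tiny_truth, design, seed=9)
    b = simulate_expression(tiny_truth, design, seed=9)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_noise_inheritance_links_parent_and_child(small_truth, small_expr):
    """A child profile correlates with its parent far above the background."""
    h = small_truth.hub_ids[0]
    terms = [c for p, c in small_truth.edges if p == h][:10]
    hv = small_expr.data.loc[h].to_numpy()
    spokes = [np.corrcoef(hv, small_expr.data.loc[t].to_numpy())[0, 1] for t in terms]
    bg = [np.corrcoef(hv, small_expr.data.loc[b].to_numpy())[0, 1]
          for b in small_truth.background_ids[:30]]
    assert min(spokes) > 0.5
    assert np.mean(np.abs(bg)) < 0.3


def test_tf_list_contains_all_superhubs(small_truth):
    tfs = select_tf_ids(small_truth, seed=1, n_decoy_independent=5,
                        n_decoy_background=5)
    assert set(small_truth.superhub_ids) <= set(tfs)
    assert len(tfs) == len(small_truth.superhub_ids) + 10


def test_annotations_cover_families(small_truth):
    ann = generate_annotations(small_truth, seed=2, n_random_categories=3)
    assert set(ann.columns) == {"gene_id", "category_id", "category_name"}
    fam_cats = {c for c in ann["category_id"] if c.startswith("FAM:")}
    assert len(fam_cats) == len(small_truth.superhub_ids)
    s = small_truth.superhub_ids[0]
    members = set(ann.loc[ann["category_id"] == f"FAM:{s}", "gene_id"])
    planted = {s} | set(small_truth.descendants_of(s))
    assert members <= planted
    assert len(members) >= 0.7 * len(planted)
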