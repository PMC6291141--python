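"""Seeded synthetic expression data with a planted regulatory hierarchy.

The generator emulates the structure of a two-condition (control vs osmotic
stress) root time course: a small top tier of stress-responsive transcription
factors ("superhubs"), each regulating a handful of hub genes, each hub
driving a family of terminal genes, plus a set of independently responding
genes that belong to no hierarchy, all embedded in a large background of
unresponsive genes. Every downstream stage of the pipeline can therefore be
scored against a recoverable ground truth.

Stress-response curves are tents in log-time with continuous peak
positions and widths, sampled at the design timepoints. Hub and terminal
expression profiles are linear mixtures of their parents' profiles plus
per-gene Gaussian noise, so a child shares both its parent's response curve
and (through the mixture) its parent's realized noise fingerprint -- the
combination that keeps regulator-target pairs statistically distinguishable
from genes that merely respond with similar temporal shapes. See
docs/methods.md for the identifiability constraints that shaped these
choices and for what they imply about recovery at realistic sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import DEFAULT_TIMEPOINTS_H, ExpressionMatrix, StudyDesign

__all__ = [
    "Effect",
    "PlantedTruth",
    "generate_planted_network",
    "simulate_expression",
    "select_tf_ids",
    "generate_annotations",
    "study_scale_truth",
    "STUDY_SCALE",
]

#: Scale template mirroring the published drought study: 9 superhubs over a
#: pool of 18 hubs (3-4 each, shared), ~2,970 terminals, 1,600 independent
#: responders and a 50,000-gene unresponsive background, sized so the called
#: DEG union lands near the study's ~5,600 with the hierarchy just above
#: half of it.
STUDY_SCALE: dict = dict(
    n_super=9,
    hubs_per_super=(3, 4),
    terminals_per_hub=(150, 180),
    n_background=50_000,
    n_hubs=18,
    n_independent=1_600,
)


@dataclass(frozen=True)
class Effect:
    """Planted stress response of one gene.

    size is the peak |log2 fold-change|; timepoints_h are the affected
    sampling times; sign is +1 (induced) or -1 (repressed) at the peak.
    """

    size: float
    timepoints_h: tuple[int, ...]
    sign: int


@dataclass
class PlantedTruth:
    """Ground truth of a planted three-tier hierarchy.

    ``delta`` holds the exact planted log2 fold-change for every responding
    gene at every non-zero design timepoint (genes x timepoints); it is the
    reference for effect-injection fidelity checks. ``independent_ids`` are
    responding genes outside the hierarchy; ``background_ids`` are pure-noise
    genes.
    """

    superhub_ids: tuple[str, ...]
    hub_ids: tuple[str, ...]
    terminal_ids: tuple[str, ...]
    independent_ids: tuple[str, ...]
    background_ids: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    effect: dict[str, Effect]
    delta: pd.DataFrame
    noise_sd: float
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    hubs_per_super_range: tuple[int, int] = (3, 4)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def all_gene_ids(self) -> tuple[str, ...]:
        return (
            self.superhub_ids
            + self.hub_ids
            + self.terminal_ids
            + self.independent_ids
            + self.background_ids
        )

    @property
    def affected_ids(self) -> tuple[str, ...]:
        return (
            self.superhub_ids + self.hub_ids + self.terminal_ids + self.independent_ids
        )

    def parents_of(self, gene: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == gene)

    def children_of(self, gene: str) -> tuple[str, ...]:
        return tuple(c for p, c in self.edges if p == gene)

    def descendants_of(self, superhub: str) -> tuple[str, ...]:
        """Hubs of a superhub plus those hubs' terminals."""
        hubs = [c for c in self.children_of(superhub) if c in set(self.hub_ids)]
        terms: list[str] = []
        for h in hubs:
            terms.extend(self.children_of(h))
        return tuple(hubs) + tuple(dict.fromkeys(terms))

    def validate(self) -> None:
        tiers = [
            set(self.superhub_ids),
            set(self.hub_ids),
            set(self.terminal_ids),
            set(self.independent_ids),
            set(self.background_ids),
        ]
        total = sum(len(t) for t in tiers)
        if len(set().union(*tiers)) != total:
            raise ValueError("tier/background gene sets must be pairwise disjoint")
        supers, hubs, terms = tiers[0], tiers[1], tiers[2]
        parent_map: dict[str, set[str]] = {}
        for p, c in self.edges:
            parent_map.setdefault(c, set()).add(p)
        for h in hubs:
            if not parent_map.get(h, set()) & supers:
                raise ValueError(f"hub {h!r} has no superhub parent")
        for t in terms:
            if not parent_map.get(t, set()) & hubs:
                raise ValueError(f"terminal {t!r} has no hub parent")
        lo, hi = self.hubs_per_super_range
        for s in supers:
            k = len(set(self.children_of(s)) & hubs)
            if not lo <= k <= hi:
                raise ValueError(
                    f"superhub {s!r} has {k} hub children, outside [{lo}, {hi}]"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _draw_effect_curve(
    rng: np.random.Generator,
    timepoints: np.ndarray,
    size_range: tuple[float, float],
    jitter: float = 0.3,
) -> tuple[np.ndarray, float, int]:
    """Random transient response: a tent in log-time with a continuous peak
    position and half-width, sampled at the design timepoints, with
    per-timepoint multiplicative jitter.

    Continuous peak positions make response shapes a smooth one-parameter
    family instead of a handful of discrete window patterns; without this,
    unrelated genes sharing a window would be exact shape clones and would
    form large indistinguishable co-expression cliques. The curve is
    rescaled so its peak sampled magnitude equals the drawn effect size.
    """
    size = float(rng.uniform(*size_range))
    sign = int(rng.choice([-1, 1]))
    logt = np.log(timepoints.astype(float))
    peak_x = float(rng.uniform(logt[0], logt[-1]))
    span = max(logt[-1] - logt[0], 1.0)
    half_width = float(rng.uniform(0.25, 0.75)) * span / 2.0
    curve = np.maximum(0.0, 1.0 - np.abs(logt - peak_x) / half_width)
    if jitter > 0:
        curve = curve * rng.uniform(1.0 - jitter, 1.0 + jitter, size=len(logt))
    peak = np.abs(curve).max()
    if peak == 0.0:  # peak fell between samples with a narrow width
        curve[int(np.argmin(np.abs(logt - peak_x)))] = 1.0
        peak = 1.0
    curve = sign * size * curve / peak
    return curve, size, sign


def _effect_from_delta(delta_row: np.ndarray, timepoints: np.ndarray) -> Effect:
    mask = delta_row != 0.0
    peak = int(np.argmax(np.abs(delta_row)))
    return Effect(
        size=float(np.abs(delta_row[peak])),
        timepoints_h=tuple(int(t) for t in timepoints[mask]),
        sign=int(np.sign(delta_row[peak])) if mask.any() else 1,
    )


def generate_planted_network(
    n_super: int,
    hubs_per_super: tuple[int, int],
    terminals_per_hub: tuple[int, int],
    n_background: int,
    seed: int,
    *,
    n_hubs: int | None = None,
    share_prob: float = 0.0,
    n_independent: int = 0,
    effect_size: tuple[float, float] = (1.4, 1.7),
    independent_effect_size: tuple[float, float] = (1.0, 1.5),
    weight_range: tuple[float, float] = (0.6, 0.9),
    hub_intrinsic_rel: tuple[float, float] = (0.35, 0.55),
    terminal_peak: tuple[float, float] = (1.3, 1.7),
    noise_sd: float = 0.3,
    timepoints_h: Sequence[int] = DEFAULT_TIMEPOINTS_H,
) -> PlantedTruth:
    """Draw a planted three-tier regulatory hierarchy.

    Parameters
    ----------
    n_super, hubs_per_super, terminals_per_hub, n_background
        Tier scale: number of superhubs, inclusive range of hub children per
        superhub, inclusive range of terminals per hub, and number of
        pure-noise background genes.
    n_hubs
        If given, hubs are drawn from a fixed pool of this size (hubs are
        then shared between superhubs so that every pool member has at least
        one parent); otherwise each hub slot creates a new hub with
        probability ``1 - share_prob``.
    n_independent
        Responding genes outside the hierarchy (their own effect curves, no
        regulatory edges).
    effect_size, independent_effect_size
        Ranges of peak |log2FC| drawn per superhub and per independent
        responder (independents are kept somewhat weaker so that genes
        sharing response shapes by chance sit close to the significance
        threshold instead of forming strong co-expression blocks).
    weight_range
        Mixture weights tying child response curves to their parents'.
    hub_intrinsic_rel
        Size of each hub's own response curve relative to its parent
        mixture. Intrinsic components keep siblings distinguishable from
        parent-child pairs -- a parent then explains only part of a child's
        variance, which is both the realistic regime for co-expression
        modules and what makes the planted tree identifiable from
        correlation structure at all.
    terminal_peak
        Range of peak |log2FC| targeted per terminal; the hub mixture
        weight is set to reach it (see the in-code rationale).
    noise_sd
        Additive Gaussian noise (log2 units) later used by
        :func:`simulate_expression`.

    Identical arguments (including seed) give identical truths.
    """
    lo_h, hi_h = int(hubs_per_super[0]), int(hubs_per_super[1])
    lo_t, hi_t = int(terminals_per_hub[0]), int(terminals_per_hub[1])
    if n_super < 1:
        raise ValueError("n_super must be >= 1")
    if lo_h < 1 or hi_h < lo_h:
        raise ValueError(f"infeasible hubs_per_super range [{lo_h}, {hi_h}]")
    if lo_t < 0 or hi_t < lo_t:
        raise ValueError(f"infeasible terminals_per_hub range [{lo_t}, {hi_t}]")
    if not 0.0 <= share_prob < 1.0:
        raise ValueError("share_prob must be in [0, 1)")
    if n_background < 0 or n_independent < 0:
        raise ValueError("gene counts must be non-negative")
    if n_hubs is not None and n_hubs > n_super * hi_h:
        raise ValueError(
            f"a pool of {n_hubs} hubs cannot all receive parents from "
            f"{n_super} superhubs with at most {hi_h} children each"
        )

    rng = np.random.default_rng(seed)
    supers = [f"sh-{i:02d}" for i in range(n_super)]

    # superhub -> hub wiring
    edges: list[tuple[str, str]] = []
    children: dict[str, list[str]] = {s: [] for s in supers}
    if n_hubs is not None:
        hubs = [f"hub-{i:03d}" for i in range(n_hubs)]
        ks = rng.integers(lo_h, hi_h + 1, size=n_super)
        while int(ks.sum()) < n_hubs:  # every pool hub needs a parent slot
            ks[int(rng.integers(0, n_super))] = hi_h
        pool = [str(h) for h in rng.permutation(hubs)]
        # deal distinct pool hubs first so every hub gets >= 1 parent
        cursor = 0
        for s, k in zip(supers, ks):
            take = pool[cursor : cursor + int(k)]
            cursor += len(take)
            children[s].extend(take)
        for s, k in zip(supers, ks):
            while len(children[s]) < int(k):
                cand = hubs[int(rng.integers(0, n_hubs))]
                if cand not in children[s]:
                    children[s].append(cand)
    else:
        hubs = []
        for s in supers:
            k = int(rng.integers(lo_h, hi_h + 1))
            for _ in range(k):
                if hubs and share_prob > 0 and rng.random() < share_prob:
                    options = [h for h in hubs if h not in children[s]]
                    if options:
                        children[s].append(options[int(rng.integers(0, len(options)))])
                        continue
                h = f"hub-{len(hubs):03d}"
                hubs.append(h)
                children[s].append(h)
    for s in supers:
        edges.extend((s, h) for h in children[s])

    # hub -> terminal wiring (each terminal gets exactly one hub parent)
    terminals: list[str] = []
    for h in hubs:
        m = int(rng.integers(lo_t, hi_t + 1))
        for _ in range(m):
            t = f"t-{len(terminals):05d}"
            terminals.append(t)
            edges.append((h, t))

    independents = [f"deg-{i:04d}" for i in range(n_independent)]
    background = [f"bg-{i:05d}" for i in range(n_background)]

    # response curves at the non-zero timepoints
    tps = np.asarray(sorted(int(t) for t in timepoints_h))
    nz = tps[tps > 0]
    if nz.size == 0:
        raise ValueError("need at least one non-zero timepoint for effects")
    affected = supers + hubs + terminals + independents
    delta = pd.DataFrame(
        np.zeros((len(affected), nz.size)), index=affected, columns=[int(t) for t in nz]
    )
    effect: dict[str, Effect] = {}
    for s in supers:
        curve, size, sign = _draw_effect_curve(rng, nz, effect_size)
        delta.loc[s] = curve
        effect[s] = Effect(size=size, timepoints_h=tuple(int(t) for t in nz[curve != 0]), sign=sign)
    parent_map: dict[str, list[str]] = {}
    for p, c in edges:
        parent_map.setdefault(c, []).append(p)
    def _add_intrinsic(mix: np.ndarray, rel_range: tuple[float, float]) -> np.ndarray:
        """Child's own response on top of the parent mixture, scaled relative
        to the inherited peak, with its own window and sign. Without an
        intrinsic part a child is a scalar multiple of its parent, siblings
        become statistically indistinguishable from parent-child pairs, and
        the planted tree is unrecoverable by any dependence measure; with a
        sign-aligned intrinsic part all curves collapse onto near-parallel
        positive bumps and unrelated genes correlate pervasively instead."""
        rel = float(rng.uniform(*rel_range))
        own, _, _ = _draw_effect_curve(rng, nz, (1.0, 1.0))
        own_sd = float(own.std())
        mix_sd = float(mix.std()) if float(mix.std()) > 0 else float(np.abs(mix).max())
        if own_sd == 0.0:
            return mix
        own = rel * (mix_sd / own_sd) * own
        # avoid destructive interference: flip the intrinsic curve globally if
        # it opposes the inherited response at the intrinsic peak (windows
        # stay random, so sibling curves do not become parallel)
        i_peak = int(np.argmax(np.abs(own)))
        if mix[i_peak] != 0 and own[i_peak] * mix[i_peak] < 0:
            own = -own
        return mix + own

    def _array_var(curve: np.ndarray) -> float:
        """Across-array variance of a response curve under the default
        layout: the curve appears in the stress arrays, zero elsewhere."""
        slots = np.concatenate([np.zeros(tps.size + (1 if 0 in tps else 0)), curve])
        return float(slots.var())

    weights: dict[tuple[str, str], float] = {}
    eff_noise_var: dict[str, float] = {g: noise_sd**2 for g in affected}
    for h in hubs:
        curve = np.zeros(nz.size)
        nvar = noise_sd**2
        for p in parent_map[h]:
            w = float(rng.uniform(*weight_range))
            contrib = w * delta.loc[p].to_numpy()
            # multi-parent mixtures: flip a later parent's contribution if it
            # opposes the accumulated response at its own peak, so random
            # parent signs cannot cancel a hub's response to uncallability;
            # the signed weight also scales the inherited noise so the shared
            # component stays coherent
            i_peak = int(np.argmax(np.abs(contrib)))
            if curve[i_peak] != 0 and contrib[i_peak] * curve[i_peak] < 0:
                contrib = -contrib
                w = -w
            weights[(p, h)] = w
            curve = curve + contrib
            nvar += w**2 * eff_noise_var[p]
        curve = _add_intrinsic(curve, hub_intrinsic_rel)
        delta.loc[h] = curve
        eff_noise_var[h] = nvar
        effect[h] = _effect_from_delta(curve, nz)
    for t in terminals:
        (h,) = parent_map[t]
        # peak-targeted mixture weight: every terminal responds at a
        # callable magnitude, and with the per-measurement noise fixed this
        # also pins each terminal's hub-explained variance share into a
        # narrow band -- uniformly separated from both the significance
        # threshold and the sibling correlations DPI must discriminate
        # against (a wide weight range would make strong-weight terminals
        # near-clones of their hub and weak-weight ones uncallable)
        hub_peak = float(np.abs(delta.loc[h]).max())
        w = float(rng.uniform(*terminal_peak)) / hub_peak if hub_peak > 0 else 1.0
        weights[(h, t)] = w
        curve = w * delta.loc[h].to_numpy()
        delta.loc[t] = curve
        eff_noise_var[t] = noise_sd**2 + w**2 * eff_noise_var[h]
        effect[t] = _effect_from_delta(curve, nz)
    for g in independents:
        curve, size, sign = _draw_effect_curve(rng, nz, independent_effect_size)
        delta.loc[g] = curve
        effect[g] = Effect(size=size, timepoints_h=tuple(int(t) for t in nz[curve != 0]), sign=sign)

    return PlantedTruth(
        superhub_ids=tuple(supers),
        hub_ids=tuple(hubs),
        terminal_ids=tuple(terminals),
        independent_ids=tuple(independents),
        background_ids=tuple(background),
        edges=tuple(edges),
        effect=effect,
        delta=delta,
        noise_sd=float(noise_sd),
        weights=weights,
        hubs_per_super_range=(lo_h, hi_h),
    )


def study_scale_truth(seed: int, *, noise_sd: float = 0.3) -> PlantedTruth:
    """Planted truth at the published study's scale (see :data:`STUDY_SCALE`)."""
    return generate_planted_network(
        STUDY_SCALE["n_super"],
        STUDY_SCALE["hubs_per_super"],
        STUDY_SCALE["terminals_per_hub"],
        STUDY_SCALE["n_background"],
        seed,
        n_hubs=STUDY_SCALE["n_hubs"],
        n_independent=STUDY_SCALE["n_independent"],
        noise_sd=noise_sd,
    )


def simulate_expression(
    truth: PlantedTruth, design: StudyDesign, seed: int
) -> ExpressionMatrix:
    """Sample a log2 expression matrix for a planted truth under a design.

    Per-gene baselines are Normal(8, 1.5) on the log2 scale (typical
    microarray intensity range); stress arrays add the planted per-timepoint
    log2 fold-change; every gene gets its own additive Gaussian noise with
    sd ``truth.noise_sd``. Child profiles are mixtures of their parents'
    profiles: baselines and planted effects are already folded into the
    child's own baseline/delta, so operationally a child additionally
    inherits its parents' (recursively accumulated) noise vectors scaled by
    the regulatory mixture weights. That shared array-space fingerprint is
    what distinguishes a regulator-target pair from two genes that merely
    respond with similar temporal shapes. Control and stress arrays share
    baselines and noise structure, so with zero noise the realized
    stress - control difference equals the planted effect exactly.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    genes = list(truth.all_gene_ids)
    arrays = list(design.arrays())
    n_arrays = len(arrays)
    baseline = rng.normal(8.0, 1.5, size=len(genes))
    values = np.tile(baseline[:, None], (1, n_arrays))

    # planted stress effects
    delta_cols = {int(c): i for i, c in enumerate(truth.delta.columns)}
    delta_mat = truth.delta.to_numpy()
    row_of = {g: i for i, g in enumerate(truth.delta.index)}
    stress_cols = [
        (j, delta_cols[int(tp)])
        for j, (cond, tp, _rep) in enumerate(arrays)
        if cond == design.stress and int(tp) in delta_cols
    ]
    gene_rows = [(i, row_of[g]) for i, g in enumerate(genes) if g in row_of]
    for j, col in stress_cols:
        for i, r in gene_rows:
            values[i, j] += delta_mat[r, col]

    # own noise plus inherited parent noise (topological: parents precede
    # children in all_gene_ids order)
    if truth.noise_sd > 0:
        index = {g: i for i, g in enumerate(genes)}
        noise = rng.normal(0.0, truth.noise_sd, size=(len(genes), n_arrays))
        children: dict[str, list[tuple[str, float]]] = {}
        for (p, c), w in truth.weights.items():
            children.setdefault(p, []).append((c, w))
        for g in genes:  # parents first; effective noise accumulates
            for c, w in children.get(g, ()):
                noise[index[c]] += w * noise[index[g]]
        values = values + noise
    return ExpressionMatrix.from_arrays(genes, arrays, values)


def select_tf_ids(
    truth: PlantedTruth,
    seed: int,
    *,
    n_decoy_independent: int = 100,
    n_decoy_background: int = 50,
) -> tuple[str, ...]:
    """Transcription-factor list: all superhubs plus decoy TFs.

    Decoys are sampled from the independent responders and the silent
    background, i.e. genes that are TFs by annotation but not at the top of
    the planted hierarchy.
    """
    rng = np.random.default_rng(seed)
    n_di = min(n_decoy_independent, len(truth.independent_ids))
    n_db = min(n_decoy_background, len(truth.background_ids))
    decoys_i = rng.choice(len(truth.independent_ids), size=n_di, replace=False) if n_di else []
    decoys_b = rng.choice(len(truth.background_ids), size=n_db, replace=False) if n_db else []
    tfs = (
        list(truth.superhub_ids)
        + [truth.independent_ids[i] for i in sorted(map(int, decoys_i))]
        + [truth.background_ids[i] for i in sorted(map(int, decoys_b))]
    )
    return tuple(tfs)


def generate_annotations(
    truth: PlantedTruth,
    seed: int,
    *,
    family_coverage: float = 0.8,
    n_random_categories: int = 25,
    random_category_size: tuple[int, int] = (40, 400),
) -> pd.DataFrame:
    """Gene -> category annotation table with planted enrichment.

    One "family" category per superhub covers ``family_coverage`` of that
    superhub's descendants (hubs + terminals), giving a known
    over-represented category per subnetwork; additional random categories
    over all genes provide a null reference. Returns a tidy frame with
    columns (gene_id, category_id, category_name).
    """
    if not 0.0 < family_coverage <= 1.0:
        raise ValueError("family_coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    for s in truth.superhub_ids:
        members = [s] + list(truth.descendants_of(s))
        n_keep = max(1, int(round(family_coverage * len(members))))
        keep = rng.choice(len(members), size=n_keep, replace=False)
        cat = f"FAM:{s}"
        name = f"regulon of {s}"
        rows.extend((members[i], cat, name) for i in sorted(map(int, keep)))
    all_genes = list(truth.all_gene_ids)
    lo, hi = random_category_size
    for j in range(n_random_categories):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(all_genes))
        pick = rng.choice(len(all_genes), size=size, replace=False)
        cat = f"RND:{j:03d}"
        name = f"random category {j}"
        rows.extend((all_genes[i], cat, name) for i in sorted(map(int, pick)))
    return pd.DataFrame(rows, columns=["gene_id", "category_id", "category_name"])
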