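"""Synthetic microbial worlds with planted eco-evolutionary HGT structure.

The generator is a stand-in for the real data sources of the analysis
(reference pangenome databases and large environmental-sample profile
collections) and is explicitly *not* a model of the real data-generating
process; every choice below is a documented fabrication whose only purpose
is to give each pipeline stage a recoverable ground truth:

* a Yule species tree;
* environment-structured relative abundances in which co-occurrence decays
  with phylogenetic distance approximately as ``CO ~ k * PD**a`` (a niche
  kernel: Brownian niche positions on the tree plus a Gaussian presence
  kernel in niche space gives an asymptotic power law with exponent
  ``-d/2`` for a ``d``-dimensional niche);
* pairwise transfer counts whose Poisson log-rate increases with the
  co-occurrence residual, with abundance tier, and between same-habitat
  specialists, while decaying with phylogenetic distance;
* pangenome ubiquities in which transferred genes are cloud-enriched with
  a configurable odds ratio;
* multi-label functional annotations with optional planted per-cell
  enrichments;
* per-family reconciliation replicate sets in which true transfers are
  flagged with probability ``1 - support_noise`` and spurious ones appear
  with probability ``support_noise``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import ENVIRONMENTS, AbundanceMatrix
from .events import HGTCountMatrix, ReconciliationSample, TransferEvent
from .trees import PhyloTree, simulate_yule_tree
from .cooccurrence import (
    co_occurrence_matrix,
    fit_power_law,
    presence_matrix,
)

# disjoint sampling ranges that populate the five nested gene-distance bins
GENE_DISTANCE_COMPONENTS = (
    (0.001, 0.01),
    (0.01, 0.05),
    (0.05, 0.25),
    (0.25, 0.50),
    (0.50, 0.75),
)
GENE_DISTANCE_WEIGHTS = (0.10, 0.15, 0.35, 0.20, 0.20)

DEFAULT_CATEGORIES = ("C", "E", "G", "J", "K", "L", "M", "P", "T", "V")


@dataclass
class WorldConfig:
    """All knobs of a synthetic world.  Defaults define the standard study
    conditions used throughout the tests; see the methods note."""

    n_species: int = 200
    n_samples: int = 1000
    env_fractions: tuple[float, float, float, float] = (0.35, 0.30, 0.20, 0.15)
    cooccur_k: float = 0.5  # target co-occurrence amplitude near PD ~ 1
    cooccur_a: float = -0.5  # power-law exponent of the CO-PD decay
    hgt_base_rate: float = 0.5
    hgt_pd_decay: float = 0.8
    beta_residual: float = 4.0
    beta_abundance: float = 0.4
    specialist_boost: float = 1.0
    cloud_odds_ratio: float = 2.0
    n_gene_families: int = 5000
    n_reconciliations: int = 100
    support_noise: float = 0.05
    seed: int = 0

    # generator internals / secondary conditions
    specialist_fraction: float = 0.5
    species_per_otu: int = 1
    base_presence: float = 0.95
    niche_rate: float = 1.8  # Brownian variance per unit branch length
    niche_kernel_width: float = 0.15
    sample_niche_sd: float = 1.5
    abundance_scale_median: float = 2e-3
    abundance_scale_sigma: float = 1.0
    cloud_base_p: float = 0.35
    annotation_background: float = 0.10
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    # plantings: (species_bin 1-3, gene_bin a-e, category, fold)
    enrichment_plantings: tuple[tuple[int, str, str, float], ...] = ()

    def __post_init__(self):
        if self.n_species < 2 or self.n_samples < 2:
            raise ValueError("all counts must be >= 2")
        if self.n_gene_families < 2 or self.n_reconciliations < 2:
            raise ValueError("all counts must be >= 2")
        if abs(sum(self.env_fractions) - 1.0) > 1e-9:
            raise ValueError("env_fractions must sum to 1")
        for p in (self.support_noise, self.specialist_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cooccur_k <= 0 or self.cloud_odds_ratio <= 0:
            raise ValueError("cooccur_k and cloud_odds_ratio must be positive")
        if self.hgt_base_rate < 0:
            raise ValueError("hgt_base_rate must be non-negative")


@dataclass
class FamilyReconciliation:
    gene_family_id: str
    gene_tree: PhyloTree
    samples: list[ReconciliationSample]
    true_event_nodes: list[str]


@dataclass
class SyntheticWorld:
    config: WorldConfig
    species_tree: PhyloTree
    species_to_otu: dict[str, str]
    abundance: AbundanceMatrix
    otu_traits: pd.DataFrame
    true_transfer_counts: HGTCountMatrix
    transfer_events: list[TransferEvent]
    pangenomes: pd.DataFrame
    annotations: dict[str, set[str]]
    reconciliation_sets: dict[str, FamilyReconciliation]
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_species: int, seed: int) -> PhyloTree:
    """Yule tree with ``n_species`` uniquely named leaves, labelled internal
    nodes and mean pairwise patristic distance 1."""
    tree = simulate_yule_tree(n_species, seed=seed, mean_pairwise_distance=1.0)
    for i, node in enumerate(tree.dendropy_tree.preorder_internal_node_iter()):
        node.label = f"N{i:04d}"
    return tree


# ---------------------------------------------------------------------------
# abundance


def _niche_dimension(cooccur_a: float) -> int:
    if cooccur_a == 0:
        return 1
    return max(1, round(-2.0 * cooccur_a))


def _brownian_traits(
    tree: PhyloTree, rate: float, dims: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        parent = node.parent_node
        base = values[id(parent)] if parent is not None else np.zeros(dims)
        edge = node.edge.length or 0.0
        step = rng.normal(0.0, math.sqrt(max(rate * edge, 0.0)), size=dims)
        values[id(node)] = base + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def simulate_abundance_matrix(
    tree: PhyloTree,
    config: WorldConfig,
    rng: np.random.Generator,
    otus: Sequence[str] | None = None,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Environment-structured abundances with a planted CO-PD decay.

    Returns the abundance bundle and a per-OTU trait table (preferred
    environment, specialist flag, latent abundance scale and tier).
    """
    otus = list(otus) if otus is not None else tree.leaf_names
    n, m = len(otus), config.n_samples
    dims = _niche_dimension(config.cooccur_a)
    rate = 0.0 if config.cooccur_a == 0 else config.niche_rate
    w = config.niche_kernel_width

    sample_ids = [f"sample{j:05d}" for j in range(m)]
    env_idx = rng.choice(4, size=m, p=np.asarray(config.env_fractions))
    sample_env = pd.Series(
        [ENVIRONMENTS[i] for i in env_idx], index=sample_ids, name="environment"
    )
    x = rng.normal(0.0, config.sample_niche_sd, size=(m, dims))

    niche = _brownian_traits(tree, rate, dims, rng)
    c = np.stack([niche[o] for o in otus])  # (n, dims)

    pref_idx = rng.choice(4, size=n, p=np.asarray(config.env_fractions))
    specialist = rng.random(n) < config.specialist_fraction
    env_w = np.empty((n, 4))
    for i in range(n):
        if specialist[i]:
            env_w[i] = 0.03
        else:
            env_w[i] = 1.0 - rng.uniform(0.05, 0.20, size=4)
        env_w[i, pref_idx[i]] = 1.0

    sq = ((c[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)  # (n, m)
    kernel = np.exp(-sq / (2.0 * w * w))
    base_p = min(0.95, config.base_presence * 3.5 ** (dims - 1))
    p = base_p * env_w[:, env_idx] * kernel
    present = rng.random((n, m)) < p

    scale = rng.lognormal(
        math.log(config.abundance_scale_median), config.abundance_scale_sigma, size=n
    )
    noise = rng.lognormal(0.0, 0.5, size=(n, m))
    values = np.where(present, np.maximum(scale[:, None] * noise, 1e-4), 0.0)
    colsum = values.sum(axis=0)
    over = colsum > 1.0
    if np.any(over):
        values[:, over] *= 0.99 / colsum[over]

    matrix = pd.DataFrame(values, index=otus, columns=sample_ids)
    hi = scale > np.quantile(scale, 0.8)
    lo = scale < np.quantile(scale, 0.2)
    traits = pd.DataFrame(
        {
            "preferred_env": [ENVIRONMENTS[i] for i in pref_idx],
            "specialist": specialist,
            "abundance_scale": scale,
            "high_tier": hi,
            "low_tier": lo,
        },
        index=otus,
    )
    return AbundanceMatrix(matrix=matrix, sample_env=sample_env), traits


# ---------------------------------------------------------------------------
# transfers


def simulate_transfers(
    tree: PhyloTree,
    abundance: AbundanceMatrix,
    traits: pd.DataFrame,
    config: WorldConfig,
    rng: np.random.Generator,
    otu_to_species: Mapping[str, str] | None = None,
) -> tuple[HGTCountMatrix, list[TransferEvent], dict]:
    """Poisson pairwise transfer counts with planted log-linear effects.

    The log rate is ``log(hgt_base_rate) - hgt_pd_decay * PD +
    beta_residual * (CO - k PD^a) + beta_abundance * (hi_i + hi_j - lo_i -
    lo_j) + specialist_boost * [same-habitat specialist pair]``.  One
    planted event (its own gene family) is emitted per transferred gene;
    gene distances come from a mixture spanning the enrichment grid's
    nested bins.
    """
    otus = abundance.otus
    species = [otu_to_species[o] if otu_to_species else o for o in otus]
    missing = [s for s in species if s not in tree]
    if missing:
        raise ValueError(f"abundance/tree OTU mismatch: {missing[:5]}")

    _, pd_mat = tree.distance_matrix(species)
    presence = presence_matrix(abundance.matrix)
    co = co_occurrence_matrix(presence).to_numpy()

    iu = np.triu_indices(len(otus), 1)
    pd_flat, co_flat = pd_mat[iu], co[iu]
    valid = ~np.isnan(co_flat) & (pd_flat > 0)
    if config.beta_residual != 0.0 and valid.sum() >= 3:
        fit = fit_power_law(pd_flat[valid], co_flat[valid])
        safe_pd = np.where(pd_mat > 0, pd_mat, 1.0)  # diagonal is never used
        resid_mat = co - fit.k * np.power(safe_pd, fit.a)
        fit_params = {"k": fit.k, "a": fit.a}
    else:
        resid_mat = np.zeros_like(co)
        fit_params = None
    resid_mat = np.nan_to_num(resid_mat, nan=0.0)

    hi = traits["high_tier"].to_numpy(dtype=float)
    lo = traits["low_tier"].to_numpy(dtype=float)
    spec = traits["specialist"].to_numpy(dtype=bool)
    pref = traits["preferred_env"].to_numpy()

    tier_term = (hi[:, None] + hi[None, :]) - (lo[:, None] + lo[None, :])
    same_spec = (
        spec[:, None] & spec[None, :] & (pref[:, None] == pref[None, :])
    )
    if config.hgt_base_rate == 0:
        rates = np.zeros_like(pd_mat)
    else:
        log_rate = (
            math.log(config.hgt_base_rate)
            - config.hgt_pd_decay * pd_mat
            + config.beta_residual * resid_mat
            + config.beta_abundance * tier_term
            + config.specialist_boost * same_spec
        )
        rates = np.exp(log_rate)
    counts_flat = rng.poisson(rates[iu])

    comp = rng.choice(
        len(GENE_DISTANCE_COMPONENTS),
        size=int(counts_flat.sum()),
        p=np.asarray(GENE_DISTANCE_WEIGHTS),
    )
    lo_hi = np.asarray(GENE_DISTANCE_COMPONENTS)
    gene_d = rng.uniform(lo_hi[comp, 0], lo_hi[comp, 1])

    counts = HGTCountMatrix()
    events: list[TransferEvent] = []
    width = max(6, len(str(int(counts_flat.sum())) ) )
    e = 0
    for (i, j), c in zip(zip(*iu), counts_flat):
        if c == 0:
            continue
        counts.add(otus[i], otus[j], int(c))
        for _ in range(int(c)):
            fam = f"F{e:0{width}d}"
            donor, recipient = (
                (species[i], species[j]) if rng.random() < 0.5
                else (species[j], species[i])
            )
            events.append(
                TransferEvent(
                    gene_family_id=fam,
                    gene_node_id=f"{fam}_E",
                    donor_leaves=frozenset({donor}),
                    recipient_leaves=frozenset({recipient}),
                    support_fraction=1.0,
                    min_branch_support=1.0,
                    mean_gene_distance=float(gene_d[e]),
                    mean_species_distance=float(pd_mat[i, j]),
                )
            )
            e += 1
    truth = {"power_law_fit": fit_params, "n_events": len(events)}
    return counts, events, truth


# ---------------------------------------------------------------------------
# gene families: pangenomes, annotations, reconciliation sets


def _caterpillar_gene_tree(
    family: str,
    core_pair: tuple[str, str] | None,
    extra_species: Sequence[str],
    gene_distance: float,
    rng: np.random.Generator,
) -> tuple[PhyloTree, str | None]:
    """Small gene tree: an optional transfer cherry (donor, recipient) at
    patristic distance ``gene_distance``, with the remaining species
    attached as a caterpillar above it.  Returns the tree and the id of the
    transfer node (None for families without an event)."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    node_i = 0

    def leaf(name: str, length: float) -> dendropy.Node:
        n = dendropy.Node()
        n.taxon = taxa.new_taxon(name)
        n.edge.length = length
        return n

    if core_pair is not None:
        donor, recipient = core_pair
        core = dendropy.Node()
        core.label = f"{family}_E"
        core.support = float(rng.uniform(0.65, 1.0))
        core.add_child(leaf(donor, gene_distance / 2.0))
        core.add_child(leaf(recipient, gene_distance / 2.0))
        core.edge.length = float(rng.uniform(0.02, 0.1))
        event_node = core.label
        depth = gene_distance / 2.0
    else:
        first, second = extra_species[0], extra_species[1]
        extra_species = extra_species[2:]
        core = dendropy.Node()
        core.label = f"{family}_n{node_i}"
        node_i += 1
        core.support = float(rng.uniform(0.4, 1.0))
        d0 = float(rng.uniform(0.05, 0.4))
        core.add_child(leaf(first, d0))
        core.add_child(leaf(second, d0))
        core.edge.length = float(rng.uniform(0.02, 0.1))
        event_node = None
        depth = d0

    current = core
    for sp in extra_species:
        parent = dendropy.Node()
        parent.label = f"{family}_n{node_i}"
        node_i += 1
        parent.support = float(rng.uniform(0.4, 1.0))
        depth += current.edge.length
        parent.add_child(current)
        parent.add_child(leaf(sp, depth + float(rng.uniform(0.02, 0.2))))
        parent.edge.length = float(rng.uniform(0.02, 0.1))
        current = parent
    current.edge.length = None
    tree.seed_node = current
    return PhyloTree(tree), event_node


def _planted_fold(
    config: WorldConfig, event: TransferEvent, category: str, grid
) -> float:
    if not config.enrichment_plantings:
        return 1.0
    sbin = grid.species_bin(event.mean_species_distance)
    gbins = grid.gene_bin_set(event.mean_gene_distance or -1.0)
    fold = 1.0
    for p_sbin, p_gbin, p_cat, p_fold in config.enrichment_plantings:
        if p_cat == category and p_sbin == sbin and p_gbin in gbins:
            fold = max(fold, p_fold)
    return fold


def simulate_gene_families(
    config: WorldConfig,
    transfer_events: Sequence[TransferEvent],
    tree: PhyloTree,
    rng: np.random.Generator,
    with_reconciliations: bool = True,
) -> tuple[pd.DataFrame, dict[str, set[str]], dict[str, FamilyReconciliation]]:
    """Pangenome rows, annotations and reconciliation replicate sets.

    Transferred (species, family) pangenome rows fall in the cloud class
    with odds ``cloud_odds_ratio`` times the non-transferred odds; the
    integer genome counts are drawn within the chosen class's valid range
    so rounding never crosses a class boundary.
    """
    from .enrichment import BinGrid

    grid = BinGrid()
    all_species = tree.leaf_names
    species_genomes = {
        sp: int(rng.integers(8, 41)) for sp in all_species
    }

    events_by_family = {e.gene_family_id: e for e in transfer_events}
    n_event_fams = len(events_by_family)
    fam_width = max(6, len(str(config.n_gene_families)))
    null_fams = [
        f"N{idx:0{fam_width}d}"
        for idx in range(max(0, config.n_gene_families - n_event_fams))
    ]

    p0 = config.cloud_base_p
    odds1 = config.cloud_odds_ratio * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)

    def draw_count(total: int, transferred: bool) -> int:
        p_cloud = p1 if transferred else p0
        if rng.random() < p_cloud:
            hi = max(1, math.floor(0.15 * total))
            return int(rng.integers(1, hi + 1))
        lo_shell = math.floor(0.15 * total) + 1
        hi_shell = math.ceil(0.90 * total) - 1
        if rng.random() < 0.6 and lo_shell <= hi_shell:
            return int(rng.integers(lo_shell, hi_shell + 1))
        lo_core = math.ceil(0.90 * total)
        return int(rng.integers(lo_core, total + 1))

    pangenome_rows = []
    annotations: dict[str, set[str]] = {}
    reconciliations: dict[str, FamilyReconciliation] = {}
    bg = config.annotation_background

    def annotate(family: str, event: TransferEvent | None) -> None:
        cats = set()
        for cat in config.categories:
            p_cat = bg
            if event is not None:
                p_cat = min(1.0, bg * _planted_fold(config, event, cat, grid))
            if rng.random() < p_cat:
                cats.add(cat)
        annotations[family] = cats

    def reconcile(
        family: str,
        gtree: PhyloTree,
        event_node: str | None,
        event: TransferEvent | None,
    ) -> FamilyReconciliation:
        fam_species = sorted({lf.split("|", 1)[0] for lf in gtree.leaf_names})
        internal = [
            n.label
            for n in gtree.dendropy_tree.preorder_internal_node_iter()
            if n.label is not None and n.label != event_node
        ]
        samples = []
        for _ in range(config.n_reconciliations):
            transfers: dict[str, tuple[str, str]] = {}
            if event is not None and rng.random() >= config.support_noise:
                donor = next(iter(event.donor_leaves))
                recipient = next(iter(event.recipient_leaves))
                transfers[event_node] = (donor, recipient)
            if internal and rng.random() < config.support_noise:
                node = internal[int(rng.integers(len(internal)))]
                d, r = rng.choice(fam_species, size=2, replace=False)
                transfers[node] = (str(d), str(r))
            samples.append(
                ReconciliationSample(
                    gene_family_id=family, root_id="r1", transfers=transfers
                )
            )
        return FamilyReconciliation(
            gene_family_id=family,
            gene_tree=gtree,
            samples=samples,
            true_event_nodes=[event_node] if event_node else [],
        )

    for family, event in events_by_family.items():
        donor = next(iter(event.donor_leaves))
        recipient = next(iter(event.recipient_leaves))
        pool = [s for s in all_species if s not in (donor, recipient)]
        k = int(rng.integers(2, 7))
        extras = [str(s) for s in rng.choice(pool, size=k, replace=False)]
        fam_species = [donor, recipient, *extras]
        for sp in fam_species:
            total = species_genomes[sp]
            transferred = sp in (donor, recipient)
            pangenome_rows.append(
                (sp, family, draw_count(total, transferred), total)
            )
        annotate(family, event)
        if with_reconciliations:
            gtree, event_node = _caterpillar_gene_tree(
                family, (donor, recipient), extras, event.mean_gene_distance, rng
            )
            reconciliations[family] = reconcile(family, gtree, event_node, event)

    for family in null_fams:
        k = int(rng.integers(4, 9))
        fam_species = [str(s) for s in rng.choice(all_species, size=k, replace=False)]
        for sp in fam_species:
            total = species_genomes[sp]
            pangenome_rows.append((sp, family, draw_count(total, False), total))
        annotate(family, None)
        if with_reconciliations:
            gtree, _ = _caterpillar_gene_tree(family, None, fam_species, 0.0, rng)
            reconciliations[family] = reconcile(family, gtree, None, None)

    pangenome = pd.DataFrame(
        pangenome_rows,
        columns=["species_id", "gene_family_id", "genomes_with_gene", "genomes_total"],
    )
    return pangenome, annotations, reconciliations


# ---------------------------------------------------------------------------
# orchestration


def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a full synthetic world; bit-deterministic given the config."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_species_tree(config.n_species, seed=int(rng.integers(2**31)))

    leaves = tree.leaf_names
    if config.species_per_otu > 1:
        groups = [
            leaves[i : i + config.species_per_otu]
            for i in range(0, len(leaves), config.species_per_otu)
        ]
        species_to_otu = {sp: grp[0] for grp in groups for sp in grp}
        otus = [grp[0] for grp in groups]
    else:
        species_to_otu = {sp: sp for sp in leaves}
        otus = leaves

    abundance, traits = simulate_abundance_matrix(tree, config, rng, otus=otus)
    counts, events, transfer_truth = simulate_transfers(
        tree, abundance, traits, config, rng
    )
    pangenome, annotations, reconciliations = simulate_gene_families(
        config, events, tree, rng
    )
    truth = {
        "config": asdict(config),
        **transfer_truth,
        "n_gene_families": len(reconciliations),
    }
    return SyntheticWorld(
        config=config,
        species_tree=tree,
        species_to_otu=species_to_otu,
        abundance=abundance,
        otu_traits=traits,
        true_transfer_counts=counts,
        transfer_events=events,
        pangenomes=pangenome,
        annotations=annotations,
        reconciliation_sets=reconciliations,
        truth=truth,
    )
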