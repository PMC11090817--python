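"""Aggregation of reconciliation replicates into supported transfer events.

A DTL reconciliation maps each internal gene-tree node to an event
(speciation, duplication or transfer with a donor and recipient species
node).  Reconciliation is run many times per gene family (and per optimal
root); a transfer call is retained only when it is supported by a large
fraction of replicates and by the gene tree's branch supports.  This module
also derives the per-event mean gene/species distances, per-species
transferred-gene fractions and the symmetric per-pair transfer-count
matrix used by all ecological stages.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trees import PhyloTree

logger = logging.getLogger(__name__)


def species_of_gene(gene_leaf: str) -> str:
    """Gene leaves are named ``<species>`` or ``<species>|<copy>``."""
    return gene_leaf.split("|", 1)[0]


@dataclass(frozen=True)
class ReconciliationSample:
    """One reconciliation replicate: gene-tree node -> transfer mapping.

    Only transfer-labelled nodes are recorded; all other internal nodes are
    implicitly speciations/duplications.  ``transfers`` maps a gene-tree
    internal node id to ``(donor_label, recipient_label)`` where the labels
    name species-tree nodes (leaf names or internal labels).
    """

    gene_family_id: str
    root_id: str
    transfers: Mapping[str, tuple[str, str]] = field(default_factory=dict)


@dataclass
class TransferEvent:
    gene_family_id: str
    gene_node_id: str
    donor_leaves: frozenset[str]
    recipient_leaves: frozenset[str]
    support_fraction: float
    min_branch_support: float
    mean_gene_distance: float | None = None
    mean_species_distance: float | None = None
    via_multifurcation_rule: bool = False


class HGTCountMatrix:
    """Symmetric sparse counts of transferred gene families per taxon pair."""

    def __init__(self):
        self._counts: dict[tuple[str, str], int] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def add(self, a: str, b: str, n: int = 1) -> None:
        if a == b:
            raise ValueError("diagonal entries are not allowed")
        key = self._key(a, b)
        self._counts[key] = self._counts.get(key, 0) + n

    def get(self, a: str, b: str) -> int:
        if a == b:
            return 0
        return self._counts.get(self._key(a, b), 0)

    def items(self):
        return self._counts.items()

    def __len__(self) -> int:
        return len(self._counts)

    def taxa(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._counts:
            out.add(a)
            out.add(b)
        return out

    def total(self) -> int:
        return sum(self._counts.values())

    def partners(self) -> dict[str, set[str]]:
        """Per taxon, the set of partners with at least one transfer."""
        out: dict[str, set[str]] = defaultdict(set)
        for (a, b), n in self._counts.items():
            if n > 0:
                out[a].add(b)
                out[b].add(a)
        return dict(out)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(a, b, n) for (a, b), n in sorted(self._counts.items())]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "n_genes"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HGTCountMatrix":
        mat = cls()
        for a, b, n in df[["otu_a", "otu_b", "n_genes"]].itertuples(index=False):
            mat.add(str(a), str(b), int(n))
        return mat


# ---------------------------------------------------------------------------
# aggregation


def _resolve_species_set(
    species_tree: PhyloTree, label: str, family_species: set[str]
) -> frozenset[str]:
    """Species-leaf set mapped by a reconciliation label, restricted to the
    species actually present in the gene family."""
    leaves = species_tree.leaves_under(label)
    restricted = leaves & family_species
    return frozenset(restricted if restricted else leaves)


def _event_min_branch_support(
    gene_tree: PhyloTree, left: Iterable[str], right: Iterable[str]
) -> float:
    vals = [
        gene_tree.min_support_on_path(a, b) for a in left for b in right
    ]
    return min(vals) if vals else 1.0


def aggregate_and_filter(
    samples: Sequence[ReconciliationSample],
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    identity_pairs: Iterable[tuple[str, str]] = (),
    min_support: float = 0.8,
    min_branch_support: float = 0.5,
    max_roots: int = 50,
    overlap: Mapping[tuple[str, str], float] | None = None,
    min_overlap: float = 0.5,
) -> list[TransferEvent]:
    """Pool reconciliation replicates (across optimal roots) into events.

    A gene-tree node becomes a :class:`TransferEvent` when it is labelled a
    transfer in at least ``min_support`` of all replicates (pooled
    denominator over all optimal roots) and the minimum branch support over
    the gene-tree paths between its left and right descendant leaves is at
    least ``min_branch_support``.  Families with more than ``max_roots``
    distinct optimal roots are excluded entirely.  Multifurcating nodes
    containing 100%-identical genes from different species are emitted as
    events regardless of replicate support.
    """
    if not samples:
        raise ValueError("empty reconciliation sample list")
    family = samples[0].gene_family_id
    if any(s.gene_family_id != family for s in samples):
        raise ValueError("samples span more than one gene family")

    roots = {s.root_id for s in samples}
    if len(roots) > max_roots:
        logger.warning(
            "family %s excluded: %d optimal roots > max_roots=%d",
            family, len(roots), max_roots,
        )
        return []

    total = len(samples)
    flag_counts: Counter[str] = Counter()
    mappings: dict[str, Counter] = defaultdict(Counter)
    for s in samples:
        for node_id, (donor, recipient) in s.transfers.items():
            flag_counts[node_id] += 1
            mappings[node_id][(donor, recipient)] += 1

    family_species = {species_of_gene(lf) for lf in gene_tree.leaf_names}
    events: list[TransferEvent] = []
    for node_id, count in sorted(flag_counts.items()):
        support_fraction = count / total
        if support_fraction < min_support:
            continue
        donor_label, recipient_label = mappings[node_id].most_common(1)[0][0]
        donor = _resolve_species_set(species_tree, donor_label, family_species)
        recipient = _resolve_species_set(species_tree, recipient_label, family_species)
        recipient = recipient - donor
        if not recipient:
            continue
        left, right = _gene_children_leaves(gene_tree, node_id)
        branch_support = _event_min_branch_support(gene_tree, left, right)
        if branch_support < min_branch_support:
            continue
        event = TransferEvent(
            gene_family_id=family,
            gene_node_id=node_id,
            donor_leaves=donor,
            recipient_leaves=recipient,
            support_fraction=support_fraction,
            min_branch_support=branch_support,
        )
        g, s = event_mean_distances(
            event, gene_tree, species_tree, overlap=overlap, min_overlap=min_overlap
        )
        event.mean_gene_distance = g
        event.mean_species_distance = s
        events.append(event)

    events.extend(
        _multifurcation_events(gene_tree, species_tree, identity_pairs, family)
    )
    return events


def _gene_children_leaves(
    gene_tree: PhyloTree, node_id: str
) -> tuple[set[str], set[str]]:
    """Leaf names under the first child vs the remaining children."""
    node = gene_tree.find_node(node_id)
    if node is None:
        raise KeyError(f"gene-tree node {node_id!r} not found")
    if node.is_leaf():
        name = node.taxon.label if node.taxon is not None else node.label
        return {name}, set()
    children = node.child_nodes()

    def leaves(n):
        return {
            lf.taxon.label if lf.taxon is not None else lf.label
            for lf in n.leaf_iter()
        }

    left = leaves(children[0])
    right = set().union(*(leaves(c) for c in children[1:]))
    return left, right


def _multifurcation_events(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    identity_pairs: Iterable[tuple[str, str]],
    family: str,
) -> list[TransferEvent]:
    """Multifurcations containing cross-species identical genes are HGT."""
    identity = {frozenset(p) for p in identity_pairs}
    if not identity:
        return []
    events = []
    for node in gene_tree.dendropy_tree.preorder_internal_node_iter():
        if len(node.child_nodes()) <= 2:
            continue
        leaves = sorted(
            lf.taxon.label if lf.taxon is not None else lf.label
            for lf in node.leaf_iter()
        )
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                if frozenset((a, b)) not in identity:
                    continue
                sp_a, sp_b = species_of_gene(a), species_of_gene(b)
                if sp_a == sp_b:
                    continue
                event = TransferEvent(
                    gene_family_id=family,
                    gene_node_id=node.label or f"mf:{leaves[0]}",
                    donor_leaves=frozenset({sp_a}),
                    recipient_leaves=frozenset({sp_b}),
                    support_fraction=0.0,
                    min_branch_support=1.0,
                    via_multifurcation_rule=True,
                )
                g = gene_tree.patristic_distance(a, b)
                event.mean_gene_distance = g
                event.mean_species_distance = species_tree.patristic_distance(
                    sp_a, sp_b
                )
                events.append(event)
    return events


# ---------------------------------------------------------------------------
# distances


class UndefinedDistanceError(ValueError):
    """All gene pairs of an event were removed by the overlap filter."""


def event_mean_distances(
    event: TransferEvent,
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    overlap: Mapping[tuple[str, str], float] | None = None,
    min_overlap: float = 0.5,
) -> tuple[float | None, float]:
    """Mean gene and species distances over left x right descendant pairs.

    The gene distance averages patristic distances between the gene leaves
    on the two sides of the transfer node, skipping pairs whose alignment
    overlap is below ``min_overlap``; the species distance averages the
    corresponding species-tree distances (no overlap filter).  If every
    gene pair is filtered out the gene distance is ``None``.
    """
    left, right = _gene_children_leaves(gene_tree, event.gene_node_id)
    if not left or not right:
        raise ValueError(f"event node {event.gene_node_id!r} has no cross pairs")

    gene_ds, species_ds = [], []
    for a in sorted(left):
        for b in sorted(right):
            species_ds.append(
                species_tree.patristic_distance(
                    species_of_gene(a), species_of_gene(b)
                )
            )
            ov = 1.0
            if overlap is not None:
                key = (a, b) if a < b else (b, a)
                ov = overlap.get(key, 1.0)
            if ov >= min_overlap:
                gene_ds.append(gene_tree.patristic_distance(a, b))
    mean_gene = float(np.mean(gene_ds)) if gene_ds else None
    mean_species = float(np.mean(species_ds))
    return mean_gene, mean_species


# ---------------------------------------------------------------------------
# per-species fractions and pair counts


def per_species_transfer_fraction(
    events: Sequence[TransferEvent],
    assessed_families: Mapping[str, Iterable[str]],
    genome_to_species: Mapping[str, str],
) -> pd.Series:
    """Mean fraction of assessed genes involved in a transfer, per species.

    ``assessed_families`` maps a genome id to the gene families assessed in
    that genome (families whose representative passed the detection
    pipeline); a gene counts as transferred when its family appears in any
    retained event.  Genomes with no assessed genes are excluded with a
    warning; the per-species value is the mean over its genomes.
    """
    transferred = {e.gene_family_id for e in events}
    per_genome: dict[str, float] = {}
    for genome, families in assessed_families.items():
        families = list(families)
        if not families:
            logger.warning("genome %s has no assessed genes; excluded", genome)
            continue
        hit = sum(1 for f in families if f in transferred)
        per_genome[genome] = hit / len(families)
    rows = defaultdict(list)
    for genome, frac in per_genome.items():
        rows[genome_to_species[genome]].append(frac)
    return pd.Series(
        {sp: float(np.mean(v)) for sp, v in rows.items()}, name="transfer_fraction"
    ).sort_index()


def pairwise_transfer_counts(
    events: Sequence[TransferEvent],
    species_to_otu: Mapping[str, str] | None = None,
) -> HGTCountMatrix:
    """Per-pair counts of transferred gene families.

    Every (donor leaf, recipient leaf) species pair of an event, mapped to
    OTUs, is incremented at most once per gene family, so nested or repeated
    calls within one family never double-count a pair.  Species without an
    OTU mapping are skipped (logged).
    """
    mat = HGTCountMatrix()
    seen: set[tuple[str, str, str]] = set()
    skipped = 0
    for event in events:
        for d in event.donor_leaves:
            for r in event.recipient_leaves:
                if species_to_otu is None:
                    otu_d, otu_r = d, r
                else:
                    otu_d = species_to_otu.get(d)
                    otu_r = species_to_otu.get(r)
                    if otu_d is None or otu_r is None:
                        skipped += 1
                        continue
                if otu_d == otu_r:
                    continue
                a, b = (otu_d, otu_r) if otu_d < otu_r else (otu_r, otu_d)
                key = (event.gene_family_id, a, b)
                if key in seen:
                    continue
                seen.add(key)
                mat.add(a, b, 1)
    if skipped:
        logger.warning("%d donor/recipient species had no OTU mapping", skipped)
    return mat


# ---------------------------------------------------------------------------
# gene-pair table (distance-distribution comparisons)


def build_gene_pair_table(
    families: Mapping[str, PhyloTree],
    species_tree: PhyloTree,
    events: Sequence[TransferEvent],
    overlap: Mapping[tuple[str, str], float] | None = None,
    min_branch_support: float = 0.5,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Cross-species gene pairs with distances, filters and transfer flags.

    Pairs with path branch support below ``min_branch_support`` or alignment
    overlap below ``min_overlap`` are excluded.  ``has_transfer`` marks pairs
    spanning a retained event's donor/recipient species sets in the same
    family.
    """
    by_family: dict[str, list[TransferEvent]] = defaultdict(list)
    for e in events:
        by_family[e.gene_family_id].append(e)

    rows = []
    for family_id in sorted(families):
        gtree = families[family_id]
        fam_events = by_family.get(family_id, [])
        leaves = gtree.leaf_names
        for i, ga in enumerate(leaves):
            for gb in leaves[i + 1:]:
                sa, sb = species_of_gene(ga), species_of_gene(gb)
                if sa == sb:
                    continue
                ov = 1.0
                if overlap is not None:
                    key = (ga, gb) if ga < gb else (gb, ga)
                    ov = overlap.get(key, 1.0)
                if ov < min_overlap:
                    continue
                support = gtree.min_support_on_path(ga, gb)
                if support < min_branch_support:
                    continue
                has_transfer = any(
                    (sa in e.donor_leaves and sb in e.recipient_leaves)
                    or (sb in e.donor_leaves and sa in e.recipient_leaves)
                    for e in fam_events
                )
                rows.append(
                    (
                        family_id, ga, gb, sa, sb,
                        gtree.patristic_distance(ga, gb),
                        species_tree.patristic_distance(sa, sb),
                        has_transfer, support, ov,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_family_id", "gene_a", "gene_b", "species_a", "species_b",
            "gene_distance", "species_distance", "has_transfer",
            "min_branch_support", "overlap_fraction",
        ],
    )
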