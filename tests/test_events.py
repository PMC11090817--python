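"""Reconciliation aggregation, event distances and pair counts."""

from collections import Counter

import numpy as np
import pytest

from hgt_ecoscape.events import (
    HGTCountMatrix,
    ReconciliationSample,
    TransferEvent,
    aggregate_and_filter,
    build_gene_pair_table,
    event_mean_distances,
    pairwise_transfer_counts,
    per_species_transfer_fraction,
)
from hgt_ecoscape.trees import PhyloTree


def make_samples(family, node, donor, recipient, flagged, total, root="r1"):
    out = []
    for i in range(total):
        transfers = {node: (donor, recipient)} if i < flagged else {}
        out.append(
            ReconciliationSample(gene_family_id=family, root_id=root, transfers=transfers)
        )
    return out


@pytest.fixture
def gene_tree():
    # transfer cherry (A, B) under node E with support 0.9
    return PhyloTree.from_newick("((A:0.05,B:0.05)E:0.1,(C:0.1,D:0.1)0.8:0.05)root;")


@pytest.fixture
def species_tree():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.25):0.1);")


class TestAggregateAndFilter:
    def test_support_above_threshold_retained(self, gene_tree, species_tree):
        samples = make_samples("f1", "E", "A", "B", flagged=412, total=500)
        events = aggregate_and_filter(samples, gene_tree, species_tree)
        assert len(events) == 1
        assert events[0].support_fraction == pytest.approx(0.824)
        assert events[0].donor_leaves == frozenset({"A"})
        assert events[0].recipient_leaves == frozenset({"B"})

    def test_support_below_threshold_dropped(self, gene_tree, species_tree):
        samples = make_samples("f1", "E", "A", "B", flagged=399, total=500)
        assert aggregate_and_filter(samples, gene_tree, species_tree) == []

    def test_support_exactly_at_threshold_retained(self, gene_tree, species_tree):
        samples = make_samples("f1", "E", "A", "B", flagged=400, total=500)
        assert len(aggregate_and_filter(samples, gene_tree, species_tree)) == 1

    def test_too_many_optimal_roots_excluded(self, gene_tree, species_tree):
        samples = []
        for r in range(51):
            samples.extend(
                make_samples("f1", "E", "A", "B", flagged=10, total=10, root=f"r{r}")
            )
        assert aggregate_and_filter(samples, gene_tree, species_tree) == []
        # 50 roots is still allowed
        samples = samples[:500]
        assert len({s.root_id for s in samples}) == 50
        assert len(aggregate_and_filter(samples, gene_tree, species_tree)) == 1

    def test_low_branch_support_dropped(self, species_tree):
        gtree = PhyloTree.from_newick(
            "((A:0.05,B:0.05)E:0.1,(C:0.1,D:0.1)0.8:0.05)root;"
        )
        node = gtree.find_node("E")
        node.support = 0.4
        samples = make_samples("f1", "E", "A", "B", flagged=500, total=500)
        assert aggregate_and_filter(samples, gtree, species_tree) == []
        node.support = 0.5  # boundary is inclusive
        assert len(aggregate_and_filter(samples, gtree, species_tree)) == 1

    def test_empty_samples_rejected(self, gene_tree, species_tree):
        with pytest.raises(ValueError):
            aggregate_and_filter([], gene_tree, species_tree)

    def test_multifurcation_identity_rule(self, species_tree):
        gtree = PhyloTree.from_newick(
            "((A:0.0,B:0.0,C:0.1)M:0.1,D:0.2)root;"
        )
        samples = make_samples("f1", "M", "A", "B", flagged=0, total=100)
        events = aggregate_and_filter(
            samples, gtree, species_tree, identity_pairs={("A", "B")}
        )
        assert len(events) == 1
        assert events[0].via_multifurcation_rule
        assert events[0].mean_gene_distance == pytest.approx(0.0)

    def test_brute_force_recount_equivalence(self, species_tree):
        """Aggregation equals a naive flag recount on random instances."""
        rng = np.random.default_rng(5)
        gtree = PhyloTree.from_newick(
            "((A:0.05,B:0.05)E:0.1,(C:0.1,D:0.1)F:0.05)root;"
        )
        for n in (E := gtree.dendropy_tree.preorder_internal_node_iter()):
            n.support = 0.9
        nodes = ["E", "F"]
        donors = {"E": ("A", "B"), "F": ("C", "D")}
        for trial in range(20):
            total = int(rng.integers(5, 30))
            samples = []
            for _ in range(total):
                transfers = {}
                for node in nodes:
                    if rng.random() < 0.5:
                        transfers[node] = donors[node]
                samples.append(
                    ReconciliationSample("f", "r1", transfers)
                )
            events = aggregate_and_filter(
                samples, gtree, species_tree, min_support=0.3
            )
            # oracle: direct recount
            counter = Counter()
            for s in samples:
                for node in s.transfers:
                    counter[node] += 1
            expected = {
                node: c / total for node, c in counter.items() if c / total >= 0.3
            }
            got = {e.gene_node_id: e.support_fraction for e in events}
            assert got == pytest.approx(expected)


class TestEventMeanDistances:
    def test_single_pair(self, gene_tree, species_tree):
        event = TransferEvent("f", "E", frozenset({"A"}), frozenset({"B"}), 1.0, 1.0)
        g, s = event_mean_distances(event, gene_tree, species_tree)
        assert g == pytest.approx(0.1)
        assert s == pytest.approx(0.3)

    def test_mean_over_descendants(self):
        stree = PhyloTree.from_newick("((A:0.2,B:0.3):0.05,C:0.2);")
        gtree = PhyloTree.from_newick("((A:0.1,B:0.1)L:0.2,C:0.1)E;")
        event = TransferEvent("f", "E", frozenset({"A", "B"}), frozenset({"C"}), 1.0, 1.0)
        g, s = event_mean_distances(event, gtree, stree)
        # species: mean of d(A,C)=0.45 and d(B,C)=0.55
        assert s == pytest.approx(0.5)
        assert g == pytest.approx(0.4)

    def test_brute_force_oracle_three_by_two(self):
        """3x2 descendant sets equal the naive mean over all 6 pairs."""
        stree = PhyloTree.from_newick(
            "(((A:0.1,B:0.2):0.1,C:0.35):0.05,(D:0.15,E:0.22):0.2);"
        )
        gtree = PhyloTree.from_newick(
            "(((A:0.11,B:0.14):0.05,C:0.3)L:0.1,(D:0.21,E:0.09)R:0.13)T;"
        )
        event = TransferEvent(
            "f", "T", frozenset({"A", "B", "C"}), frozenset({"D", "E"}), 1.0, 1.0
        )
        g, s = event_mean_distances(event, gtree, stree)
        gene_oracle = np.mean(
            [gtree.patristic_distance(x, y) for x in "ABC" for y in "DE"]
        )
        species_oracle = np.mean(
            [stree.patristic_distance(x, y) for x in "ABC" for y in "DE"]
        )
        assert g == pytest.approx(gene_oracle)
        assert s == pytest.approx(species_oracle)

    def test_overlap_filter_only_affects_gene_distance(self):
        stree = PhyloTree.from_newick("((A:0.2,B:0.3):0.05,C:0.2);")
        gtree = PhyloTree.from_newick("((A:0.1,B:0.1)L:0.2,C:0.1)E;")
        event = TransferEvent("f", "E", frozenset({"A", "B"}), frozenset({"C"}), 1.0, 1.0)
        overlap = {("A", "C"): 0.3, ("B", "C"): 0.9}
        g, s = event_mean_distances(event, gtree, stree, overlap=overlap)
        assert g == pytest.approx(gtree.patristic_distance("B", "C"))
        assert s == pytest.approx(0.5)  # unchanged

    def test_all_pairs_filtered_flags_missing_gene_distance(self):
        stree = PhyloTree.from_newick("((A:0.2,B:0.3):0.05,C:0.2);")
        gtree = PhyloTree.from_newick("((A:0.1,B:0.1)L:0.2,C:0.1)E;")
        event = TransferEvent("f", "E", frozenset({"A", "B"}), frozenset({"C"}), 1.0, 1.0)
        overlap = {("A", "C"): 0.1, ("B", "C"): 0.1}
        g, s = event_mean_distances(event, gtree, stree, overlap=overlap)
        assert g is None
        assert s == pytest.approx(0.5)


class TestPerSpeciesFraction:
    def test_fraction_and_species_mean(self):
        events = [
            TransferEvent("f1", "n", frozenset({"X"}), frozenset({"Y"}), 1.0, 1.0),
            TransferEvent("f2", "n", frozenset({"X"}), frozenset({"Z"}), 1.0, 1.0),
        ]
        assessed = {
            "g1": [f"f{i}" for i in range(1, 11)],  # 2 of 10 transferred -> 0.2
            "g2": ["f1", "f2", "f3", "f4", "f9"],  # 2 of 5 -> 0.4
        }
        genome_species = {"g1": "S", "g2": "S"}
        frac = per_species_transfer_fraction(events, assessed, genome_species)
        assert frac["S"] == pytest.approx(0.3)

    def test_no_events_gives_zero(self):
        frac = per_species_transfer_fraction(
            [], {"g1": ["f1", "f2"]}, {"g1": "S"}
        )
        assert frac["S"] == 0.0

    def test_empty_genome_excluded(self):
        frac = per_species_transfer_fraction(
            [], {"g1": [], "g2": ["f1"]}, {"g1": "S", "g2": "S"}
        )
        assert frac["S"] == 0.0  # only g2 contributes


class TestPairwiseCounts:
    def test_single_event(self):
        events = [TransferEvent("f", "n", frozenset({"X"}), frozenset({"Y"}), 1.0, 1.0)]
        mat = pairwise_transfer_counts(events)
        assert mat.get("X", "Y") == 1
        assert mat.get("Y", "X") == 1

    def test_family_pair_deduplication(self):
        events = [
            TransferEvent("f", "n1", frozenset({"X"}), frozenset({"Y"}), 1.0, 1.0),
            TransferEvent("f", "n2", frozenset({"Y"}), frozenset({"X"}), 1.0, 1.0),
            TransferEvent("g", "n1", frozenset({"X"}), frozenset({"Y"}), 1.0, 1.0),
        ]
        mat = pairwise_transfer_counts(events)
        assert mat.get("X", "Y") == 2  # families f and g once each

    def test_within_species_events_ignored(self):
        events = [TransferEvent("f", "n", frozenset({"X"}), frozenset({"X"}), 1.0, 1.0)]
        assert len(pairwise_transfer_counts(events)) == 0

    def test_symmetry_and_zero_diagonal_always(self, small_world):
        mat = small_world.true_transfer_counts
        for (a, b), n in mat.items():
            assert a != b
            assert mat.get(a, b) == mat.get(b, a) == n

    def test_total_invariant_under_relabelling(self):
        events = [
            TransferEvent("f", "n", frozenset({"X"}), frozenset({"Y"}), 1.0, 1.0),
            TransferEvent("g", "n", frozenset({"Y"}), frozenset({"Z"}), 1.0, 1.0),
        ]
        base = pairwise_transfer_counts(events)
        relabel = {"X": "ot3", "Y": "ot1", "Z": "ot2"}
        mapped = pairwise_transfer_counts(events, relabel)
        assert mapped.total() == base.total()


class TestGenePairTable:
    def test_filters_and_transfer_flags(self, species_tree):
        gtree = PhyloTree.from_newick(
            "((A:0.05,B:0.05)0.5:0.1,(C:0.1,D:0.1)0.45:0.05);"
        )
        events = [
            TransferEvent("f", "E", frozenset({"A"}), frozenset({"B"}), 1.0, 1.0)
        ]
        overlap = {("A", "D"): 0.4}  # below the 0.5 cutoff -> excluded
        table = build_gene_pair_table(
            {"f": gtree}, species_tree, events, overlap=overlap
        )
        pairs = set(map(tuple, table[["gene_a", "gene_b"]].to_numpy()))
        assert ("A", "D") not in pairs
        # support exactly 0.5 is inclusive: the (A, B) pair survives
        ab = table[(table.gene_a == "A") & (table.gene_b == "B")]
        assert len(ab) == 1
        assert bool(ab.iloc[0].has_transfer)
        # pairs through the 0.45 node are excluded
        assert ("C", "D") not in pairs

    def test_family_without_events_all_false(self, species_tree):
        gtree = PhyloTree.from_newick("((A:0.05,B:0.05):0.1,C:0.1);")
        table = build_gene_pair_table({"f": gtree}, species_tree, [])
        assert not table.has_transfer.any()

    def test_same_species_pairs_skipped(self, species_tree):
        gtree = PhyloTree.from_newick("((A|1:0.05,A|2:0.05):0.1,B:0.1);")
        table = build_gene_pair_table({"f": gtree}, species_tree, [])
        assert set(zip(table.species_a, table.species_b)) == {("A", "B")}


def test_noiseless_world_recovered_exactly(small_world):
    """With no replicate noise, retained events equal planted events."""
    from hgt_ecoscape.io import PipelineConfig, detect_events

    detected = detect_events(
        small_world.reconciliation_sets, small_world.species_tree, PipelineConfig()
    )
    got = {(e.gene_family_id, e.gene_node_id) for e in detected}
    expected = {
        (e.gene_family_id, e.gene_node_id) for e in small_world.transfer_events
    }
    assert got == expected
    # and the planted mean distances are recovered to numerical precision
    planted = {
        e.gene_family_id: (e.mean_gene_distance, e.mean_species_distance)
        for e in small_world.transfer_events
    }
    for e in detected:
        g, s = planted[e.gene_family_id]
        assert e.mean_gene_distance == pytest.approx(g, abs=1e-12)
        assert e.mean_species_distance == pytest.approx(s, abs=1e-12)
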