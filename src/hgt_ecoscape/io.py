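"""On-disk formats, dataset validation and pipeline orchestration.

All tables are plain TSV with documented headers (trees are Newick, scalar
summaries JSON).  ``write_world`` / ``load_dataset`` round-trip a synthetic
world; ``run_pipeline`` executes the analysis stages in order and emits a
manifest with input hashes, parameter values and the seed of every
stochastic step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .containers import ENVIRONMENTS, AbundanceMatrix
from .events import (
    HGTCountMatrix,
    ReconciliationSample,
    TransferEvent,
    aggregate_and_filter,
    pairwise_transfer_counts,
)
from .synthetic import FamilyReconciliation, SyntheticWorld
from .trees import PhyloTree

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


@dataclass
class PipelineConfig:
    """Thresholds (paper defaults) and paths for a pipeline run."""

    data_dir: str = "."
    out_dir: str = "results"
    min_support: float = 0.8
    min_branch_support: float = 0.5
    max_roots: int = 50
    min_overlap: float = 0.5
    core_min: float = 0.90
    cloud_max: float = 0.15
    min_genomes: int = 10
    presence_threshold: float = 1e-4
    min_partners: int = 30
    min_samples: int = 20
    n_bins: int = 80
    q_high: float = 0.8
    q_low: float = 0.2
    n_per_env: int = 200
    n_background: int = 1000
    n_shuffles: int = 20
    n_distance_bins: int = 20
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# writers


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_world(world: SyntheticWorld, out_dir) -> dict[str, Path]:
    """Serialize a synthetic world to TSV/Newick files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["species_tree"] = out / "species_tree.nwk"
    paths["species_tree"].write_text(world.species_tree.to_newick() + "\n")

    ab = world.abundance.matrix.copy()
    ab.insert(0, "otu", ab.index)
    paths["abundance"] = out / "abundance.tsv"
    _write_tsv(ab, paths["abundance"])
    paths["sample_env"] = out / "sample_environments.tsv"
    _write_tsv(
        world.abundance.sample_env.rename_axis("sample").reset_index(),
        paths["sample_env"],
    )
    paths["species_to_otu"] = out / "species_to_otu.tsv"
    _write_tsv(
        pd.DataFrame(
            sorted(world.species_to_otu.items()), columns=["species_id", "otu"]
        ),
        paths["species_to_otu"],
    )
    paths["counts"] = out / "true_transfer_counts.tsv"
    _write_tsv(world.true_transfer_counts.to_dataframe(), paths["counts"])

    paths["events"] = out / "transfer_events.tsv"
    _write_tsv(events_to_frame(world.transfer_events), paths["events"])

    paths["pangenome"] = out / "pangenome.tsv"
    _write_tsv(world.pangenomes, paths["pangenome"])

    paths["annotations"] = out / "annotations.tsv"
    _write_tsv(
        pd.DataFrame(
            [
                (fam, ",".join(sorted(cats)))
                for fam, cats in sorted(world.annotations.items())
            ],
            columns=["gene_family_id", "categories"],
        ),
        paths["annotations"],
    )

    rec_rows = []
    tree_rows = []
    for fam, rec in sorted(world.reconciliation_sets.items()):
        tree_rows.append((fam, rec.gene_tree.to_newick(), len(rec.samples)))
        for rep, sample in enumerate(rec.samples):
            for node, (donor, recipient) in sorted(sample.transfers.items()):
                rec_rows.append(
                    (fam, sample.root_id, rep, node, "transfer", donor, recipient)
                )
    paths["reconciliations"] = out / "reconciliations.tsv"
    _write_tsv(
        pd.DataFrame(
            rec_rows,
            columns=[
                "gene_family_id", "root_id", "replicate", "node_id",
                "event_type", "donor", "recipient",
            ],
        ),
        paths["reconciliations"],
    )
    paths["gene_trees"] = out / "gene_trees.tsv"
    _write_tsv(
        pd.DataFrame(tree_rows, columns=["gene_family_id", "newick", "n_replicates"]),
        paths["gene_trees"],
    )
    return paths


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.gene_family_id, e.gene_node_id,
                ";".join(sorted(e.donor_leaves)),
                ";".join(sorted(e.recipient_leaves)),
                e.support_fraction, e.min_branch_support,
                e.mean_gene_distance if e.mean_gene_distance is not None else np.nan,
                e.mean_species_distance, e.via_multifurcation_rule,
            )
            for e in events
        ],
        columns=[
            "gene_family_id", "gene_node_id", "donor_leaves", "recipient_leaves",
            "support_fraction", "min_branch_support", "mean_gene_distance",
            "mean_species_distance", "via_multifurcation_rule",
        ],
    )


def events_from_frame(df: pd.DataFrame) -> list[TransferEvent]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TransferEvent(
                gene_family_id=row.gene_family_id,
                gene_node_id=row.gene_node_id,
                donor_leaves=frozenset(str(row.donor_leaves).split(";")),
                recipient_leaves=frozenset(str(row.recipient_leaves).split(";")),
                support_fraction=float(row.support_fraction),
                min_branch_support=float(row.min_branch_support),
                mean_gene_distance=(
                    None if pd.isna(row.mean_gene_distance)
                    else float(row.mean_gene_distance)
                ),
                mean_species_distance=float(row.mean_species_distance),
                via_multifurcation_rule=bool(row.via_multifurcation_rule),
            )
        )
    return out


# ---------------------------------------------------------------------------
# readers / validation


class DatasetValidationError(ValueError):
    pass


@dataclass
class Dataset:
    species_tree: PhyloTree
    abundance: AbundanceMatrix
    species_to_otu: dict[str, str]
    counts: HGTCountMatrix
    events: list[TransferEvent]
    pangenome: pd.DataFrame
    annotations: dict[str, set[str]]
    reconciliations: dict[str, FamilyReconciliation]


def load_dataset(data_dir) -> Dataset:
    """Load and cross-validate a written world; errors list every mismatch."""
    d = Path(data_dir)
    problems: list[str] = []

    tree = PhyloTree.from_file(d / "species_tree.nwk")

    ab_df = pd.read_csv(d / "abundance.tsv", sep="\t")
    ab_df = ab_df.set_index("otu")
    bad = ab_df.stack()
    bad = bad[(bad < 0) | (bad > 1)]
    for (otu, sample), value in bad.items():
        problems.append(f"abundance[{otu},{sample}]={value} outside [0,1]")
    env = pd.read_csv(d / "sample_environments.tsv", sep="\t").set_index("sample")[
        "environment"
    ]
    unknown_env = set(env.unique()) - set(ENVIRONMENTS) - {"none"}
    if unknown_env:
        problems.append(f"unknown environment labels: {sorted(unknown_env)}")

    mapping_df = pd.read_csv(d / "species_to_otu.tsv", sep="\t")
    species_to_otu = dict(
        zip(mapping_df["species_id"].astype(str), mapping_df["otu"].astype(str))
    )
    tree_leaves = set(tree.leaf_names)
    for sp in species_to_otu:
        if sp not in tree_leaves:
            problems.append(f"mapped species {sp} missing from species tree")
    missing_ab = set(species_to_otu.values()) - set(ab_df.index.astype(str))
    if missing_ab:
        logger.warning(
            "%d OTUs absent from abundance table: %s",
            len(missing_ab), sorted(missing_ab)[:5],
        )

    counts = HGTCountMatrix.from_dataframe(
        pd.read_csv(d / "true_transfer_counts.tsv", sep="\t")
    )
    events = events_from_frame(pd.read_csv(d / "transfer_events.tsv", sep="\t"))
    pangenome = pd.read_csv(d / "pangenome.tsv", sep="\t")
    ann_df = pd.read_csv(d / "annotations.tsv", sep="\t")
    annotations = {
        str(row.gene_family_id): (
            set() if pd.isna(row.categories) or row.categories == ""
            else set(str(row.categories).split(","))
        )
        for row in ann_df.itertuples(index=False)
    }

    gt_df = pd.read_csv(d / "gene_trees.tsv", sep="\t")
    rec_df = pd.read_csv(d / "reconciliations.tsv", sep="\t")
    reconciliations: dict[str, FamilyReconciliation] = {}
    rec_groups = {k: g for k, g in rec_df.groupby("gene_family_id")}
    for row in gt_df.itertuples(index=False):
        fam = str(row.gene_family_id)
        gtree = PhyloTree.from_newick(row.newick)
        n_reps = int(row.n_replicates)
        transfers_by_rep: dict[int, dict] = {r: {} for r in range(n_reps)}
        roots_by_rep: dict[int, str] = {r: "r1" for r in range(n_reps)}
        if fam in rec_groups:
            for r in rec_groups[fam].itertuples(index=False):
                transfers_by_rep[int(r.replicate)][str(r.node_id)] = (
                    str(r.donor), str(r.recipient),
                )
                roots_by_rep[int(r.replicate)] = str(r.root_id)
        samples = [
            ReconciliationSample(
                gene_family_id=fam,
                root_id=roots_by_rep[r],
                transfers=transfers_by_rep[r],
            )
            for r in range(n_reps)
        ]
        reconciliations[fam] = FamilyReconciliation(
            gene_family_id=fam, gene_tree=gtree, samples=samples,
            true_event_nodes=[],
        )

    if problems:
        raise DatasetValidationError("; ".join(problems))
    return Dataset(
        species_tree=tree,
        abundance=AbundanceMatrix(matrix=ab_df, sample_env=env),
        species_to_otu=species_to_otu,
        counts=counts,
        events=events,
        pangenome=pangenome,
        annotations=annotations,
        reconciliations=reconciliations,
    )


# ---------------------------------------------------------------------------
# pipeline


def detect_events(
    reconciliations: Mapping[str, FamilyReconciliation],
    species_tree: PhyloTree,
    config: PipelineConfig,
) -> list[TransferEvent]:
    """Stage 1: aggregate every family's replicates into retained events."""
    events: list[TransferEvent] = []
    for fam in sorted(reconciliations):
        rec = reconciliations[fam]
        events.extend(
            aggregate_and_filter(
                rec.samples,
                rec.gene_tree,
                species_tree,
                min_support=config.min_support,
                min_branch_support=config.min_branch_support,
                max_roots=config.max_roots,
                min_overlap=config.min_overlap,
            )
        )
    return events


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(dataset: Dataset, config: PipelineConfig, out_dir=None) -> dict:
    """Run all analysis stages in order; returns a results bundle.

    Stages: event detection -> pair counts -> ubiquity odds ratio ->
    functional enrichment -> co-occurrence correction -> abundance tiers and
    generalism Z-scores.  Every stochastic step derives its seed from
    ``config.seed``; the returned bundle carries a manifest of parameters
    and stage summaries and is written to ``out_dir`` when given.
    """
    from . import cooccurrence as cooc
    from . import ecology
    from .enrichment import enrichment_grid
    from .pangenome import classify_table, transfer_ubiquity_test

    results: dict = {}

    events = detect_events(dataset.reconciliations, dataset.species_tree, config)
    results["n_events"] = len(events)
    events_df = events_to_frame(events)

    counts = pairwise_transfer_counts(events, dataset.species_to_otu)
    results["n_pairs_with_transfer"] = len(counts)

    classified = classify_table(
        dataset.pangenome,
        core_min=config.core_min,
        cloud_max=config.cloud_max,
        min_genomes=config.min_genomes,
    )
    transferred_pairs = {
        (sp, e.gene_family_id)
        for e in events
        for sp in (*e.donor_leaves, *e.recipient_leaves)
    }
    fisher = transfer_ubiquity_test(classified, transferred_pairs, "cloud")
    results["cloud_odds_ratio"] = fisher.odds_ratio
    results["cloud_fisher_p"] = fisher.p_value

    categories = sorted({c for cats in dataset.annotations.values() for c in cats})
    enrich = enrichment_grid(
        events_df,
        dataset.annotations,
        assessed_families=list(dataset.reconciliations),
        categories=categories,
    )
    results["enrichment"] = enrich

    presence = cooc.presence_matrix(
        dataset.abundance.matrix, config.presence_threshold
    )
    co_mat = cooc.co_occurrence_matrix(presence)
    otus = list(dataset.abundance.matrix.index)
    _, pd_arr = dataset.species_tree.distance_matrix(otus)
    pd_mat = pd.DataFrame(pd_arr, index=otus, columns=otus)
    focal, eligible = cooc.eligibility_filter(
        counts, presence, config.min_partners, config.min_samples
    )
    pair_table = cooc.build_pair_table(co_mat, pd_mat, counts, eligible)
    resid = cooc.residual_correlation_analysis(
        pair_table, sorted(focal), n_shuffles=config.n_shuffles,
        seed=config.seed + 1,
    )
    results["residual_correlation"] = resid
    results["median_rho_post"] = (
        float(resid.per_otu["rho_post"].median()) if len(resid.per_otu) else np.nan
    )

    profiles = ecology.habitat_profiles(
        dataset.abundance.matrix, dataset.abundance.sample_env,
        q_high=config.q_high, q_low=config.q_low,
    )
    classes = ecology.select_generalists_specialists(profiles, config.n_per_env)
    results["profiles"] = profiles
    results["classes"] = classes

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {
            "events": results["n_events"],
            "pairs": results["n_pairs_with_transfer"],
            "cloud_odds_ratio": results["cloud_odds_ratio"],
            "median_rho_post": results["median_rho_post"],
            "n_enrichment_tests": int(len(enrich)),
        },
    }
    results["manifest"] = manifest
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(events_df, out / "detected_events.tsv")
        _write_tsv(counts.to_dataframe(), out / "detected_counts.tsv")
        _write_tsv(enrich, out / "enrichment_cells.tsv")
        _write_tsv(resid.per_otu, out / "residual_correlations.tsv")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n"
        )
    return results
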