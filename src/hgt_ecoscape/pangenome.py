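"""Gene ubiquity classes within pangenomes and the transfer/ubiquity test.

Gene ubiquity is the fraction of a species' genomes carrying a gene
family.  Families are classified as extended core (>=90% ubiquity), cloud
(<=15%) or shell (in between); species with fewer than ten genomes are
excluded.  In a transferring species pair the higher-ubiquity species is
the putative donor.  Composition differences (e.g. transferred vs
non-transferred by cloud vs non-cloud) are tested with the two-sided
Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CORE_MIN = 0.90
CLOUD_MAX = 0.15
MIN_GENOMES = 10

PANGENOME_COLUMNS = [
    "species_id", "gene_family_id", "genomes_with_gene", "genomes_total",
]


def classify_ubiquity(
    genomes_with_gene: int,
    genomes_total: int,
    core_min: float = CORE_MIN,
    cloud_max: float = CLOUD_MAX,
    min_genomes: int = MIN_GENOMES,
) -> str | None:
    """Classify one pangenome row; ``None`` when the species is too small.

    The class boundaries are inclusive: ubiquity exactly 0.90 is extended
    core and exactly 0.15 is cloud.
    """
    if not 0 < genomes_with_gene <= genomes_total:
        raise ValueError("need 0 < genomes_with_gene <= genomes_total")
    if genomes_total < min_genomes:
        return None
    fraction = genomes_with_gene / genomes_total
    if fraction >= core_min:
        return "extended_core"
    if fraction <= cloud_max:
        return "cloud"
    return "shell"


def classify_table(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Vectorized classification; adds ``ubiquity`` and ``ubiquity_class``
    columns and drops excluded (small-species) rows."""
    out = table.copy()
    out["ubiquity"] = out["genomes_with_gene"] / out["genomes_total"]
    out["ubiquity_class"] = [
        classify_ubiquity(w, t, **kwargs)
        for w, t in zip(out["genomes_with_gene"], out["genomes_total"])
    ]
    return out[out["ubiquity_class"].notna()].reset_index(drop=True)


def assign_donor_recipient(
    species_a: str, ubiquity_a: float | None, species_b: str, ubiquity_b: float | None
) -> tuple[str, str] | None:
    """Label the higher-ubiquity species the putative donor.

    Returns ``(donor, recipient)`` or ``None`` when either ubiquity is
    missing or the two are exactly equal (no basis for a direction).
    """
    if ubiquity_a is None or ubiquity_b is None:
        return None
    if ubiquity_a == ubiquity_b:
        return None
    if ubiquity_a > ubiquity_b:
        return species_a, species_b
    return species_b, species_a


@dataclass
class FisherResult:
    odds_ratio: float  # may be inf or 0 with a zero cell
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_odds_ratio(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The odds ratio is the sample cross-product (n11*n22)/(n12*n21); the
    p-value sums hypergeometric probabilities of all tables (with the same
    margins) no more likely than the observed one.
    """
    (n11, n12), (n21, n22) = [[int(x) for x in row] for row in table]
    if min(n11, n12, n21, n22) < 0:
        raise ValueError("counts must be non-negative")
    if (n11 + n12 == 0 or n21 + n22 == 0 or n11 + n21 == 0 or n12 + n22 == 0):
        raise ValueError("row and column sums must be positive")
    if n12 * n21 == 0:
        odds = math.inf if n11 * n22 > 0 else 0.0
    else:
        odds = (n11 * n22) / (n12 * n21)
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return FisherResult(odds_ratio=odds, p_value=float(p), table=((n11, n12), (n21, n22)))


def transfer_ubiquity_test(
    classified: pd.DataFrame,
    transferred: set[tuple[str, str]] | set[str],
    focal_class: str = "cloud",
) -> FisherResult:
    """2x2 test: (transferred vs not) x (``focal_class`` vs other classes).

    ``transferred`` holds gene families involved in retained events, either
    as ``(species_id, gene_family_id)`` pairs or bare family ids.
    """
    if transferred and isinstance(next(iter(transferred)), tuple):
        is_t = [
            (s, g) in transferred
            for s, g in zip(classified["species_id"], classified["gene_family_id"])
        ]
    else:
        is_t = classified["gene_family_id"].isin(transferred).to_numpy()
    is_t = np.asarray(is_t, dtype=bool)
    is_focal = (classified["ubiquity_class"] == focal_class).to_numpy()
    n11 = int(np.sum(is_t & is_focal))
    n12 = int(np.sum(is_t & ~is_focal))
    n21 = int(np.sum(~is_t & is_focal))
    n22 = int(np.sum(~is_t & ~is_focal))
    return fisher_odds_ratio([[n11, n12], [n21, n22]])
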