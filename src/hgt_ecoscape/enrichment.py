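"""Functional enrichment of transfer events on a distance bin grid.

Transfer events are placed on a grid of species-distance bins (three
equal-width bins spanning 0.08-2.00) crossed with gene-distance bins, where
gene distance acts as a proxy for time since the transfer.  The three broad
gene bins a (0.50-0.75], b (0.25-0.50] and c (0.00-0.25] are disjoint, and
two recent-transfer bins d (0.00-0.05] and e (0.00-0.01] nest inside c, so
one recent event can contribute to up to three cells.  Within every cell
each functional category is tested with a two-sided exact binomial test
against the category's pipeline-wide background fraction, and p-values are
corrected with the Holm-Sidak step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BinGrid:
    species_edges: tuple[float, ...] = (0.08, 0.72, 1.36, 2.00)
    gene_bins: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "a": (0.50, 0.75),
            "b": (0.25, 0.50),
            "c": (0.00, 0.25),
            "d": (0.00, 0.05),
            "e": (0.00, 0.01),
        }
    )

    def species_bin(self, distance: float) -> int | None:
        """1-based species bin, or None when outside the grid range."""
        edges = self.species_edges
        if distance < edges[0] or distance > edges[-1]:
            return None
        for i in range(1, len(edges)):
            if distance <= edges[i]:
                return i
        return None  # pragma: no cover

    def gene_bin_set(self, distance: float) -> frozenset[str]:
        """All gene bins whose (lo, hi] interval contains the distance."""
        return frozenset(
            label
            for label, (lo, hi) in self.gene_bins.items()
            if lo < distance <= hi
        )


def assign_bins(
    mean_species_distance: float, mean_gene_distance: float | None, grid: BinGrid
) -> tuple[int | None, frozenset[str]]:
    """Grid placement of one event; empty gene set if distance undefined."""
    sbin = grid.species_bin(mean_species_distance)
    gbins = (
        frozenset()
        if mean_gene_distance is None
        else grid.gene_bin_set(mean_gene_distance)
    )
    return sbin, gbins


def background_fraction(
    annotations: Mapping[str, set[str]], assessed_families: Iterable[str], category: str
) -> float:
    """Fraction of assessed gene families annotated to ``category``."""
    assessed = list(assessed_families)
    if not assessed:
        raise ValueError("assessed family set is empty")
    hit = sum(1 for f in assessed if category in annotations.get(f, ()))
    return hit / len(assessed)


@dataclass
class EnrichmentCell:
    species_bin: int
    gene_bin: str
    category: str
    n_events_in_cell: int
    n_annotated: int
    observed_fraction: float
    expected_fraction: float
    direction: str  # enriched / depleted / none
    p_raw: float
    p_adjusted: float = float("nan")


def cell_enrichment(
    event_families: Sequence[str],
    annotations: Mapping[str, set[str]],
    category: str,
    expected_fraction: float,
    species_bin: int = 0,
    gene_bin: str = "",
) -> EnrichmentCell:
    """Two-sided exact binomial test of one (cell, category) combination.

    ``event_families`` lists the gene family of every event in the cell;
    an event counts as annotated when its family carries the category.
    """
    n = len(event_families)
    if n < 1:
        raise ValueError("cell must contain at least one event")
    k = sum(1 for f in event_families if category in annotations.get(f, ()))
    observed = k / n
    if expected_fraction in (0.0, 1.0) and observed == expected_fraction:
        p = 1.0
    else:
        p = float(stats.binomtest(k, n, expected_fraction).pvalue)
    if observed > expected_fraction:
        direction = "enriched"
    elif observed < expected_fraction:
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentCell(
        species_bin=species_bin,
        gene_bin=gene_bin,
        category=category,
        n_events_in_cell=n,
        n_annotated=k,
        observed_fraction=observed,
        expected_fraction=expected_fraction,
        direction=direction,
        p_raw=p,
    )


def holm_sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    With p-values sorted ascending, the i-th (1-based) adjusted value is
    ``max_{j<=i} (1 - (1 - p_(j))^(m - j + 1))`` clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, step)
        adjusted_sorted[rank] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def enrichment_grid(
    events: pd.DataFrame,
    annotations: Mapping[str, set[str]],
    assessed_families: Iterable[str],
    categories: Sequence[str],
    grid: BinGrid | None = None,
    adjust_within: str = "global",
) -> pd.DataFrame:
    """Run the full grid x category enrichment screen.

    ``events`` needs columns ``gene_family_id``, ``mean_species_distance``,
    ``mean_gene_distance``.  Events with an undefined gene distance are
    excluded from the gene-binned tests.  ``adjust_within`` selects the
    multiple-testing family: ``"global"`` (all cells and categories in one
    family, the default) or ``"cell"``.
    """
    grid = grid or BinGrid()
    assessed = list(assessed_families)
    background = {
        c: background_fraction(annotations, assessed, c) for c in categories
    }

    cell_members: dict[tuple[int, str], list[str]] = {}
    for fam, sd, gd in events[
        ["gene_family_id", "mean_species_distance", "mean_gene_distance"]
    ].itertuples(index=False):
        gd = None if pd.isna(gd) else float(gd)
        sbin, gbins = assign_bins(float(sd), gd, grid)
        if sbin is None:
            continue
        for gbin in gbins:
            cell_members.setdefault((sbin, gbin), []).append(fam)

    cells: list[EnrichmentCell] = []
    for (sbin, gbin), fams in sorted(cell_members.items()):
        for category in categories:
            p0 = background[category]
            cells.append(
                cell_enrichment(fams, annotations, category, p0, sbin, gbin)
            )

    if cells:
        if adjust_within == "global":
            adj = holm_sidak_adjust([c.p_raw for c in cells])
            for c, a in zip(cells, adj):
                c.p_adjusted = a
        elif adjust_within == "cell":
            df_idx: dict[tuple[int, str], list[int]] = {}
            for i, c in enumerate(cells):
                df_idx.setdefault((c.species_bin, c.gene_bin), []).append(i)
            for idxs in df_idx.values():
                adj = holm_sidak_adjust([cells[i].p_raw for i in idxs])
                for i, a in zip(idxs, adj):
                    cells[i].p_adjusted = a
        else:
            raise ValueError("adjust_within must be 'global' or 'cell'")

    return pd.DataFrame([c.__dict__ for c in cells])
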