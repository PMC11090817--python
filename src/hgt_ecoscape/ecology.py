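"""Habitat preference, abundance tiers and the generalist/specialist screen.

Every OTU is assigned a preferred habitat (the environment - animal,
aquatic, plant or soil - with its highest mean relative abundance), an
abundance tier within that habitat (above the 80% quantile = high, below
the 20% quantile = low) and a generalism index (Shannon entropy of its
across-environment abundance profile).  Transfer probability is then
compared across tiers along phylogenetic distance, and across environment
pairs for generalists vs specialists on distance-equalized subsamples,
with resampled Z-scores against an all-species background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import HGTCountMatrix
from .matching import _bin_edges, _bin_index, match_to_target, mwu_compare

ENVIRONMENTS = ("animal", "aquatic", "plant", "soil")
LN4 = float(np.log(4.0))


def habitat_means(abundance: pd.DataFrame, sample_env: pd.Series) -> pd.DataFrame:
    """Per-OTU mean relative abundance in each of the four environments."""
    cols = {}
    for env in ENVIRONMENTS:
        samples = sample_env.index[sample_env == env]
        cols[env] = (
            abundance[samples].mean(axis=1) if len(samples) else
            pd.Series(0.0, index=abundance.index)
        )
    return pd.DataFrame(cols)


def preferred_habitat(means: pd.DataFrame) -> pd.Series:
    """Argmax environment per OTU; NaN on an all-zero profile or exact tie."""
    out = {}
    for otu, row in means.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.all(vals == 0):
            out[otu] = np.nan
            continue
        top = vals.max()
        winners = [e for e, v in zip(means.columns, vals) if v == top]
        out[otu] = winners[0] if len(winners) == 1 else np.nan
    return pd.Series(out, name="preferred_env")


def generalism_entropy(means_row) -> float:
    """Shannon entropy (natural log) of the normalized four-environment
    profile; 0 for a point mass, ln 4 for a uniform profile."""
    q = np.asarray(means_row, dtype=float)
    total = q.sum()
    if total <= 0:
        raise ValueError("all-zero abundance profile has no entropy")
    q = q / total
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def habitat_profiles(
    abundance: pd.DataFrame,
    sample_env: pd.Series,
    q_high: float = 0.8,
    q_low: float = 0.2,
) -> pd.DataFrame:
    """Combined per-OTU table: environment means, preferred habitat,
    abundance tier and generalism entropy.

    OTUs with an all-zero profile or a tied argmax are dropped.  Tiers use
    each OTU's mean abundance within its preferred environment, with
    quantiles (linear interpolation) computed within that environment;
    "above"/"below" are strict, everything else is mid.
    """
    means = habitat_means(abundance, sample_env)
    pref = preferred_habitat(means)
    keep = pref.notna()
    means, pref = means[keep], pref[keep]
    entropy = means.apply(generalism_entropy, axis=1)

    own = pd.Series(
        [means.at[otu, env] for otu, env in pref.items()], index=pref.index
    )
    tier = pd.Series("mid", index=pref.index, dtype=object)
    for env in ENVIRONMENTS:
        members = pref.index[pref == env]
        if len(members) == 0:
            continue
        vals = own[members]
        hi = np.quantile(vals, q_high)
        lo = np.quantile(vals, q_low)
        tier[members[vals[members] > hi]] = "high"
        tier[members[vals[members] < lo]] = "low"

    out = means.copy()
    out["preferred_env"] = pref
    out["own_env_abundance"] = own
    out["tier"] = tier
    out["entropy"] = entropy
    out["entropy_normalized"] = entropy / LN4
    return out


def select_generalists_specialists(
    profiles: pd.DataFrame, n_per_env: int = 200
) -> pd.Series:
    """Class labels: top-n entropy per environment = generalist, bottom-n =
    specialist, remainder = neither.  Ties break on the OTU identifier."""
    labels = pd.Series("neither", index=profiles.index, dtype=object)
    for env in ENVIRONMENTS:
        members = profiles.index[profiles["preferred_env"] == env]
        if len(members) == 0:
            continue
        n = n_per_env
        if len(members) < 2 * n:
            n = len(members) // 2
            import warnings

            warnings.warn(
                f"{env}: only {len(members)} OTUs; n_per_env reduced to {n}",
                stacklevel=2,
            )
        if n == 0:
            continue
        ent = profiles.loc[members, "entropy"]
        order = sorted(members, key=lambda o: (-ent[o], o))
        generalists = order[:n]
        labels[generalists] = "generalist"
        remaining = [o for o in members if labels[o] != "generalist"]
        order_low = sorted(remaining, key=lambda o: (ent[o], o))
        labels[order_low[:n]] = "specialist"
    return labels.rename("class")


def build_ecology_pair_table(
    profiles: pd.DataFrame,
    pd_matrix: pd.DataFrame,
    counts: HGTCountMatrix,
) -> pd.DataFrame:
    """All OTU pairs with distances, environments, tiers and transfer flags.

    One row per unordered pair of profiled OTUs, including pairs with zero
    transfers (the denominator of every transfer-fraction estimate).
    """
    otus = [o for o in profiles.index if o in pd_matrix.index]
    env = profiles["preferred_env"]
    tier = profiles["tier"]
    rows = []
    for i, a in enumerate(otus):
        for b in otus[i + 1:]:
            n = counts.get(a, b)
            ta, tb = tier[a], tier[b]
            group = "-".join(sorted((ta, tb)))
            rows.append(
                (a, b, env[a], env[b], float(pd_matrix.at[a, b]), n, n >= 1,
                 ta, tb, group)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "otu_a", "otu_b", "env_a", "env_b", "pd", "n_genes",
            "has_transfer", "tier_a", "tier_b", "group",
        ],
    )


# ---------------------------------------------------------------------------
# abundance-tier transfer curves


@dataclass
class TierCurve:
    group: str  # high-high / high-low / low-low
    bin_centers: np.ndarray
    fractions: np.ndarray
    error_bands: np.ndarray  # sqrt(p (1 - p) / n) per bin
    n_pairs: np.ndarray


def bernoulli_band(p_hat: float, n: int) -> float:
    """Binomial standard error of a fraction."""
    return float(np.sqrt(p_hat * (1.0 - p_hat) / n)) if n > 0 else float("nan")


def tier_transfer_curves(
    pair_table: pd.DataFrame,
    n_distance_bins: int = 20,
) -> tuple[dict[str, TierCurve], pd.DataFrame]:
    """Fraction of pairs with >=1 transfer per tier group and distance bin.

    ``pair_table`` needs columns ``pd``, ``has_transfer`` (bool) and
    ``group`` in {high-high, high-low, low-low}.  Bins are equal-count
    (quantile) bins on the pooled phylogenetic distances.  Groups are
    pairwise compared with a one-sided Wilcoxon rank-sum test on per-bin
    fractions, testing the ordering high-high > high-low > low-low; the
    caller is expected to apply Benjamini-Hochberg across environments.
    """
    edges = np.unique(
        np.quantile(pair_table["pd"], np.linspace(0, 1, n_distance_bins + 1))
    )
    if len(edges) < 2:
        raise ValueError("degenerate distance distribution")
    idx = _bin_index(pair_table["pd"].to_numpy(dtype=float), edges)

    curves: dict[str, TierCurve] = {}
    for group in ("high-high", "high-low", "low-low"):
        mask = (pair_table["group"] == group).to_numpy()
        centers, fracs, bands, ns = [], [], [], []
        for b in range(len(edges) - 1):
            sel = mask & (idx == b)
            n = int(sel.sum())
            if n == 0:
                continue
            p_hat = float(pair_table.loc[sel, "has_transfer"].mean())
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            fracs.append(p_hat)
            bands.append(bernoulli_band(p_hat, n))
            ns.append(n)
        curves[group] = TierCurve(
            group=group,
            bin_centers=np.asarray(centers),
            fractions=np.asarray(fracs),
            error_bands=np.asarray(bands),
            n_pairs=np.asarray(ns, dtype=int),
        )

    comparisons = []
    for hi, lo in (
        ("high-high", "high-low"),
        ("high-high", "low-low"),
        ("high-low", "low-low"),
    ):
        a, b = curves[hi].fractions, curves[lo].fractions
        if len(a) == 0 or len(b) == 0:
            comparisons.append((hi, lo, float("nan"), float("nan")))
            continue
        u, p = mwu_compare(a, b, alternative="greater")
        comparisons.append((hi, lo, u, p))
    tests = pd.DataFrame(comparisons, columns=["group_a", "group_b", "U", "p_raw"])
    return curves, tests


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# inter-environment transfer matrices and Z-scores


@dataclass
class EnvTransferResult:
    matrices: dict[str, pd.DataFrame]  # group -> 4x4 fraction matrix
    cell_sizes: pd.DataFrame
    statistics: pd.DataFrame  # group x (mean, sd, range)
    zscores: pd.DataFrame  # group x statistic
    background: dict[str, np.ndarray]  # statistic -> n_background draws


def _cell_of(env_a: str, env_b: str) -> tuple[str, str]:
    return (env_a, env_b) if env_a <= env_b else (env_b, env_a)


def env_transfer_zscores(
    pair_table: pd.DataFrame,
    classes: pd.Series,
    n_background: int = 1000,
    n_distance_bins: int = 20,
    seed: int = 0,
) -> EnvTransferResult:
    """Inter-environment transfer fractions on PD-equalized subsamples.

    ``pair_table`` needs columns ``otu_a``, ``otu_b``, ``env_a``, ``env_b``,
    ``pd`` and ``has_transfer``; ``classes`` maps OTUs to
    generalist/specialist/neither.  For each group (all species, generalist
    pairs, specialist pairs) and each unordered environment-pair cell, pairs
    are subsampled so every (group, cell) shares one phylogenetic-distance
    histogram, and the fraction of pairs with a transfer is recorded in a
    4x4 matrix.  Mean, s.d. and range (max - min) over the ten distinct
    cells summarize each matrix.  A background distribution for each
    statistic comes from ``n_background`` re-subsamples of the all-species
    pairs matched to the same distance target; a normal fit to it yields
    Z = (observed - mean) / s.d.
    """
    rng = np.random.default_rng(seed)
    df = pair_table.copy()
    cls_a = classes.reindex(df["otu_a"]).to_numpy()
    cls_b = classes.reindex(df["otu_b"]).to_numpy()
    group_masks = {
        "all": np.ones(len(df), dtype=bool),
        "generalist": (cls_a == "generalist") & (cls_b == "generalist"),
        "specialist": (cls_a == "specialist") & (cls_b == "specialist"),
    }
    cells = [
        _cell_of(a, b)
        for i, a in enumerate(ENVIRONMENTS)
        for b in ENVIRONMENTS[i:]
    ]
    cell_key = [
        _cell_of(a, b) for a, b in zip(df["env_a"], df["env_b"])
    ]
    df["_cell"] = pd.Series(cell_key, index=df.index, dtype=object)

    pd_all = df["pd"].to_numpy(dtype=float)
    edges = _bin_edges(pd_all, n_distance_bins, quantile=False)

    # per (group, cell): per-bin histogram; shared target = elementwise min
    hists: dict[tuple[str, tuple[str, str]], np.ndarray] = {}
    index_sets: dict[tuple[str, tuple[str, str]], np.ndarray] = {}
    n_bins = len(edges) - 1
    for group, mask in group_masks.items():
        for cell in cells:
            sel = np.flatnonzero(mask & (df["_cell"] == cell).to_numpy())
            if len(sel) == 0:
                raise ValueError(
                    f"environment-pair cell {cell} is empty for group {group!r}"
                )
            index_sets[(group, cell)] = sel
            hists[(group, cell)] = np.bincount(
                _bin_index(pd_all[sel], edges), minlength=n_bins
            )
    target = np.min(np.stack(list(hists.values())), axis=0)
    if target.sum() == 0:
        raise ValueError("PD-equalization target is empty in every bin")

    has_transfer = df["has_transfer"].to_numpy(dtype=bool)

    def matrix_for(group: str, generator: np.random.Generator) -> pd.DataFrame:
        mat = pd.DataFrame(np.nan, index=ENVIRONMENTS, columns=ENVIRONMENTS)
        for cell in cells:
            sel = index_sets[(group, cell)]
            keep = match_to_target(pd_all[sel], edges, target, generator)
            frac = float(has_transfer[sel[keep]].mean())
            mat.at[cell[0], cell[1]] = frac
            mat.at[cell[1], cell[0]] = frac
        return mat

    def stats_of(mat: pd.DataFrame) -> dict[str, float]:
        vals = np.array([mat.at[c[0], c[1]] for c in cells])
        return {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "range": float(vals.max() - vals.min()),
        }

    matrices = {g: matrix_for(g, rng) for g in group_masks}
    observed = {g: stats_of(m) for g, m in matrices.items()}

    background: dict[str, list[float]] = {"mean": [], "sd": [], "range": []}
    for _ in range(n_background):
        m = matrix_for("all", rng)
        for name, value in stats_of(m).items():
            background[name].append(value)
    bg_arrays = {k: np.asarray(v) for k, v in background.items()}
    bg_fit = {k: stats.norm.fit(v) for k, v in bg_arrays.items()}

    stat_df = pd.DataFrame(observed).T
    z = pd.DataFrame(
        {
            name: {
                g: (observed[g][name] - bg_fit[name][0]) / bg_fit[name][1]
                for g in group_masks
            }
            for name in ("mean", "sd", "range")
        }
    )
    sizes = pd.DataFrame(
        [
            (g, f"{c[0]}-{c[1]}", int(target.sum()))
            for g in group_masks
            for c in cells
        ],
        columns=["group", "cell", "n_pairs"],
    )
    return EnvTransferResult(
        matrices=matrices,
        cell_sizes=sizes,
        statistics=stat_df,
        zscores=z,
        background=bg_arrays,
    )
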