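"""Distribution-matched subsampling and rank-based group comparison.

Two groups are reduced to a common covariate distribution by splitting the
pooled covariate range into equal-width bins (a grid of bin cells for two
covariates) and randomly downsampling, within every bin, the group with
more records to the other group's count.  The matched outcome
distributions are then compared with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class MatchSpec:
    """Covariate matching specification.

    ``covariates``: one or two column names; ``n_bins`` equal-width bins per
    covariate over the pooled range; ``quantile_bins`` switches to
    equal-count (quantile) bin edges computed on the pooled values.

    The realized bin grid is cached on the spec at first use, so repeated
    matching with one spec applies the identical binning — re-matching a
    matched pair of groups is then an exact no-op.
    """

    covariates: tuple[str, ...]
    n_bins: int = 80
    seed: int = 0
    quantile_bins: bool = False
    edges: tuple | None = None

    def __post_init__(self):
        if isinstance(self.covariates, str):
            self.covariates = (self.covariates,)
        self.covariates = tuple(self.covariates)
        if not 1 <= len(self.covariates) <= 2:
            raise ValueError("one or two covariates required")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def _bin_edges(pooled: np.ndarray, n_bins: int, quantile: bool) -> np.ndarray:
    if not np.all(np.isfinite(pooled)):
        raise ValueError("covariates must be finite")
    if quantile:
        edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)))
        if len(edges) < 2:
            edges = np.array([pooled.min(), pooled.max() + 1.0])
        return edges
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi == lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Right-open bins except the last, which is closed."""
    idx = np.digitize(values, edges, right=False) - 1
    idx[values == edges[-1]] = len(edges) - 2
    return np.clip(idx, 0, len(edges) - 2)


def matched_subsample(group_a, group_b, spec: MatchSpec):
    """Downsample both groups to identical per-bin covariate counts.

    Parameters are two record tables (anything with ``__getitem__`` by
    column name returning array-likes, e.g. pandas DataFrames) and a
    :class:`MatchSpec`.  Returns positional index arrays into each group.
    Bin edges are computed on the pooled values of both groups;
    deterministic given ``spec.seed``.

    Downsampling always retains the records carrying the pooled extremes of
    each covariate (when their bin survives), so the pooled range — and
    hence the bin grid — is unchanged by matching and re-matching a matched
    pair of groups is a no-op.
    """
    cols = spec.covariates
    a_vals = [np.asarray(group_a[c], dtype=float) for c in cols]
    b_vals = [np.asarray(group_b[c], dtype=float) for c in cols]
    n_a, n_b = len(a_vals[0]), len(b_vals[0])
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    rng = np.random.default_rng(spec.seed)
    if spec.edges is None:
        spec.edges = tuple(
            _bin_edges(
                np.concatenate([va, vb]), spec.n_bins, spec.quantile_bins
            )
            for va, vb in zip(a_vals, b_vals)
        )
    cell_a = np.zeros(n_a, dtype=np.int64)
    cell_b = np.zeros(n_b, dtype=np.int64)
    forced_a, forced_b = set(), set()
    for va, vb, edges in zip(a_vals, b_vals, spec.edges):
        k = len(edges) - 1
        cell_a = cell_a * k + _bin_index(va, edges)
        cell_b = cell_b * k + _bin_index(vb, edges)
        pooled = np.concatenate([va, vb])
        for extreme in (np.argmin(pooled), np.argmax(pooled)):
            if extreme < n_a:
                forced_a.add(int(extreme))
            else:
                forced_b.add(int(extreme) - n_a)

    keep_a, keep_b = [], []
    cells = np.intersect1d(np.unique(cell_a), np.unique(cell_b))

    def pick(indices, n, forced):
        if len(indices) <= n:
            return indices
        must = np.array(sorted(set(indices.tolist()) & forced), dtype=np.int64)
        free = np.setdiff1d(indices, must)
        take = n - len(must)
        if take <= 0:
            return must[:n]
        return np.concatenate([must, rng.choice(free, size=take, replace=False)])

    for cell in cells:
        ia = np.flatnonzero(cell_a == cell)
        ib = np.flatnonzero(cell_b == cell)
        n = min(len(ia), len(ib))
        keep_a.append(pick(ia, n, forced_a))
        keep_b.append(pick(ib, n, forced_b))
    if not keep_a:
        import warnings

        warnings.warn("matched_subsample: disjoint covariate supports", stacklevel=2)
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    return (
        np.sort(np.concatenate(keep_a)),
        np.sort(np.concatenate(keep_b)),
    )


def mwu_compare(values_a, values_b, alternative: str = "two-sided"):
    """Mann-Whitney U test between two samples.

    Exact null distribution when the problem is small (n_a * n_b <= 10000)
    and tie-free; otherwise the normal approximation with tie correction.
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    method = "exact" if (len(a) * len(b) <= 10_000 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def match_to_target(
    values: np.ndarray,
    edges: np.ndarray,
    target_counts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Subsample ``values`` to a fixed per-bin count profile.

    Used when several groups must all be reduced to one shared covariate
    histogram (e.g. equalizing phylogenetic distance across environment
    pairs).  ``target_counts[i]`` must not exceed the number of values in
    bin ``i``.  Returns positional indices.
    """
    idx = _bin_index(np.asarray(values, dtype=float), edges)
    keep = []
    for b, want in enumerate(target_counts):
        if want <= 0:
            continue
        pool = np.flatnonzero(idx == b)
        if len(pool) < want:
            raise ValueError(f"bin {b}: {len(pool)} values < target {want}")
        keep.append(rng.choice(pool, size=int(want), replace=False))
    if not keep:
        return np.array([], dtype=np.int64)
    return np.sort(np.concatenate(keep))
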