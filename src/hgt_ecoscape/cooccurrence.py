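"""Co-occurrence, power-law phylogenetic correction and HGT association.

Co-occurrence between two OTUs is a conditional prevalence: the number of
samples containing both divided by the sample count of the less prevalent
OTU.  Because closely related taxa prefer similar environments,
co-occurrence decays with phylogenetic distance; that confound is removed
by fitting

    CO ~ k * PD**a

per focal OTU (nonlinear least squares, initialized from the log-log OLS
slope) and correlating the residuals, rather than raw co-occurrence, with
the number of genes transferred.  The significance of the per-OTU Spearman
correlations is judged against a background built by shuffling transfer
counts across each OTU's partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .events import HGTCountMatrix
from .matching import matched_subsample, mwu_compare, MatchSpec

PRESENCE_THRESHOLD = 1e-4  # relative abundance of at least 0.01%


def presence_matrix(abundance: pd.DataFrame, threshold: float = PRESENCE_THRESHOLD) -> pd.DataFrame:
    """Boolean OTU x sample presence at the relative-abundance threshold
    (inclusive: exactly 0.01% counts as present)."""
    return abundance >= threshold


def co_occurrence(presence: pd.DataFrame, otu_a: str, otu_b: str) -> float:
    """Shared-sample count over the less prevalent OTU's sample count."""
    pa = presence.loc[otu_a].to_numpy(dtype=bool)
    pb = presence.loc[otu_b].to_numpy(dtype=bool)
    na, nb = int(pa.sum()), int(pb.sum())
    if na == 0 or nb == 0:
        raise ValueError("both OTUs must be present in at least one sample")
    return float(np.sum(pa & pb) / min(na, nb))


def co_occurrence_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Dense symmetric co-occurrence matrix (NaN for never-present OTUs)."""
    P = presence.to_numpy(dtype=np.float64)
    counts = P.sum(axis=1)
    inter = P @ P.T
    mins = np.minimum.outer(counts, counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        co = np.where(mins > 0, inter / mins, np.nan)
    np.fill_diagonal(co, 1.0)
    return pd.DataFrame(co, index=presence.index, columns=presence.index)


def eligibility_filter(
    counts: HGTCountMatrix,
    presence: pd.DataFrame,
    min_partners: int = 30,
    min_samples: int = 20,
) -> tuple[set[str], set[tuple[str, str]]]:
    """Focal OTUs and eligible transfer pairs for the correction analysis.

    Focal OTUs exchanged at least one gene with ``min_partners`` other
    OTUs; a pair is eligible when both members are present in at least
    ``min_samples`` samples.  Boundaries are inclusive.
    """
    sample_counts = presence.sum(axis=1)
    well_sampled = set(sample_counts.index[sample_counts >= min_samples])
    partners = counts.partners()
    focal = {o for o, ps in partners.items() if len(ps) >= min_partners}
    pairs = {
        (a, b)
        for (a, b), n in counts.items()
        if n >= 1 and a in well_sampled and b in well_sampled
    }
    return focal, pairs


@dataclass
class PowerLawFit:
    k: float
    a: float
    residuals: np.ndarray
    converged: bool


class PowerLawFitError(RuntimeError):
    def __init__(self, message: str, k0: float, a0: float):
        super().__init__(message)
        self.initial_estimate = (k0, a0)


def fit_power_law(pd_values, co_values) -> PowerLawFit:
    """Nonlinear least squares of CO on k * PD**a.

    Pairs with PD = 0 are excluded; the starting point comes from ordinary
    least squares of log CO on log PD over CO > 0 pairs.  Residuals are on
    the natural scale: ``CO - k * PD**a``.
    """
    x = np.asarray(pd_values, dtype=float)
    y = np.asarray(co_values, dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs with PD > 0")

    pos = y > 0
    if pos.sum() >= 2 and len(np.unique(x[pos])) >= 2:
        slope, intercept = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        k0, a0 = float(np.exp(intercept)), float(slope)
    else:
        k0, a0 = max(float(np.mean(y)), 1e-6), 0.0

    def model(pdist, k, a):
        return k * np.power(pdist, a)

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=[max(k0, 1e-9), a0],
            bounds=([1e-12, -np.inf], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as err:
        raise PowerLawFitError(str(err), k0, a0) from err
    k, a = float(popt[0]), float(popt[1])
    residuals = y - model(x, k, a)
    return PowerLawFit(k=k, a=a, residuals=residuals, converged=True)


def power_law_residuals(df: pd.DataFrame, fit: PowerLawFit | None = None) -> pd.Series:
    """Residual co-occurrence for a pair table with ``pd``/``co`` columns."""
    if fit is None:
        fit = fit_power_law(df["pd"], df["co"])
    return df["co"] - fit.k * np.power(df["pd"], fit.a)


@dataclass
class ResidualCorrelationResult:
    per_otu: pd.DataFrame  # otu, n_partners, rho_pre, rho_post
    background: np.ndarray  # pooled shuffled-count correlations
    mwu_statistic: float
    mwu_p: float  # rho_post vs background, two-sided


def residual_correlation_analysis(
    pairs: pd.DataFrame,
    focal_otus: Sequence[str],
    n_shuffles: int = 100,
    seed: int = 0,
    min_partners: int = 3,
    fit_per_otu: bool = True,
) -> ResidualCorrelationResult:
    """Per-OTU Spearman correlations of transfer counts with co-occurrence.

    ``pairs`` needs columns ``otu_a``, ``otu_b``, ``co``, ``pd``,
    ``n_genes``.  For each focal OTU the power law is fitted over its own
    partners (``fit_per_otu=True``, the default) and Spearman correlations
    are computed for raw co-occurrence (pre-correction) and residuals
    (post-correction); the background shuffles counts within the OTU's
    partner list.  OTUs with fewer than ``min_partners`` partners or
    constant counts are skipped.
    """
    rng = np.random.default_rng(seed)
    long = pd.concat(
        [
            pairs.rename(columns={"otu_a": "focal", "otu_b": "partner"}),
            pairs.rename(columns={"otu_b": "focal", "otu_a": "partner"}),
        ],
        ignore_index=True,
    )
    global_fit = None
    if not fit_per_otu:
        global_fit = fit_power_law(pairs["pd"], pairs["co"])

    rows = []
    background: list[float] = []
    for otu in sorted(set(focal_otus)):
        sub = long[long["focal"] == otu]
        if len(sub) < min_partners:
            continue
        counts = sub["n_genes"].to_numpy(dtype=float)
        if np.all(counts == counts[0]):
            continue
        co = sub["co"].to_numpy(dtype=float)
        pdist = sub["pd"].to_numpy(dtype=float)
        try:
            fit = global_fit or fit_power_law(pdist, co)
        except (ValueError, PowerLawFitError):
            continue
        resid = co - fit.k * np.power(pdist, fit.a)
        rho_pre = stats.spearmanr(co, counts).statistic
        rho_post = stats.spearmanr(resid, counts).statistic
        rows.append((otu, len(sub), rho_pre, rho_post))
        for _ in range(n_shuffles):
            shuffled = rng.permutation(counts)
            background.append(stats.spearmanr(resid, shuffled).statistic)

    per_otu = pd.DataFrame(
        rows, columns=["otu", "n_partners", "rho_pre", "rho_post"]
    )
    bg = np.asarray(background, dtype=float)
    bg = bg[~np.isnan(bg)]
    if len(per_otu) and len(bg):
        u, p = mwu_compare(per_otu["rho_post"].dropna(), bg, "two-sided")
    else:
        u, p = float("nan"), float("nan")
    return ResidualCorrelationResult(
        per_otu=per_otu, background=bg, mwu_statistic=u, mwu_p=p
    )


def multi_transfer_threshold(counts: HGTCountMatrix, quantile: float = 0.8) -> int:
    """Count cutoff separating 'many transfers' pairs.

    The nearest-rank 80% quantile of per-pair counts restricted to pairs
    with at least one transfer, rounded up to an integer.
    """
    values = np.array([n for _, n in counts.items() if n >= 1])
    if len(values) == 0:
        raise ValueError("no pairs with at least one transfer")
    q = np.quantile(values, quantile, method="inverted_cdf")
    return int(np.ceil(q))


@dataclass
class InteractionEnrichment:
    n_interacting_multi: int
    n_interacting_low: int
    fold: float | None


def interaction_enrichment(
    interacting: set[tuple[str, str]],
    multi_pairs: Sequence[tuple[str, str]],
    low_pairs: Sequence[tuple[str, str]],
) -> InteractionEnrichment:
    """Fold enrichment of predicted ecological interactions.

    ``multi_pairs``/``low_pairs`` are the matched pair sets (multi-transfer
    vs at-most-one-transfer, subsampled to shared PD and co-occurrence
    distributions upstream); ``interacting`` holds unordered OTU pairs with
    a positive interaction score.
    """
    inter = {frozenset(p) for p in interacting}
    n_multi = sum(1 for p in multi_pairs if frozenset(p) in inter)
    n_low = sum(1 for p in low_pairs if frozenset(p) in inter)
    fold = (n_multi / n_low) if n_low > 0 else None
    return InteractionEnrichment(
        n_interacting_multi=n_multi, n_interacting_low=n_low, fold=fold
    )


def build_pair_table(
    co_matrix: pd.DataFrame,
    pd_matrix: pd.DataFrame,
    counts: HGTCountMatrix,
    eligible_pairs: set[tuple[str, str]] | None = None,
    include_zero_pairs: bool = False,
) -> pd.DataFrame:
    """Long-format pair table with co-occurrence, PD and transfer counts."""
    otus = list(co_matrix.index)
    rows = []
    for i, a in enumerate(otus):
        for b in otus[i + 1:]:
            n = counts.get(a, b)
            if n == 0 and not include_zero_pairs:
                continue
            if eligible_pairs is not None and (a, b) not in eligible_pairs and (b, a) not in eligible_pairs:
                continue
            co = co_matrix.at[a, b]
            if np.isnan(co):
                continue
            rows.append((a, b, float(co), float(pd_matrix.at[a, b]), n))
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "co", "pd", "n_genes"])
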