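"""Co-occurrence statistics, power-law correction and thresholds."""

import numpy as np
import pandas as pd
import pytest

from hgt_ecoscape.cooccurrence import (
    InteractionEnrichment,
    build_pair_table,
    co_occurrence,
    co_occurrence_matrix,
    eligibility_filter,
    fit_power_law,
    interaction_enrichment,
    multi_transfer_threshold,
    presence_matrix,
    residual_correlation_analysis,
)
from hgt_ecoscape.events import HGTCountMatrix


def presence_from_sets(sets, n_samples):
    otus = sorted(sets)
    mat = pd.DataFrame(
        False, index=otus, columns=[f"s{i}" for i in range(1, n_samples + 1)]
    )
    for otu, samples in sets.items():
        for s in samples:
            mat.loc[otu, f"s{s}"] = True
    return mat


class TestPresence:
    def test_threshold_inclusive(self):
        ab = pd.DataFrame({"s1": [1e-4, 9e-5, 0.0]}, index=["a", "b", "c"])
        pres = presence_matrix(ab)
        assert bool(pres.loc["a", "s1"]) is True  # exactly 0.01% is present
        assert bool(pres.loc["b", "s1"]) is False
        assert bool(pres.loc["c", "s1"]) is False


class TestCoOccurrence:
    def test_formula(self):
        pres = presence_from_sets({"a": {1, 2, 3}, "b": {2, 3, 4, 5}}, 6)
        assert co_occurrence(pres, "a", "b") == pytest.approx(2 / 3)

    def test_identical_and_disjoint(self):
        pres = presence_from_sets({"a": {1, 2}, "b": {1, 2}, "c": {3, 4}}, 4)
        assert co_occurrence(pres, "a", "b") == 1.0
        assert co_occurrence(pres, "a", "c") == 0.0

    def test_symmetry_and_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        pres = pd.DataFrame(
            rng.random((5, 30)) < 0.4,
            index=list("abcde"),
            columns=[f"s{i}" for i in range(30)],
        )
        perm = pres.iloc[:, rng.permutation(30)]
        for x in "abcd":
            for y in "bcde":
                if x == y or not pres.loc[y].any():
                    continue
                assert co_occurrence(pres, x, y) == co_occurrence(pres, y, x)
                assert co_occurrence(pres, x, y) == co_occurrence(perm, x, y)

    def test_never_present_otu_rejected(self):
        pres = presence_from_sets({"a": {1}, "b": set()}, 2)
        with pytest.raises(ValueError):
            co_occurrence(pres, "a", "b")

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(5)
        pres = pd.DataFrame(
            rng.random((6, 40)) < 0.5,
            index=[f"o{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(40)],
        )
        mat = co_occurrence_matrix(pres)
        for a in pres.index:
            for b in pres.index:
                if a != b:
                    assert mat.at[a, b] == pytest.approx(co_occurrence(pres, a, b))


class TestEligibility:
    def test_boundaries(self):
        counts = HGTCountMatrix()
        for i in range(30):
            counts.add("focal", f"p{i:02d}")  # exactly 30 partners
        for i in range(29):
            counts.add("weak", f"p{i:02d}")
        sets = {f"p{i:02d}": set(range(1, 21)) for i in range(30)}
        sets["focal"] = set(range(1, 21))  # exactly 20 samples
        sets["weak"] = set(range(1, 20))  # 19 samples
        pres = presence_from_sets(sets, 25)
        focal, pairs = eligibility_filter(counts, pres)
        assert "focal" in focal
        assert "weak" not in focal
        assert all("weak" not in p for p in pairs)
        assert ("focal", "p00") in pairs or ("p00", "focal") in pairs


class TestPowerLawFit:
    def test_noiseless_exact_recovery(self):
        pd_vals = np.array([0.25, 0.49, 1.0, 4.0])
        co_vals = 0.5 * pd_vals**-0.5
        fit = fit_power_law(pd_vals, co_vals)
        assert fit.k == pytest.approx(0.5, abs=1e-6)
        assert fit.a == pytest.approx(-0.5, abs=1e-6)
        assert np.abs(fit.residuals).max() < 1e-9

    def test_flat_data(self):
        pd_vals = np.linspace(0.1, 3.0, 50)
        fit = fit_power_law(pd_vals, np.full(50, 0.4))
        assert fit.a == pytest.approx(0.0, abs=1e-6)
        assert fit.k == pytest.approx(0.4, abs=1e-6)

    def test_zero_distance_pairs_excluded(self):
        pd_vals = np.array([0.0, 0.25, 1.0, 4.0])
        co_vals = np.array([9.9, 1.0, 0.5, 0.25])
        fit = fit_power_law(pd_vals, co_vals)
        assert fit.a == pytest.approx(-0.5, abs=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0], [0.5, 0.4])

    def test_lognormal_noise_recovery(self):
        """|a_hat - a| < 0.1 on average with sigma=0.2 noise at n=500."""
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pd_vals = rng.uniform(0.05, 3.0, 500)
            co_vals = 0.6 * pd_vals**-0.7 * rng.lognormal(0.0, 0.2, 500)
            fit = fit_power_law(pd_vals, co_vals)
            errs.append(abs(fit.a + 0.7))
        assert np.mean(errs) < 0.1


class TestMultiTransferThreshold:
    def test_nearest_rank_oracle(self):
        """Cutoff equals the nearest-rank quantile (sorted[ceil(q n)])."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = rng.integers(1, 15, size=int(rng.integers(3, 30)))
            counts = HGTCountMatrix()
            for i, v in enumerate(values):
                counts.add("a", f"b{i}", int(v))
            oracle = int(np.sort(values)[int(np.ceil(0.8 * len(values))) - 1])
            assert multi_transfer_threshold(counts) == oracle

    def test_all_ones(self):
        counts = HGTCountMatrix()
        for i in range(5):
            counts.add("a", f"b{i}", 1)
        assert multi_transfer_threshold(counts) == 1

    def test_uniform_one_to_ten(self):
        counts = HGTCountMatrix()
        for i, v in enumerate(range(1, 11)):
            counts.add("a", f"b{i}", v)
        assert multi_transfer_threshold(counts) == 8

    def test_no_transfers_rejected(self):
        with pytest.raises(ValueError):
            multi_transfer_threshold(HGTCountMatrix())


class TestInteractionEnrichment:
    def test_fold_from_counts(self):
        inter = {(f"a{i}", f"b{i}") for i in range(20)}
        multi = [(f"a{i}", f"b{i}") for i in range(12)]
        low = [(f"a{i}", f"b{i}") for i in range(12, 18)] + [("x", "y")] * 4
        res = interaction_enrichment(inter, multi, low)
        assert res.n_interacting_multi == 12
        assert res.n_interacting_low == 6
        assert res.fold == pytest.approx(2.0)

    def test_equal_counts_fold_one(self):
        inter = {("a", "b"), ("c", "d")}
        res = interaction_enrichment(inter, [("a", "b")], [("c", "d")])
        assert res.fold == pytest.approx(1.0)

    def test_zero_denominator(self):
        res = interaction_enrichment({("a", "b")}, [("a", "b")], [("x", "y")])
        assert res.fold is None
        assert res.n_interacting_multi == 1

    def test_pair_order_irrelevant(self):
        res = interaction_enrichment({("b", "a")}, [("a", "b")], [("a", "b")])
        assert res.n_interacting_multi == res.n_interacting_low == 1


def _pair_table_for_one_focal(counts_by_partner, co_by_partner, pd_by_partner):
    rows = [
        ("focal", p, co_by_partner[p], pd_by_partner[p], counts_by_partner[p])
        for p in counts_by_partner
    ]
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "co", "pd", "n_genes"])


class TestResidualCorrelation:
    def test_perfect_monotone_counts_give_rho_one(self):
        rng = np.random.default_rng(0)
        partners = [f"p{i}" for i in range(20)]
        pd_vals = {p: rng.uniform(0.2, 2.0) for p in partners}
        co_vals = {p: 0.5 * pd_vals[p] ** -0.5 for p in partners}
        # counts strictly increasing in residual: residuals ~ 0, add ranks
        resid_rank = {p: i for i, p in enumerate(
            sorted(partners, key=lambda q: co_vals[q] - 0.5 * pd_vals[q] ** -0.5)
        )}
        counts = {p: resid_rank[p] + 1 for p in partners}
        # perturb CO so residuals are non-degenerate and counts follow them
        for i, p in enumerate(partners):
            co_vals[p] *= 1.0 + 0.01 * counts[p]
        table = _pair_table_for_one_focal(counts, co_vals, pd_vals)
        res = residual_correlation_analysis(table, ["focal"], n_shuffles=5, seed=1)
        assert len(res.per_otu) == 1
        assert res.per_otu.iloc[0].rho_post > 0.9

    def test_constant_counts_skipped(self):
        partners = [f"p{i}" for i in range(10)]
        table = _pair_table_for_one_focal(
            {p: 3 for p in partners},
            {p: 0.5 for p in partners},
            {p: 1.0 + i * 0.1 for i, p in enumerate(partners)},
        )
        res = residual_correlation_analysis(table, ["focal"], n_shuffles=5, seed=1)
        assert len(res.per_otu) == 0

    def test_too_few_partners_skipped(self):
        table = _pair_table_for_one_focal(
            {"p1": 1, "p2": 2}, {"p1": 0.5, "p2": 0.4}, {"p1": 1.0, "p2": 2.0}
        )
        res = residual_correlation_analysis(table, ["focal"], n_shuffles=5, seed=1)
        assert len(res.per_otu) == 0

    def test_rho_invariant_to_monotone_count_rescaling(self):
        rng = np.random.default_rng(3)
        partners = [f"p{i}" for i in range(25)]
        pd_vals = {p: rng.uniform(0.2, 2.0) for p in partners}
        co_vals = {p: 0.5 * pd_vals[p] ** -0.5 * rng.lognormal(0, 0.2) for p in partners}
        counts = {p: int(rng.integers(0, 40)) for p in partners}
        t1 = _pair_table_for_one_focal(counts, co_vals, pd_vals)
        t2 = t1.assign(n_genes=t1.n_genes**3)  # monotone transform
        r1 = residual_correlation_analysis(t1, ["focal"], n_shuffles=2, seed=5)
        r2 = residual_correlation_analysis(t2, ["focal"], n_shuffles=2, seed=5)
        assert r1.per_otu.iloc[0].rho_post == pytest.approx(
            r2.per_otu.iloc[0].rho_post
        )


def test_build_pair_table_includes_counts_and_distances():
    pres = pd.DataFrame(
        [[True, True, False], [True, False, True], [True, True, True]],
        index=["a", "b", "c"],
        columns=["s1", "s2", "s3"],
    )
    co = co_occurrence_matrix(pres)
    pdm = pd.DataFrame(
        [[0, 1.0, 2.0], [1.0, 0, 1.5], [2.0, 1.5, 0]],
        index=["a", "b", "c"],
        columns=["a", "b", "c"],
    )
    counts = HGTCountMatrix()
    counts.add("a", "b", 3)
    table = build_pair_table(co, pdm, counts)
    assert len(table) == 1
    row = table.iloc[0]
    assert row.n_genes == 3 and row.pd == 1.0
    full = build_pair_table(co, pdm, counts, include_zero_pairs=True)
    assert len(full) == 3
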