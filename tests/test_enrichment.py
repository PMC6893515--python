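"""Motif counting, frequency, clustering, Fisher and BH contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

import phagescape as ps
from phagescape.enrichment import (
    MotifCountTable,
    adjust_and_flag,
    bh_adjust,
    cluster_profiles,
    count_motifs,
    extract_motifs,
    fisher_enrichment,
    fisher_one_sided_p,
    motif_frequencies,
    pool_counts,
    select_tissue_selective,
)
from phagescape.examples import TUMOR_PEPTIDE_FAMILIES


def brute_force_tail_p(a, b, c, d):
    """Exact one-sided Fisher p by enumerating the hypergeometric tail with
    integer arithmetic (margins fixed, X >= a)."""
    M, n, N = a + b + c + d, a + c, a + b
    lo, hi = max(0, n + N - M), min(n, N)
    num = sum(math.comb(n, k) * math.comb(M - n, N - k) for k in range(a, hi + 1))
    return num / math.comb(M, N)


def step_up_oracle(p):
    """Independent BH step-up: q(i) = min_{j>=i} min(1, p(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    best = 1.0
    for rank in range(m, 0, -1):
        best = min(best, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = best
    return q


class TestExtractMotifs:
    @pytest.mark.parametrize(
        "peptide,expected",
        [
            ("AMYWDRASD", ["AMY", "MYW", "YWD", "WDR", "DRA", "RAS", "ASD"]),
            ("AAAAAAAAA", ["AAA"] * 7),
            ("VHKA", ["VHK", "HKA"]),
        ],
    )
    def test_windows(self, peptide, expected):
        assert extract_motifs(peptide) == expected

    def test_too_short(self):
        with pytest.raises(ValueError):
            extract_motifs("AM")


class TestCountMotifs:
    def test_homopolymer_counts_once_per_peptide(self):
        table = count_motifs(["AAAAAAAAA"])
        assert dict(table.counts) == {"AAA": 1} and table.total_motifs == 1

    def test_single_peptide_seven_distinct_motifs(self):
        table = count_motifs(["AMYWDRASD"])
        assert (table.counts == 1).all() and table.total_motifs == 7

    def test_myw_family_count(self):
        """Every peptide of the isolated-motif example family contains MYW."""
        table = count_motifs(TUMOR_PEPTIDE_FAMILIES["MYW"])
        brute = sum(1 for p in TUMOR_PEPTIDE_FAMILIES["MYW"] if "MYW" in p)
        assert table.counts["MYW"] == brute == 16

    def test_read_weighted_mode(self):
        recs = [ps.PeptideRecord("AAAAAAAAA", 5, 2), ps.PeptideRecord("WWWWWWWWW", 2, 1)]
        table = count_motifs(recs, weighting="read_weighted")
        assert dict(table.counts) == {"AAA": 5, "WWW": 2}

    def test_empty_collection(self):
        with pytest.raises(ValueError):
            count_motifs([])


class TestFrequencies:
    def test_percentages(self):
        table = MotifCountTable("t", pd.Series({"m1": 3, "m2": 1}), "unique_peptide")
        prof = motif_frequencies(table)
        assert prof.frequencies["m1"] == 75.0 and prof.frequencies["m2"] == 25.0

    def test_sum_to_100(self, rng):
        counts = pd.Series(rng.integers(1, 50, size=200), index=[f"m{i}" for i in range(200)])
        prof = motif_frequencies(MotifCountTable("t", counts, "unique_peptide"))
        assert prof.frequencies.sum() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_8000_hits_filter_boundary(self):
        counts = pd.Series(1, index=[f"m{i}" for i in range(8000)])
        prof = motif_frequencies(MotifCountTable("t", counts, "unique_peptide"))
        assert np.allclose(prof.frequencies, 0.0125)


class TestClusterProfiles:
    @staticmethod
    def _profile(tissue, values):
        return ps.MotifFrequencyProfile(tissue, pd.Series(values))

    def test_identical_profiles_merge_at_zero(self):
        p = {"AAA": 60.0, "CCC": 40.0}
        clustered = cluster_profiles([self._profile("a", p), self._profile("b", p)],
                                     min_frequency=0.0)
        assert clustered.tissue_linkage[0, 2] == pytest.approx(0.0)

    def test_low_frequency_motif_removed(self):
        vals = {"AAA": 99.99, "CCC": 0.01}
        clustered = cluster_profiles([self._profile("a", vals), self._profile("b", vals)])
        assert "CCC" not in clustered.matrix.index and "AAA" in clustered.matrix.index

    def test_closest_pair_merges_first(self):
        base = {"AAA": 50.0, "CCC": 50.0}
        far = {"AAA": 90.0, "CCC": 10.0}
        clustered = cluster_profiles(
            [self._profile("a", base), self._profile("b", base), self._profile("c", far)],
            min_frequency=0.0,
        )
        first = set(clustered.tissue_linkage[0, :2].astype(int))
        labels = list(clustered.matrix.columns)
        assert {labels[i] for i in first} == {"a", "b"}

    def test_all_filtered_is_error(self):
        vals = {"AAA": 0.001}
        with pytest.raises(ValueError, match="below the frequency filter"):
            cluster_profiles([self._profile("a", vals), self._profile("b", vals)])


class TestFisher:
    def test_zero_count_gives_p_one(self):
        assert fisher_one_sided_p(0, 10, 5, 5) == pytest.approx(1.0)

    def test_example_table_vs_enumeration(self):
        p = fisher_one_sided_p(5, 5, 1, 9)
        assert p == pytest.approx(brute_force_tail_p(5, 5, 1, 9), abs=1e-14)

    def test_matches_scipy_fisher_exact(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            ours = fisher_one_sided_p(a, b, c, d)
            ref = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_monotone_in_enriched_cell(self):
        # shift one count from b to a with margins fixed: p must not increase
        ps_ = [fisher_one_sided_p(a, 20 - a, 5, 45) for a in range(0, 21)]
        assert all(x >= y - 1e-15 for x, y in zip(ps_, ps_[1:]))

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided_p(-1, 2, 3, 4)


class TestFisherEnrichment:
    def _tables(self):
        tissue = MotifCountTable("tumor", pd.Series({"MYW": 20, "AAA": 80}), "unique_peptide")
        norm = MotifCountTable("library", pd.Series({"MYW": 5, "AAA": 95}), "unique_peptide")
        return tissue, norm

    def test_fold_change_is_frequency_ratio(self):
        tissue, norm = self._tables()
        res = fisher_enrichment(tissue, norm).set_index("motif")
        assert res.loc["MYW", "fold_change"] == pytest.approx((20 / 100) / (5 / 100))

    def test_zero_normalizer_pseudocount_only_affects_fold(self):
        tissue = MotifCountTable("t", pd.Series({"WKH": 10, "AAA": 90}), "unique_peptide")
        norm = MotifCountTable("library", pd.Series({"AAA": 100}), "unique_peptide")
        res = fisher_enrichment(tissue, norm).set_index("motif")
        assert res.loc["WKH", "fold_change"] == pytest.approx((10.5 / 100) / (0.5 / 100))
        assert res.loc["WKH", "p_value"] == pytest.approx(
            brute_force_tail_p(10, 90, 0, 100), abs=1e-12
        )

    def test_motif_absent_from_both_skipped(self):
        tissue, norm = self._tables()
        res = fisher_enrichment(tissue, norm)
        assert set(res["motif"]) == {"MYW", "AAA"}

    def test_pool_counts_sums_raw_counts(self):
        t1 = MotifCountTable("a", pd.Series({"AAA": 2}), "unique_peptide")
        t2 = MotifCountTable("b", pd.Series({"AAA": 3, "CCC": 1}), "unique_peptide")
        pooled = pool_counts([t1, t2])
        assert dict(pooled.counts) == {"AAA": 5, "CCC": 1}


class TestBH:
    def test_step_up_arithmetic_forces_equality(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_independent_oracle(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 400))
            assert bh_adjust(p) == pytest.approx(step_up_oracle(p), abs=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.random(500)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestSelection:
    def _results(self):
        return pd.DataFrame(
            {
                "motif": ["m1", "m2", "m3"],
                "tissue_id": "t",
                "normalization_scheme": "library",
                "fold_change": [10.0, 10.0, 1.5],
                "p_value": [0.0001, 0.2, 0.0001],
                "p_adjusted": [0.001, 0.2, 0.001],
            }
        )

    def test_selection_thresholds(self):
        selected, volcano = select_tissue_selective(self._results())
        assert selected == {"m1"}  # m2 fails p, m3 fails fold
        assert set(volcano.columns) >= {"log2_fold_change", "neg_log2_p_adjusted", "selective"}

    def test_adjust_and_flag_families_are_per_tissue_scheme(self):
        df = pd.concat(
            [
                pd.DataFrame({"motif": ["a", "b"], "tissue_id": "t1",
                              "normalization_scheme": "library",
                              "fold_change": 3.0, "p_value": [0.01, 0.04]}),
                pd.DataFrame({"motif": ["a"], "tissue_id": "t2",
                              "normalization_scheme": "library",
                              "fold_change": 3.0, "p_value": [0.04]}),
            ],
            ignore_index=True,
        )
        out = adjust_and_flag(df)
        # t2's single test is not penalized by t1's family size
        assert out.loc[(out.tissue_id == "t2"), "p_adjusted"].iloc[0] == pytest.approx(0.04)
        assert out.loc[(out.tissue_id == "t1"), "p_adjusted"].tolist() == pytest.approx([0.02, 0.04])
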