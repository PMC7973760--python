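from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddradkit.variants import (
    DEFAULT_MIN_REPEATS,
    GenotypeMatrix,
    MISSING,
    SSRRecord,
    VariantRecord,
    classify_indel_ssr,
    density_windows,
    filter_dataset,
    indel_stats,
    rate_summary,
    sharing_distribution,
    ssr_motif_summary,
    ssr_scan,
    tstv,
    variants_per_common_site,
)


class TestSSRScan:
    def test_mono_threshold_10(self):
        recs = ssr_scan("T" * 10)
        assert len(recs) == 1
        assert (recs[0].motif, recs[0].repeats, recs[0].perfect) == ("T", 10, True)

    def test_mono_9_rejected(self):
        assert ssr_scan("A" * 9) == []

    def test_di_5_rejected(self):
        assert ssr_scan("AT" * 5) == []

    def test_di_6_detected(self):
        recs = ssr_scan("AT" * 6)
        assert [(r.motif, r.repeats) for r in recs] == [("AT", 6)]

    def test_tri_5_detected(self):
        recs = ssr_scan("ATG" * 5)
        assert [(r.motif, r.repeats) for r in recs] == [("ATG", 5)]

    @pytest.mark.parametrize("m,motif", [(4, "ATGC"), (5, "ATGCC"), (6, "ATGCCT")])
    def test_longer_motifs_threshold_5(self, m, motif):
        assert ssr_scan(motif * 4) == []
        recs = ssr_scan(motif * 5)
        assert [(r.motif, r.repeats) for r in recs] == [(motif, 5)]

    def test_reducible_motif_suppressed(self):
        # (AT)x8 must be reported once as an AT repeat, not also as ATAT
        recs = ssr_scan("AT" * 8)
        assert [(r.motif, len(r.motif)) for r in recs] == [("AT", 2)]

    def test_embedded_in_context(self):
        seq = "GCGCGATCGG" + "CA" * 7 + "GGATCCGGAT"
        recs = ssr_scan(seq)
        assert [(r.motif, r.repeats, r.start) for r in recs] == [("CA", 7, 10)]

    def test_interrupted_run_merges_to_imperfect(self):
        # two (AT)x3 runs separated by 2 bases merge: 6 units total
        seq = "AT" * 3 + "GG" + "AT" * 3
        recs = ssr_scan(seq, max_interruption=4)
        assert len(recs) == 1
        assert (recs[0].repeats, recs[0].perfect) == (6, False)
        assert (recs[0].start, recs[0].end) == (0, len(seq))

    def test_interruption_beyond_limit_not_merged(self):
        seq = "AT" * 3 + "G" * 5 + "AT" * 3
        assert ssr_scan(seq, max_interruption=4) == []

    def test_rotated_phase_merges(self):
        # TATATA is an AT-repeat in a different phase
        seq = "AT" * 3 + "GG" + "TA" * 3
        recs = ssr_scan(seq, max_interruption=4)
        assert len(recs) == 1 and recs[0].repeats == 6

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            ssr_scan("ACGTQ")

    def test_poly_n_not_an_ssr(self):
        assert ssr_scan("N" * 20) == []

    def test_span_invariant(self):
        for rec in ssr_scan("A" * 12 + "GG" + "ATG" * 6 + "C" * 3 + "GT" * 9):
            assert rec.end - rec.start >= len(rec.motif) * DEFAULT_MIN_REPEATS[len(rec.motif)]

    @given(
        st.sampled_from(["A", "AT", "AG", "ATG", "ACGT"]),
        st.integers(2, 15),
    )
    @settings(max_examples=80, deadline=None)
    def test_pure_repeat_threshold_rule(self, motif, reps):
        recs = ssr_scan(motif * reps)
        threshold = DEFAULT_MIN_REPEATS[len(motif)]
        if reps >= threshold:
            assert [(r.motif, r.repeats) for r in recs] == [(motif, reps)]
        else:
            assert recs == []


class TestClassifyIndelSSR:
    GENOME = {
        "c": "GCTTACGGAC" + "AT" * 5 + "CGGATCGTTA" + "GCCTAGCTAG" * 3,
    }

    def test_insertion_crossing_threshold(self):
        # inserting AT inside (AT)5 produces (AT)6
        v = VariantRecord("c", 10, "A", ("AAT",), "InDel")
        assert classify_indel_ssr(v, self.GENOME) is True

    def test_nonrepetitive_context(self):
        v = VariantRecord("c", 3, "T", ("TG",), "InDel")
        assert classify_indel_ssr(v, self.GENOME) is False

    def test_missing_chromosome_rejected(self):
        v = VariantRecord("zzz", 1, "A", ("AT",), "InDel")
        with pytest.raises(ValueError):
            classify_indel_ssr(v, self.GENOME)

    def test_planted_truth_batch(self, small_dataset):
        design, genome, truth = small_dataset
        chrom = design.chrom_name
        for motif, repeats, start, end in truth["ssr_tracts"]:
            if DEFAULT_MIN_REPEATS[len(motif)] > repeats + 1:
                continue
            ref = genome[chrom][start - 1]
            v = VariantRecord(chrom, start, ref, (ref + motif,), "InDel")
            assert classify_indel_ssr(v, genome) is True


class TestTsTv:
    def test_single_transition_flagged_ratio(self):
        assert tstv([("A", "G")]) == (1, 0, None)

    def test_small_mixture(self):
        assert tstv([("A", "G"), ("C", "T"), ("A", "C")]) == (2, 1, 2.0)

    def test_published_counts_give_ratio(self):
        pairs = [("A", "G")] * 225_942 + [("A", "C")] * 169_551
        ts, tv, ratio = tstv(pairs)
        assert (ts, tv, ratio) == (225_942, 169_551, 1.33)

    def test_all_pairs_classified(self):
        pairs = [(a, b) for a, b in itertools.permutations("ACGT", 2)]
        ts, tv, _ = tstv(pairs)
        assert ts + tv == len(pairs)
        assert ts == 4  # AG, GA, CT, TC

    def test_non_snp_rejected(self):
        with pytest.raises(ValueError):
            tstv([("AC", "A")])


class TestIndelStats:
    def test_published_ratio(self):
        recs = [VariantRecord("c", i + 1, "AT", ("A",), "InDel") for i in range(515)]
        recs += [VariantRecord("c", i + 1000, "A", ("AT",), "InDel") for i in range(556)]
        stats = indel_stats(recs)
        assert (stats.deletions, stats.insertions, stats.del_ins_ratio) == (515, 556, 0.93)

    def test_insertion_classified(self):
        stats = indel_stats([VariantRecord("c", 1, "A", ("AT",), "InDel")])
        assert (stats.deletions, stats.insertions) == (0, 1)
        assert stats.length_diff_histogram == {1: 1}

    def test_triallelic_contributes_both_classes(self):
        stats = indel_stats([VariantRecord("c", 1, "AAT", ("A", "AATGG"), "InDel")])
        assert (stats.deletions, stats.insertions) == (1, 1)

    def test_same_length_flagged(self):
        stats = indel_stats([VariantRecord("c", 1, "AT", ("GC",), "InDel")])
        assert stats.flagged_same_length == 1
        assert stats.deletions == stats.insertions == 0

    def test_planted_histogram(self):
        rng = np.random.default_rng(3)
        diffs = rng.integers(1, 15, size=200)
        recs = []
        for i, d in enumerate(diffs):
            recs.append(VariantRecord("c", i + 1, "A" * (1 + d), ("A",), "InDel"))
        stats = indel_stats(recs)
        expected = {int(d): int(n) for d, n in zip(*np.unique(diffs, return_counts=True))}
        assert dict(stats.length_diff_histogram) == expected
        assert sum(stats.class_fractions.values()) == pytest.approx(1.0)


def _matrix(rows, samples=None, var_types=None):
    """Build a GenotypeMatrix from per-variant genotype code rows.

    Codes: -1 missing, 0 hom ref, 1 het, 2 hom alt.
    """
    rows = np.asarray(rows)
    n_var, n_samp = rows.shape
    samples = samples or [f"s{j}" for j in range(n_samp)]
    var_types = var_types or ["SNP"] * n_var
    variants = [
        VariantRecord("c", 10 * (i + 1), "A", ("G",), var_types[i]) for i in range(n_var)
    ]
    alleles = np.full((n_var, n_samp, 2), MISSING, dtype=np.int8)
    alleles[rows == 0] = (0, 0)
    alleles[rows == 1] = (0, 1)
    alleles[rows == 2] = (1, 1)
    return GenotypeMatrix(variants, samples, alleles)


class TestSharing:
    def test_all_present(self):
        gm = _matrix(np.zeros((4, 5), dtype=int))
        sharing = sharing_distribution(gm)
        assert sharing["per_k"].tolist() == [0, 0, 0, 0, 4]
        assert sharing["at_least_k"].tolist() == [4, 4, 4, 4, 4]

    def test_exactly_three_of_five(self):
        gm = _matrix([[0, 1, 2, -1, -1]])
        sharing = sharing_distribution(gm)
        assert sharing["per_k"].tolist() == [0, 0, 1, 0, 0]

    def test_bernoulli_missingness_matches_direct_count(self):
        rng = np.random.default_rng(11)
        rows = rng.choice([-1, 0, 1, 2], size=(300, 20), p=[0.3, 0.3, 0.2, 0.2])
        gm = _matrix(rows)
        sharing = sharing_distribution(gm)
        called = (rows != -1).sum(axis=1)
        for k in range(1, 21):
            assert sharing["per_k"][k - 1] == (called == k).sum()
        assert sharing["per_k"].sum() == (called >= 1).sum()
        assert (np.diff(sharing["at_least_k"]) <= 0).all()


class TestFilter:
    def test_balanced_variant_kept(self):
        gm = _matrix([[0, 0, 2, 2]])
        kept, summary = filter_dataset(gm, 0.5, 0.5)
        assert kept.n_variants == 1

    def test_strict_missing_bound(self):
        # exactly 5% missing with threshold < 5% -> excluded
        row = [0] * 19 + [-1]
        gm = _matrix([row])
        kept, _ = filter_dataset(gm, max_missing_fraction=0.05, min_maf=0.0)
        assert kept.n_variants == 0

    def test_inclusive_maf_bound(self):
        # MAF exactly 1%: 1 het among 50 diploid samples = 1/100 alleles
        row = [0] * 49 + [1]
        gm = _matrix([row])
        kept, _ = filter_dataset(gm, max_missing_fraction=0.5, min_maf=0.01)
        assert kept.n_variants == 1

    def test_all_missing_excluded_and_counted(self):
        gm = _matrix([[-1, -1, -1], [0, 1, 0]])
        kept, summary = filter_dataset(gm, 0.9, 0.0)
        assert summary.all_missing == 1
        assert kept.n_variants == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        rows = rng.choice([-1, 0, 1, 2], size=(500, 20), p=[0.1, 0.5, 0.2, 0.2])
        gm = _matrix(rows)
        for max_missing, min_maf in itertools.product(
            (0.0, 0.05, 0.1, 0.5, 1.0), (0.0, 0.01, 0.05, 0.25, 0.5)
        ):
            kept, _ = filter_dataset(gm, max_missing, min_maf)
            expected = []
            for i in range(rows.shape[0]):
                row = rows[i]
                called = row[row != -1]
                miss_frac = (row == -1).sum() / len(row)
                if len(called):
                    alt = ((called == 1) + 2 * (called == 2)).sum()
                    total = 2 * len(called)
                    freqs = sorted([alt / total, 1 - alt / total], reverse=True)
                    maf = freqs[1] if alt not in (0, total) else 0.0
                else:
                    maf = 0.0
                if miss_frac < max_missing and maf >= min_maf:
                    expected.append(i)
            assert kept.n_variants == len(expected), (max_missing, min_maf)

    def test_triallelic_second_most_frequent(self):
        # alleles: 0 appears 4x, 1 appears 3x, 2 appears 1x among 4 samples
        alleles = np.array(
            [[[0, 0], [0, 1], [0, 1], [1, 2]]], dtype=np.int8
        )
        gm = GenotypeMatrix(
            [VariantRecord("c", 1, "A", ("G", "T"), "SNP")], list("wxyz"), alleles
        )
        assert gm.maf()[0] == pytest.approx(3 / 8)
        assert gm.maf("one_minus_major")[0] == pytest.approx(4 / 8)

    def test_kept_by_type_partition(self):
        rows = np.zeros((10, 4), dtype=int)
        rows[:, 2:] = 2
        types = ["SNP"] * 5 + ["InDel"] * 3 + ["SSR"] * 2
        gm = _matrix(rows, var_types=types)
        kept, summary = filter_dataset(gm, 0.5, 0.01)
        assert summary.kept_by_type == {"SNP": 5, "InDel": 3, "SSR": 2}
        assert sum(summary.kept_by_type.values()) == summary.kept_total

    def test_bad_thresholds_rejected(self):
        gm = _matrix([[0, 1]])
        with pytest.raises(ValueError):
            filter_dataset(gm, 1.5, 0.01)


class TestRates:
    def test_published_data_points(self):
        gm = _matrix(np.zeros((7, 191), dtype=int))
        assert rate_summary(gm)["data_points"] == 7 * 191

    def test_rates(self):
        gm = _matrix([[0, 1, -1, 1], [0, 0, 0, 0]])
        rates = rate_summary(gm)
        assert rates["pct_missing"] == pytest.approx(100 / 8)
        assert rates["pct_heterozygous"] == pytest.approx(200 / 8)

    def test_all_hom_ref(self):
        gm = _matrix(np.zeros((3, 4), dtype=int))
        rates = rate_summary(gm)
        assert rates["pct_missing"] == 0.0
        assert rates["pct_heterozygous"] == 0.0


class TestDensity:
    def test_single_variant(self):
        d = density_windows([VariantRecord("c", 150, "A", ("G",))], {"c": 1000}, 1000)
        assert d["c"].tolist() == [1]

    def test_two_variants_same_window(self):
        recs = [
            VariantRecord("c", 100, "A", ("G",)),
            VariantRecord("c", 200, "A", ("G",)),
        ]
        d = density_windows(recs, {"c": 2500}, 1000)
        assert d["c"].tolist() == [2, 0, 0]

    def test_hotspot_recovered(self):
        rng = np.random.default_rng(8)
        recs = [
            VariantRecord("c", int(p), "A", ("G",))
            for p in rng.integers(1, 50_000, size=100)
        ]
        recs += [VariantRecord("c", int(p), "A", ("G",)) for p in range(30_001, 30_040)]
        d = density_windows(recs, {"c": 50_000}, 1000)
        assert int(np.argmax(d["c"])) == 30
        assert d["c"].sum() == len(recs)


class TestVariantsPerCommonSite:
    def test_published_ratio(self):
        assert variants_per_common_site(2_026_509, 6_819) == 297

    def test_simple(self):
        assert variants_per_common_site(1000, 10) == 100

    def test_floor(self):
        assert variants_per_common_site(7, 2) == 3

    def test_zero_variants_rejected(self):
        with pytest.raises(ValueError):
            variants_per_common_site(1000, 0)


class TestMotifSummary:
    def test_partition_and_fractions(self):
        recs = (
            [SSRRecord("T", 10, 0, 10)] * 3
            + [SSRRecord("AT", 6, 0, 12)] * 5
            + [SSRRecord("ATG", 5, 0, 15, perfect=False)] * 2
        )
        summary = ssr_motif_summary(recs)
        assert summary["total"] == 10
        assert summary["by_motif_length"] == {1: 3, 2: 5, 3: 2}
        assert sum(summary["by_motif_length"].values()) == summary["total"]
        assert sum(summary["by_motif"].values()) == summary["total"]
        assert summary["perfect"] + summary["imperfect"] == summary["total"]
        assert summary["pct_by_motif_length"][2] == pytest.approx(50.0)
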