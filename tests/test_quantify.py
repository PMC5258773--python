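import numpy as np
import pandas as pd
import pytest

from ectoseq.models import fragments_frame
from ectoseq.quantify import (
    average_detection,
    classify_band,
    compute_fpkm,
    compute_tpm,
    count_detected,
    count_fragments,
    count_fragments_bruteforce,
    mean_expression,
    quantify,
)
from conftest import random_instance, single_exon_gene


class TestCountFragments:
    def test_contained_fragment_counts_once(self):
        gene = single_exon_gene(start=100, length=1000)
        frags = fragments_frame("s1", "chr1", [[(200, 400)]])
        counts, lib, _ = count_fragments(frags, [gene])
        assert counts.at["G1", "s1"] == 1
        assert lib["s1"] == 1

    def test_forty_percent_overlap_not_assigned(self):
        gene = single_exon_gene(start=120, length=1000)
        # 200 bp fragment with 80 bp exonic overlap (40%)
        frags = fragments_frame("s1", "chr1", [[(0, 200)]])
        counts, lib, _ = count_fragments(frags, [gene])
        assert counts.to_numpy().sum() == 0
        assert lib["s1"] == 0

    def test_exactly_half_overlap_is_assigned(self):
        gene = single_exon_gene(start=100, length=1000)
        frags = fragments_frame("s1", "chr1", [[(0, 200)]])
        counts, _, _ = count_fragments(frags, [gene])
        assert counts.at["G1", "s1"] == 1

    def test_greatest_overlap_wins_and_ties_drop(self):
        g1 = single_exon_gene("G1", start=0, length=300)
        g2 = single_exon_gene("G2", start=250, length=300)
        # 80% in G2, 53% in G1 -> greatest overlap wins
        frags = fragments_frame("s1", "chr1", [[(220, 370)]])
        counts, _, stats = count_fragments(frags, [g1, g2])
        assert counts.at["G2", "s1"] == 1 and counts.at["G1", "s1"] == 0
        # perfectly split fragment across adjacent genes -> dropped
        g3 = single_exon_gene("G3", start=300, length=300)
        tie = fragments_frame("s1", "chr1", [[(250, 350)]])
        counts, _, stats = count_fragments(tie, [g1, g3])
        assert counts.to_numpy().sum() == 0
        assert stats["n_ties_dropped"] == 1

    def test_unique_only_skips_multimappers(self):
        gene = single_exon_gene(start=100, length=1000)
        frags = fragments_frame(
            "s1", "chr1", [[(200, 400)], [(300, 500)]], [True, False]
        )
        counts, lib, _ = count_fragments(frags, [gene], unique_only=True)
        assert counts.at["G1", "s1"] == 1

    def test_unknown_chromosome_warns_and_skips(self):
        gene = single_exon_gene(start=100, length=1000)
        frags = fragments_frame("s1", ["chrZ"], [[(200, 400)]])
        with pytest.warns(UserWarning, match="absent"):
            counts, _, stats = count_fragments(frags, [gene])
        assert stats["n_skipped_unknown_chrom"] == 1
        assert counts.to_numpy().sum() == 0

    def test_counts_equal_simulator_draws_without_noise(self, noise_free_dataset):
        ds = noise_free_dataset
        counts, _, _ = count_fragments(ds.fragments, ds.genes)
        pd.testing.assert_frame_equal(
            counts, ds.drawn_counts.loc[counts.index, counts.columns]
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_on_random_instances(self, seed):
        """Vectorized counting matches the quadratic all-pairs scan,
        including overlapping genes and split fragments."""
        rng = np.random.default_rng(1000 + seed)
        for _ in range(6):
            genes, frags = random_instance(rng)
            if frags is None:
                continue
            fast, lib_fast, _ = count_fragments(frags, genes)
            slow, lib_slow = count_fragments_bruteforce(frags, genes)
            pd.testing.assert_frame_equal(fast, slow)
            pd.testing.assert_series_equal(lib_fast, lib_slow)


class TestFpkm:
    def test_worked_formula_examples(self):
        counts = pd.DataFrame({"s": [100, 0, 1]}, index=["a", "b", "c"])
        lengths = pd.Series({"a": 2000, "b": 500, "c": 1000})
        lib = pd.Series({"s": 10_000_000})
        fpkm = compute_fpkm(counts, lengths, lib)
        assert fpkm.at["a", "s"] == pytest.approx(5.0)
        assert fpkm.at["b", "s"] == 0.0
        lib1 = pd.Series({"s": 1_000_000})
        assert compute_fpkm(counts, lengths, lib1).at["c", "s"] == pytest.approx(1.0)

    def test_zero_library_is_an_error(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"a": 1000}), pd.Series({"s": 0}))

    def test_scale_invariance_under_count_doubling(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 2)), columns=["s1", "s2"]
        )
        lengths = pd.Series(rng.integers(200, 5000, size=30), index=counts.index)
        lib = counts.sum(axis=0)
        doubled = counts * 2
        f1 = compute_fpkm(counts, lengths, lib)
        f2 = compute_fpkm(doubled, lengths, doubled.sum(axis=0))
        pd.testing.assert_frame_equal(f1, f2)
        t1, t2 = compute_tpm(counts, lengths), compute_tpm(doubled, lengths)
        pd.testing.assert_frame_equal(t1, t2)

    def test_monotone_in_counts(self):
        lengths = pd.Series({"a": 1000, "b": 1000})
        lib = pd.Series({"s": 1_000_000})
        lo = pd.DataFrame({"s": [5, 7]}, index=["a", "b"])
        hi = pd.DataFrame({"s": [6, 7]}, index=["a", "b"])
        assert (
            compute_fpkm(hi, lengths, lib).at["a", "s"]
            > compute_fpkm(lo, lengths, lib).at["a", "s"]
        )
        assert (
            compute_tpm(hi, lengths).at["a", "s"] > compute_tpm(lo, lengths).at["a", "s"]
        )


class TestTpm:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        tpm = compute_tpm(counts, pd.Series({"a": 700, "b": 700}))
        assert tpm["s"].to_numpy() == pytest.approx([500000.0, 500000.0])

    def test_length_normalization_hand_computed(self):
        # counts (10,10,10), lengths (1,2,4) kb -> rates prop. (4,2,1)
        counts = pd.DataFrame({"s": [10, 10, 10]}, index=["a", "b", "c"])
        tpm = compute_tpm(counts, pd.Series({"a": 1000, "b": 2000, "c": 4000}))
        np.testing.assert_allclose(
            tpm["s"].to_numpy(),
            [1e6 * 4 / 7, 1e6 * 2 / 7, 1e6 * 1 / 7],
        )

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 100, size=(50, 4)))
        lengths = pd.Series(rng.integers(100, 9000, size=50), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_degenerate_sample_stays_zero_with_warning(self):
        counts = pd.DataFrame({"ok": [3], "empty": [0]}, index=["a"])
        with pytest.warns(UserWarning, match="empty"):
            tpm = compute_tpm(counts, pd.Series({"a": 1000}))
        assert tpm.at["a", "empty"] == 0.0


class TestSummaries:
    def test_mean_expression_examples(self):
        m = pd.DataFrame(
            {"r1": [16.0, 0.0], "r2": [21.0, 0.0], "r3": [17.0, 0.0]},
            index=["g1", "g2"],
        )
        mfpkm = mean_expression(m, ["r1", "r2", "r3"])
        assert mfpkm["g1"] == pytest.approx(18.0)
        assert mfpkm["g2"] == 0.0
        assert mean_expression(m, ["r2"])["g1"] == 21.0
        with pytest.raises(KeyError):
            mean_expression(m, ["nope"])
        with pytest.raises(ValueError):
            mean_expression(m, [])

    @pytest.mark.parametrize(
        "value,band",
        [
            (0.05, "absent"),
            (0.1, "weak"),
            (9.99, "weak"),
            (10.0, "moderate"),
            (99.9, "moderate"),
            (100.0, "high"),
            (2700.0, "high"),
        ],
    )
    def test_expression_bands(self, value, band):
        assert classify_band(value) == band

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            classify_band(-1.0)

    def test_count_detected_modes(self):
        fpkm = pd.DataFrame(
            {"s1": [0.5, 0.2, 0.0], "s2": [0.4, 0.31, 0.0]},
            index=["o1", "o2", "x"],
        )
        per = count_detected(fpkm, ["o1", "o2"], 0.3, "per_sample")
        assert per.tolist() == [1, 2]
        # o2's mean (0.255) falls below the threshold its s2 value meets
        assert count_detected(fpkm, ["o1", "o2"], 0.3, "mean") == 1
        assert count_detected(fpkm, ["o1", "o2"], 0.0, "mean") == 2
        with pytest.warns(UserWarning):
            assert count_detected(fpkm, ["absent_gene"], 0.3, "mean") == 0

    def test_reported_average_of_per_sample_counts(self):
        mean, reported = average_detection([13, 19, 11])
        assert mean == pytest.approx(14.333, abs=1e-3)
        assert reported == 14


class TestEndToEnd:
    def test_quantify_bundle_consistency(self, small_dataset):
        ds = small_dataset
        m = quantify(ds.fragments, ds.genes, unique_only=True)
        assert (m.counts.to_numpy() >= 0).all()
        assert (m.fpkm.to_numpy() >= 0).all()
        np.testing.assert_allclose(m.tpm.sum(axis=0), 1e6, rtol=1e-6)
        assert (m.library_size == m.counts.sum(axis=0)).all()
        assert set(m.gene_info["family"]) >= {"OR", "marker_retina", "other"}
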