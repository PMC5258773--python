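import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ectoseq.background import (
    IntergenicPlacementError,
    background_fraction,
    calibrate,
    evaluate_background,
    sample_intergenic_placements,
    select_cutoff,
)
from ectoseq.models import GeneModel, fragments_frame
from ectoseq.quantify import count_fragments
from conftest import single_exon_gene


@pytest.fixture
def sparse_annotation():
    return [
        GeneModel(
            "OR1", "OR1", "chr1", "+",
            [[(10_000, 10_400), (11_000, 11_600)]],
            family="OR",
        ),
        single_exon_gene("X1", "chr1", 50_000, 2_000),
    ]


CHROMS = {"chr1": 200_000}


class TestPlacements:
    def test_structure_preserved_and_disjoint(self, sparse_annotation):
        rng = np.random.default_rng(3)
        shifted = sample_intergenic_placements(
            sparse_annotation, "OR", CHROMS, rng
        )
        assert len(shifted) == 1
        s = shifted[0]
        assert [e - b for b, e in s.transcripts[0]] == [400, 600]
        # intron length preserved too
        assert s.transcripts[0][1][0] - s.transcripts[0][0][1] == 600
        orig_span = sparse_annotation[0].span
        assert s.span[1] <= orig_span[0] or s.span[0] >= orig_span[1]

    def test_fixed_seed_reproduces_placements(self, sparse_annotation):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            runs.append(
                [
                    g.transcripts
                    for g in sample_intergenic_placements(
                        sparse_annotation, "OR", CHROMS, rng
                    )
                ]
            )
        assert runs[0] == runs[1]

    def test_fully_annotated_genome_is_infeasible(self):
        genes = [single_exon_gene("G", "chr1", 0, 10_000, family="OR")]
        with pytest.raises(IntergenicPlacementError):
            sample_intergenic_placements(
                genes, "OR", {"chr1": 10_000}, np.random.default_rng(0)
            )

    def test_many_placements_never_overlap(self, default_dataset):
        ds = default_dataset
        rng = np.random.default_rng(17)
        shifted = sample_intergenic_placements(
            ds.genes, "OR", ds.chromosome_lengths, rng
        )
        assert len(shifted) == 20
        spans = [(g.chromosome,) + g.span for g in shifted] + [
            (g.chromosome,) + g.span for g in ds.genes
        ]
        spans.sort()
        for (c0, s0, e0), (c1, s1, e1) in zip(spans, spans[1:]):
            assert c0 != c1 or e0 <= s1


class TestEvaluateBackground:
    def test_no_noise_means_no_background(self, noise_free_dataset):
        ds = noise_free_dataset
        rng = np.random.default_rng(5)
        shifted = sample_intergenic_placements(
            ds.genes, "OR", ds.chromosome_lengths, rng
        )
        lib = pd.Series(
            {s: 1_000_000 for s in ds.fragments["sample_id"].unique()}
        )
        binned, fpkm = evaluate_background(
            ds.fragments, shifted, [(0.0, 0.1), (0.1, math.inf)], lib
        )
        assert binned.to_numpy().sum() == 0
        assert (fpkm.to_numpy() == 0).all()

    def test_binning_assigns_mass_to_containing_bin(self):
        gene = single_exon_gene("S1", "chr1", 10_000, 1_000, family="OR")
        # 2 fragments on a 1 kb model at library 1e7 -> FPKM 0.2
        frags = fragments_frame(
            "s1", "chr1", [[(10_100, 10_300)], [(10_500, 10_700)]]
        )
        binned, fpkm = evaluate_background(
            frags, [gene], [(0.1, 0.3), (0.3, math.inf)],
            pd.Series({"s1": 10_000_000}),
        )
        assert fpkm.at["S1", "s1"] == pytest.approx(0.2)
        assert binned.loc["(0.1,0.3]", "s1"] == 1
        assert binned.loc["(0.3,inf]", "s1"] == 0

    def test_background_counts_match_poisson_expectation(self, default_dataset):
        """Mean noise fragments captured by shifted models agree with
        the closed-form expectation rate * span within 3 SE."""
        ds = default_dataset
        rng = np.random.default_rng(23)
        shifted = sample_intergenic_placements(
            ds.genes, "OR", ds.chromosome_lengths, rng
        )
        # the expectation below covers diffuse noise only: shifted
        # models that happen to land in the unannotated-transcript
        # region are excluded from the comparison
        oc, os_, oe = ds.truth.overlap_region
        shifted = [
            g
            for g in shifted
            if g.chromosome != oc or g.span[1] <= os_ or g.span[0] >= oe
        ]
        counts, _, _ = count_fragments(ds.fragments, shifted)
        total = int(counts.to_numpy().sum())
        # a noise fragment of length fl is assigned when >= fl/2 of it
        # overlaps the exon union; for a single-exon model of length L
        # that is ~L+1 valid starts, at rate*1e-3 starts per bp
        rate = ds.config.intergenic_noise_rate / 1e3
        n_samples = ds.config.n_samples
        expected = 0.0
        for g in shifted:
            for s, e in g.exon_union:
                expected += rate * (e - s + 1) * n_samples
        assert abs(total - expected) <= 3 * math.sqrt(expected)


class TestCutoffSelection:
    def test_printed_background_profile_selects_upper_candidate(self):
        # mean background 1.3 above the lower candidate, none above the
        # upper one -> the upper candidate is the detection cutoff
        assert select_cutoff([21.7, 21.7], [1.3, 0.0], [0.1, 0.3]) == 0.3

    def test_clean_background_keeps_lowest_candidate(self):
        assert select_cutoff([10, 8], [0.0, 0.0], [0.1, 0.3]) == 0.1

    def test_persistent_background_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="largest candidate"):
            assert select_cutoff([10, 8], [2.0, 1.0], [0.1, 0.3]) == 0.3

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            select_cutoff([], [], [])

    def test_background_fraction_examples(self):
        assert round(background_fraction(21.7, 1.3)) == 6
        assert background_fraction(21.7, 1.3) == pytest.approx(5.9907, abs=1e-3)
        assert background_fraction(5.0, 0.0) == 0.0
        assert background_fraction(10.0, 10.0) == 100.0
        with pytest.warns(UserWarning):
            assert math.isnan(background_fraction(0.0, 1.0))


class TestCalibrate:
    def test_full_calibration_on_synthetic_data(self, default_dataset):
        ds = default_dataset
        cal = calibrate(
            ds.fragments,
            ds.genes,
            ds.chromosome_lengths,
            n_replicates=2,
            seed=101,
            unique_only=True,
        )
        assert cal.selected_cutoff in (0.1, 0.3)
        # monotone: background above t never increases with t
        above = cal.background_above.to_numpy()
        assert (np.diff(above) <= 1e-12).all()
        # at the selected cutoff every truly expressed family gene is
        # detected and nothing else is
        detected = (
            cal.family_fpkm.mean(axis=1) >= cal.selected_cutoff
        )
        assert set(detected.index[detected]) == set(ds.truth.expressed_or_genes)

    def test_calibrate_warns_when_background_persists(self, default_dataset):
        ds = default_dataset
        with pytest.warns(UserWarning, match="largest candidate"):
            calibrate(
                ds.fragments,
                ds.genes,
                ds.chromosome_lengths,
                n_replicates=1,
                seed=7,
                unique_only=True,
            )
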