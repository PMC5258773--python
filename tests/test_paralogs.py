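import numpy as np
import pandas as pd
import pytest

from ectoseq.models import fragments_frame
from ectoseq.paralogs import (
    analyze_paralog_pair,
    call_expressed_paralog,
    coverage_uniformity,
    discriminative_positions,
    orf_positions_to_genomic,
)
from conftest import single_exon_gene


class TestDiscriminativePositions:
    def test_identical_sequences(self):
        a, b, identity = discriminative_positions("ACGTACGT", "ACGTACGT")
        assert identity == 1.0
        assert len(a) == 0 and len(b) == 0

    def test_five_differences_in_hundred(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, 100))
        other = list(seq)
        for p in (3, 20, 41, 77, 96):
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        a, b, identity = discriminative_positions(seq, "".join(other))
        assert identity == pytest.approx(0.95)
        assert list(a) == [3, 20, 41, 77, 96]
        assert list(b) == [3, 20, 41, 77, 96]

    def test_every_twentieth_base_substituted(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 960))
        other = list(seq)
        for p in range(0, 960, 20):
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        a, _, identity = discriminative_positions(seq, "".join(other))
        assert len(a) == 48
        assert identity == pytest.approx(1 - 48 / 960)

    def test_unequal_lengths_instruct_prealignment(self):
        with pytest.raises(ValueError, match="align"):
            discriminative_positions("ACGT", "ACG")

    def test_non_nucleotide_alphabet_rejected(self):
        with pytest.raises(ValueError):
            discriminative_positions("ACGN", "ACGT")


class TestOrfMapping:
    def test_plus_and_minus_strand_mapping(self):
        plus = single_exon_gene("P", start=1000, length=100, strand="+")
        minus = single_exon_gene("M", start=1000, length=100, strand="-")
        pos = np.array([0, 10])
        assert list(orf_positions_to_genomic(plus, pos)) == [1000, 1010]
        assert list(orf_positions_to_genomic(minus, pos)) == [1089, 1099]


class TestParalogCall:
    def make_pair(self):
        a = single_exon_gene("A", "chr1", 1000, 100)
        b = single_exon_gene("B", "chr1", 9000, 100)
        spec_a = np.arange(1000, 1100, 10)
        spec_b = np.arange(9000, 9100, 10)
        return a, b, spec_a, spec_b

    def frags_at(self, positions, n_each=1):
        blocks = [[(p, p + 50)] for p in positions for _ in range(n_each)]
        return fragments_frame("s1", "chr1", blocks)

    def test_zero_fragments_is_neither(self):
        a, b, sa, sb = self.make_pair()
        empty = fragments_frame("s1", "chr1", [])
        call = call_expressed_paralog(empty, a, b, sa, sb)
        assert call.call == "neither"

    def test_supported_member_is_called(self):
        a, b, sa, sb = self.make_pair()
        call = call_expressed_paralog(self.frags_at([1000] * 6), a, b, sa, sb)
        assert call.call == "A"
        swapped = call_expressed_paralog(self.frags_at([1000] * 6), b, a, sb, sa)
        assert swapped.call == "B"

    def test_six_vs_four_support_is_ambiguous(self):
        a, b, sa, sb = self.make_pair()
        frags = pd.concat(
            [self.frags_at([1000] * 6), self.frags_at([9000] * 4)],
            ignore_index=True,
        )
        call = call_expressed_paralog(frags, a, b, sa, sb)
        assert (call.unique_fragments_a, call.unique_fragments_b) == (6, 4)
        assert call.call == "ambiguous"

    def test_both_supported(self):
        a, b, sa, sb = self.make_pair()
        frags = pd.concat(
            [self.frags_at([1000] * 5), self.frags_at([9000] * 5)],
            ignore_index=True,
        )
        assert call_expressed_paralog(frags, a, b, sa, sb).call == "both"

    def test_no_discriminative_positions_is_ambiguous(self):
        a, b, *_ = self.make_pair()
        with pytest.warns(UserWarning, match="ambiguous"):
            call = call_expressed_paralog(
                self.frags_at([1000] * 9), a, b, np.array([]), np.array([])
            )
        assert call.call == "ambiguous"

    def test_fragments_on_identical_segments_never_change_the_call(self):
        a, b, sa, sb = self.make_pair()
        base = self.frags_at([1000] * 6)
        call0 = call_expressed_paralog(base, a, b, sa, sb)
        # fragments that avoid every discriminative position (between
        # 9001 and 9009 there is no specific site, 8-bp blocks)
        blocks = [[(9001, 9009)] for _ in range(50)]
        extra = fragments_frame("s1", "chr1", blocks)
        call1 = call_expressed_paralog(
            pd.concat([base, extra], ignore_index=True), a, b, sa, sb
        )
        assert call0.call == call1.call == "A"
        assert call1.unique_fragments_b == 0

    def test_multimapping_fragments_are_ignored(self):
        a, b, sa, sb = self.make_pair()
        blocks = [[(1000, 1050)] for _ in range(9)]
        frags = fragments_frame("s1", "chr1", blocks, [False] * 9)
        assert call_expressed_paralog(frags, a, b, sa, sb).call == "neither"

    def test_simulated_pair_resolves_to_truth(self, noise_free_dataset):
        from Bio.Seq import Seq

        ds = noise_free_dataset
        by_id = {g.gene_id: g for g in ds.genes}
        ga, gb = (by_id[g] for g in ds.truth.paralog_pair)

        def orf(g):
            s = ds.genome[g.chromosome][g.cds[0]:g.cds[1]]
            return s if g.strand == "+" else str(Seq(s).reverse_complement())

        call = analyze_paralog_pair(ds.fragments, ga, gb, orf(ga), orf(gb))
        assert call.identity == pytest.approx(0.95, abs=2e-3)
        assert call.call == "A"
        assert call.unique_fragments_b == 0


class TestCoverageUniformity:
    def test_orf_only_fragments_not_flagged(self):
        g = single_exon_gene("G", "chr1", 10_000, 1000)
        frags = fragments_frame(
            "s1", "chr1", [[(10_000 + 50 * i, 10_000 + 50 * i + 100)] for i in range(15)]
        )
        f = coverage_uniformity(frags, g, flank_bp=1000)
        assert f.enrichment > 2
        assert not f.flagged_uniform

    def test_uniform_coverage_is_flagged(self):
        g = single_exon_gene("G", "chr1", 10_000, 1000)
        blocks = [[(9_000 + 100 * i, 9_000 + 100 * i + 100)] for i in range(30)]
        f = coverage_uniformity(
            fragments_frame("s1", "chr1", blocks), g, flank_bp=1000
        )
        assert f.enrichment == pytest.approx(1.0, abs=0.2)
        assert f.flagged_uniform

    def test_simulated_overlap_gene_flagged_twin_not(self, default_dataset):
        ds = default_dataset
        by_id = {g.gene_id: g for g in ds.genes}
        over = coverage_uniformity(
            ds.fragments, by_id[ds.truth.overlap_gene],
            chromosome_length=ds.chromosome_lengths[
                by_id[ds.truth.overlap_gene].chromosome
            ],
        )
        twin = coverage_uniformity(
            ds.fragments, by_id[ds.truth.overlap_twin],
            chromosome_length=ds.chromosome_lengths[
                by_id[ds.truth.overlap_twin].chromosome
            ],
        )
        assert over.flagged_uniform
        assert not twin.flagged_uniform

    def test_enrichment_stable_under_downsampling(self, default_dataset):
        """Enrichment is a ratio of mean coverages, so uniform 50%
        down-sampling preserves it in expectation (within 3 SE)."""
        ds = default_dataset
        by_id = {g.gene_id: g for g in ds.genes}
        g = by_id[ds.truth.overlap_gene]
        rng = np.random.default_rng(8)
        keep = rng.random(len(ds.fragments)) < 0.5
        full = coverage_uniformity(ds.fragments, g)
        half = coverage_uniformity(ds.fragments[keep], g)

        # 3-SE band from the Poisson fragment counts underlying the
        # sparser (half-sampled) windows
        def n_overlapping(frags, lo, hi):
            sub = frags[
                (frags["chromosome"] == g.chromosome)
                & (frags["end"] > lo)
                & (frags["start"] < hi)
            ]
            return max(1, len(sub))

        span = g.span
        n_orf = n_overlapping(ds.fragments[keep], span[0], span[1])
        n_flank = n_overlapping(
            ds.fragments[keep], span[0] - 5000, span[0]
        ) + n_overlapping(ds.fragments[keep], span[1], span[1] + 5000)
        rel_tol = 3 * np.sqrt(1 / n_orf + 1 / n_flank)
        assert half.enrichment == pytest.approx(full.enrichment, rel=rel_tol)
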