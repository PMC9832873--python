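"""Transcript geometry: coordinate maps, five-segment partition, peak
localization and metagene density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polym6a.geometry import (
    DEFAULT_BINS,
    SEGMENTS,
    AnnotationError,
    Peak,
    TranscriptModel,
    assign_peak,
    five_segments,
    load_annotation,
    metagene_peak_density,
    relative_enrichment,
    segment_density_mass,
)

from conftest import GFF_SINGLE_MINUS, GFF_SINGLE_PLUS, GFF_TWO_ISOFORMS


def make_tx(L=1000, cds=(200, 800), strand="+", exons=None, chrom="chr1"):
    exons = exons or [(0, L)]
    return TranscriptModel("g", "g.1", chrom, strand, exons, cds[0], cds[1])


class TestLoadAnnotation:
    def test_plus_strand_coordinates(self, gff_file):
        txs = load_annotation(gff_file(GFF_SINGLE_PLUS))
        tx = txs["g1"]
        assert tx.mature_length == 1000
        assert tx.cds_transcript_interval == (200, 800)

    def test_minus_strand_position_zero_is_genomic_end(self, gff_file):
        txs = load_annotation(gff_file(GFF_SINGLE_MINUS))
        tx = txs["g1"]
        assert tx.transcript_to_genomic(0) == 999
        assert tx.genomic_to_transcript(999) == 0
        # CDS genomic 200..800 maps to transcript [200, 800) after the flip
        assert tx.cds_transcript_interval == (200, 800)

    def test_longest_cds_isoform_selected(self, gff_file):
        txs = load_annotation(gff_file(GFF_TWO_ISOFORMS))
        assert txs["g1"].transcript_id == "g1.b"

    def test_gene_without_cds_skipped_with_warning(self, gff_file):
        text = GFF_SINGLE_PLUS.replace("chr1\tsim\tCDS\t201\t800\t.\t+\t0\tParent=g1.1\n", "")
        with pytest.warns(UserWarning, match="no mRNA with CDS"):
            txs = load_annotation(gff_file(text))
        assert txs == {}


class TestCoordinateMaps:
    def test_spliced_roundtrip(self):
        tx = make_tx(L=300, cds=(50, 350), exons=[(0, 100), (200, 300), (400, 500)])
        for t in range(tx.mature_length):
            assert tx.genomic_to_transcript(tx.transcript_to_genomic(t)) == t

    def test_minus_strand_roundtrip(self):
        tx = make_tx(L=300, cds=(210, 480), strand="-",
                     exons=[(0, 100), (200, 300), (400, 500)])
        assert tx.transcript_to_genomic(0) == 499
        for t in range(tx.mature_length):
            assert tx.genomic_to_transcript(tx.transcript_to_genomic(t)) == t

    def test_intronic_position_rejected(self):
        tx = make_tx(exons=[(0, 100), (200, 300)], cds=(10, 290))
        with pytest.raises(AnnotationError):
            tx.genomic_to_transcript(150)


class TestFiveSegments:
    def test_reference_partition(self):
        # CDS 201-800 1-based: start codon at 200, stop codon at 797
        sm = five_segments(make_tx())
        assert sm.intervals == {
            "5UTR": (0, 100), "startC": (100, 300), "CDS": (300, 697),
            "stopC": (697, 897), "3UTR": (897, 1000),
        }

    def test_short_utr_clips_startc(self):
        sm = five_segments(make_tx(cds=(50, 650)))
        assert sm.intervals["5UTR"] == (0, 0)
        assert sm.intervals["startC"] == (0, 150)

    def test_stopc_wins_over_startc_in_short_cds(self):
        # CDS of 60 nt: startC and stopC windows overlap
        sm = five_segments(make_tx(L=600, cds=(250, 310)))
        a, b, c, d = sm.bounds
        assert c == 207  # stop codon first base 307, minus 100
        assert b <= c and sm.intervals["CDS"] == (b, c)
        assert sum(sm.lengths.values()) == 600

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(L=st.integers(300, 5000), data=st.data())
    def test_partition_sums_and_disjoint(self, L, data):
        cds_len = data.draw(st.integers(1, max(1, (L - 2) // 3))) * 3
        s = data.draw(st.integers(0, L - cds_len))
        sm = five_segments(make_tx(L=L, cds=(s, s + cds_len)))
        ivals = list(sm.intervals.values())
        assert sum(e - b for b, e in ivals) == L
        for (b1, e1), (b2, e2) in zip(ivals, ivals[1:]):
            assert e1 == b2  # contiguous, hence disjoint

    def test_strand_symmetry(self):
        plus = five_segments(make_tx())
        minus = five_segments(make_tx(strand="-"))
        assert plus.bounds == minus.bounds


class TestAssignPeak:
    def make_peak(self, summit):
        return Peak("g", "chr1", 0, 1, summit, summit + 1, summit, 1.0, 0.5)

    def test_summit_containment(self):
        sm = five_segments(make_tx())
        assert assign_peak(self.make_peak(750), sm) == "stopC"
        assert assign_peak(self.make_peak(0), sm) == "5UTR"
        assert assign_peak(self.make_peak(999), sm) == "3UTR"

    def test_summit_outside_transcript_errors(self):
        sm = five_segments(make_tx())
        with pytest.raises(AnnotationError):
            assign_peak(self.make_peak(1000), sm)

    def test_uniform_summits_match_length_fractions(self, rng):
        tx = make_tx()
        sm = five_segments(tx)
        n = 10_000
        summits = rng.integers(0, 1000, size=n)
        counts = {seg: 0 for seg in SEGMENTS}
        for s in summits:
            counts[sm.segment_of(int(s))] += 1
        # multinomial 99% CI per segment
        for seg, ln in sm.lengths.items():
            p = ln / 1000
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[seg] / n - p) < 2.58 * se + 1e-9


class TestRelativeEnrichment:
    def test_all_summits_in_stopc(self):
        # stopC is exactly 20% of a 1000-nt transcript
        tx = make_tx(L=1000, cds=(150, 753))
        sm = five_segments(tx)
        assert sm.lengths["stopC"] == 200
        peaks = [Peak("g", "chr1", 0, 1, 700, 701, 700, 1.0, 0.5) for _ in range(10)]
        tab = relative_enrichment(peaks, {"g": sm})
        assert tab.loc["stopC", "enrichment"] == pytest.approx(5.0)
        for seg in ("5UTR", "startC", "CDS", "3UTR"):
            assert tab.loc[seg, "enrichment"] == 0.0

    def test_zero_length_segment_reported_missing(self):
        tx = make_tx(cds=(50, 950))  # no room for UTRs after clipping
        sm = five_segments(tx)
        assert sm.lengths["5UTR"] == 0
        peaks = [Peak("g", "chr1", 0, 1, 500, 501, 500, 1.0, 0.5)]
        tab = relative_enrichment(peaks, {"g": sm})
        assert np.isnan(tab.loc["5UTR", "enrichment"])

    def test_uniform_summits_give_unit_scores(self, rng):
        tx = make_tx()
        sm = five_segments(tx)
        peaks = [Peak("g", "chr1", 0, 1, int(s), int(s) + 1, int(s), 1.0, 0.5)
                 for s in rng.integers(0, 1000, size=5000)]
        tab = relative_enrichment(peaks, {"g": sm})
        for seg in SEGMENTS:
            p = sm.lengths[seg] / 1000
            se = np.sqrt(p * (1 - p) / 5000)
            assert abs(tab.loc[seg, "peak_fraction"] - p) < 2.58 * se + 1e-9


class TestMetagene:
    def test_profile_sums_to_one_and_concentrates(self):
        tx = make_tx()
        sm = five_segments(tx)
        center = (697 + 897) // 2
        peaks = [Peak("g", "chr1", 0, 1, center, center + 1, center, 1.0, 0.5)
                 for _ in range(7)]
        prof = metagene_peak_density(peaks, {"g": sm})
        assert prof.sum() == pytest.approx(1.0)
        assert segment_density_mass(prof)["stopC"] == pytest.approx(1.0)

    def test_no_peaks_warns_zero_vector(self):
        with pytest.warns(UserWarning, match="no peaks"):
            prof = metagene_peak_density([], {})
        assert prof.sum() == 0
        assert prof.size == sum(DEFAULT_BINS)
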