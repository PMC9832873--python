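"""Signal profiling: anchored windows, scaled gene bodies, weighted
methylation levels."""

import numpy as np
import pandas as pd
import pytest

from polym6a.geometry import TranscriptModel
from polym6a.profiles import (
    methylation_profile,
    profile_around_points,
    scaled_gene_profile,
)
from polym6a.tracks import SignalTrack


def const_track(value=2.0, size=20_000):
    return SignalTrack({"chr1": np.full(size, value)})


class TestAnchoredProfile:
    def test_constant_track_gives_constant_profile(self):
        prof = profile_around_points(const_track(), [("chr1", 5000, "+")],
                                     flank=1000, n_bins=40)
        assert np.allclose(prof.values, 2.0)

    def test_step_indicator_splits_halves(self):
        arr = np.zeros(20_000)
        arr[5000:6000] = 1.0  # indicator of [anchor, anchor+flank)
        prof = profile_around_points(SignalTrack({"chr1": arr}),
                                     [("chr1", 5000, "+")], flank=1000, n_bins=10)
        assert np.allclose(prof.values[:5], 0.0)
        assert np.allclose(prof.values[5:], 1.0)

    def test_minus_strand_flips_window(self):
        arr = np.zeros(20_000)
        arr[5000:6000] = 1.0
        prof = profile_around_points(SignalTrack({"chr1": arr}),
                                     [("chr1", 5000, "-")], flank=1000, n_bins=10)
        assert np.allclose(prof.values[:5], 1.0)
        assert np.allclose(prof.values[5:], 0.0)

    def test_truncated_window_weighted_not_zero_filled(self):
        prof = profile_around_points(const_track(3.0), [("chr1", 100, "+")],
                                     flank=1000, n_bins=10)
        # left bins fall entirely off-chromosome -> missing, not 0
        assert np.isnan(prof.values[0])
        assert prof.values[-1] == pytest.approx(3.0)

    def test_mass_conservation(self, rng):
        arr = rng.poisson(5, size=20_000).astype(float)
        track = SignalTrack({"chr1": arr})
        prof = profile_around_points(track, [("chr1", 10_000, "+")],
                                     flank=1000, n_bins=40)
        # equal-width bins: mean of bin means equals the window mean
        assert np.mean(prof.values) == pytest.approx(arr[9000:11000].mean())

    def test_planted_gaussian_bump_located(self, rng):
        arr = np.full(40_000, 0.5)
        xs = np.arange(40_000)
        anchors = [("chr1", int(c), "+") for c in (8000, 20_000, 31_000)]
        for c, _, _ in []:
            pass
        for c in (8000, 20_000, 31_000):
            arr += 3.0 * np.exp(-((xs - c) ** 2) / (2 * 150.0**2))
        arr += rng.normal(0, 0.05, size=arr.size)
        prof = profile_around_points(SignalTrack({"chr1": arr}), anchors,
                                     flank=2000, n_bins=100)
        center_bin = int(np.nanargmax(prof.values))
        assert abs(center_bin - 50) <= 1


class TestScaledGeneProfile:
    def make_txs(self):
        return {
            "g1": TranscriptModel("g1", "g1.1", "chr1", "+", [(5000, 7000)], 5300, 6500),
            "g2": TranscriptModel("g2", "g2.1", "chr1", "-", [(10_000, 13_000)],
                                  10_300, 12_400),
        }

    def test_constant_track_flat_all_strata(self):
        profs = scaled_gene_profile(const_track(1.5), self.make_txs(),
                                    strata=pd.Series({"g1": "x", "g2": "y"}))
        for p in profs.values():
            assert np.allclose(p.values[np.isfinite(p.values)], 1.5)

    def test_class_specific_tss_amplitude_detected(self):
        from polym6a.simulate import SimConfig, simulate_all
        from polym6a.profiles import scaled_gene_profile as sgp

        cfg = SimConfig(seed=13, n_genes=40,
                        h3k4me3_amp_by_class={"singleton": 5.0, "duplicate": 1.0})
        ds = simulate_all(cfg)
        profs = sgp(ds.epimark_tracks["H3K4me3"], ds.annotation.transcripts,
                    strata=ds.truth.genes["duplication_status"], flank=2000,
                    flank_bins=50, body_bins=100)
        tss_bin = 50  # first body bin
        assert profs["singleton"].values[tss_bin] > profs["duplicate"].values[tss_bin]

    def test_strand_reversal_leaves_profiles_unchanged(self):
        arr = np.zeros(20_000)
        arr[5000:5300] = 2.0  # fixed feature at the 5' end of g1 (+)
        track = SignalTrack({"chr1": arr})
        txs = self.make_txs()
        profs = scaled_gene_profile(track, {"g1": txs["g1"]})
        # mirrored gene on the minus strand with the feature at its 5' end
        arr2 = np.zeros(20_000)
        arr2[6700:7000] = 2.0
        flipped = TranscriptModel("g1", "g1.1", "chr1", "-", [(5000, 7000)], 5500, 6700)
        profs2 = scaled_gene_profile(SignalTrack({"chr1": arr2}), {"g1": flipped})
        assert np.allclose(profs["all"].values, profs2["all"].values, equal_nan=True)


def test_plot_profiles_writes_image(tmp_path):
    from polym6a.profiles import plot_profiles

    prof = profile_around_points(const_track(), [("chr1", 5000, "+")],
                                 flank=1000, n_bins=20)
    out = tmp_path / "profile.png"
    plot_profiles([prof], str(out))
    assert out.stat().st_size > 0


class TestMethylationProfile:
    def cx(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                           "count_methylated", "count_unmethylated"])

    def test_uniform_half_methylation(self):
        rows = [("chr1", p, "+", "CG", 5, 5) for p in range(1, 4002, 10)]
        prof = methylation_profile(self.cx(rows), [("chr1", 2000, "+")], "CG",
                                   flank=1000, n_bins=10)
        assert np.allclose(prof.values, 0.5)

    def test_context_filter_excludes_other_rows(self):
        rows = [("chr1", p, "+", "CG", 10, 0) for p in range(1, 4002, 20)]
        rows += [("chr1", p + 5, "+", "CHH", 0, 10) for p in range(1, 4002, 20)]
        prof = methylation_profile(self.cx(rows), [("chr1", 2000, "+")], "CHH",
                                   flank=1000, n_bins=5)
        assert np.allclose(prof.values, 0.0)

    def test_split_rows_invariance(self):
        rows_once = [("chr1", p, "+", "CG", 6, 4) for p in range(1, 4002, 10)]
        rows_split = [("chr1", p, "+", "CG", 3, 2) for p in range(1, 4002, 10)] * 2
        a = methylation_profile(self.cx(rows_once), [("chr1", 2000, "+")], "CG",
                                flank=1000, n_bins=8)
        b = methylation_profile(self.cx(rows_split), [("chr1", 2000, "+")], "CG",
                                flank=1000, n_bins=8)
        assert np.allclose(a.values, b.values)

    def test_empty_bins_missing(self):
        rows = [("chr1", 2100, "+", "CG", 5, 5)]
        prof = methylation_profile(self.cx(rows), [("chr1", 2000, "+")], "CG",
                                   flank=1000, n_bins=10)
        assert np.isfinite(prof.values).sum() == 1

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError, match="context"):
            methylation_profile(self.cx([]), [("chr1", 100, "+")], "CpG")
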