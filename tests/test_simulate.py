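"""Synthetic-data generator: determinism, configured proportions,
ground-truth consistency and controlled divergence."""

import numpy as np
import pytest
from scipy import stats as sps

from polym6a.evolution import STOP_CODONS, ng86_kaks
from polym6a.geometry import load_annotation
from polym6a.simulate import (
    ConfigError,
    SimConfig,
    generate_ground_truth,
    simulate_annotation,
    simulate_cds_pairs,
    simulate_epimarks,
    simulate_expression,
    simulate_merip,
)


class TestConfigValidation:
    def test_bad_segment_probs_rejected(self):
        with pytest.raises(ConfigError, match="segment_probs"):
            SimConfig(segment_probs=(0.3, 0.3, 0.3, 0.3, 0.3))

    def test_bad_enrichment_and_dispersion_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(ip_enrichment=0.5)
        with pytest.raises(ConfigError):
            SimConfig(nb_dispersion=0.0)

    def test_ks_target_range_enforced(self):
        with pytest.raises(ConfigError):
            SimConfig(ks_target=1.5)


class TestDeterminism:
    def test_identical_config_identical_gff_bytes(self):
        a = simulate_annotation(SimConfig(seed=1, n_genes=50))
        b = simulate_annotation(SimConfig(seed=1, n_genes=50))
        assert a.gff3 == b.gff3
        assert a.transcript_fasta == b.transcript_fasta

    def test_identical_config_identical_tracks_and_counts(self, tmp_path):
        outputs = []
        for _ in range(2):
            cfg = SimConfig(seed=4, n_genes=12)
            ann = simulate_annotation(cfg)
            truth = generate_ground_truth(cfg, ann)
            merip = simulate_merip(cfg, truth, ann)
            ip, _ = merip[("A", 1)]
            p = tmp_path / "t.bedgraph"
            ip.to_bedgraph(p)
            counts = simulate_expression(cfg, truth)
            outputs.append((p.read_bytes(), counts.to_csv()))
        assert outputs[0] == outputs[1]


class TestAnnotation:
    def test_gff3_roundtrips_through_parser(self, tmp_path):
        ann = simulate_annotation(SimConfig(seed=2, n_genes=15))
        p = tmp_path / "ann.gff3"
        p.write_text(ann.gff3)
        loaded = load_annotation(str(p))
        assert set(loaded) == set(ann.transcripts)
        for gid, tx in loaded.items():
            ref = ann.transcripts[gid]
            assert tx.exons == ref.exons
            assert tx.mature_length == ref.mature_length
            assert tx.cds_transcript_interval == ref.cds_transcript_interval
            cds_len = tx.cds_transcript_interval[1] - tx.cds_transcript_interval[0]
            assert cds_len % 3 == 0

    def test_degenerate_dup_props_all_wgd(self):
        ann = simulate_annotation(SimConfig(seed=3, n_genes=30,
                                            dup_type_props=(1, 0, 0, 0, 0)))
        dups = ann.genes[ann.genes["duplication_status"] == "duplicate"]
        assert (dups["dup_type"] == "WGD").all()

    def test_singleton_fraction_within_binomial_ci(self):
        cfg = SimConfig(seed=7, n_genes=2000, singleton_prop=0.087)
        ann = simulate_annotation(cfg)
        frac = (ann.genes["duplication_status"] == "singleton").mean()
        n = len(ann.genes)
        # 99% binomial CI, plus the odd-leftover-per-subgenome correction
        half = 2.58 * np.sqrt(0.087 * (1 - 0.087) / n)
        assert abs(frac - 0.087) < half + 2 / n

    def test_minimum_size_enforced(self):
        with pytest.raises(ConfigError):
            simulate_annotation(SimConfig(n_genes=5))


class TestGroundTruth:
    def test_consistency_checks_pass(self, small_dataset):
        # planted peaks inside transcripts; peak implies m6A status
        small_dataset.truth.validate(small_dataset.annotation.transcripts)

    def test_m6a_gene_owns_at_least_one_peak(self, small_dataset):
        truth = small_dataset.truth
        for geno in small_dataset.config.genotypes:
            with_peak = set(truth.peaks.loc[truth.peaks["genotype"] == geno, "gene_id"])
            m6a = {g for g in truth.status.index if truth.status.at[g, geno] is True}
            assert m6a == with_peak

    def test_pair_members_share_subgenome(self, small_dataset):
        genes = small_dataset.truth.genes
        for row in small_dataset.truth.pairs.itertuples():
            assert genes.at[row.gene1, "subgenome"] == genes.at[row.gene2, "subgenome"]


class TestMerip:
    def test_unit_enrichment_makes_ip_input_exchangeable(self):
        # under ip_enrichment=1 the IP and input tracks are draws from the
        # same per-base Poisson law: the KS test should accept at alpha=0.01
        # in at least 95% of seeds
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, n_genes=10, ip_enrichment=1.0,
                            n_replicates=1)
            ann = simulate_annotation(cfg)
            truth = generate_ground_truth(cfg, ann)
            merip = simulate_merip(cfg, truth, ann)
            ip, inp = merip[("A", 1)]
            tx = next(t for t in ann.transcripts.values() if t.chrom == "chrA")
            s, e = tx.span
            p = sps.ks_2samp(ip.data["chrA"][s:e], inp.data["chrA"][s:e]).pvalue
            ok += p > 0.01
        assert ok >= 0.95 * n_seeds

    def test_no_peak_gene_has_unit_ratio(self, small_dataset):
        ds = small_dataset
        truth, ann = ds.truth, ds.annotation
        geno = "A"
        quiet = [g for g in truth.status.index
                 if truth.status.at[g, geno] is False]
        ip = np.zeros(0)
        inp = np.zeros(0)
        for rep in (1, 2, 3):
            t_ip, t_in = ds.merip[(geno, rep)]
            for g in quiet:
                s, e = ann.transcripts[g].span
                ip = np.concatenate([ip, t_ip.data["chrA"][s:e]])
                inp = np.concatenate([inp, t_in.data["chrA"][s:e]])
        assert ip.sum() / inp.sum() == pytest.approx(1.0, abs=0.02)

    def test_unknown_gene_in_truth_rejected(self, small_dataset):
        cfg = small_dataset.config
        bad_truth = small_dataset.truth
        peaks = bad_truth.peaks.copy()
        peaks.loc[len(peaks)] = {"gene_id": "ghost", "genotype": "A",
                                 "tx_start": 0, "tx_end": 10, "summit": 5,
                                 "segment": "stopC", "width": 10}
        bad = type(bad_truth)(bad_truth.genes, bad_truth.status, peaks,
                              bad_truth.expr, bad_truth.pairs)
        with pytest.raises(KeyError, match="ghost"):
            simulate_merip(cfg, bad, small_dataset.annotation)


class TestExpressionCounts:
    def test_tiny_dispersion_approaches_poisson(self):
        cfg = SimConfig(seed=6, n_genes=400, nb_dispersion=1e-6)
        ann = simulate_annotation(cfg)
        truth = generate_ground_truth(cfg, ann)
        counts = simulate_expression(cfg, truth)
        cols = [f"NAC_rep{r}" for r in (1, 2, 3)]
        sub = counts[cols]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        keep = mean > 50
        ratio = (var[keep] / mean[keep]).mean()
        assert 0.9 < ratio < 1.1

    def test_null_genes_have_near_zero_log2fc(self):
        cfg = SimConfig(seed=8, n_genes=200, de_gene_prob=0.0)
        ann = simulate_annotation(cfg)
        truth = generate_ground_truth(cfg, ann)
        counts = simulate_expression(cfg, truth)
        a = counts[[f"RAC_rep{r}" for r in (1, 2, 3)]].mean(axis=1)
        b = counts[[f"NAC_rep{r}" for r in (1, 2, 3)]].mean(axis=1)
        keep = (a > 20) & (b > 20)
        lfc = np.log2(b[keep] / a[keep])
        assert abs(np.median(lfc)) < 0.1


class TestEpimarks:
    def test_zero_amplitude_gives_flat_active_marks(self, small_dataset):
        cfg = SimConfig(seed=11, n_genes=40, h3k4me3_tss_amp=0.0,
                        h3k27ac_tss_amp=0.0, peak_mark_amp=0.0)
        tracks, _ = simulate_epimarks(cfg, small_dataset.truth,
                                      small_dataset.annotation)
        assert np.allclose(tracks["H3K4me3"].data["chrA"], 0.2)
        assert np.allclose(tracks["H3K27ac"].data["chrC"], 0.2)

    def test_cx_counts_are_consistent(self, small_dataset):
        cx = small_dataset.cx_report
        assert (cx["count_methylated"] >= 0).all()
        assert (cx["count_unmethylated"] >= 0).all()
        assert (cx["count_methylated"] <=
                cx["count_methylated"] + cx["count_unmethylated"]).all()
        assert set(cx["context"]) <= {"CG", "CHG", "CHH"}


class TestCdsPairs:
    def test_identical_mode_gives_zero_rates(self, small_dataset):
        table, records = simulate_cds_pairs(small_dataset.config,
                                            small_dataset.truth, identical=True)
        pid = table.index[0]
        r = ng86_kaks(records[f"{pid}|1"], records[f"{pid}|2"])
        assert r.Ka == 0 and r.Ks == 0

    def test_omega_zero_target_plants_no_nonsynonymous_changes(self, small_dataset):
        cfg = SimConfig(seed=11, n_genes=40,
                        omega_by_class={c: 0.0 for c in
                                        ("singleton", "duplicate", "IM", "DM", "NM")})
        table, records = simulate_cds_pairs(cfg, small_dataset.truth)
        assert (table["n_non_planted"] == 0).all()
        pid = table.index[0]
        r = ng86_kaks(records[f"{pid}|1"], records[f"{pid}|2"])
        assert r.Nd == 0

    def test_sequences_inframe_and_stop_free(self, small_dataset):
        _, records = simulate_cds_pairs(small_dataset.config, small_dataset.truth)
        for seq in list(records.values())[:40]:
            assert len(seq) % 3 == 0
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)
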