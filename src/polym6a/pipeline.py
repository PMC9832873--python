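"""End-to-end pipeline: simulate (or load) a dataset, run every analysis
stage, and write a report of the study's table layouts.

Stage order: MeRIP peak calling per replicate -> consensus per genotype
-> five-segment localization and metagene -> gene m6A status -> pattern
taxonomy (parents vs polyploids, polyploid vs polyploid) -> duplicate
pair IM/DM/NM -> stratified proportions -> FPKM / DE / ED -> differential
methylation and DM x DE integration -> NG86 omega group contrasts ->
epigenomic profiles.  Every run is deterministic given the seed, and all
report numbers are recomputed from stage outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr_mod
from . import genestats, patterns, peaks, profiles
from .geometry import assign_peak, five_segments, metagene_peak_density, \
    relative_enrichment, segment_density_mass
from .evolution import group_omega_comparison, kaks_table
from .simulate import SimConfig, SyntheticDataset, simulate_all
from .tracks import SignalTrack

log = logging.getLogger("polym6a")

PARENT_OF = {"A": "A", "C": "C"}  # subgenome -> parent genotype


@dataclass
class RunConfig:
    """Thresholds and geometry for one pipeline run."""

    seed: int = 0
    n_genes: int = 150
    outdir: str | None = None
    alpha: float = 0.05
    peak_fc_min: float = 2.0
    raw_p: bool = False
    window: int = 150
    step: int = 50
    min_support: int = 2
    dm_fc_min: float = 2.0
    dm_p_max: float = 1e-4
    de_p_max: float = 0.05
    de_lfc_min: float = 1.0
    metagene_bins: tuple = (10, 20, 50, 20, 10)
    flank: int = 2000
    profile_bins: int = 100
    #: stage toggles; disabling a stage makes dependents fail fast
    disable: tuple = ()
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides

    KNOWN_STAGES = ("peak_calling", "expression", "kaks", "profiles")

    def __post_init__(self) -> None:
        unknown = set(self.disable) - set(self.KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages in disable: {sorted(unknown)}")

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, n_genes=self.n_genes, **self.sim)


def pool_tracks(tracks: list[SignalTrack]) -> SignalTrack:
    """Sum tracks per chromosome (union of chromosomes)."""
    data: dict[str, np.ndarray] = {}
    for t in tracks:
        for chrom, arr in t.data.items():
            if chrom in data:
                data[chrom] = data[chrom] + arr
            else:
                data[chrom] = arr.copy()
    return SignalTrack(data)


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: SyntheticDataset
    consensus: dict  # genotype -> list[Peak]
    status: pd.DataFrame  # genes x genotypes, boolean (NaN where absent)
    tables: dict  # name -> DataFrame

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{name}.tsv", sep="\t")
        thresholds = {k: v for k, v in asdict(self.config).items() if k != "sim"}
        (out / "run_config.json").write_text(json.dumps(thresholds, indent=2))


def run_pipeline(config: RunConfig, dataset: SyntheticDataset | None = None
                 ) -> PipelineResult:
    """Run every stage on a synthetic dataset (generated from the config's
    seed unless one is supplied) and return all report tables."""
    ds = dataset if dataset is not None else simulate_all(config.sim_config())
    cfg = ds.config
    txs = ds.annotation.transcripts
    genes = ds.truth.genes
    tables: dict[str, pd.DataFrame] = {}

    def require(stage: str, needed_by: str) -> None:
        if stage in config.disable:
            raise RuntimeError(
                f"stage {needed_by!r} requires output of disabled stage {stage!r}")

    # ---- peak calling + consensus per genotype -------------------------
    log.info("stage: peak calling")
    consensus: dict[str, list] = {}
    if "peak_calling" in config.disable:
        require("peak_calling", "segments")
    for geno in cfg.genotypes:
        chroms = set(cfg.chroms_of(geno))
        gtx = {g: t for g, t in txs.items() if t.chrom in chroms}
        rep_sets = []
        for rep in range(1, cfg.n_replicates + 1):
            ip, inp = ds.merip[(geno, rep)]
            rep_sets.append(peaks.call_peaks(
                ip, inp, gtx, w=config.window, step=config.step,
                alpha=config.alpha, fc_min=config.peak_fc_min, raw_p=config.raw_p))
        consensus[geno] = peaks.consensus_peaks(rep_sets, config.min_support)

    # ---- segment localization ------------------------------------------
    segmaps = {g: five_segments(t) for g, t in txs.items()}
    seg_rows, meta_rows = [], []
    for geno, cons in consensus.items():
        for p in cons:
            assign_peak(p, segmaps[p.gene_id])
        if cons:
            enr = relative_enrichment(cons, {g: segmaps[g] for g in
                                             {p.gene_id for p in cons}})
            enr["genotype"] = geno
            seg_rows.append(enr.reset_index())
            prof = metagene_peak_density(cons, segmaps, config.metagene_bins)
            mass = segment_density_mass(prof, config.metagene_bins)
            meta_rows.append(pd.DataFrame([{**mass, "genotype": geno}]))
    tables["segment_enrichment"] = pd.concat(seg_rows, ignore_index=True)
    tables["metagene_segment_mass"] = pd.concat(meta_rows, ignore_index=True)

    # ---- gene status -----------------------------------------------------
    status = pd.DataFrame(index=genes.index, columns=list(cfg.genotypes), dtype=object)
    status[:] = np.nan
    for geno, cons in consensus.items():
        chroms = set(cfg.chroms_of(geno))
        gtx = {g: t for g, t in txs.items() if t.chrom in chroms}
        for s in genestats.classify_m6a_genes(cons, gtx, geno):
            status.at[s.gene_id, geno] = s.status == "m6A"
    tables["gene_status"] = status

    # ---- pattern taxonomy ------------------------------------------------
    status_bool = {g: status[g].dropna().astype(bool) for g in cfg.genotypes}
    parent_ref = patterns.parent_reference_status(
        status_bool, genes["subgenome"], PARENT_OF)
    comparisons = {
        "AC_vs_RAC": (parent_ref, status_bool["RAC"]),
        "AC_vs_NAC": (parent_ref, status_bool["NAC"]),
        "RAC_vs_NAC": (status_bool["RAC"], status_bool["NAC"]),
    }
    pat_rows = []
    for name, (ref, test) in comparisons.items():
        _, summary = patterns.classify_patterns(ref, test.reindex(ref.index), name)
        for pat in patterns.PATTERNS:
            pat_rows.append({"comparison": name, "pattern": pat,
                             "count": summary.counts[pat],
                             "percent": summary.percentages[pat]})
    tables["pattern_summary"] = pd.DataFrame(pat_rows)

    # ---- pair patterns + stratified proportions -------------------------
    pair_rows = []
    for geno in cfg.genotypes:
        pres = status_bool[geno]
        ok = ds.truth.pairs[(ds.truth.pairs["gene1"].isin(pres.index)) &
                            (ds.truth.pairs["gene2"].isin(pres.index))]
        if ok.empty:
            continue
        pp = patterns.classify_pair_patterns(ok.reset_index(), pres)
        pp["genotype"] = geno
        pair_rows.append(pp.reset_index())
    tables["pair_patterns"] = pd.concat(pair_rows, ignore_index=True)

    strat_all, strat_tests = [], []
    for geno in cfg.genotypes:
        pres = status_bool[geno]
        summary, tests = patterns.stratified_m6a_proportion(
            pres, genes.loc[pres.index], ["duplication_status"])
        summary["genotype"] = geno
        tests["genotype"] = geno
        strat_all.append(summary)
        strat_tests.append(tests)
    tables["stratified_proportion"] = pd.concat(strat_all, ignore_index=True)
    tables["stratified_tests"] = pd.concat(strat_tests, ignore_index=True)

    # ---- expression ------------------------------------------------------
    log.info("stage: expression")
    require("expression", "differential_expression")
    fpkm_tab = expr_mod.fpkm(ds.counts, genes["mature_length"])
    tables["fpkm"] = fpkm_tab
    rep_cols = {g: [f"{g}_rep{r}" for r in range(1, cfg.n_replicates + 1)]
                for g in cfg.genotypes}
    de_tabs = {}
    for name, (ref, test) in (("RAC_vs_NAC", ("RAC", "NAC")),):
        de_tabs[name] = expr_mod.differential_expression(
            fpkm_tab[rep_cols[ref]], fpkm_tab[rep_cols[test]],
            p_max=config.de_p_max, lfc_min=config.de_lfc_min)
    # parents vs polyploid: compare each gene against its parent of origin
    for poly in ("RAC", "NAC"):
        parts = []
        for sub, parent in PARENT_OF.items():
            idx = genes.index[genes["subgenome"] == sub]
            parts.append(expr_mod.differential_expression(
                fpkm_tab.loc[idx, rep_cols[parent]], fpkm_tab.loc[idx, rep_cols[poly]],
                p_max=config.de_p_max, lfc_min=config.de_lfc_min))
        de_tabs[f"AC_vs_{poly}"] = pd.concat(parts)
    for name, tab in de_tabs.items():
        tables[f"de_{name}"] = tab

    # expression divergence by pair pattern (per genotype)
    ed_rows = []
    for geno in cfg.genotypes:
        mean_f = fpkm_tab[rep_cols[geno]].mean(axis=1)
        pres = status_bool[geno]
        ok = ds.truth.pairs[(ds.truth.pairs["gene1"].isin(pres.index)) &
                            (ds.truth.pairs["gene2"].isin(pres.index))]
        if ok.empty:
            continue
        eds = expr_mod.ed_frame(expr_mod.expression_divergence(ok.reset_index(), mean_f))
        pp = patterns.classify_pair_patterns(ok.reset_index(), pres)
        eds["pattern"] = pp["pattern"]
        eds["genotype"] = geno
        ed_rows.append(eds.reset_index())
    tables["expression_divergence"] = pd.concat(ed_rows, ignore_index=True)

    # ---- differential methylation + integration -------------------------
    log.info("stage: differential methylation")
    pooled = {g: (pool_tracks([ds.merip[(g, r)][0] for r in range(1, cfg.n_replicates + 1)]),
                  pool_tracks([ds.merip[(g, r)][1] for r in range(1, cfg.n_replicates + 1)]))
              for g in cfg.genotypes}
    union = _union_peaks(consensus["RAC"], consensus["NAC"])
    dms = peaks.differential_methylation(
        union, *pooled["RAC"], *pooled["NAC"], txs,
        fc_min=config.dm_fc_min, p_max=config.dm_p_max)
    dm_tab = peaks.dm_frame(dms)
    tables["dm_RAC_vs_NAC"] = dm_tab
    flagged = dm_tab[dm_tab["direction"].isin(["hyper", "hypo"])]
    tables["dm_de_crosstab"] = expr_mod.integrate_dm_de(flagged, de_tabs["RAC_vs_NAC"])

    # ---- Ka/Ks group contrasts ------------------------------------------
    log.info("stage: Ka/Ks")
    require("kaks", "omega_group_comparison")
    kaks = kaks_table([(pid, ds.cds_records[f"{pid}|1"], ds.cds_records[f"{pid}|2"])
                       for pid in ds.cds_pairs.index])
    kaks_cls = ds.cds_pairs["class"]
    orth = kaks[kaks["pair_id"].str.startswith("orth_")]
    para = kaks[kaks["pair_id"].str.startswith("para_")]
    summ_o, tests_o = group_omega_comparison(orth, kaks_cls)
    summ_p, tests_p = group_omega_comparison(para, kaks_cls)
    tables["omega_singleton_vs_duplicate"] = summ_o
    tables["omega_singleton_vs_duplicate_tests"] = tests_o
    tables["omega_pair_patterns"] = summ_p
    tables["omega_pair_patterns_tests"] = tests_p

    # ---- epigenomic profiles --------------------------------------------
    log.info("stage: profiles")
    require("profiles", "peak_center_profiles")
    epi_geno = "NAC"
    anchors = profiles.peak_centers(consensus[epi_geno], txs)
    prof_rows = []
    for mark, track in ds.epimark_tracks.items():
        prof = profiles.profile_around_points(track, anchors, config.flank,
                                              config.profile_bins)
        df = prof.to_frame()
        df["mark"] = mark
        prof_rows.append(df)
    for ctx in ("CG", "CHG", "CHH"):
        prof = profiles.methylation_profile(ds.cx_report, anchors, ctx,
                                            config.flank, config.profile_bins)
        df = prof.to_frame()
        df["mark"] = f"mC_{ctx}"
        prof_rows.append(df)
    tables["peak_center_profiles"] = pd.concat(prof_rows, ignore_index=True)

    strata = genes["duplication_status"]
    body = profiles.scaled_gene_profile(
        ds.epimark_tracks["H3K4me3"], txs, strata=strata, flank=config.flank)
    tables["genebody_H3K4me3"] = pd.concat(
        [p.to_frame() for p in body.values()], ignore_index=True)

    # ---- replicate QC ----------------------------------------------------
    qc_rows = []
    for geno in cfg.genotypes:
        ips = [ds.merip[(geno, r)][0] for r in range(1, cfg.n_replicates + 1)]
        mat = peaks.qc_replicate_correlation(ips)
        vals = mat.values[np.triu_indices(len(ips), k=1)]
        qc_rows.append({"genotype": geno, "min_spearman": float(np.nanmin(vals))})
    tables["replicate_qc"] = pd.DataFrame(qc_rows)

    result = PipelineResult(config, ds, consensus, status, tables)
    if config.outdir:
        result.write(config.outdir)
    return result


def _union_peaks(a: list, b: list) -> list:
    """Union of two consensus peak sets: peaks from b whose transcript
    interval overlaps a peak from a on the same gene are dropped."""
    out = list(a)
    by_gene: dict[str, list] = {}
    for p in a:
        by_gene.setdefault(p.gene_id, []).append(p)
    for p in b:
        if not any(p.tx_start < q.tx_end and q.tx_start < p.tx_end
                   for q in by_gene.get(p.gene_id, [])):
            out.append(p)
    return out
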