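"""Synthetic multi-genotype m6A dataset with recorded ground truth.

Emulates the study design this pipeline targets: two diploid parents (A
and C) and two allopolyploids carrying both subgenomes (RAC, newly
resynthesized; NAC, naturally evolved), three replicates each.  The
generator plants, per genotype: m6A genes with stopC-biased peak
placement (configurable segment-probability vector), IP enrichment over
a Poisson input background at planted peaks, negative-binomial expression
counts, duplicate pairs with controlled m6A co-occurrence and controlled
Ka/Ks, and histone enrichment / DNA-methylation depletion around planted
peak centers.

Every output is byte-identical for an identical :class:`SimConfig`
(independent numpy Generator streams keyed by seed and stage).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .evolution import NUCS, STOP_CODONS, _syn_sites, translate_codon
from .geometry import SEGMENTS, TranscriptModel, five_segments
from .tracks import SignalTrack, write_chrom_sizes

GENOTYPES = ("A", "C", "RAC", "NAC")
SUBGENOMES = ("A", "C")
DUP_TYPES = ("WGD", "TD", "PD", "TRD", "DSD")

# rng stream codes (second word of the Generator seed)
_S_ANN, _S_STATUS, _S_PEAKS, _S_EXPR, _S_MERIP, _S_EPI, _S_CDS = range(1, 8)


class ConfigError(ValueError):
    pass


def _default_m6a_probs() -> dict:
    # parents differ (A > C, as the study system does); the old polyploid
    # has gained methylated genes relative to the young one
    return {
        ("A", "A"): 0.45, ("C", "C"): 0.38,
        ("RAC", "A"): 0.43, ("RAC", "C"): 0.40,
        ("NAC", "A"): 0.50, ("NAC", "C"): 0.48,
    }


def _default_omega() -> dict:
    return {"singleton": 0.18, "duplicate": 0.15,
            "IM": 0.12, "DM": 0.16, "NM": 0.18}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the conditions the
    whole test-suite runs under."""

    seed: int = 0
    n_genes: int = 150  # per subgenome
    subgenomes: tuple = SUBGENOMES
    genotypes: tuple = GENOTYPES
    n_replicates: int = 3
    m6a_gene_prob: dict = field(default_factory=_default_m6a_probs)
    #: probability a planted summit falls in (5UTR, startC, CDS, stopC, 3UTR)
    segment_probs: tuple = (0.02, 0.20, 0.15, 0.61, 0.02)
    ip_enrichment: float = 4.0
    depth: float = 30.0  # mean input coverage per transcript base
    dup_type_props: tuple = (0.55, 0.07, 0.05, 0.18, 0.15)  # WGD,TD,PD,TRD,DSD
    singleton_prop: float = 0.087
    dosage_dependent_prop: float = 0.4
    #: latent (Gaussian-copula) correlation between pair members' m6A status
    pair_m6a_corr: float = 0.5
    #: latent correlation of one gene's m6A status across genotypes
    genotype_m6a_corr: float = 0.6
    omega_by_class: dict = field(default_factory=_default_omega)
    ks_target: float = 0.3
    expr_lognormal_params: tuple = (3.0, 1.0)  # natural-log mean / sd
    nb_dispersion: float = 0.1
    library_size: float = 1e6
    de_gene_prob: float = 0.15
    de_log2fc: float = 2.0
    dm_de_coupling: float = 0.0  # P(m6A-gain gene forced up in the polyploid)
    peak_width_range: tuple = (100, 400)
    max_exons: int = 12
    # epigenomic marks
    h3k4me3_tss_amp: float = 3.0
    h3k27ac_tss_amp: float = 2.5
    peak_mark_amp: float = 2.0
    bump_sd: float = 200.0
    h3k4me3_amp_by_class: dict | None = None  # duplication_status -> amp override
    meth_baseline: dict = field(default_factory=lambda: {"CG": 0.6, "CHG": 0.3, "CHH": 0.1})
    meth_dip: float = 0.3
    meth_dip_sd: float = 300.0
    cx_spacing: int = 10
    cx_depth: int = 20

    def __post_init__(self) -> None:
        sp = np.asarray(self.segment_probs, dtype=float)
        if sp.size != 5 or abs(sp.sum() - 1.0) > 1e-9 or np.any(sp < 0):
            raise ConfigError("segment_probs must be 5 non-negative values summing to 1")
        dp = np.asarray(self.dup_type_props, dtype=float)
        if dp.size != 5 or abs(dp.sum() - 1.0) > 1e-9 or np.any(dp < 0):
            raise ConfigError("dup_type_props must be 5 non-negative values summing to 1")
        for p in (*self.m6a_gene_prob.values(), self.singleton_prop,
                  self.dosage_dependent_prop, self.de_gene_prob, self.dm_de_coupling):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.ip_enrichment < 1:
            raise ConfigError("ip_enrichment must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not 0 < self.ks_target <= 1:
            raise ConfigError("ks_target must lie in (0, 1]")
        # saturation guard: corrected Ks must stay defined
        if 0.75 <= 0.75 * (1 - np.exp(-4 * self.ks_target / 3)):
            raise ConfigError("ks_target saturates the Jukes-Cantor correction")

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), *key])

    def chroms_of(self, genotype: str) -> list[str]:
        if genotype in ("A", "C"):
            return [f"chr{genotype}"]
        return [f"chr{s}" for s in self.subgenomes]


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    genes: pd.DataFrame  # per gene: subgenome, class labels, geometry
    status: pd.DataFrame  # genes x genotypes, boolean m6A truth (NaN if absent)
    peaks: pd.DataFrame  # planted peaks: gene_id, genotype, tx interval, summit, segment
    expr: pd.DataFrame  # genes x genotypes true expression means (FPKM scale)
    pairs: pd.DataFrame  # pair_id, gene1, gene2, dup_type

    def validate(self, transcripts: dict[str, TranscriptModel]) -> None:
        for row in self.peaks.itertuples(index=False):
            L = transcripts[row.gene_id].mature_length
            if not (0 <= row.tx_start < row.tx_end <= L):
                raise AssertionError(f"peak outside transcript for {row.gene_id}")
            if not self.status.loc[row.gene_id, row.genotype]:
                raise AssertionError(f"peak on non-m6A gene {row.gene_id}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    transcripts: dict[str, TranscriptModel]
    genes: pd.DataFrame
    chrom_sizes: dict[str, int]
    gff3: str
    transcript_fasta: str


def _gene_geometry(rng: np.random.Generator, cfg: SimConfig):
    u5 = int(rng.integers(100, 301))
    n_codons = int(rng.integers(80, 401))
    u3 = int(rng.integers(150, 401))
    mature = u5 + 3 * n_codons + u3
    n_exons = int(rng.integers(1, cfg.max_exons + 1))
    # split the mature transcript into exon pieces (>= 30 nt each)
    if n_exons > 1:
        base = mature // n_exons
        jitter = rng.integers(-(base - 30), base - 30, size=n_exons - 1) if base > 60 else \
            np.zeros(n_exons - 1, dtype=int)
        cuts = np.sort(np.arange(1, n_exons) * base + jitter)
        pieces = np.diff(np.concatenate([[0], cuts, [mature]]))
    else:
        pieces = np.array([mature])
    introns = rng.integers(80, 501, size=n_exons - 1)
    strand = "+" if rng.random() < 0.5 else "-"
    return u5, n_codons, u3, pieces, introns, strand


def simulate_annotation(config: SimConfig) -> AnnotationBundle:
    """Generate the genome annotation: one chromosome per subgenome, one
    mRNA per gene, intergenic gaps >= 2 kb, and the gene-class table
    (singleton/duplicate, duplication type, dosage label)."""
    if config.n_genes < 10:
        raise ConfigError("n_genes must be >= 10")
    rng = config.rng(_S_ANN)
    transcripts: dict[str, TranscriptModel] = {}
    gene_rows = []
    chrom_sizes = {}
    gff = io.StringIO()
    gff.write("##gff-version 3\n")
    fasta = io.StringIO()

    for sub in config.subgenomes:
        chrom = f"chr{sub}"
        cursor = int(rng.integers(2000, 3001))
        for i in range(config.n_genes):
            gid = f"{sub}g{i + 1:04d}"
            u5, n_codons, u3, pieces, introns, strand = _gene_geometry(rng, config)
            exons = []
            pos = cursor
            for j, ln in enumerate(pieces):
                exons.append((pos, pos + int(ln)))
                pos += int(ln)
                if j < len(introns):
                    pos += int(introns[j])
            gene_start, gene_end = exons[0][0], exons[-1][1]
            mature = int(sum(e - s for s, e in exons))
            # CDS transcript interval [u5, u5 + 3*n_codons) -> genomic bounds
            tx_tmp = TranscriptModel(gid, gid + ".1", chrom, strand, exons, gene_start,
                                     gene_end)
            cds_t = (u5, u5 + 3 * n_codons)
            g1 = tx_tmp.transcript_to_genomic(cds_t[0])
            g2 = tx_tmp.transcript_to_genomic(cds_t[1] - 1)
            cds_start, cds_end = (g1, g2 + 1) if g1 <= g2 else (g2, g1 + 1)
            tm = TranscriptModel(gid, gid + ".1", chrom, strand, exons, cds_start, cds_end)
            transcripts[gid] = tm
            gene_rows.append({
                "gene_id": gid, "subgenome": sub, "chrom": chrom, "strand": strand,
                "start": gene_start, "end": gene_end, "mature_length": mature,
                "utr5": u5, "n_codons": n_codons, "utr3": u3, "n_exons": len(exons),
            })
            _write_gene_gff(gff, tm)
            seq = _transcript_sequence(rng, u5, n_codons, u3)
            fasta.write(f">{gid}.1\n")
            for k in range(0, len(seq), 70):
                fasta.write(seq[k:k + 70] + "\n")
            cursor = gene_end + int(rng.integers(2000, 3001))
        chrom_sizes[chrom] = cursor + 2000

    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    _assign_classes(genes, config, rng)
    return AnnotationBundle(transcripts, genes, chrom_sizes, gff.getvalue(),
                            fasta.getvalue())


def _write_gene_gff(gff: io.StringIO, tm: TranscriptModel) -> None:
    s, e = tm.span
    gid, mid = tm.gene_id, tm.transcript_id
    gff.write(f"{tm.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{tm.strand}\t.\tID={gid}\n")
    gff.write(f"{tm.chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{tm.strand}\t.\tID={mid};Parent={gid}\n")
    for xs, xe in tm.exons:
        gff.write(f"{tm.chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{tm.strand}\t.\tParent={mid}\n")
    for cs, ce in tm.transcript_interval_to_genomic(*tm.cds_transcript_interval):
        gff.write(f"{tm.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{tm.strand}\t0\tParent={mid}\n")


def _transcript_sequence(rng: np.random.Generator, u5: int, n_codons: int, u3: int) -> str:
    sense = [c for c in ("".join(t) for t in product(NUCS, repeat=3))
             if c not in STOP_CODONS]
    utr5 = "".join(rng.choice(list(NUCS), size=u5))
    body = "ATG" + "".join(rng.choice(sense, size=n_codons - 2)) + "TAA"
    utr3 = "".join(rng.choice(list(NUCS), size=u3))
    return utr5 + body + utr3


def _assign_classes(genes: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> None:
    """Mark genes singleton/duplicate, form duplicate pairs within each
    subgenome, and assign duplication type and dosage labels."""
    genes["duplication_status"] = "duplicate"
    genes["dup_type"] = "NA"
    genes["dosage"] = "NA"
    genes["pair_id"] = "NA"
    singles = rng.random(len(genes)) < config.singleton_prop
    genes.loc[genes.index[singles], "duplication_status"] = "singleton"
    pair_n = 0
    for sub in config.subgenomes:
        dups = [g for g in genes.index
                if genes.at[g, "subgenome"] == sub
                and genes.at[g, "duplication_status"] == "duplicate"]
        rng.shuffle(dups)
        if len(dups) % 2:  # unpaired leftover becomes a singleton
            genes.at[dups.pop(), "duplication_status"] = "singleton"
        for g1, g2 in zip(dups[::2], dups[1::2]):
            pair_n += 1
            pid = f"pair{pair_n:04d}"
            dt = DUP_TYPES[int(rng.choice(5, p=config.dup_type_props))]
            dosage = "dependent" if rng.random() < config.dosage_dependent_prop \
                else "independent"
            for g in (g1, g2):
                genes.at[g, "dup_type"] = dt
                genes.at[g, "pair_id"] = pid
                genes.at[g, "dosage"] = dosage


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def generate_ground_truth(config: SimConfig, ann: AnnotationBundle) -> GroundTruth:
    genes = ann.genes
    rng_s = config.rng(_S_STATUS)
    status = pd.DataFrame(index=genes.index, columns=list(config.genotypes), dtype=object)

    pairs_rows = []
    for pid, sub in genes[genes["pair_id"] != "NA"].groupby("pair_id"):
        g1, g2 = sorted(sub.index)
        pairs_rows.append({"pair_id": pid, "gene1": g1, "gene2": g2,
                           "dup_type": sub["dup_type"].iloc[0]})
    pairs = pd.DataFrame(pairs_rows).set_index("pair_id") if pairs_rows else \
        pd.DataFrame(columns=["gene1", "gene2", "dup_type"])

    # Gaussian-copula latent model: thresholding keeps every per-genotype
    # marginal exactly at m6a_gene_prob while a shared gene factor gives
    # cross-genotype persistence (genotype_m6a_corr) and a shared pair
    # factor gives within-genotype co-occurrence of pair members
    # (pair_m6a_corr * genotype_m6a_corr on the latent scale).
    from scipy.stats import norm

    rg = config.genotype_m6a_corr
    rp = config.pair_m6a_corr
    pair_factor: dict[str, float] = {}
    gene_factor = {}
    for gid in genes.index:
        pid = genes.at[gid, "pair_id"]
        h = rng_s.standard_normal()
        if pid != "NA":
            if pid not in pair_factor:
                pair_factor[pid] = rng_s.standard_normal()
            g = np.sqrt(rp) * pair_factor[pid] + np.sqrt(1 - rp) * h
        else:
            g = h
        gene_factor[gid] = g
    for geno in config.genotypes:
        present = set(genes.index) if geno in ("RAC", "NAC") else \
            set(genes.index[genes["subgenome"] == geno])
        for gid in genes.index:
            if gid not in present:
                status.at[gid, geno] = np.nan
                continue
            p = config.m6a_gene_prob[(geno, genes.at[gid, "subgenome"])]
            z = np.sqrt(rg) * gene_factor[gid] + np.sqrt(1 - rg) * rng_s.standard_normal()
            status.at[gid, geno] = bool(z < norm.ppf(p))

    peaks = _plant_peaks(config, ann, status)
    expr = _expression_means(config, genes, status)
    return GroundTruth(genes=genes, status=status, peaks=peaks, expr=expr, pairs=pairs)


def _plant_peaks(config: SimConfig, ann: AnnotationBundle, status: pd.DataFrame) -> pd.DataFrame:
    rng = config.rng(_S_PEAKS)
    probs = np.asarray(config.segment_probs, dtype=float)
    rows = []
    for geno in config.genotypes:
        for gid in ann.genes.index:
            if status.at[gid, geno] is not True:
                continue
            tx = ann.transcripts[gid]
            sm = five_segments(tx)
            lens = sm.lengths
            avail = np.array([probs[i] if lens[seg] > 0 else 0.0
                              for i, seg in enumerate(SEGMENTS)])
            avail = avail / avail.sum()
            seg = SEGMENTS[int(rng.choice(5, p=avail))]
            s, e = sm.intervals[seg]
            summit = int(rng.integers(s, e))
            w = int(rng.integers(*config.peak_width_range))
            ts = max(0, summit - w // 2)
            te = min(tx.mature_length, summit + (w + 1) // 2)
            rows.append({"gene_id": gid, "genotype": geno, "tx_start": ts,
                         "tx_end": te, "summit": summit, "segment": seg, "width": te - ts})
    return pd.DataFrame(rows)


def _expression_means(config: SimConfig, genes: pd.DataFrame, status: pd.DataFrame
                      ) -> pd.DataFrame:
    rng = config.rng(_S_EXPR)
    mu, sd = config.expr_lognormal_params
    base = np.exp(rng.normal(mu, sd, size=len(genes)))
    expr = pd.DataFrame(index=genes.index, columns=list(config.genotypes), dtype=float)
    for geno in config.genotypes:
        present = genes.index if geno in ("RAC", "NAC") else \
            genes.index[genes["subgenome"] == geno]
        vals = pd.Series(np.nan, index=genes.index)
        v = base.copy()
        if geno in ("RAC", "NAC"):
            # polyploid-specific differential expression relative to the
            # parental baseline, balanced in sign
            de_mask = rng.random(len(genes)) < config.de_gene_prob
            de_sign = np.where(rng.random(len(genes)) < 0.5, 1.0, -1.0)
            v = v * np.where(de_mask, 2.0 ** (de_sign * config.de_log2fc), 1.0)
        vals.loc[present] = v[genes.index.get_indexer(present)]
        expr[geno] = vals
    if config.dm_de_coupling > 0:
        # genes gaining m6A in a polyploid relative to their parent tend up
        for geno in ("RAC", "NAC"):
            for i, gid in enumerate(genes.index):
                parent = genes.at[gid, "subgenome"]
                sp, sg = status.at[gid, parent], status.at[gid, geno]
                if sp is False and sg is True and rng.random() < config.dm_de_coupling:
                    expr.at[gid, geno] = base[i] * 2.0 ** config.de_log2fc
    return expr


# ---------------------------------------------------------------------------
# MeRIP coverage
# ---------------------------------------------------------------------------

def simulate_merip(config: SimConfig, truth: GroundTruth, ann: AnnotationBundle
                   ) -> dict[tuple[str, int], tuple[SignalTrack, SignalTrack]]:
    """Per genotype x replicate IP and input coverage tracks.

    Input coverage is Poisson with per-base rate depth * (gene expression
    weight); IP multiplies that rate by ``ip_enrichment`` inside planted
    peaks.  Replicates differ only by sampling noise.
    """
    unknown = set(truth.peaks["gene_id"]) - set(ann.transcripts)
    if unknown:
        raise KeyError(f"truth references unknown genes {sorted(unknown)[:5]}")
    out = {}
    peak_idx = truth.peaks.groupby(["genotype", "gene_id"])
    for gi, geno in enumerate(config.genotypes):
        chroms = config.chroms_of(geno)
        present = [g for g, tx in ann.transcripts.items() if tx.chrom in set(chroms)]
        med = float(np.nanmedian(truth.expr.loc[present, geno]))
        for rep in range(1, config.n_replicates + 1):
            rng = config.rng(_S_MERIP, gi, rep)
            ip = {c: np.zeros(ann.chrom_sizes[c]) for c in chroms}
            inp = {c: np.zeros(ann.chrom_sizes[c]) for c in chroms}
            for gid in present:
                tx = ann.transcripts[gid]
                L = tx.mature_length
                weight = truth.expr.at[gid, geno] / med
                rate = np.full(L, config.depth * weight)
                ip_rate = rate.copy()
                try:
                    sub = peak_idx.get_group((geno, gid))
                except KeyError:
                    sub = None
                if sub is not None:
                    for r in sub.itertuples(index=False):
                        # fragment pileups peak at the modified site: the
                        # multiplier is Gaussian around the summit within
                        # the planted interval, maximal ip_enrichment
                        xs = np.arange(r.tx_start, r.tx_end)
                        sigma = max((r.tx_end - r.tx_start) / 3.0, 1.0)
                        bump = np.exp(-((xs - r.summit) ** 2) / (2 * sigma**2))
                        ip_rate[r.tx_start:r.tx_end] *= \
                            1.0 + (config.ip_enrichment - 1.0) * bump
                in_cov = rng.poisson(rate).astype(float)
                ip_cov = rng.poisson(ip_rate).astype(float)
                if tx.strand == "-":
                    in_cov, ip_cov = in_cov[::-1], ip_cov[::-1]
                off = 0
                for s, e in tx.exons:
                    inp[tx.chrom][s:e] = in_cov[off:off + e - s]
                    ip[tx.chrom][s:e] = ip_cov[off:off + e - s]
                    off += e - s
            out[(geno, rep)] = (SignalTrack(ip), SignalTrack(inp))
    return out


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Gene x sample negative-binomial count matrix (three replicates per
    genotype, columns ``GENOTYPE_rep{i}``)."""
    rng = config.rng(_S_EXPR, 99)
    genes = truth.genes
    cols = {}
    for geno in config.genotypes:
        means = truth.expr[geno].fillna(0.0)
        weight = means * genes["mature_length"] / 1000.0
        tot = weight.sum()
        mu = (weight / tot * config.library_size).to_numpy()
        for rep in range(1, config.n_replicates + 1):
            if config.nb_dispersion < 1e-8:
                counts = rng.poisson(mu)
            else:
                n = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(n, n / (n + np.maximum(mu, 1e-12)))
                counts = np.where(mu <= 0, 0, counts)
            cols[f"{geno}_rep{rep}"] = counts
    return pd.DataFrame(cols, index=genes.index)


# ---------------------------------------------------------------------------
# epigenomic marks
# ---------------------------------------------------------------------------

def _add_bumps(arr: np.ndarray, centers: np.ndarray, amp, sd: float) -> None:
    half = int(4 * sd)
    xs = np.arange(-half, half + 1)
    kernel = np.exp(-xs**2 / (2 * sd**2))
    amps = np.broadcast_to(np.asarray(amp, dtype=float), centers.shape)
    for c, a in zip(centers, amps):
        lo, hi = max(0, c - half), min(arr.size, c + half + 1)
        arr[lo:hi] += a * kernel[lo - (c - half): hi - (c - half)]


def simulate_epimarks(config: SimConfig, truth: GroundTruth, ann: AnnotationBundle,
                      genotype: str = "NAC"):
    """Histone tracks and a CX methylation report for one genotype.

    H3K4me3/H3K27ac get Gaussian bumps at every TSS and at planted m6A
    peak centers; H3K27me3 is flat with a mild gene-body elevation.  The
    cytosine report covers every simulated site with context CG/CHG/CHH
    and a methylation proportion dipping around planted peak centers.
    """
    chroms = config.chroms_of(genotype)
    sizes = {c: ann.chrom_sizes[c] for c in chroms}
    present = [g for g, tx in ann.transcripts.items() if tx.chrom in set(chroms)]

    centers_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    sub = truth.peaks[truth.peaks["genotype"] == genotype]
    for r in sub.itertuples(index=False):
        tx = ann.transcripts[r.gene_id]
        mid = (r.tx_start + r.tx_end) // 2
        centers_by_chrom[tx.chrom].append(
            tx.transcript_to_genomic(min(mid, tx.mature_length - 1)))

    tracks = {name: SignalTrack({c: np.zeros(n) for c, n in sizes.items()})
              for name in ("H3K4me3", "H3K27ac", "H3K27me3")}
    for name, base in (("H3K4me3", 0.2), ("H3K27ac", 0.2), ("H3K27me3", 0.3)):
        for c in chroms:
            tracks[name].data[c] += base
    for gid in present:
        tx = ann.transcripts[gid]
        arr4, arr27ac = tracks["H3K4me3"].data[tx.chrom], tracks["H3K27ac"].data[tx.chrom]
        amp4 = config.h3k4me3_tss_amp
        if config.h3k4me3_amp_by_class:
            amp4 = config.h3k4me3_amp_by_class.get(
                truth.genes.at[gid, "duplication_status"], amp4)
        _add_bumps(arr4, np.array([tx.tss]), amp4, config.bump_sd)
        _add_bumps(arr27ac, np.array([tx.tss]), config.h3k27ac_tss_amp, config.bump_sd)
        s, e = tx.span
        tracks["H3K27me3"].data[tx.chrom][s:e] += 0.3
    for c in chroms:
        ctrs = np.asarray(centers_by_chrom[c], dtype=int)
        if ctrs.size:
            _add_bumps(tracks["H3K4me3"].data[c], ctrs, config.peak_mark_amp, config.bump_sd)
            _add_bumps(tracks["H3K27ac"].data[c], ctrs, config.peak_mark_amp, config.bump_sd)

    cx = _cx_report(config, sizes, centers_by_chrom)
    return tracks, cx


def _cx_report(config: SimConfig, sizes: dict[str, int],
               centers_by_chrom: dict[str, list[int]]) -> pd.DataFrame:
    rng = config.rng(_S_EPI)
    rows = []
    for chrom in sorted(sizes):
        n = sizes[chrom]
        pos = np.arange(config.cx_spacing, n, config.cx_spacing)
        context = rng.choice(["CG", "CHG", "CHH"], size=pos.size, p=[0.25, 0.25, 0.5])
        strand = rng.choice(["+", "-"], size=pos.size)
        level = np.array([config.meth_baseline[c] for c in context])
        for c0 in centers_by_chrom[chrom]:
            d = pos - c0
            level = level - config.meth_dip * np.exp(-d**2 / (2 * config.meth_dip_sd**2))
        level = np.clip(level, 0.01, 0.99)
        meth = rng.binomial(config.cx_depth, level)
        for p, st, ctx, m in zip(pos, strand, context, meth):
            rows.append((chrom, int(p) + 1, st, ctx, int(m), config.cx_depth - int(m)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "count_methylated", "count_unmethylated"])


# ---------------------------------------------------------------------------
# CDS pairs
# ---------------------------------------------------------------------------

def _inv_jc(K: float) -> float:
    """Expected raw difference proportion giving corrected distance K."""
    return 0.75 * (1.0 - np.exp(-4.0 * K / 3.0))


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    sense = sorted(set("".join(t) for t in product(NUCS, repeat=3)) - STOP_CODONS)
    return list(rng.choice(sense, size=n_codons))


def _evolve(rng: np.random.Generator, codons: list[str], n_syn: int, n_non: int
            ) -> list[str]:
    """Apply the requested numbers of synonymous / non-synonymous
    single-nucleotide substitutions, never creating a stop codon."""
    out = list(codons)
    want = {"syn": n_syn, "non": n_non}
    guard = 0
    while (want["syn"] > 0 or want["non"] > 0) and guard < 200 * (n_syn + n_non + 1):
        guard += 1
        ci = int(rng.integers(len(out)))
        pos = int(rng.integers(3))
        alt = NUCS[int(rng.integers(4))]
        codon = out[ci]
        if alt == codon[pos]:
            continue
        new = codon[:pos] + alt + codon[pos + 1:]
        if new in STOP_CODONS:
            continue
        kind = "syn" if translate_codon(new) == translate_codon(codon) else "non"
        if want[kind] <= 0:
            continue
        out[ci] = new
        want[kind] -= 1
    return out


def simulate_cds_pairs(config: SimConfig, truth: GroundTruth,
                       reference_genotype: str = "NAC",
                       identical: bool = False) -> tuple[pd.DataFrame, dict[str, str]]:
    """Aligned CDS pairs with controlled omega = Ka/Ks per gene class.

    Two pair families are produced: *ortholog* pairs (one per gene; class
    singleton/duplicate, matching the between-species comparison) and
    *paralog* pairs (one per duplicate pair; class IM/DM/NM under
    ``reference_genotype``).  Sequences are equal-length, in-frame and
    stop-free; ``identical=True`` emits unmutated pairs (Ka = Ks = 0).

    Returns a pair table (pair_id, family, class, omega_target, n_codons)
    and a dict of FASTA records keyed ``pair_id|1`` / ``pair_id|2``.
    """
    rng = config.rng(_S_CDS)
    genes = truth.genes
    jobs = []
    for gid in genes.index:
        cls = genes.at[gid, "duplication_status"]
        jobs.append((f"orth_{gid}", "ortholog", cls, int(genes.at[gid, "n_codons"])))
    pair_patterns = {}
    for row in truth.pairs.itertuples():
        s1 = truth.status.at[row.gene1, reference_genotype]
        s2 = truth.status.at[row.gene2, reference_genotype]
        pat = "IM" if (s1 and s2) else ("NM" if not (s1 or s2) else "DM")
        pair_patterns[row.Index] = pat
        n_codons = int(min(genes.at[row.gene1, "n_codons"], genes.at[row.gene2, "n_codons"]))
        jobs.append((f"para_{row.Index}", "paralog", pat, n_codons))

    records: dict[str, str] = {}
    rows = []
    for pid, family, cls, n_codons in jobs:
        omega = config.omega_by_class.get(cls, 0.15)
        anc = _random_cds(rng, n_codons)
        if identical:
            seq1 = seq2 = "".join(anc)
            n_syn = n_non = 0
        else:
            S = sum(_syn_sites(c) for c in anc)
            N = 3 * n_codons - S
            # quotas are actual substitution counts (Ks/Ka are per-site
            # substitution numbers); the Jukes-Cantor correction in the
            # estimator undoes the resulting multiple hits
            n_syn = int(rng.poisson(S * config.ks_target))
            n_non = int(rng.poisson(N * omega * config.ks_target))
            seq1 = "".join(anc)
            seq2 = "".join(_evolve(rng, anc, n_syn, n_non))
        records[f"{pid}|1"] = seq1
        records[f"{pid}|2"] = seq2
        rows.append({"pair_id": pid, "family": family, "class": cls,
                     "omega_target": omega, "n_codons": n_codons,
                     "n_syn_planted": n_syn, "n_non_planted": n_non})
    return pd.DataFrame(rows).set_index("pair_id"), records


def write_fasta(records: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimConfig
    annotation: AnnotationBundle
    truth: GroundTruth
    merip: dict
    counts: pd.DataFrame
    epimark_tracks: dict
    cx_report: pd.DataFrame
    cds_pairs: pd.DataFrame
    cds_records: dict

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "annotation.gff3").write_text(self.annotation.gff3)
        (out / "transcripts.fa").write_text(self.annotation.transcript_fasta)
        write_chrom_sizes(self.annotation.chrom_sizes, out / "chrom.sizes")
        self.truth.genes.to_csv(out / "gene_classes.tsv", sep="\t")
        self.truth.status.to_csv(out / "truth_status.tsv", sep="\t")
        self.truth.peaks.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
        self.truth.pairs.to_csv(out / "duplicate_pairs.tsv", sep="\t")
        self.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
        for (geno, rep), (ip, inp) in self.merip.items():
            ip.to_bedgraph(out / f"{geno}_rep{rep}_IP.bedgraph")
            inp.to_bedgraph(out / f"{geno}_rep{rep}_input.bedgraph")
        for name, track in self.epimark_tracks.items():
            track.to_bedgraph(out / f"{name}.bedgraph")
        self.cx_report.to_csv(out / "cx_report.tsv", sep="\t", header=False, index=False)
        self.cds_pairs.to_csv(out / "cds_pairs.tsv", sep="\t")
        write_fasta(self.cds_records, out / "cds_pairs.fa")


def simulate_all(config: SimConfig, epimark_genotype: str = "NAC") -> SyntheticDataset:
    """Run every generator stage and return the full dataset in memory."""
    ann = simulate_annotation(config)
    truth = generate_ground_truth(config, ann)
    truth.validate(ann.transcripts)
    merip = simulate_merip(config, truth, ann)
    counts = simulate_expression(config, truth)
    epimarks, cx = simulate_epimarks(config, truth, ann, genotype=epimark_genotype)
    cds_pairs, records = simulate_cds_pairs(config, truth)
    return SyntheticDataset(config, ann, truth, merip, counts, epimarks, cx,
                            cds_pairs, records)
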