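# polym6a

Comparative mRNA m⁶A methylome analysis for allopolyploids and their
diploid progenitors.

N⁶-methyladenosine (m⁶A) is the most widespread internal mRNA
modification. In a polyploid study system — two diploid parents (A, C)
and two allopolyploids carrying both subgenomes (a resynthesized RAC and
a naturally evolved NAC) — the questions are where m⁶A sits on
transcripts, how methylation status is kept, lost or gained through
hybridization, genome doubling and subsequent evolution, how it
stratifies across singleton and duplicated genes, and how it relates to
expression, evolutionary rate and chromatin state. `polym6a` implements
that analysis as a tested, reusable pipeline and ships a synthetic-data
generator with planted ground truth, so every stage is verifiable without
any sequencing download.

## What it computes

* **Peak calling** from IP vs input coverage with a sliding Poisson
  window test in mature-transcript coordinates (w = 150, step = 50,
  BH-adjusted p < 0.05, fold ≥ 2), replicate consensus (≥ 2 of 3), and
  per-peak differential methylation between genotypes (Fisher exact,
  fold ≥ 2 and p < 10⁻⁴).
* **Five-segment anatomy**: 5′UTR / startC / CDS / stopC / 3′UTR, where
  startC and stopC are 200-nt windows centered on the start and stop
  codons; peak localization by summit, relative enrichment
  (summit fraction ÷ length fraction) and metagene density profiles.
* **Pattern taxonomy**: per gene across genotypes — I kept methylated,
  II kept unmethylated, III lost, IV gained; per duplicate pair within a
  genotype — IM (both methylated), DM (one), NM (neither); m⁶A
  proportions stratified by singleton/duplicate, duplication type
  (WGD/TD/PD/TRD/DSD), dosage class and subgenome, with χ² contrasts.
* **Expression**: FPKM, differential expression (Wilcoxon on replicate
  FPKM, p ≤ 0.05 and |log₂FC| ≥ 1), expression divergence of duplicate
  pairs ED = |E1−E2|/(E1+E2), and DM × DE cross-tabulation.
* **Evolutionary rate**: Ka, Ks and ω = Ka/Ks by the Nei–Gojobori (NG86)
  counting method — path-averaged difference counts with stop-excluded
  mutational paths and Jukes–Cantor correction — compared across gene
  groups with Wilcoxon tests.
* **Chromatin profiles**: histone signal (bedGraph) and weighted DNA
  methylation (Bismark-style CX report, CG/CHG/CHH) around m⁶A peak
  centers and across scaled gene bodies, stratified by gene class.

## Worked example

Run the full pipeline on the default synthetic study (two subgenomes ×
100 genes, four genotypes, three replicates, 30× depth, 4× IP
enrichment):

```python
from polym6a.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=1, n_genes=100, outdir="report"))
print(res.tables["segment_enrichment"]
      .groupby("segment")["enrichment"].mean().round(2))
```

```
segment
3UTR      0.09
5UTR      0.89
CDS       0.62
startC    1.40
stopC     2.51
```

The generator plants 61% of summits in the 200-nt stop-codon window, and
the called peaks recover that geometry: stopC is 2.5-fold enriched over
its share of transcript length, startC mildly enriched, everything else
depleted — the hallmark m⁶A topology. The same run recovers the planted
class-dependent evolutionary rates from the 200-plus duplicate pairs:

```python
print(res.tables["omega_pair_patterns"].round(4))
```

```
        n  n_missing  mean_omega  sd_omega
group
DM     34          0      0.1732    0.0550
IM     21          0      0.1284    0.0348
NM     36          0      0.1766    0.0445
```

Pairs with identical methylation (IM, planted ω = 0.12) show
significantly lower ω than diverged (DM, 0.16) or unmethylated (NM,
0.18) pairs — conserved pairs sit under stronger purifying selection.
`report/` holds every stage's table (pattern summary, stratified
proportions, DE/ED, DM × DE cross-tab, profiles, replicate QC — the
minimum replicate Spearman here is 0.9999).

The same stages are available from the shell:

```sh
polym6a simulate --outdir sim --seed 1
polym6a callpeaks --gff3 sim/annotation.gff3 --ip sim/A_rep1_IP.bedgraph \
    --input sim/A_rep1_input.bedgraph --chrom-sizes sim/chrom.sizes --out peaks.bed
polym6a kaks --fasta sim/cds_pairs.fa --out kaks.tsv
polym6a run --outdir report --seed 1
```

## Layout

```
src/polym6a/
  simulate.py    synthetic multi-genotype dataset with ground truth
  geometry.py    transcript models, five segments, metagene profiles
  peaks.py       window test, consensus, differential methylation, QC
  genestats.py   m6A/non-m6A classes, Wilcoxon, chi-square, features
  patterns.py    patterns I-IV, IM/DM/NM, stratified proportions
  expression.py  FPKM, DE, expression divergence, DM x DE
  evolution.py   NG86 Ka/Ks and omega group contrasts
  profiles.py    anchored, gene-body and methylation profiles
  tracks.py      bedGraph / CX-report / chrom-sizes I/O
  pipeline.py    end-to-end orchestration and report tables
  cli.py         `polym6a` command group
```

See `docs/methods.md` for the models, defaults and their rationale.
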