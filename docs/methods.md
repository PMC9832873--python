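# Methods

`polym6a` implements a comparative mRNA m⁶A (N⁶-methyladenosine) methylome
analysis for an allopolyploid study system: two diploid parents (genotypes
A and C) and two allopolyploids carrying both subgenomes — a newly
resynthesized one (RAC) and a naturally evolved one (NAC) — with three
biological replicates per genotype. Because the pipeline is exercised
end-to-end on synthetic data with planted ground truth, this note covers
both the analysis models and the generator that defines the test
conditions.

## Peak calling from MeRIP-seq–style coverage

Peaks are called in **mature-transcript coordinates**: exonic coverage is
concatenated 5′→3′ per gene, so spliced genes are handled exactly.
Windows of `w = 150` nt slide in steps of 50 nt; for each window the IP
count is tested against a Poisson rate equal to the input count scaled by
the IP/input library-size ratio, with the upper-tail p-value
P(X ≥ ip_count). By default p-values are Benjamini–Hochberg-adjusted
across all windows of a sample before the `alpha = 0.05` gate (a
`raw_p` switch reproduces the raw-threshold dialect of genome-browser
peak callers). Significant windows also need fold enrichment ≥ 2 (with a
pseudocount of 0.5 to bound ratios at zero coverage); passing windows
within 50 nt of each other merge into one peak whose summit is the center
of the minimal-p window (5′-most on ties).

Replicate peak sets reduce to a per-genotype consensus: overlapping peaks
on the same gene (single linkage) form a cluster, clusters supported by
≥ 2 of 3 replicates are kept, the consensus interval is the intersection
of the supporting peaks (union as a fallback when a linkage chain has no
common core) and the summit is the median of supporting summits.

Two properties anchor the caller: under the Poisson null the
per-transcript false-positive rate stays below the nominal alpha (the BH
gate makes it conservative), and scaling the input track together with
its recorded library size leaves every call unchanged.

Differential methylation between genotypes is a per-consensus-peak
Fisher exact test on the 2×2 table of pooled IP/input counts, with the
printed gates — fold change of library-normalized enrichment ≥ 2 and
p < 10⁻⁴ — deciding hyper/hypo calls. The gates, not a sliding-window
engine, define the differential sets; this stands in for
negative-binomial window scanners whose outputs the gates would filter
anyway.

## Five-segment transcript anatomy

Each representative transcript (per gene: longest CDS, ties broken by
mature length then transcript id) is partitioned into five contiguous
segments: 5′ UTR, `startC` (200 nt centered on the first base of the
start codon), CDS, `stopC` (200 nt centered on the first base of the stop
codon), 3′ UTR. Windows are clipped at transcript ends; where a short CDS
makes the two codon windows collide, `stopC` wins (the biology of
interest is stop-codon-proximal). The five segment lengths always sum to
the mature length.

A peak is localized by its **summit** only, giving each peak exactly one
segment label (percentages then sum to 100). Relative enrichment of a
segment is (fraction of summits in it) / (fraction of aggregate transcript
length in it), so 1 means "no enrichment"; uniform random summits give 1
in every segment within multinomial sampling error. Metagene profiles
rescale the five segments to 10/20/50/20/10 bins and histogram summit
positions into a density.

## Gene, pattern and pair taxonomy

A gene is an **m⁶A gene** in a genotype iff it carries ≥ 1 consensus peak
there. Across a (reference, test) genotype comparison each gene falls in
exactly one of four patterns: I (methylated in both), II (in neither),
III (reference only — loss), IV (test only — gain); swapping the
comparison direction exchanges III and IV. When the reference is "the two
parents", a polyploid gene is compared against its parent of origin
(A_n ↔ A, C_n ↔ C). The pattern universe is all genes with a
representative transcript. Percentages are rounded half-up to one
decimal.

Duplicate pairs within one genotype are IM (both members methylated), DM
(exactly one; the methylated member is recorded) or NM (neither).
Stratified m⁶A proportions (singleton vs duplicate, the five duplication
types WGD/TD/PD/TRD/DSD, dosage classes, subgenomes) are compared with
Pearson χ² tests, BH-adjusted across the contrasts tested.

## Expression

FPKM = count · 10⁹ / (transcript length in nt · library size), library
sizes defaulting to column sums. Differential expression uses a
replicate-level Wilcoxon rank-sum test on FPKM plus the printed gates
(p ≤ 0.05 and |log₂FC| ≥ 1, log₂FC on mean FPKM with a 0.5 pseudocount);
an externally computed DE table can be substituted. Note that FPKM is a
relative measure: comparing a parent library (one subgenome) against a
polyploid library (two subgenomes) carries a compositional dilution of
roughly the total-expression ratio; the same-universe polyploid-vs-
polyploid comparison is free of it.

Expression divergence of a pair is ED = |E1 − E2| / (E1 + E2) on
genotype-mean FPKM — bounded in [0, 1], symmetric, scale-invariant, and
undefined (reported missing) when both members are silent.

## Statistical tests

The Wilcoxon rank-sum test uses mid-ranks for ties; with combined n ≤ 12
and no ties the two-sided p is exact (2·min(tail)/C(n, n_x) over all
labelings), otherwise a normal approximation with tie and continuity
corrections. The χ² test is the Pearson statistic without continuity
correction (Yates available for 2×2); df = (r−1)(c−1).

## Ka/Ks by NG86 counting

For aligned, in-frame, stop-free CDS pairs: each codon contributes
synonymous sites as the per-position fraction of the three possible
changes that are synonymous (changes to stop codons count as
non-synonymous), averaged over the two sequences. Codons differing at
2–3 positions are resolved by averaging over all orderings of single-step
paths, excluding paths through stop codons and re-weighting the rest
uniformly (if every path crosses a stop, all are kept). Proportions are
Jukes–Cantor corrected, K = −¾·ln(1 − 4p/3), undefined at p ≥ ¾; ω =
Ka/Ks is reported missing when Ks = 0. Codons with gaps, ambiguity codes
or stops are excluded pairwise. The difference counting is verified
against a brute-force path-enumeration oracle exhaustively on
single-codon pairs and on random multi-codon pairs. This counting
estimator is desk-verifiable and recovers group contrasts; an external
Ka/Ks table can be supplied through the CLI when a maximum-likelihood
codon model is preferred.

## Signal profiles

Three geometries: fixed windows around anchor points (peak centers, TSS)
split into equal bins with length-weighted means; scaled gene bodies
(TSS→TES rescaled to 100 bins with 2-kb flanks at 50 bins); and weighted
DNA-methylation levels (Σ methylated / Σ total per bin, pooling strands)
for CG/CHG/CHH contexts separately. Windows truncated at chromosome ends
keep per-bin weight bookkeeping — uncovered bins are missing, never
zero-filled. A constant track always yields a constant profile, and
equal-width bin means recompose to the window mean.

## The synthetic generator

The generator emulates the study design, not sequencing reads: no
read-level errors, no alignment, no isoform switching.

* **Genome/annotation** — one chromosome per subgenome; intergenic gaps
  ≥ 2 kb so flanking profiles cannot collide; one mRNA per gene with
  1–12 exons, 5′ UTR of 100–300 nt, CDS of 80–400 codons, 3′ UTR of
  150–400 nt (the geometry loader nevertheless handles multi-isoform
  GFF3 by the longest-CDS rule). Genes are singletons with probability
  0.087 (the fractionation level typical of this study system); the rest
  form within-subgenome pairs labeled WGD/TD/PD/TRD/DSD with proportions
  (0.55, 0.07, 0.05, 0.18, 0.15), reflecting WGD/DSD/TRD dominance.
* **m⁶A status** — a Gaussian-copula latent model: thresholding keeps
  each genotype×subgenome marginal exactly at `m6a_gene_prob`
  (defaults 0.38–0.50, parents differing and the evolved polyploid
  highest), a shared per-gene factor gives cross-genotype persistence
  (latent correlation 0.6 — most genes keep their status, as the pattern
  taxonomy requires to be non-degenerate) and a shared per-pair factor
  gives pair co-occurrence (latent correlation 0.5).
* **Peaks** — each methylated gene×genotype gets one peak; the summit's
  segment is drawn from `segment_probs` (default (0.02, 0.20, 0.15,
  0.61, 0.02), stopC-dominant), the summit uniform within the segment,
  the width uniform in 100–400 nt (fragment scale).
* **Coverage** — input is per-base Poisson at `depth` (default 30×)
  scaled by the gene's expression weight; IP multiplies the rate by a
  Gaussian bump peaking at `ip_enrichment` (default 4×) at the summit —
  fragment pileups in real MeRIP data peak at the modified site, and a
  flat-top alternative would make summit positions unrecoverable in
  principle. Replicates differ only by Poisson noise.
* **Counts** — negative binomial (dispersion 0.1) around library-scaled
  means from log-normal expression (ln-mean 3, ln-sd 1); polyploid-
  specific DE effects (15% of genes, |log₂FC| = 2, balanced signs); an
  optional coupling knob forces m⁶A-gaining genes up in the polyploid.
* **Epigenomic marks** — H3K4me3/H3K27ac as Gaussian bumps at TSS
  (amplitudes 3/2.5, σ = 200 nt) and at m⁶A peak centers (amplitude 2);
  H3K27me3 flat with a mild gene-body elevation; a CX-style cytosine
  report every 10 bp (CG/CHG/CHH baselines 0.6/0.3/0.1, binomial depth
  20) with a 0.3-deep Gaussian dip (σ = 300 nt) around peak centers.
* **CDS pairs** — an ancestral stop-free CDS is mutated with
  substitution-count quotas S·Ks (synonymous) and N·Ka (non-synonymous),
  Ka = ω·Ks, ω set per class (singleton 0.18, duplicate 0.15; IM 0.12 <
  DM 0.16 < NM 0.18 — conserved pairs under stronger purifying
  selection); the Jukes–Cantor correction in the estimator is the exact
  inverse of this planting process, and mean ω recovery is within ±0.01
  at 200 pairs × 300 codons. Ks targets are restricted to (0, 1], where
  the correction cannot saturate.

Every output is byte-identical for an identical configuration (all
randomness flows through named `numpy` generator streams keyed by the
seed and stage).

### What passing tests do and do not show

Recovery on this generator demonstrates that the estimators invert the
planted models at realistic effect sizes and depths: it does not
demonstrate robustness to mappability artifacts, fragment-length biases,
antibody efficiency differences between libraries, isoform mixtures, or
overdispersed coverage — none of which are simulated. Called-peak
summits carry ±50–75 nt jitter from the 50-nt window grid, so
segment-composition estimates from called peaks are systematically
blurrier than from planted summits; the pipeline-level check is
therefore dominance of the stopC segment, while the ±0.03
segment-probability recovery is established on planted summits.

## Problem sizes and numerical choices

The default test-suite and report sizes are 100–150 genes per subgenome,
3 replicates, 30× depth — chosen so the full pipeline and the whole
suite run comfortably on a single CPU while keeping ≥ 100 pairs per
omega class and ≥ 300 consensus peaks in play. Tolerances mirror the
sampling error at these sizes (e.g. ±0.03 on proportions at ~2000 genes,
±0.03 on mean ω at 200 pairs). Ties in the minimal-p window break
5′-most; empty strata are reported with n = 0 and excluded from tests;
segments of zero aggregate length yield missing enrichment rather than
zero; constant tracks yield missing correlations.
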