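# Methods

## Scope and model of the data

`aluedit` analyzes paired tumor–normal, reverse-stranded, paired-end
RNA-seq of a glioma cohort for two Alu-associated post-transcriptional
signals: A-to-I RNA editing and circular-RNA (circRNA) expression.
Inosine base-pairs like guanosine, so an A-to-I event appears in
sequencing as an A>G mismatch on the transcribed strand; on the genome's
forward strand a site in a gene transcribed from `-` therefore shows
T>C. Back-splicing — a downstream splice donor joining an upstream
acceptor — produces circRNA and is observed as back-splice junction
(BSJ) reads. Both processes concentrate around inverted Alu repeat
pairs, which fold into the double-stranded RNA that ADAR enzymes edit
and that promotes back-splicing; the analyses therefore center on Alu
annotation.

## Editing-site calling

Read-level exclusions, applied independently (any one suffices to drop
a read):

1. PCR-duplicate flag set (duplicate marking is consumed, not
   performed);
2. multi-mapped, signalled by an alignment-occupancy tag (`NH` > 1)
   and/or a mapping quality below the aligner's unique-mapping value
   (255 in the STAR dialect used by the simulator) — which signal is
   authoritative is configurable because aligner conventions differ;
3. total clipped length (soft + hard, both ends) ≥ 5 nt;
4. total nucleotides inside maximal homopolymer runs (≥ 4 identical
   bases) > 10 nt, computed on the read's own sequence — exactly 10 nt
   passes, 11 fails;
5. any insertion or deletion in the alignment.

Site-level cascade on the surviving reads: a base contributes to the
pileup only with Phred quality strictly greater than 20. For every
position with at least one quality-passing mismatch:

- **positional filter** — drop the site when more than half of its
  mismatch-carrying reads see the mismatch within 5 nt of either read
  end (1-based distance in read coordinates; the terminal base has
  distance 1, so the five outermost bases on each side count as
  end-proximal);
- **major-allele rule** — with a single alternative allele the rule
  does not apply; with several, one allele must have ≥ 5 reads and
  strictly more than twice the reads of every other alternative;
- **call threshold** — the major alternative needs ≥ 3 reads;
- **SNP exclusion** — positions present in the common-SNP catalog are
  removed, except records carrying the configurable INFO flag that
  marks cDNA-template discoveries (those entries in dbSNP are largely
  RNA-editing sites mis-deposited as DNA variants, so excluding them
  would discard true signal);
- **strand and class** — each quality-passing read votes for a
  transcribed strand (reverse-stranded protocol: mate 2's genome
  strand, mate 1's opposite); the site takes the majority, exact ties
  are dropped with a logged reason. On a `-` site both alleles are
  complemented, mapping the 12 genomic substitution classes onto
  transcript-strand classes (genomic T>C on `-` → A>G).

The editing level is alt/(ref+alt) over quality-passing reads, i.e. the
inosine-supporting fraction of adenosine-or-inosine-supporting reads.

Across samples, a site is kept only when every sample that called it
agrees on class and strand, and the calls span at least two distinct
patients (either tissue counts). This consolidation runs jointly over
all samples, before any per-pathology analysis, and is idempotent.
Overlapping mates of one fragment are counted independently by default
(a config switch collapses them to one observation); the field has no
consensus here and the simulator's fragments rarely overlap.

## Beta-binomial differential testing

For a unit (an editing site, or a gene's junction counts) with
successes k_i of trials n_i per sample, the model is beta-binomial with
mean mu_i = logistic(x_i'beta) and a single intraclass correlation rho
shared within the unit: the Beta parameters are a_i = mu_i(1-rho)/rho,
b_i = (1-mu_i)(1-rho)/rho, so rho → 0 recovers the binomial and rho
captures extra-binomial variability across samples. The design is an
intercept, a tumor indicator and fixed-effect patient indicators
(first patient as reference) — the minimal faithful encoding of
"patient as covariate" in a paired design.

`fit_bb_regression` maximizes the joint likelihood (L-BFGS-B, fixed
start: intercept at the logit of the pooled rate, other coefficients 0,
rho = 0.01, rho bounded in [1e-6, 1-1e-6]), and `lrt_condition` refers
twice the log-likelihood difference to chi-square(1). Both are exposed
and tested as primitives. However, with one tumor and one normal
observation per patient the patient dummies leave ~2 observations per
nuisance parameter, and joint ML underestimates rho severely (observed
~4-fold in simulation); the chi-square LRT is then anticonservative
(empirical type-I error 0.10–0.23 at nominal 0.05 in null
simulations). The pipeline's per-unit test (`differential_test`)
therefore uses a quasi-likelihood form of the same model:

1. fit the full mean model at a provisional rho;
2. estimate rho from the degrees-of-freedom-corrected Pearson moment
   equation sum_i r_i^2 / (1 + (n_i - 1) rho) = N - p, with r_i^2 the
   squared Pearson residual under the binomial variance — the N - p
   target undoes the ML bias (two alternating iterations);
3. refit full and reduced mean models at the fixed rho and refer twice
   the log-likelihood ratio to F(1, N - p_full), the residual-df
   reference familiar from quasi-likelihood testing in count-based
   genomics; chi-square(1) is the fallback when no residual df remain.

In null simulations spanning 4–20 patients, rho 0–0.2 and 30–100
trials this keeps the empirical type-I error between about 0.003 and
0.07 at nominal 0.05, while power at a planted level shift of −0.3
(10 patients, 50 trials) remains essentially 1. The cost is
conservatism at very small cohorts: with 3 patients the residual df is
1 and the F reference is heavy-tailed, so such pathologies yield few
or no significant units — consistent with excluding the 2-patient
pathology from testing altogether (the pipeline default skips
pathologies with fewer than 3 patients).

Multiple testing uses Benjamini–Hochberg within each pathology;
significance is FDR-adjusted p strictly below 0.05. Degenerate units
(k identically 0 or identically n) are reported with p = 1 rather than
dropped. Per-pathology test sets contain exactly the consolidated
sites called in both tissues of every patient of that pathology.

## Alu Editing Index

The AEI of a sample is 100 × (sum of edited-base reads) / (sum of
edited + unedited reads) over every reference adenosine on the
transcribed strand inside Alu intervals — on `+` that is G/(A+G), on
`-` C/(T+C) in genomic bases. It equals the coverage-weighted mean of
per-position editing levels, exactly. The transcribed strand per
position comes from the same read-vote machinery as site calling;
positions with tied votes or no informative coverage contribute
nothing, and a sample with zero informative reads is flagged undefined
rather than given 0.

## circRNA expression rate

Per gene and sample, the circRNA expression rate is BSJ/(BSJ + linear
junction reads), with the gene's total annotated splice-junction reads
as the linear denominator. A gene enters differential testing within a
pathology only if its maximum BSJ count over that pathology's samples
is strictly greater than 3. Rate testing reuses the beta-binomial
machinery (k = BSJ, n = BSJ + linear). Gene-level association between
a circRNA signature (any BSJ read in any sample) and Alu content (any
Alu interval intersecting the gene body) is a two-sided Fisher exact
test on the 2×2 table; the overlap between differentially-edited and
differentially-circularized gene sets is a Fisher test against an
explicit expressed-gene universe. For flanking-intron co-localization,
only exonic circRNAs are considered and "flanking" means the single
intron genomically adjacent to the back-splice acceptor (upstream) or
donor (downstream); a gene counts when at least one
differentially-edited site falls in such an intron for any of its
circRNAs. The contrast of editing deltas between genes with and
without decreased circRNA rates is a two-sided two-sample KS test.

## Synthetic cohort generator

The generator emulates the study design: 41 patients by default
(O2:6, O3:9, A2:4, A3:5, A4:2, GBM:15), one tumor and one neurotypical
sample each. The genome is one chromosome of three-exon genes with
alternating strands (exons 250 nt, introns 700 nt, 300 nt spacers);
Alu-subfamily intervals (300 nt, named AluSx/AluY/AluJb/AluSq2) sit
inside introns of a configurable fraction of genes, and each gene
carries one 6 nt reference homopolymer run (long enough to exercise
run detection, short enough not to trip the read filter by itself).

Editing sites are planted at adenosines (transcribed strand) inside
intronic Alus. Per-site baseline levels are drawn from Beta(2, 6)
(mean 0.25, the right order for Alu sites) truncated to a configurable
range; tumor samples shift the level by a per-pathology delta on the
raw [0,1] scale and clamp. The default deltas are the per-pathology
mean differences of the emulated design (O2 +0.04, O3 −0.08, A2 −0.30,
A3 −0.19, GBM −0.07); A4 is never tested there (n = 2), so its
generator default (−0.15) is an interpolation between the neighboring
astrocytoma grades. Fragments are one RNA molecule each: the edit
state at every covered variant is drawn once per fragment and shared
by both mates, with per-sample site-level probabilities drawn
Beta-binomially around the true level (intraclass correlation
`site_dispersion`, default 0.05). Germline SNPs are planted in gene
bodies at DNA-like fractions (heterozygous 0.5 / homozygous 1.0 per
patient) and written to the catalog VCF, so only the catalog exclusion
can remove them — an end-to-end specificity probe. Every 10th editing
site is additionally written to the catalog flagged as cDNA-derived,
probing the exemption path. Read pathologies are planted per fragment
at configured fractions: flagged PCR-duplicate copies, multi-mappers
(MAPQ 1 + NH:2), 5 nt soft-clips, 1 nt insertions, and homopolymer
stretches totaling 12 nt. Junction tables draw per-gene total depth
Poisson(`junction_depth_mean`) and BSJ counts beta-binomially around
the sample's true rate (default normal rate 0.10; genes without a
circRNA signature have rate 0); circRNA coordinate records place one
exonic circRNA over each gene's middle exon so both flanking introns
exist.

Everything is deterministic in the seed (per-sample substreams from a
`SeedSequence`, so cohort composition does not perturb other samples).
What the generator does not emulate — and what green tests therefore
do not certify on real data: realistic expression heterogeneity and
spliced alignments (reads are genomic fragments), instrument error
profiles and quality-score variation (all bases Q37, errors uniform),
hyper-edited reads that fail alignment, structural variation, and
annotation errors. The filters facing those read classes are exercised
structurally (planted pathologies, boundary unit tests, a naive-oracle
equivalence), not distributionally.

## Numerical and procedural choices

- Coordinates are 0-based half-open internally; 1-based only at
  VCF/GTF/output-table boundaries.
- `bb_loglik` evaluates through `betaln`/`gammaln`; below rho = 1e-9
  it switches to the explicit binomial form, and the mean is kept off
  {0,1} by clipping at 1e-12 so Beta parameters stay positive while
  the optimizer explores extreme coefficients.
- Fisher exact and KS statistics come from scipy; BH from statsmodels;
  the test suite cross-checks Fisher against an exhaustive
  hypergeometric enumeration and BH against a sorting step-up oracle.
- Strand ties, degenerate margins, zero-coverage AEI and empty test
  sets all resolve to explicit flagged outcomes, never silent drops.
- Problem sizes in the test and acceptance runs are desk-scale by
  design: cohorts of 4–12 patients, 8–12 genes, 50–200 planted sites,
  30–60× coverage, 500-replicate null calibrations. The analysis
  scripts default to the full 41-patient design.

## Known limitations

- Fixed-effect patient dummies with paired data make the plain ML LRT
  unusable without the quasi-likelihood correction described above; a
  random-effects model was deliberately left out of scope.
- The per-site strand vote can be diluted at loci covered by
  overlapping transcription on both strands; the simulator's gene
  spacing avoids this except at gene edges.
- The AEI here is restricted to positions with resolvable transcribed
  strand; indexes defined over all Alu adenosines regardless of strand
  evidence will differ on real data.
- The flanking-intron definition is the single adjacent intron; wider
  windows would need a different choice.
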