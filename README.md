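# aluedit

Strand-aware A-to-I RNA-editing calling and circular-RNA expression
analysis for paired tumor–normal stranded RNA-seq cohorts, built around
the glioma setting: oligodendroglioma and astrocytoma grades plus GBM,
with one tumor and one neurotypical sample per patient.

Inosine reads as guanosine, so A-to-I editing appears as A>G mismatches
on the transcribed strand; back-splice junction (BSJ) reads mark
circular RNA. Both signals cluster around inverted Alu repeats. The
package provides:

- **read filters + pileup** — the five-rule read exclusion cascade
  (PCR duplicates, multi-mappers, ≥5 nt clipped, >10 nt of homopolymer
  content, any indel) and a quality-aware mismatch pileup (base quality
  strictly > 20);
- **editing caller** — end-proximity and major-allele site filters,
  ≥3 alternative reads, common-SNP exclusion with a cDNA-template
  exemption, transcribed-strand typing of the 12 substitution classes
  by read vote, and cross-sample consolidation (consistent type/strand,
  ≥2 patients);
- **beta-binomial testing** — editing levels k/n per site (and BSJ
  rates per gene) modeled as beta-binomial with logit mean
  `condition + patient` and shared intraclass correlation ρ; the
  per-unit condition test uses a degrees-of-freedom–corrected moment
  estimate of ρ and an F(1, N−p) reference (see `docs/methods.md` for
  why the naive chi-square LRT is anticonservative here), with
  Benjamini–Hochberg FDR < 0.05 within each pathology;
- **summaries** — the Alu Editing Index (coverage-weighted percent
  editing over transcribed-strand adenosines in Alu), A>G sites and BSJ
  reads per million mapped reads, cumulative delta distributions with
  paired t/Wilcoxon tests, Fisher tests for Alu association and
  editing×circRNA gene overlap, flanking-intron co-localization, and a
  KS contrast of editing deltas between gene groups;
- **synthetic cohort generator** — a first-class module producing
  reference + GTF + RepeatMasker-style BED + SNP VCF + duplicate-marked
  BAMs + junction tables + sample sheet with a full truth table, so
  every stage is testable without external data.

## Worked example

Simulate a small cohort and call one sample from the shell:

```sh
aluedit simulate --out cohort --seed 5 --patients 2 --genes 2 --sites 10
aluedit call --bam cohort/bams/P01T.bam --ref cohort/reference.fa \
    --snp-vcf cohort/snps.vcf --repeats-bed cohort/repeats.bed \
    --genes-gtf cohort/genes.gtf --out calls.tsv
# cohort written to cohort (4 samples)
# P01T: 9 calls from 1822/2676 kept reads
```

The calls are planted sites (one of the ten has too low a level in
this sample to clear the 3-alternative-read threshold): `calls.tsv`
lists each with its transcribed strand, class `A>G`, read counts and
editing level, e.g.

```
chrom  pos_1based  strand  variant_class  ref_reads  alt_reads  editing_level  in_alu  in_intron  gene_id
chr1   600         +       A>G            37         14         0.2745         True    True       G001
chr1   603         +       A>G            20         32         0.6154         True    True       G001
```

The `analysis/` scripts run the full study-shaped workflow (41
patients by default; artifacts under `scratch/`, tables under
`results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_call_editing_sites.py
python analysis/03_differential_editing.py
python analysis/04_circular_rna.py
python analysis/05_editing_circrna_overlap.py
```

On the default seed this prints, among other things:

```
planted-site recovery: 100.0%
planted SNPs leaking through: 0
A>G fraction among consolidated calls: 100.00%

differential editing per pathology:
pathology  n_sites_tested  n_significant_fdr05  mean_level_delta ...
       A2               6                    3           -0.2958
       A3              16                    0           -0.1484
      GBM              27                    4           -0.0577
       O2              58                    0            0.0325
       O3              36                    0           -0.0897

global BSJ/M, paired log10 t test over 41 patients: t = -5.63, p = 1.57e-06
Alu association: 81.8% of circRNA genes vs 11.1% of other genes carry Alu
```

Read: every planted editing site was recovered and no planted germline
SNP survived the catalog exclusion; the mean editing-level change per
pathology tracks the planted per-pathology shifts (strong loss in
grade-2 astrocytoma, slight gain in grade-2 oligodendroglioma, the
pathology that stays centered); circRNA levels drop globally in tumors
and the circRNA signature associates strongly with Alu content.

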