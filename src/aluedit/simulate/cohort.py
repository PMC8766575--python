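"""One-call cohort simulation: genome + truth + BAMs + tables on disk."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aluedit import io
from aluedit.simulate.genome import GenomeBundle, simulate_genome
from aluedit.simulate.junctions import circ_coordinates, simulate_junction_counts
from aluedit.simulate.reads import simulate_alignments
from aluedit.simulate.truth import TruthTable, make_truth


@dataclass
class CohortBundle:
    """Paths and in-memory objects of one simulated cohort."""

    config: object
    genome: GenomeBundle
    truth: TruthTable
    fasta: Path
    repeats_bed: Path
    genes_gtf: Path
    snp_vcf: Path
    sample_sheet: Path
    junctions_tsv: Path
    circ_coords_tsv: Path
    bam_table: pd.DataFrame  # sample_id, bam, n_mapped_reads


def simulate_cohort(config, outdir: str | Path, with_alignments: bool = True) -> CohortBundle:
    """Generate and write every artifact of a synthetic cohort.

    Deterministic in ``config.seed``. ``with_alignments=False`` skips
    BAM generation for junction-only analyses.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = simulate_genome(config)
    truth = make_truth(config, genome)

    paths = io.write_genome_bundle(genome, outdir)
    snp_vcf = outdir / "snps.vcf"
    io.write_snp_vcf(
        snp_vcf, truth.catalog, contigs={genome.chrom: len(genome.sequence)}
    )
    sheet_path = outdir / "sample_sheet.tsv"
    io.write_sample_sheet(sheet_path, truth.sample_sheet)

    junctions = simulate_junction_counts(config, truth)
    junctions_tsv = outdir / "junctions.tsv"
    junctions.to_csv(junctions_tsv, sep="\t", index=False)
    circ_tsv = outdir / "circ_coords.tsv"
    circ_coordinates(genome).to_csv(circ_tsv, sep="\t", index=False)

    truth.write(outdir / "truth")

    if with_alignments:
        bam_table = simulate_alignments(config, genome, truth, outdir / "bams")
    else:
        bam_table = pd.DataFrame(columns=["sample_id", "bam", "n_mapped_reads"])
    bam_table.to_csv(outdir / "bam_table.tsv", sep="\t", index=False)

    return CohortBundle(
        config=config,
        genome=genome,
        truth=truth,
        fasta=paths["fasta"],
        repeats_bed=paths["repeats"],
        genes_gtf=paths["genes"],
        snp_vcf=snp_vcf,
        sample_sheet=sheet_path,
        junctions_tsv=junctions_tsv,
        circ_coords_tsv=circ_tsv,
        bam_table=bam_table,
    )
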