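"""End-to-end orchestration: call -> consolidate -> test -> report.

Stages run in a fixed order with a manifest recording the configuration
hash, applied thresholds and per-stage row counts; rerunning with the
same inputs and configuration reproduces identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd

from aluedit import __version__, circrna, editing_analysis, editing_caller, io
from aluedit.config import PipelineConfig
from aluedit.read_filters import build_pileup, evaluate_read, read_bam_records

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Pre-flight checks: files exist, contig names agree, the sample
    sheet is complete and every patient has both tissues."""
    rep = ValidationReport()
    required = {
        "sample_sheet": config.sample_sheet,
        "reference_fasta": config.reference_fasta,
    }
    for name, path in required.items():
        if path is None or not Path(path).exists():
            rep.failures.append(f"missing required input: {name}")
    if rep.failures:
        return rep

    import pyfaidx

    fasta = pyfaidx.Fasta(str(config.reference_fasta))
    contigs = set(fasta.keys())
    lengths = {c: len(fasta[c]) for c in contigs}

    sheet = io.read_sample_sheet(config.sample_sheet)
    for col in ("sample_id", "patient_id", "condition", "pathology"):
        if sheet[col].isna().any():
            rep.failures.append(f"sample sheet has empty values in {col}")
    for patient, grp in sheet.groupby("patient_id"):
        conditions = set(grp.condition)
        if conditions != {"tumor", "normal"}:
            rep.failures.append(
                f"patient {patient} lacks a paired design (has {sorted(conditions)})"
            )

    if config.repeats_bed and Path(config.repeats_bed).exists():
        for r in io.read_repeats_bed(config.repeats_bed):
            if r.chrom not in contigs:
                rep.failures.append(f"BED contig {r.chrom} absent from FASTA")
                break
            if not 0 <= r.start < r.end <= lengths[r.chrom]:
                rep.failures.append(f"BED interval out of bounds: {r.chrom}:{r.start}-{r.end}")
                break
    if config.genes_gtf and Path(config.genes_gtf).exists():
        for g in io.read_genes_gtf(config.genes_gtf):
            if g.chrom not in contigs:
                rep.failures.append(f"GTF contig {g.chrom} absent from FASTA")
                break
    if config.snp_vcf and Path(config.snp_vcf).exists():
        for chrom, _pos in io.load_snp_catalog(config.snp_vcf, config.cdna_info_flag):
            if chrom not in contigs:
                rep.failures.append(f"VCF contig {chrom} absent from FASTA")
            break
    if config.bam_dir:
        import pysam

        for sample_id in sheet.sample_id:
            bam = Path(config.bam_dir) / f"{sample_id}.bam"
            if not bam.exists():
                rep.failures.append(f"missing BAM for sample {sample_id}")
                continue
            with pysam.AlignmentFile(str(bam)) as fh:
                if set(fh.references) - contigs:
                    rep.failures.append(f"BAM contigs of {sample_id} absent from FASTA")
    return rep


def call_sample_bam(
    bam_path: str | Path,
    reference: str,
    chrom: str,
    snp_catalog: set[tuple[str, int]],
    sample_id: str,
    config: PipelineConfig,
):
    """Filter reads, build the pileup and call sites for one BAM.

    Returns (calls, pileup, n_mapped_reads, n_kept_reads).
    """
    records = read_bam_records(bam_path, config.multimap_mode, config.unique_mapq)
    kept = [r for r in records if evaluate_read(r).kept]
    pileup = build_pileup(
        kept,
        reference,
        min_qual=config.min_qual,
        strandedness=config.strandedness,
        dedup_overlapping_mates=config.dedup_overlapping_mates,
    )
    calls = editing_caller.call_sample(
        pileup,
        chrom,
        snp_catalog,
        sample_id,
        min_alt_reads=config.min_alt_reads,
        end_distance=config.end_distance,
        major_allele_min=config.major_allele_min,
        major_allele_ratio=config.major_allele_ratio,
    )
    return calls, pileup, len(records), len(kept)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    if config.sample_sheet is None or not Path(config.sample_sheet).exists():
        raise FileNotFoundError("sample sheet missing — nothing was run")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, value in config.threshold_dict().items():
        logger.info("threshold %s = %s", name, value)

    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "thresholds": config.threshold_dict(),
        "stages": {},
    }
    sheet = io.read_sample_sheet(config.sample_sheet)

    pathologies = [
        p
        for p, grp in sheet.groupby("pathology", sort=True)
        if config.include_small_pathologies
        or grp.patient_id.nunique() >= config.min_patients_per_pathology
    ]
    skipped = sorted(set(sheet.pathology) - set(pathologies))
    if skipped:
        logger.info("pathologies skipped for testing (too few patients): %s", skipped)
    manifest["pathologies_tested"] = pathologies
    manifest["pathologies_skipped"] = skipped

    # ---------------- editing side (needs BAMs) ----------------
    all_calls = []
    aei_rows = []
    spm_rows = []
    mapped_totals = {}
    consolidated = []
    if config.bam_dir is not None:
        fasta = io.load_reference(config.reference_fasta)
        chrom = list(fasta.keys())[0]
        reference = str(fasta[chrom][:])
        snp_catalog = (
            io.load_snp_catalog(config.snp_vcf, config.cdna_info_flag)
            if config.snp_vcf
            else set()
        )
        repeats = io.read_repeats_bed(config.repeats_bed) if config.repeats_bed else []
        genes = io.read_genes_gtf(config.genes_gtf) if config.genes_gtf else []

        for sample_id in sheet.sample_id:
            bam = Path(config.bam_dir) / f"{sample_id}.bam"
            calls, pileup, n_mapped, n_kept = call_sample_bam(
                bam, reference, chrom, snp_catalog, sample_id, config
            )
            all_calls.extend(calls)
            mapped_totals[sample_id] = n_mapped
            spm_rows.append(
                {
                    "sample_id": sample_id,
                    "n_mapped_reads": n_mapped,
                    "n_kept_reads": n_kept,
                    "n_calls": len(calls),
                    "ag_sites_per_million": editing_caller.sites_per_million(
                        calls, n_mapped
                    ),
                }
            )
            aei = editing_analysis.compute_aei(pileup, repeats, reference, sample_id)
            aei_rows.append(
                {
                    "sample_id": sample_id,
                    "edited_read_total": aei.edited_read_total,
                    "informative_read_total": aei.informative_read_total,
                    "aei_percent": aei.aei,
                }
            )

        editing_caller.annotate_sites(all_calls, repeats, genes)
        calls_frame = editing_caller.calls_to_frame(all_calls)
        calls_frame.to_csv(outdir / "calls_per_sample.tsv", sep="\t", index=False)
        consolidated = editing_caller.consolidate(all_calls, sheet, config.min_patients)
        editing_caller.annotate_sites(consolidated, repeats, genes)
        cons_frame = editing_caller.consolidated_to_frame(consolidated)
        cons_frame.to_csv(outdir / "consolidated_sites.tsv", sep="\t", index=False)
        pd.DataFrame(spm_rows).to_csv(outdir / "sites_per_million.tsv", sep="\t", index=False)
        pd.DataFrame(aei_rows).to_csv(outdir / "aei.tsv", sep="\t", index=False)
        manifest["stages"]["calls"] = len(all_calls)
        manifest["stages"]["consolidated_sites"] = len(consolidated)

        diff_frames = []
        for pathology in pathologies:
            test_set = editing_analysis.select_test_sites(consolidated, sheet, pathology)
            if not test_set.site_ids:
                logger.info("pathology %s: no testable sites", pathology)
                continue
            result = editing_analysis.diff_editing(test_set, fdr=config.fdr)
            diff_frames.append(result)
            summary = editing_analysis.delta_summary(result, pathology)
            summary.ecdf.assign(pathology=pathology).to_csv(
                outdir / f"editing_delta_cdf_{pathology}.tsv", sep="\t", index=False
            )
        diff_editing_frame = (
            pd.concat(diff_frames, ignore_index=True) if diff_frames else pd.DataFrame()
        )
        diff_editing_frame.to_csv(outdir / "diff_editing.tsv", sep="\t", index=False)
        manifest["stages"]["diff_editing_tests"] = len(diff_editing_frame)

    # ---------------- circRNA side (junction tables) ----------------
    if config.junctions_tsv is not None:
        junctions = io.read_junction_table(config.junctions_tsv)
        if mapped_totals:
            totals = pd.Series(mapped_totals)
            gl = circrna.global_circ_level(junctions, totals)
            gl.rename("bsj_per_million").to_csv(outdir / "global_circ_level.tsv", sep="\t")
        circ_frames = []
        for pathology in pathologies:
            result = circrna.diff_circ_rate(
                junctions, sheet, pathology, min_bsj=config.min_bsj, fdr=config.fdr
            )
            circ_frames.append(result)
        diff_circ_frame = (
            pd.concat(circ_frames, ignore_index=True) if circ_frames else pd.DataFrame()
        )
        diff_circ_frame.to_csv(outdir / "diff_circ.tsv", sep="\t", index=False)
        manifest["stages"]["diff_circ_tests"] = len(diff_circ_frame)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
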