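"""Readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open everywhere; conversion to
1-based happens only at the VCF/GTF boundaries. BAM access goes through
pysam, FASTA through pyfaidx, VCF through pysam.VariantFile.
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import pandas as pd
import pysam

from aluedit.simulate.genome import GeneModel, GenomeBundle, RepeatInterval


# --------------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, chrom: str, sequence: str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{chrom}\n")
        for line in textwrap.wrap(sequence, 60):
            fh.write(line + "\n")
    pysam.faidx(str(path))


# ----------------------------------------------------------------------- BED

def write_repeats_bed(path: str | Path, repeats: list[RepeatInterval]) -> None:
    """BED6, 0-based half-open, subfamily name in column 4."""
    with Path(path).open("w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


def read_repeats_bed(path: str | Path) -> list[RepeatInterval]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        RepeatInterval(r.chrom, int(r.start), int(r.end), r.name, r.strand)
        for r in df.itertuples()
    ]


# ----------------------------------------------------------------------- GTF

def write_genes_gtf(path: str | Path, genes: list[GeneModel]) -> None:
    """Minimal GENCODE-dialect GTF (gene/transcript/exon), 1-based inclusive."""
    with Path(path).open("w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{tattrs}\n"
            )
            for es, ee in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{tattrs}\n"
                )


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Parse gene models back from the GTF's exon records."""
    import re

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    gene_re = re.compile(r'gene_id "([^"]+)"')
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = gene_re.search(f[8])
            if not m:
                raise ValueError(f"GTF exon without gene_id: {line!r}")
            gid = m.group(1)
            exons.setdefault(gid, []).append((int(f[3]) - 1, int(f[4])))
            meta[gid] = (f[0], f[6])
    genes = []
    for gid, ex in exons.items():
        chrom, strand = meta[gid]
        genes.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, exons=tuple(sorted(ex)))
        )
    genes.sort(key=lambda g: g.start)
    return genes


# ----------------------------------------------------------------------- VCF

def write_snp_vcf(
    path: str | Path,
    catalog: pd.DataFrame,
    cdna_flag: str = "CDNA",
    contigs: dict[str, int] | None = None,
) -> None:
    """Common-SNP catalog as VCF (1-based); cDNA-derived records carry an
    INFO flag so the caller can exempt them from exclusion."""
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            f'##INFO=<ID={cdna_flag},Number=0,Type=Flag,'
            'Description="Variant discovered using a cDNA template">\n'
        )
        fh.write('##INFO=<ID=COMMON,Number=0,Type=Flag,Description="Common variant">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in catalog.itertuples():
            info = f"COMMON;{cdna_flag}" if r.cdna else "COMMON"
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.id}\t{r.ref}\t{r.alt}\t.\t.\t{info}\n")


def load_snp_catalog(path: str | Path, cdna_flag: str = "CDNA") -> set[tuple[str, int]]:
    """Positions (chrom, 0-based) to exclude: catalog records without the
    cDNA-template flag."""
    excluded: set[tuple[str, int]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if cdna_flag in rec.info:
                continue
            excluded.add((rec.chrom, rec.pos - 1))
    return excluded


# ----------------------------------------------------------------------- TSV

def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "condition", "pathology"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def read_junction_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample_id", "backsplice_reads", "linear_junction_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    return df


def load_reference(path: str | Path):
    import pyfaidx

    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_genome_bundle(genome: GenomeBundle, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + BED + GTF for one bundle; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fa",
        "repeats": outdir / "repeats.bed",
        "genes": outdir / "genes.gtf",
    }
    write_fasta(paths["fasta"], genome.chrom, genome.sequence)
    write_repeats_bed(paths["repeats"], genome.repeats)
    write_genes_gtf(paths["genes"], genome.genes)
    return paths
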