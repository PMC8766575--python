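"""Ground-truth planting: editing sites, germline SNPs, circRNA rates.

The truth table is what every downstream test compares against: which
positions carry true A-to-I events (and at what per-sample level),
which carry DNA variants that only the SNP-catalog exclusion should
remove, and which genes carry which true back-splice rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aluedit.simulate.genome import ALU_LENGTH, GenomeBundle

#: every k-th planted editing site also appears in the SNP catalog with
#: the cDNA-derived flag set — the caller must NOT exclude these
CDNA_CATALOG_EVERY = 10


@dataclass
class TruthTable:
    """Planted ground truth for one simulated cohort.

    ``sites`` has one row per editing site (position 0-based, transcribed
    strand, variant class on that strand, Alu/intron membership, host
    gene); ``site_levels`` the per-sample true mean editing level;
    ``snps`` the planted DNA variants with per-patient zygosity;
    ``catalog`` the SNP-catalog records to serialize as VCF (including
    cDNA-flagged editing sites); ``circ_rates`` the per-gene, per-sample
    true back-splice rate; ``sample_sheet`` the cohort design.
    """

    sites: pd.DataFrame
    site_levels: pd.DataFrame
    snps: pd.DataFrame
    snp_genotypes: pd.DataFrame
    catalog: pd.DataFrame
    circ_rates: pd.DataFrame
    sample_sheet: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "sites",
            "site_levels",
            "snps",
            "snp_genotypes",
            "catalog",
            "circ_rates",
            "sample_sheet",
        ):
            getattr(self, name).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


def build_sample_sheet(config) -> pd.DataFrame:
    rows = []
    for i, pathology in enumerate(config.pathology_labels):
        patient = f"P{i + 1:02d}"
        for condition, suffix in (("tumor", "T"), ("normal", "N")):
            rows.append(
                {
                    "sample_id": f"{patient}{suffix}",
                    "patient_id": patient,
                    "condition": condition,
                    "pathology": pathology,
                }
            )
    return pd.DataFrame(rows)


def _truncated_beta(rng: np.random.Generator, a: float, b: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.beta(a, b)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def make_truth(config, genome: GenomeBundle, rng: np.random.Generator | None = None) -> TruthTable:
    """Plant editing sites and SNPs into the genome and tabulate truth.

    Mutates ``genome.sequence`` so every editing site has an adenosine on
    its transcribed strand (A on '+', T on '-'). Editing sites live in
    intronic Alu intervals; SNPs anywhere else in gene bodies. Raises
    ``ValueError`` when the requested sites cannot fit.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sample_sheet = build_sample_sheet(config)

    n_alus = len(genome.repeats)
    if config.n_editing_sites > 0 and n_alus == 0:
        raise ValueError("cannot plant editing sites without Alu intervals")
    if n_alus:
        per_alu = -(-config.n_editing_sites // n_alus)  # ceil
        if per_alu > (ALU_LENGTH - 10) // 3:
            raise ValueError(
                f"{config.n_editing_sites} editing sites do not fit in {n_alus} Alu intervals"
            )

    gene_by_pos = []
    for g in genome.genes:
        gene_by_pos.append((g.start, g.end, g))

    def host_gene(pos: int):
        for s, e, g in gene_by_pos:
            if s <= pos < e:
                return g
        return None

    arr = np.frombuffer(genome.sequence.encode(), dtype="S1").copy()
    taken: set[int] = set()
    lo, hi = config.editing_level_range

    # --- editing sites: round-robin over Alu intervals ---
    site_rows = []
    for i in range(config.n_editing_sites):
        alu = genome.repeats[i % n_alus]
        for _ in range(200):
            pos = int(rng.integers(alu.start + 5, alu.end - 5))
            if all(abs(pos - t) > 2 for t in taken):
                break
        else:  # pragma: no cover - capacity pre-checked above
            raise ValueError("could not place editing site")
        taken.add(pos)
        gene = host_gene(pos)
        strand = alu.strand
        ref_genomic = "A" if strand == "+" else "T"
        alt_genomic = "G" if strand == "+" else "C"
        arr[pos] = ref_genomic.encode()
        site_rows.append(
            {
                "site_id": f"ES{i + 1:04d}",
                "chrom": genome.chrom,
                "pos": pos,
                "strand": strand,
                "ref_genomic": ref_genomic,
                "alt_genomic": alt_genomic,
                "variant_class": "A>G",
                "gene_id": gene.gene_id if gene else ".",
                "in_alu": True,
                "in_intron": True,
                "is_snp": False,
                "level_normal": _truncated_beta(rng, *config.editing_level_normal, lo, hi),
            }
        )
    sites = pd.DataFrame(
        site_rows,
        columns=[
            "site_id",
            "chrom",
            "pos",
            "strand",
            "ref_genomic",
            "alt_genomic",
            "variant_class",
            "gene_id",
            "in_alu",
            "in_intron",
            "is_snp",
            "level_normal",
        ],
    )

    # per-sample true mean level (tumor shifted on the level scale, clamped)
    level_rows = []
    for _, sam in sample_sheet.iterrows():
        delta = (
            config.editing_delta_tumor[sam.pathology] if sam.condition == "tumor" else 0.0
        )
        for _, site in sites.iterrows():
            level_rows.append(
                {
                    "site_id": site.site_id,
                    "sample_id": sam.sample_id,
                    "true_level": float(np.clip(site.level_normal + delta, 0.0, 1.0)),
                }
            )
    site_levels = pd.DataFrame(
        level_rows, columns=["site_id", "sample_id", "true_level"]
    )

    # --- germline SNPs: in gene bodies, disjoint from editing sites ---
    snp_rows = []
    geno_rows = []
    patients = sample_sheet.patient_id.unique()
    gene_positions = np.concatenate(
        [np.arange(g.start + 5, g.end - 5) for g in genome.genes]
    ) if genome.genes else np.array([], dtype=int)
    for j in range(config.n_snps):
        for _ in range(500):
            pos = int(rng.choice(gene_positions))
            if all(abs(pos - t) > 2 for t in taken):
                break
        else:
            raise ValueError("could not place SNP away from editing sites")
        taken.add(pos)
        ref = arr[pos].decode()
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        gene = host_gene(pos)
        snp_rows.append(
            {
                "snp_id": f"rs{j + 1:06d}",
                "chrom": genome.chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene_id": gene.gene_id if gene else ".",
            }
        )
        for patient in patients:
            geno_rows.append(
                {
                    "snp_id": f"rs{j + 1:06d}",
                    "patient_id": patient,
                    "genotype": "het" if rng.random() < 0.6 else "hom",
                }
            )
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "gene_id"])
    snp_genotypes = pd.DataFrame(geno_rows, columns=["snp_id", "patient_id", "genotype"])

    # --- SNP catalog (to be written as VCF): all common SNPs, plus every
    # k-th editing site flagged as a cDNA-template discovery ---
    cat_rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "id": r.snp_id,
            "ref": r.ref,
            "alt": r.alt,
            "cdna": False,
        }
        for r in snps.itertuples()
    ]
    for k, site in enumerate(sites.itertuples()):
        if (k + 1) % CDNA_CATALOG_EVERY == 0:
            cat_rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "id": f"rsE{k + 1:05d}",
                    "ref": site.ref_genomic,
                    "alt": site.alt_genomic,
                    "cdna": True,
                }
            )
    catalog = pd.DataFrame(
        cat_rows, columns=["chrom", "pos", "id", "ref", "alt", "cdna"]
    ).sort_values("pos", kind="stable").reset_index(drop=True)

    # --- circRNA truth rates: genes carry a circRNA signature with a
    # probability depending on Alu content (echoing the strong Alu
    # association of back-splicing); non-circ genes have rate 0 ---
    circ_rows = []
    gene_is_circ = {}
    for g in genome.genes:
        has_alu = any(g.start <= r.start < g.end for r in genome.repeats)
        p_circ = config.circ_prob_alu if has_alu else config.circ_prob_no_alu
        gene_is_circ[g.gene_id] = bool(rng.random() < p_circ)
    for _, sam in sample_sheet.iterrows():
        delta = config.circ_delta_tumor[sam.pathology] if sam.condition == "tumor" else 0.0
        rate = float(np.clip(config.circ_rate_normal + delta, 0.0, 1.0))
        for g in genome.genes:
            circ_rows.append(
                {
                    "gene_id": g.gene_id,
                    "sample_id": sam.sample_id,
                    "true_rate": rate if gene_is_circ[g.gene_id] else 0.0,
                }
            )
    circ_rates = pd.DataFrame(circ_rows, columns=["gene_id", "sample_id", "true_rate"])

    genome.sequence = arr.tobytes().decode()
    return TruthTable(
        sites=sites,
        site_levels=site_levels,
        snps=snps,
        snp_genotypes=snp_genotypes,
        catalog=catalog,
        circ_rates=circ_rates,
        sample_sheet=sample_sheet,
    )
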