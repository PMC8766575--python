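"""Per-gene back-splice / linear junction count tables.

Total junction depth per gene and sample is Poisson; the back-splice
share of it is beta-binomial around the sample's true circular-RNA
expression rate (tumor rates shifted by the configured per-pathology
delta and clamped to [0, 1]). Also emits exonic circRNA coordinates
(the middle exon of each gene) for flanking-intron analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from aluedit.simulate.genome import GenomeBundle
from aluedit.simulate.truth import TruthTable


def simulate_junction_counts(
    config,
    truth: TruthTable,
    rng: np.random.Generator | None = None,
    gene_deltas: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Junction counts per gene x sample.

    ``gene_deltas`` optionally overrides the tumor shift per gene
    (genes absent from it get the config's per-pathology delta),
    letting callers plant a mix of shifted and null genes.

    Returns columns: gene_id, sample_id, backsplice_reads,
    linear_junction_reads.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    rho = config.site_dispersion
    rows = []
    gene_ids = truth.circ_rates.gene_id.unique()
    sheet = truth.sample_sheet.set_index("sample_id")
    rate_of = {
        (r.gene_id, r.sample_id): r.true_rate for r in truth.circ_rates.itertuples()
    }
    normal_of = dict(
        truth.sample_sheet[truth.sample_sheet.condition == "normal"]
        .set_index("patient_id")
        .sample_id
    )
    for sample_id, sam in sheet.iterrows():
        for gene_id in gene_ids:
            rate = float(rate_of[(gene_id, sample_id)])
            if (
                gene_deltas is not None
                and gene_id in gene_deltas
                and sam.condition == "tumor"
            ):
                base = float(rate_of[(gene_id, normal_of[sam.patient_id])])
                rate = float(np.clip(base + gene_deltas[gene_id], 0.0, 1.0)) if base > 0 else 0.0
            depth = int(rng.poisson(config.junction_depth_mean))
            if depth == 0 or rate <= 0.0:
                bsj = 0
            elif rate >= 1.0:
                bsj = depth
            elif rho < 1e-9:
                bsj = int(rng.binomial(depth, rate))
            else:
                q = rng.beta(rate * (1 - rho) / rho, (1 - rate) * (1 - rho) / rho)
                bsj = int(rng.binomial(depth, q))
            rows.append(
                {
                    "gene_id": gene_id,
                    "sample_id": sample_id,
                    "backsplice_reads": bsj,
                    "linear_junction_reads": depth - bsj,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "sample_id", "backsplice_reads", "linear_junction_reads"],
    )


def circ_coordinates(genome: GenomeBundle) -> pd.DataFrame:
    """Exonic circRNA records: the middle exon of every gene.

    The back-splice acceptor is the exon's genomic start and the donor
    its genomic end, so both flanking introns exist within the gene.
    Columns: gene_id, chrom, circ_start, circ_end (0-based half-open).
    """
    rows = []
    for g in genome.genes:
        mid = g.exons[len(g.exons) // 2]
        rows.append(
            {"gene_id": g.gene_id, "chrom": g.chrom, "circ_start": mid[0], "circ_end": mid[1]}
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "circ_start", "circ_end"])
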