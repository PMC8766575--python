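#!/usr/bin/env python
"""Relate perturbed A-to-I editing to circRNA changes gene by gene.

From the pipeline outputs of 02: (1) the Fisher overlap between genes
with differentially-edited sites and genes with differential circRNA
rates, against the universe of genes with junction coverage; (2) the
fraction of overlap genes whose perturbed sites sit in circRNA-flanking
introns; (3) the KS comparison of editing deltas between sites in
genes with vs without decreased circRNA rates. Writes
results/overlap_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from aluedit import io
from aluedit.circrna import (
    delta_cdf_comparison,
    flanking_intron_colocalization,
    overlap_diff_genes,
)

ROOT = Path(__file__).resolve().parent.parent
PIPE = ROOT / "results" / "pipeline"
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    diff_editing = pd.read_csv(PIPE / "diff_editing.tsv", sep="\t")
    diff_circ = pd.read_csv(PIPE / "diff_circ.tsv", sep="\t")
    cons = pd.read_csv(PIPE / "consolidated_sites.tsv", sep="\t")
    junctions = pd.read_csv(COHORT / "junctions.tsv", sep="\t")

    site_gene = cons.drop_duplicates("pos_1based").set_index(
        cons.drop_duplicates("pos_1based").chrom
        + ":"
        + (cons.drop_duplicates("pos_1based").pos_1based - 1).astype(str)
    ).gene_id
    diff_editing = diff_editing.assign(gene_id=diff_editing.unit_id.map(site_gene))

    editing_genes = set(diff_editing[diff_editing.significant].gene_id.dropna())
    circ_genes = set(diff_circ[diff_circ.significant].unit_id)
    universe = set(junctions.gene_id)
    result = overlap_diff_genes(editing_genes, circ_genes, universe)
    print(f"genes with perturbed editing: {len(editing_genes)}; with perturbed "
          f"circRNA rate: {len(circ_genes)}; overlap {result['n_overlap']} "
          f"(Fisher p = {result['p_value']:.3g}, N = {len(universe)} genes)")

    genes = io.read_genes_gtf(COHORT / "genes.gtf")
    circ_coords = pd.read_csv(COHORT / "circ_coords.tsv", sep="\t")
    sig_sites = diff_editing[diff_editing.significant].copy()
    sig_sites["pos"] = sig_sites.unit_id.str.split(":").str[1].astype(int)
    table, fraction = flanking_intron_colocalization(
        sig_sites[["gene_id", "pos"]].dropna(), circ_coords, genes
    )
    if len(table):
        print(f"flanking-intron co-localization: {100 * fraction:.0f}% "
              f"({int(table.site_in_flanking_intron.sum())}/{len(table)} genes)")

    decreased = set(diff_circ[diff_circ.significant & (diff_circ.difference < 0)].unit_id)
    ks_row = {}
    try:
        ks = delta_cdf_comparison(diff_editing.dropna(subset=["gene_id"]), decreased)
        print(f"KS comparison of editing deltas (decreased-circ vs other genes): "
              f"D = {ks['statistic']:.3f}, p = {ks['p_value']:.3g} "
              f"(N = {ks['n_decreased'] + ks['n_other']} sites)")
        ks_row = {"ks_statistic": ks["statistic"], "ks_p": ks["p_value"]}
    except ValueError as err:
        print(f"KS comparison not computable: {err}")

    pd.DataFrame(
        [
            {
                "n_editing_genes": len(editing_genes),
                "n_circ_genes": len(circ_genes),
                "n_overlap": result["n_overlap"],
                "fisher_p": result["p_value"],
                "flanking_fraction": fraction,
                **ks_row,
            }
        ]
    ).to_csv(ROOT / "results" / "overlap_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
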