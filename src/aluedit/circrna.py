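"""Circular-RNA expression rate analysis.

The circular-RNA expression rate of a gene in a sample is the ratio of
back-splice junction reads to all junction reads (back-splice +
linear). Genes are tested for tumor-vs-normal rate differences with the
same beta-binomial machinery as editing levels, restricted to genes
with more than three back-splice reads in at least one of the compared
samples (strict gate). The stage also provides the global normalized
back-splice level per sample, the Alu-association contingency test,
the overlap test between differentially-edited and
differentially-circularized genes, flanking-intron co-localization of
perturbed editing sites, and the KS comparison of editing deltas
between gene groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from aluedit import bbstat
from aluedit.simulate.genome import GeneModel, RepeatInterval

logger = logging.getLogger(__name__)


def circ_rate(backsplice: int, linear: int) -> float | None:
    """BSJ / (BSJ + linear); None when the gene has no junction reads."""
    total = backsplice + linear
    if total == 0:
        return None
    return backsplice / total


def global_circ_level(junctions: pd.DataFrame, total_mapped_reads: pd.Series) -> pd.Series:
    """Back-splice reads per one million mapped reads, per sample."""
    bsj = junctions.groupby("sample_id")["backsplice_reads"].sum()
    totals = total_mapped_reads.reindex(bsj.index)
    if totals.isna().any() or (totals <= 0).any():
        raise ZeroDivisionError("every sample needs a positive mapped-read total")
    return bsj * 1e6 / totals


@dataclass
class CircGeneFlags:
    """Per-gene circRNA signature and Alu-overlap flags."""

    table: pd.DataFrame  # gene_id, has_circ_signature, overlaps_alu


def gene_circ_flags(
    junctions: pd.DataFrame,
    genes: list[GeneModel],
    repeats: list[RepeatInterval],
) -> CircGeneFlags:
    """Flag genes by any back-splice read in any sample and by gene-body
    intersection with >= 1 Alu interval."""
    has_circ = junctions.groupby("gene_id")["backsplice_reads"].max() > 0
    alu = [(r.start, r.end) for r in repeats if r.name.startswith("Alu")]
    rows = []
    for g in genes:
        overlaps = any(s < g.end and g.start < e for s, e in alu)
        rows.append(
            {
                "gene_id": g.gene_id,
                "has_circ_signature": bool(has_circ.get(g.gene_id, False)),
                "overlaps_alu": overlaps,
            }
        )
    return CircGeneFlags(pd.DataFrame(rows))


def alu_association_test(flags: CircGeneFlags) -> dict:
    """2x2 association of circRNA signature with Alu overlap.

    Returns the contingency table, per-group Alu proportions and the
    two-sided Fisher exact p. Degenerate margins give p = 1 with a
    warning.
    """
    df = flags.table
    circ = df[df.has_circ_signature]
    nocirc = df[~df.has_circ_signature]
    if circ.empty or nocirc.empty:
        raise ValueError("need >= 1 gene in each circRNA group")
    table = np.array(
        [
            [int(circ.overlaps_alu.sum()), int((~circ.overlaps_alu).sum())],
            [int(nocirc.overlaps_alu.sum()), int((~nocirc.overlaps_alu).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any():
        logger.warning("degenerate margins in Alu association table")
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {
        "table": table,
        "prop_alu_circ": table[0, 0] / table[0].sum(),
        "prop_alu_nocirc": table[1, 0] / table[1].sum(),
        "p_value": p,
    }


def diff_circ_rate(
    junctions: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pathology: str,
    min_bsj: int = 3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential circRNA expression rate within one pathology.

    A gene is tested only when its maximum back-splice count over the
    pathology's samples is strictly greater than ``min_bsj``.
    """
    cohort = sample_sheet[sample_sheet.pathology == pathology]
    if cohort.empty:
        raise KeyError(f"unknown pathology label: {pathology}")
    sub = junctions[junctions.sample_id.isin(cohort.sample_id)].copy()
    if sub.empty:
        raise ValueError(f"no junction counts for pathology {pathology}")
    testable = sub.groupby("gene_id")["backsplice_reads"].max()
    tested_genes = testable[testable > min_bsj].index
    sub = sub[sub.gene_id.isin(tested_genes)]
    if sub.empty:
        return bbstat.differential_test(
            pd.DataFrame(columns=["unit_id", "k", "n", "condition", "patient_id"]),
            fdr=fdr,
        ).assign(pathology=pathology)
    sub = sub.merge(
        cohort[["sample_id", "condition", "patient_id"]], on="sample_id"
    )
    obs = pd.DataFrame(
        {
            "unit_id": sub.gene_id,
            "sample_id": sub.sample_id,
            "k": sub.backsplice_reads,
            "n": sub.backsplice_reads + sub.linear_junction_reads,
            "condition": sub.condition,
            "patient_id": sub.patient_id,
        }
    )
    result = bbstat.differential_test(obs, fdr=fdr)
    result.insert(0, "pathology", pathology)
    return result


def overlap_diff_genes(
    editing_genes: set[str],
    circ_genes: set[str],
    expressed_genes: set[str],
) -> dict:
    """Overlap of differentially-edited and differentially-circularized
    gene sets against the expressed-gene universe, Fisher exact."""
    if not expressed_genes:
        raise ValueError("expressed-gene universe is empty")
    stray = (editing_genes | circ_genes) - expressed_genes
    if stray:
        raise ValueError(
            f"genes outside the expressed universe: {sorted(stray)[:5]}"
        )
    both = editing_genes & circ_genes
    only_e = editing_genes - circ_genes
    only_c = circ_genes - editing_genes
    neither = expressed_genes - editing_genes - circ_genes
    table = np.array([[len(both), len(only_e)], [len(only_c), len(neither)]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {"overlap": both, "n_overlap": len(both), "table": table, "p_value": p}


def flanking_intron_colocalization(
    diff_sites: pd.DataFrame,
    circ_coords: pd.DataFrame,
    genes: list[GeneModel],
) -> tuple[pd.DataFrame, float]:
    """Do perturbed editing sites sit in circRNA-flanking introns?

    ``diff_sites`` needs gene_id and pos (0-based); ``circ_coords``
    needs gene_id, circ_start, circ_end (exon-boundary coordinates,
    0-based half-open). For each gene carrying both signals, True iff
    >= 1 differentially-edited site lies in the intron genomically
    adjacent to a circRNA boundary (immediately upstream of the
    acceptor or downstream of the donor). Returns the per-gene table
    and the fraction of genes satisfying it.
    """
    gene_map = {g.gene_id: g for g in genes}
    sites_by_gene = {
        gid: grp.pos.to_numpy() for gid, grp in diff_sites.groupby("gene_id")
    }
    shared = sorted(set(sites_by_gene) & set(circ_coords.gene_id))
    rows = []
    for gid in shared:
        gene = gene_map.get(gid)
        if gene is None:
            raise KeyError(f"gene {gid} missing from annotation")
        introns = gene.introns
        hit = False
        for circ in circ_coords[circ_coords.gene_id == gid].itertuples():
            if circ.circ_start < gene.start or circ.circ_end > gene.end:
                logger.warning(
                    "circRNA %s:%d-%d outside gene body, skipped",
                    gid, circ.circ_start, circ.circ_end,
                )
                continue
            flanks = [i for i in introns if i[1] == circ.circ_start] + [
                i for i in introns if i[0] == circ.circ_end
            ]
            for s, e in flanks:
                if np.any((sites_by_gene[gid] >= s) & (sites_by_gene[gid] < e)):
                    hit = True
        rows.append({"gene_id": gid, "site_in_flanking_intron": hit})
    table = pd.DataFrame(rows, columns=["gene_id", "site_in_flanking_intron"])
    fraction = float(table.site_in_flanking_intron.mean()) if len(table) else float("nan")
    return table, fraction


def delta_cdf_comparison(
    editing_deltas: pd.DataFrame,
    circ_decreased_genes: set[str],
) -> dict:
    """Two-sample KS test of editing level differences between sites in
    genes with vs without decreased circRNA expression rate.

    ``editing_deltas`` needs gene_id and difference columns.
    """
    in_group = editing_deltas[editing_deltas.gene_id.isin(circ_decreased_genes)]
    out_group = editing_deltas[~editing_deltas.gene_id.isin(circ_decreased_genes)]
    if len(in_group) < 2 or len(out_group) < 2:
        raise ValueError("each gene group needs >= 2 editing deltas")
    res = stats.ks_2samp(
        in_group.difference.to_numpy(),
        out_group.difference.to_numpy(),
        alternative="two-sided",
    )
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_decreased": len(in_group),
        "n_other": len(out_group),
    }
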