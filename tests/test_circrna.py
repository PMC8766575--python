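"""circRNA rates, gates, Fisher/KS tests, flanking-intron logic."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from aluedit.circrna import (
    CircGeneFlags,
    alu_association_test,
    circ_rate,
    delta_cdf_comparison,
    diff_circ_rate,
    flanking_intron_colocalization,
    gene_circ_flags,
    global_circ_level,
    overlap_diff_genes,
)
from aluedit.simulate.genome import GeneModel, RepeatInterval


def fisher_oracle(table: np.ndarray) -> float:
    """Exhaustive hypergeometric enumeration over fixed margins."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d

    def log_pmf(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(n - r1 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = math.exp(log_pmf(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_pmf(x))
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestRates:
    def test_rate_arithmetic(self):
        assert circ_rate(3, 7) == pytest.approx(0.3)

    def test_rate_undefined_without_reads(self):
        assert circ_rate(0, 0) is None

    def test_global_level(self):
        junctions = pd.DataFrame(
            {
                "gene_id": ["G1", "G2"],
                "sample_id": ["s1", "s1"],
                "backsplice_reads": [1500, 500],
                "linear_junction_reads": [0, 0],
            }
        )
        totals = pd.Series({"s1": 40_000_000})
        assert global_circ_level(junctions, totals)["s1"] == pytest.approx(50.0)

    def test_global_level_no_bsj(self):
        junctions = pd.DataFrame(
            {
                "gene_id": ["G1"],
                "sample_id": ["s1"],
                "backsplice_reads": [0],
                "linear_junction_reads": [10],
            }
        )
        assert global_circ_level(junctions, pd.Series({"s1": 1_000}))["s1"] == 0.0

    def test_global_level_zero_denominator(self):
        junctions = pd.DataFrame(
            {
                "gene_id": ["G1"],
                "sample_id": ["s1"],
                "backsplice_reads": [5],
                "linear_junction_reads": [5],
            }
        )
        with pytest.raises(ZeroDivisionError):
            global_circ_level(junctions, pd.Series({"s1": 0}))


class TestAluAssociation:
    def test_fisher_matches_enumeration(self):
        flags = CircGeneFlags(
            pd.DataFrame(
                {
                    "gene_id": [f"G{i}" for i in range(20)],
                    "has_circ_signature": [True] * 10 + [False] * 10,
                    "overlaps_alu": [True] * 8 + [False] * 2 + [True] * 1 + [False] * 9,
                }
            )
        )
        result = alu_association_test(flags)
        assert np.array_equal(result["table"], [[8, 2], [1, 9]])
        assert result["p_value"] == pytest.approx(fisher_oracle(result["table"]), rel=1e-9)

    def test_balanced_table_p_one(self):
        flags = CircGeneFlags(
            pd.DataFrame(
                {
                    "gene_id": [f"G{i}" for i in range(20)],
                    "has_circ_signature": [True] * 10 + [False] * 10,
                    "overlaps_alu": ([True] * 5 + [False] * 5) * 2,
                }
            )
        )
        assert alu_association_test(flags)["p_value"] == pytest.approx(1.0)

    def test_constructed_proportions(self):
        genes = [
            GeneModel(f"G{i}", "chr1", "+", ((i * 1000, i * 1000 + 100),
                                             (i * 1000 + 300, i * 1000 + 400)))
            for i in range(6)
        ]
        # Alus only inside the first three gene bodies
        repeats = [
            RepeatInterval("chr1", i * 1000 + 150, i * 1000 + 250, "AluSx", "+")
            for i in range(3)
        ]
        junctions = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "sample_id": ["s1"] * 6,
                "backsplice_reads": [5, 5, 5, 0, 0, 0],
                "linear_junction_reads": [10] * 6,
            }
        )
        flags = gene_circ_flags(junctions, genes, repeats)
        result = alu_association_test(flags)
        assert result["prop_alu_circ"] == 1.0
        assert result["prop_alu_nocirc"] == 0.0

    def test_single_group_rejected(self):
        flags = CircGeneFlags(
            pd.DataFrame(
                {"gene_id": ["G1"], "has_circ_signature": [True], "overlaps_alu": [True]}
            )
        )
        with pytest.raises(ValueError):
            alu_association_test(flags)


def _junctions(bsj_by_gene: dict[str, list[int]], sheet: pd.DataFrame, depth=20):
    rows = []
    for gene, bsjs in bsj_by_gene.items():
        for sample_id, bsj in zip(sheet.sample_id, bsjs):
            rows.append(
                {
                    "gene_id": gene,
                    "sample_id": sample_id,
                    "backsplice_reads": bsj,
                    "linear_junction_reads": depth - bsj,
                }
            )
    return pd.DataFrame(rows)


SHEET4 = pd.DataFrame(
    {
        "sample_id": ["P1T", "P1N", "P2T", "P2N", "P3T", "P3N", "P4T", "P4N"],
        "patient_id": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
        "condition": ["tumor", "normal"] * 4,
        "pathology": ["A2"] * 8,
    }
)


class TestDiffCirc:
    def test_gate_is_strictly_greater_than_three(self):
        junctions = _junctions(
            {"Gmax3": [3, 3, 2, 3, 1, 3, 0, 3], "Gmax4": [4, 3, 2, 3, 1, 3, 0, 3]},
            SHEET4,
        )
        result = diff_circ_rate(junctions, SHEET4, "A2", min_bsj=3)
        assert set(result.unit_id) == {"Gmax4"}

    def test_rate_difference_reported(self):
        junctions = _junctions({"G1": [2, 6, 2, 6, 2, 6, 2, 6]}, SHEET4, depth=20)
        result = diff_circ_rate(junctions, SHEET4, "A2")
        assert result.difference.iloc[0] == pytest.approx(0.1 - 0.3)

    def test_unknown_pathology(self):
        with pytest.raises(KeyError):
            diff_circ_rate(_junctions({"G1": [5] * 8}, SHEET4), SHEET4, "ZZ")


class TestOverlap:
    def test_disjoint_sets(self):
        universe = {f"G{i}" for i in range(100)}
        result = overlap_diff_genes({"G1", "G2"}, {"G3", "G4"}, universe)
        assert result["n_overlap"] == 0

    def test_identical_sets_match_hypergeometric_oracle(self):
        universe = {f"G{i}" for i in range(100)}
        genes = {f"G{i}" for i in range(10)}
        result = overlap_diff_genes(genes, genes, universe)
        assert result["n_overlap"] == 10
        assert result["p_value"] == pytest.approx(fisher_oracle(result["table"]), rel=1e-9)

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            overlap_diff_genes({"GX"}, set(), {"G1", "G2"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_diff_genes(set(), set(), set())


GENE3EX = GeneModel(
    "G1", "chr1", "+",
    ((0, 100), (200, 300), (400, 500)),  # introns: 100-200, 300-400
)


class TestFlankingIntrons:
    def _coords(self):
        # circRNA = middle exon; flanking introns are 100-200 and 300-400
        return pd.DataFrame(
            {"gene_id": ["G1"], "chrom": ["chr1"], "circ_start": [200], "circ_end": [300]}
        )

    def test_site_in_acceptor_flanking_intron(self):
        sites = pd.DataFrame({"gene_id": ["G1"], "pos": [150]})
        table, fraction = flanking_intron_colocalization(sites, self._coords(), [GENE3EX])
        assert bool(table.site_in_flanking_intron.iloc[0])
        assert fraction == 1.0

    def test_site_in_donor_flanking_intron(self):
        sites = pd.DataFrame({"gene_id": ["G1"], "pos": [350]})
        _table, fraction = flanking_intron_colocalization(sites, self._coords(), [GENE3EX])
        assert fraction == 1.0

    def test_site_in_distal_intron_is_negative(self):
        gene = GeneModel(
            "G1", "chr1", "+",
            ((0, 100), (200, 300), (400, 500), (600, 700)),
        )
        coords = pd.DataFrame(
            {"gene_id": ["G1"], "chrom": ["chr1"], "circ_start": [200], "circ_end": [300]}
        )
        sites = pd.DataFrame({"gene_id": ["G1"], "pos": [550]})  # intron 500-600
        _table, fraction = flanking_intron_colocalization(sites, coords, [gene])
        assert fraction == 0.0

    def test_circ_outside_gene_body_skipped(self):
        coords = pd.DataFrame(
            {"gene_id": ["G1"], "chrom": ["chr1"], "circ_start": [800], "circ_end": [900]}
        )
        sites = pd.DataFrame({"gene_id": ["G1"], "pos": [150]})
        _table, fraction = flanking_intron_colocalization(sites, coords, [GENE3EX])
        assert fraction == 0.0  # record skipped, no flank found

    def test_fraction_over_constructed_genes(self):
        gene2 = GeneModel("G2", "chr1", "+", ((1000, 1100), (1200, 1300), (1400, 1500)))
        coords = pd.DataFrame(
            {
                "gene_id": ["G1", "G2"],
                "chrom": ["chr1", "chr1"],
                "circ_start": [200, 1200],
                "circ_end": [300, 1300],
            }
        )
        sites = pd.DataFrame({"gene_id": ["G1", "G2"], "pos": [150, 1050]})
        # G1 site in flank; G2 site in exon -> not in flank
        _table, fraction = flanking_intron_colocalization(sites, coords, [GENE3EX, gene2])
        assert fraction == pytest.approx(0.5)


def test_generated_cohort_association_structure():
    """With circ signatures tied to Alu content, the association test on
    generator output recovers the planted 100%/0% group proportions."""
    from aluedit.config import SimulationConfig
    from aluedit.simulate import make_truth, simulate_genome
    from aluedit.simulate.junctions import simulate_junction_counts

    config = SimulationConfig(
        seed=13,
        n_patients=2,
        pathology_labels=["O2", "A2"],
        n_genes=10,
        n_alu_per_gene=1,
        frac_alu_genes=0.5,
        circ_prob_alu=1.0,
        circ_prob_no_alu=0.0,
        n_editing_sites=5,
        n_snps=0,
        junction_depth_mean=100.0,
    )
    genome = simulate_genome(config)
    assert len(genome.repeats) == 5  # half the genes carry an Alu
    truth = make_truth(config, genome)
    junctions = simulate_junction_counts(config, truth)
    flags = gene_circ_flags(junctions, genome.genes, genome.repeats)
    result = alu_association_test(flags)
    assert result["prop_alu_circ"] == 1.0
    assert result["prop_alu_nocirc"] == 0.0
    assert result["p_value"] < 0.05


class TestDeltaCdfComparison:
    def test_identical_groups(self):
        deltas = pd.DataFrame(
            {"gene_id": ["A"] * 10 + ["B"] * 10, "difference": list(range(10)) * 2}
        )
        result = delta_cdf_comparison(deltas, {"A"})
        assert result["statistic"] == pytest.approx(0.0)
        assert result["p_value"] == pytest.approx(1.0)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(3)
        deltas = pd.DataFrame(
            {
                "gene_id": ["A"] * 500 + ["B"] * 500,
                "difference": np.concatenate(
                    [rng.normal(0, 0.1, 500), rng.normal(0.5, 0.1, 500)]
                ),
            }
        )
        assert delta_cdf_comparison(deltas, {"A"})["p_value"] < 1e-6

    def test_small_group_rejected(self):
        deltas = pd.DataFrame({"gene_id": ["A", "B", "B"], "difference": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            delta_cdf_comparison(deltas, {"A"})
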