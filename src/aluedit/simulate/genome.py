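"""Reference genome, gene models and repeat annotation for the simulator.

The genome is one chromosome of tandem three-exon genes with alternating
strands. Alu-subfamily repeat intervals sit inside introns (where most
A-to-I editing happens in primate transcriptomes, because inverted Alu
pairs form the double-stranded RNA that ADAR targets), and a short
homopolymer run is planted in each gene so the read-level homopolymer
filter sees realistic reference context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.array(list("ACGT"))
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

ALU_SUBFAMILIES = ("AluSx", "AluY", "AluJb", "AluSq2")
ALU_LENGTH = 300
#: planted reference homopolymer run length; kept <= 10 so reads covering
#: it are not themselves discarded by the homopolymer read filter
REF_HOMOPOLYMER_RUN = 6


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # sorted genomically

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class RepeatInterval:
    """RepeatMasker-style repeat interval, 0-based half-open.

    ``strand`` is the repeat's annotated strand; in the simulator it is
    set to the host gene's strand so it doubles as the transcribed
    strand at the repeat's positions.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str


@dataclass
class GenomeBundle:
    """Reference sequence plus gene and repeat annotation."""

    chrom: str
    sequence: str
    genes: list[GeneModel]
    repeats: list[RepeatInterval]
    homopolymer_runs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def simulate_genome(config, rng: np.random.Generator | None = None) -> GenomeBundle:
    """Build the reference genome with genes, intronic Alus and homopolymers.

    Each gene has three exons and two introns; ``n_alu_per_gene`` Alu
    intervals are distributed over the two introns. Raises ``ValueError``
    when the requested Alus cannot fit inside the introns.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    exon_len = config.exon_length
    intron_len = config.intron_length
    spacer = config.intergenic_length
    n_introns = 2
    alus_per_intron_max = (intron_len - 2 * 20) // (ALU_LENGTH + 20)
    if config.n_alu_per_gene > n_introns * alus_per_intron_max:
        raise ValueError(
            f"cannot fit {config.n_alu_per_gene} Alu intervals of {ALU_LENGTH} nt "
            f"into {n_introns} introns of {intron_len} nt"
        )

    chrom = "chr1"
    gene_span = 3 * exon_len + 2 * intron_len
    genome_len = spacer + config.n_genes * (gene_span + spacer)
    seq = rng.choice(BASES, size=genome_len)

    genes: list[GeneModel] = []
    repeats: list[RepeatInterval] = []
    homopolymer_runs: list[tuple[int, int]] = []

    pos = spacer
    for gi in range(config.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        exons = []
        cursor = pos
        introns = []
        for part in range(5):  # E I E I E
            if part % 2 == 0:
                exons.append((cursor, cursor + exon_len))
                cursor += exon_len
            else:
                introns.append((cursor, cursor + intron_len))
                cursor += intron_len
        gene = GeneModel(
            gene_id=f"G{gi + 1:03d}", chrom=chrom, strand=strand, exons=tuple(exons)
        )
        genes.append(gene)

        # Bresenham-style deterministic selection of Alu-carrying genes
        has_alu = int((gi + 1) * config.frac_alu_genes) > int(gi * config.frac_alu_genes)
        # distribute Alus round-robin over the introns, padded from edges
        for ai in range(config.n_alu_per_gene if has_alu else 0):
            intron = introns[ai % n_introns]
            slot = ai // n_introns
            astart = intron[0] + 20 + slot * (ALU_LENGTH + 20)
            aend = astart + ALU_LENGTH
            name = ALU_SUBFAMILIES[(gi + ai) % len(ALU_SUBFAMILIES)]
            repeats.append(RepeatInterval(chrom, astart, aend, name, strand))

        # one reference homopolymer run per gene, in the last intron after
        # any Alu slots (constrained to stay clear of them)
        run_start = introns[-1][1] - REF_HOMOPOLYMER_RUN - 10
        run_base = str(rng.choice(BASES))
        seq[run_start : run_start + REF_HOMOPOLYMER_RUN] = run_base
        homopolymer_runs.append((run_start, run_start + REF_HOMOPOLYMER_RUN))

        pos = cursor + spacer

    return GenomeBundle(
        chrom=chrom,
        sequence="".join(seq),
        genes=genes,
        repeats=repeats,
        homopolymer_runs=homopolymer_runs,
    )
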