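"""Paired-end stranded alignment simulator.

Fragments are drawn per gene so interior coverage is approximately
uniform at ``coverage_mean``. Each fragment is one RNA molecule: its
edit state at every covered site is drawn once and shared by both
mates. The library follows the reverse-stranded convention — mate 2
aligns to the transcribed strand — and configured fractions of
fragments carry read pathologies (PCR-duplicate copies, multi-mapper
MAPQ/occupancy encoding, >=5 nt soft-clips, insertions, homopolymer
stretches) that the read filters must remove.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from aluedit.simulate.genome import GenomeBundle
from aluedit.simulate.truth import TruthTable

BASE_QUALITY = 37
UNIQUE_MAPQ = 255  # STAR dialect: 255 marks a uniquely mapping read
MULTIMAP_MAPQ = 1
FRAG_MEAN, FRAG_SD, FRAG_MIN, FRAG_MAX = 280, 25, 240, 340

_OTHER = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


def _sample_q(rng: np.random.Generator, mu: float, rho: float) -> float:
    """Per-sample success probability: Beta draw around mu, or mu at rho→0."""
    if mu <= 0.0:
        return 0.0
    if mu >= 1.0:
        return 1.0
    if rho < 1e-9:
        return mu
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return float(rng.beta(a, b))


def _apply_errors(seq: list[str], rng: np.random.Generator, rate: float) -> None:
    if rate <= 0.0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        seq[i] = _OTHER[seq[i]][rng.integers(3)]


def simulate_alignments(
    config,
    genome: GenomeBundle,
    truth: TruthTable,
    outdir: str | Path,
) -> pd.DataFrame:
    """Write one coordinate-sorted, indexed BAM per sample.

    Returns a table (sample_id, bam, n_mapped_reads). Deterministic for
    a fixed config seed.
    """
    if config.coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rl = config.read_length
    rho = config.site_dispersion
    glen = len(genome.sequence)
    ref = genome.sequence

    levels = truth.site_levels.merge(
        truth.sites[["site_id", "pos", "alt_genomic"]], on="site_id"
    )
    snp_geno = truth.snp_genotypes.merge(
        truth.snps[["snp_id", "pos", "alt"]], on="snp_id"
    )

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.chrom, "LN": glen}],
    }

    # fraction thresholds for the per-fragment pathology draw
    cuts = np.cumsum(
        [
            config.frac_duplicates,
            config.frac_multimap,
            config.frac_clipped,
            config.frac_indel,
            config.frac_homopolymer_reads,
        ]
    )
    if cuts[-1] > 1.0 + 1e-9:
        raise ValueError("read-pathology fractions sum to more than 1")

    rows = []
    for s_idx, sam in truth.sample_sheet.reset_index(drop=True).iterrows():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303, int(s_idx)]))
        sample_id = sam.sample_id

        # per-sample realized allele probability at every variant position
        sample_levels = levels[levels.sample_id == sample_id]
        var_pos: list[int] = []
        var_alt: list[str] = []
        var_q: list[float] = []
        for r in sample_levels.itertuples():
            var_pos.append(int(r.pos))
            var_alt.append(r.alt_genomic)
            var_q.append(_sample_q(rng, float(r.true_level), rho))
        geno = snp_geno[snp_geno.patient_id == sam.patient_id]
        for r in geno.itertuples():
            var_pos.append(int(r.pos))
            var_alt.append(r.alt)
            var_q.append(1.0 if r.genotype == "hom" else 0.5)
        var_pos_a = np.array(var_pos, dtype=int)
        order = np.argsort(var_pos_a, kind="stable")
        var_pos_a = var_pos_a[order]
        var_alt = [var_alt[i] for i in order]
        var_q = [var_q[i] for i in order]

        reads: list[pysam.AlignedSegment] = []
        frag_counter = 0
        for gene in genome.genes:
            width = (gene.end - gene.start) + FRAG_MEAN
            n_frags = int(round(config.coverage_mean * width / (2 * rl)))
            for _ in range(n_frags):
                frag_len = int(np.clip(round(rng.normal(FRAG_MEAN, FRAG_SD)), FRAG_MIN, FRAG_MAX))
                start = int(rng.integers(gene.start - frag_len + 1, gene.end))
                start = max(0, min(start, glen - frag_len))
                end = start + frag_len

                # fragment-level edit state at covered variant positions
                lo = np.searchsorted(var_pos_a, start)
                hi = np.searchsorted(var_pos_a, end)
                edits = {
                    int(var_pos_a[i]): var_alt[i]
                    for i in range(lo, hi)
                    if rng.random() < var_q[i]
                }

                category = int(np.searchsorted(cuts, rng.random(), side="right"))
                frag_counter += 1
                qname = f"{sample_id}_f{frag_counter}"
                pair = _make_pair(
                    qname, genome.chrom, ref, start, end, rl, gene.strand,
                    edits, rng, config.base_error_rate, category,
                )
                reads.extend(pair)
                if category == 0:  # PCR duplicate: an extra flagged copy
                    frag_counter += 1
                    dup = _make_pair(
                        f"{sample_id}_f{frag_counter}", genome.chrom, ref, start, end,
                        rl, gene.strand, edits, rng, config.base_error_rate, 5,
                    )
                    for seg in dup:
                        seg.is_duplicate = True
                    reads.extend(dup)

        reads.sort(key=lambda r: (r.reference_start, r.query_name, r.flag))
        bam_path = outdir / f"{sample_id}.bam"
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            for seg in reads:
                bam.write(seg)
        pysam.index(str(bam_path))
        rows.append(
            {"sample_id": sample_id, "bam": str(bam_path), "n_mapped_reads": len(reads)}
        )
    return pd.DataFrame(rows)


def _read_bases(ref: str, start: int, length: int, edits: dict[int, str]) -> list[str]:
    seq = list(ref[start : start + length])
    for pos, alt in edits.items():
        off = pos - start
        if 0 <= off < length:
            seq[off] = alt
    return seq


def _make_pair(
    qname: str,
    chrom: str,
    ref: str,
    start: int,
    end: int,
    rl: int,
    gene_strand: str,
    edits: dict[int, str],
    rng: np.random.Generator,
    error_rate: float,
    category: int,
) -> list[pysam.AlignedSegment]:
    """Build the two mates of one fragment.

    ``category``: 0 duplicate-origin (pair itself is normal; the flagged
    copy is added by the caller), 1 multimap, 2 clipped, 3 insertion,
    4 homopolymer, 5+ normal.
    """
    fwd_start = start                # forward mate on [start, start+rl)
    rev_start = end - rl             # reverse mate on [end-rl, end)

    fwd_seq = _read_bases(ref, fwd_start, rl, edits)
    rev_seq = _read_bases(ref, rev_start, rl, edits)
    _apply_errors(fwd_seq, rng, error_rate)
    _apply_errors(rev_seq, rng, error_rate)

    # reverse-stranded protocol: mate 2 sits on the transcribed strand
    fwd_is_mate2 = gene_strand == "+"

    fwd = _segment(qname, chrom, fwd_start, fwd_seq, rl, reverse=False,
                   is_mate2=fwd_is_mate2, mate_start=rev_start)
    rev = _segment(qname, chrom, rev_start, rev_seq, rl, reverse=True,
                   is_mate2=not fwd_is_mate2, mate_start=fwd_start)
    fwd.template_length = end - start
    rev.template_length = -(end - start)

    if category == 1:  # multi-mapper
        for seg in (fwd, rev):
            seg.mapping_quality = MULTIMAP_MAPQ
            seg.set_tag("NH", 2)
    elif category == 2:  # soft-clip >= 5 nt on mate 1's genomic left end
        target = fwd if not fwd_is_mate2 else rev
        _soft_clip_left(target, ref, rng)
    elif category == 3:  # 1-nt insertion in mate 1
        target = fwd if not fwd_is_mate2 else rev
        _insert_base(target, rng)
    elif category == 4:  # homopolymer stretches totaling > 10 nt
        target = fwd if not fwd_is_mate2 else rev
        seq = list(target.query_sequence)
        seq[30:37] = ["A"] * 7
        seq[50:55] = ["G"] * 5
        target.query_sequence = "".join(seq)
        target.query_qualities = pysam.qualitystring_to_array(chr(BASE_QUALITY + 33) * rl)
    return [fwd, rev]


def _segment(
    qname: str,
    chrom: str,
    pos: int,
    seq: list[str],
    rl: int,
    reverse: bool,
    is_mate2: bool,
    mate_start: int,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment()
    seg.query_name = qname
    seg.query_sequence = "".join(seq)
    seg.reference_id = 0
    seg.reference_start = pos
    seg.mapping_quality = UNIQUE_MAPQ
    seg.cigartuples = [(0, rl)]
    seg.query_qualities = pysam.qualitystring_to_array(chr(BASE_QUALITY + 33) * rl)
    seg.next_reference_id = 0
    seg.next_reference_start = mate_start
    seg.is_paired = True
    seg.is_proper_pair = True
    seg.is_reverse = reverse
    seg.mate_is_reverse = not reverse
    seg.is_read2 = is_mate2
    seg.is_read1 = not is_mate2
    seg.set_tag("NH", 1)
    return seg


def _soft_clip_left(seg: pysam.AlignedSegment, ref: str, rng: np.random.Generator) -> None:
    """Turn the leftmost 5 aligned bases into a randomized soft-clip."""
    rl = seg.query_length
    seq = list(seg.query_sequence)
    for i in range(5):
        seq[i] = "ACGT"[rng.integers(4)]
    quals = seg.query_qualities
    seg.reference_start = seg.reference_start + 5
    seg.query_sequence = "".join(seq)
    seg.cigartuples = [(4, 5), (0, rl - 5)]
    seg.query_qualities = quals


def _insert_base(seg: pysam.AlignedSegment, rng: np.random.Generator) -> None:
    rl = seg.query_length
    a = 48
    seq = list(seg.query_sequence)
    new_seq = seq[:a] + ["ACGT"[rng.integers(4)]] + seq[a : rl - 1]
    quals = seg.query_qualities
    seg.query_sequence = "".join(new_seq)
    seg.cigartuples = [(0, a), (1, 1), (0, rl - 1 - a)]
    seg.query_qualities = quals
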