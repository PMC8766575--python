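"""Independent naive re-implementation of the editing-call cascade.

Used as the equivalence oracle: reads BAMs with pysam directly,
applies the five read filters with regex/string scans, builds the
pileup with a direct CIGAR walk, and applies the site rules
exhaustively. Deliberately shares no code with the package.
"""

from __future__ import annotations

import re
from collections import defaultdict

import pysam

HOMOPOLYMER_RE = re.compile(r"(A{4,}|C{4,}|G{4,}|T{4,})")
CLIP_RE = re.compile(r"(\d+)[SH]")


def naive_read_reasons(seg: pysam.AlignedSegment, unique_mapq: int = 255) -> set[str]:
    reasons = set()
    if seg.flag & 0x400:
        reasons.add("duplicate")
    nh = seg.get_tag("NH") if seg.has_tag("NH") else 1
    if nh > 1 or seg.mapping_quality < unique_mapq:
        reasons.add("multimapped")
    clipped = sum(int(m) for m in CLIP_RE.findall(seg.cigarstring or ""))
    if clipped >= 5:
        reasons.add("clipped>=5")
    homo = sum(len(m.group(0)) for m in HOMOPOLYMER_RE.finditer(seg.query_sequence))
    if homo > 10:
        reasons.add("homopolymer>10")
    if re.search(r"\d+[ID]", seg.cigarstring or ""):
        reasons.add("indel")
    return reasons


def naive_cigar_walk(seg: pysam.AlignedSegment):
    """(read_offset, genome_position) pairs for aligned (M) bases."""
    pairs = []
    qpos = 0
    rpos = seg.reference_start
    for num, op in re.findall(r"(\d+)([MIDNSHP=X])", seg.cigarstring):
        num = int(num)
        if op in "M=X":
            for i in range(num):
                pairs.append((qpos + i, rpos + i))
            qpos += num
            rpos += num
        elif op in "IS":
            qpos += num
        elif op in "DN":
            rpos += num
    return pairs


def naive_call_bam(
    bam_path,
    reference: str,
    chrom: str,
    snp_positions: set[int],
    min_qual: int = 20,
    min_alt: int = 3,
    end_distance: int = 5,
    major_min: int = 5,
    major_ratio: float = 2.0,
) -> tuple[dict, dict]:
    """Returns (verdicts, calls).

    verdicts: (qname, mate) -> kept bool;
    calls: pos -> dict(ref, alt, class, strand, ref_reads, alt_reads).
    """
    counts: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    end_dists: dict[int, list[int]] = defaultdict(list)
    votes: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    verdicts = {}

    with pysam.AlignmentFile(str(bam_path)) as bam:
        for seg in bam.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            reasons = naive_read_reasons(seg)
            mate = 2 if seg.flag & 0x80 else 1
            verdicts[(seg.query_name, mate)] = not reasons
            if reasons:
                continue
            seq = seg.query_sequence
            quals = seg.query_qualities
            rl = len(seq)
            genome_strand = "-" if seg.flag & 0x10 else "+"
            # reverse-stranded protocol: mate 2 shows the transcribed strand
            if mate == 2:
                vote = genome_strand
            else:
                vote = "-" if genome_strand == "+" else "+"
            for qoff, gpos in naive_cigar_walk(seg):
                if quals[qoff] <= min_qual:
                    continue
                base = seq[qoff]
                if base not in "ACGT":
                    continue
                counts[gpos][base] += 1
                votes[gpos][vote] += 1
                if base != reference[gpos]:
                    end_dists[gpos].append(min(qoff + 1, rl - qoff))

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    calls = {}
    for pos, cnt in counts.items():
        ref_base = reference[pos]
        alts = {b: c for b, c in cnt.items() if b != ref_base and c > 0}
        if not alts:
            continue
        n_mis = sum(alts.values())
        n_prox = sum(1 for d in end_dists[pos] if d <= end_distance)
        if n_prox > n_mis / 2.0:
            continue
        if len(alts) == 1:
            major = next(iter(alts))
        else:
            major = None
            for cand, c in alts.items():
                if c >= major_min and all(
                    c > major_ratio * c2 for b2, c2 in alts.items() if b2 != cand
                ):
                    major = cand
            if major is None:
                continue
        if alts[major] < min_alt:
            continue
        if pos in snp_positions:
            continue
        v = votes[pos]
        if v.get("+", 0) > v.get("-", 0):
            strand = "+"
        elif v.get("-", 0) > v.get("+", 0):
            strand = "-"
        else:
            continue  # ambiguous strand
        r, a = ref_base, major
        if strand == "-":
            r, a = comp[r], comp[a]
        calls[pos] = {
            "ref": ref_base,
            "alt": major,
            "class": f"{r}>{a}",
            "strand": strand,
            "ref_reads": cnt.get(ref_base, 0),
            "alt_reads": alts[major],
        }
    return verdicts, calls
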