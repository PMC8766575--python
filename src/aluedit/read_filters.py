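"""Read-level exclusion filters and quality-aware mismatch pileups.

Five independent read filters precede any site-level work: PCR
duplicates, multi-mapped reads, reads with >= 5 clipped nucleotides
(soft + hard, both ends summed), reads whose homopolymer content (total
nucleotides inside maximal runs of >= 4 identical bases) exceeds 10 nt,
and reads carrying any insertion or deletion. Surviving reads feed a
pileup in which a base counts only when its Phred quality is strictly
greater than the threshold (default 20).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pysam

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
INDEX_BASE = "ACGT"
VALID_OPS = set("MIDSHN")
_CIGAR_OPS = "MIDNSHP=X"

REASON_DUPLICATE = "duplicate"
REASON_MULTIMAP = "multimapped"
REASON_CLIPPED = "clipped>=5"
REASON_HOMOPOLYMER = "homopolymer>10"
REASON_INDEL = "indel"


class CigarError(ValueError):
    """Malformed CIGAR, naming the offending read."""


@dataclass
class AlignedReadRecord:
    """One mate of a paired alignment, aligner-agnostic."""

    read_id: str
    mate: int  # 1 or 2
    genome_strand: str  # '+' or '-'
    duplicate_flag: bool
    multimap_indicator: bool
    cigar: list[tuple[str, int]]
    sequence: str
    base_qualities: np.ndarray  # Phred integers per nt
    aligned_pairs: list[tuple[int, int]]  # (read_offset, genome_position), M ops only

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError(
                f"read {self.read_id}: sequence and qualities lengths differ"
            )

    @classmethod
    def from_pysam(
        cls,
        seg: pysam.AlignedSegment,
        multimap_mode: str = "either",
        unique_mapq: int = 255,
    ) -> "AlignedReadRecord":
        """Convert a pysam record, deciding the multimap indicator by the
        occupancy tag (NH > 1), by mapping quality (< unique_mapq), or by
        either signal."""
        nh = seg.get_tag("NH") if seg.has_tag("NH") else 1
        by_tag = nh > 1
        by_mapq = seg.mapping_quality < unique_mapq
        if multimap_mode == "tag":
            multimap = by_tag
        elif multimap_mode == "mapq":
            multimap = by_mapq
        else:
            multimap = by_tag or by_mapq
        cigar = [
            (_CIGAR_OPS[op], length) for op, length in (seg.cigartuples or [])
        ]
        return cls(
            read_id=seg.query_name,
            mate=2 if seg.is_read2 else 1,
            genome_strand="-" if seg.is_reverse else "+",
            duplicate_flag=seg.is_duplicate,
            multimap_indicator=multimap,
            cigar=cigar,
            sequence=seg.query_sequence,
            base_qualities=np.asarray(seg.query_qualities, dtype=int),
            aligned_pairs=seg.get_aligned_pairs(matches_only=True),
        )


@dataclass(frozen=True)
class ReadFilterVerdict:
    read_id: str
    kept: bool
    reasons: frozenset[str]


def homopolymer_content(sequence: str, min_run: int = 4) -> int:
    """Total nucleotides inside maximal runs of >= min_run identical bases."""
    total = 0
    i = 0
    n = len(sequence)
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_run:
            total += j - i
        i = j
    return total


def evaluate_read(read: AlignedReadRecord) -> ReadFilterVerdict:
    """Apply the five exclusion rules; reasons are mutually independent."""
    for op, length in read.cigar:
        if op not in VALID_OPS or length <= 0:
            raise CigarError(f"read {read.read_id}: malformed CIGAR op {op}{length}")
    reasons = set()
    if read.duplicate_flag:
        reasons.add(REASON_DUPLICATE)
    if read.multimap_indicator:
        reasons.add(REASON_MULTIMAP)
    clipped = sum(length for op, length in read.cigar if op in "SH")
    if clipped >= 5:
        reasons.add(REASON_CLIPPED)
    if homopolymer_content(read.sequence) > 10:
        reasons.add(REASON_HOMOPOLYMER)
    if any(op in "ID" for op, _ in read.cigar):
        reasons.add(REASON_INDEL)
    return ReadFilterVerdict(read.read_id, kept=not reasons, reasons=frozenset(reasons))


def transcribed_strand_vote(read: AlignedReadRecord, strandedness: str = "reverse") -> str:
    """The transcribed strand this read testifies for.

    Reverse-stranded protocol: mate 2 lies on the transcribed strand,
    mate 1 on its opposite; the forward-stranded protocol swaps roles.
    """
    on_transcript = (read.mate == 2) == (strandedness == "reverse")
    if on_transcript:
        return read.genome_strand
    return "-" if read.genome_strand == "+" else "+"


@dataclass
class PileupColumn:
    """Quality-passing allele counts and mismatch metadata at one position."""

    genome_position: int
    ref_base: str
    counts: Counter = field(default_factory=Counter)  # allele -> reads
    end_distances: list[int] = field(default_factory=list)  # mismatch reads only
    strand_tallies: dict = field(default_factory=dict)  # allele -> Counter(strand)
    strand_votes: Counter = field(default_factory=Counter)  # transcribed strand

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PileupResult:
    """Mismatch columns plus full quality-passing base counts.

    ``columns`` holds only positions with >= 1 quality-passing mismatch
    (the caller's candidates); ``base_counts`` holds A/C/G/T counts for
    every covered position and every covered position's transcribed-strand
    votes feed the Alu Editing Index.
    """

    columns: dict[int, PileupColumn]
    base_counts: dict[int, np.ndarray]
    strand_votes: dict[int, Counter]


def build_pileup(
    reads: list[AlignedReadRecord],
    reference: str,
    min_qual: int = 20,
    strandedness: str = "reverse",
    dedup_overlapping_mates: bool = False,
) -> PileupResult:
    """Pile up quality-passing bases of kept reads against the reference.

    A base contributes only when its Phred quality is strictly greater
    than ``min_qual``. End distances of mismatch-carrying reads are the
    1-based distance from the nearer read end in read coordinates. With
    ``dedup_overlapping_mates`` the two mates of a fragment count once
    at positions they both cover (first mate encountered wins).
    """
    ref_len = len(reference)
    base_counts: dict[int, np.ndarray] = {}
    columns: dict[int, PileupColumn] = {}
    votes: dict[int, Counter] = {}
    seen: set[tuple[str, int]] = set()

    for read in reads:
        read_len = len(read.sequence)
        vote = transcribed_strand_vote(read, strandedness)
        for read_off, gpos in read.aligned_pairs:
            if gpos is None or read_off is None:
                continue
            if gpos >= ref_len or gpos < 0:
                raise IndexError(
                    f"read {read.read_id}: position {gpos} outside reference"
                )
            if read.base_qualities[read_off] <= min_qual:
                continue
            base = read.sequence[read_off]
            if base not in BASE_INDEX:
                continue
            if dedup_overlapping_mates:
                key = (read.read_id, gpos)
                if key in seen:
                    continue
                seen.add(key)
            counts = base_counts.get(gpos)
            if counts is None:
                counts = base_counts[gpos] = np.zeros(4, dtype=int)
                votes[gpos] = Counter()
            counts[BASE_INDEX[base]] += 1
            votes[gpos][vote] += 1

            ref_base = reference[gpos]
            if base != ref_base:
                col = columns.get(gpos)
                if col is None:
                    col = columns[gpos] = PileupColumn(gpos, ref_base)
                end_dist = min(read_off + 1, read_len - read_off)
                col.end_distances.append(end_dist)
                col.strand_tallies.setdefault(base, Counter())[read.genome_strand] += 1

    # finalize columns: counts, votes, ref-strand tallies
    for gpos, col in columns.items():
        counts = base_counts[gpos]
        for i, n in enumerate(counts):
            if n:
                col.counts[INDEX_BASE[i]] = int(n)
        col.strand_votes = votes[gpos]
    return PileupResult(columns=columns, base_counts=base_counts, strand_votes=votes)


def read_bam_records(
    bam_path,
    multimap_mode: str = "either",
    unique_mapq: int = 255,
) -> list[AlignedReadRecord]:
    """Load all mapped reads of a BAM as AlignedReadRecords."""
    records = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for seg in bam.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            records.append(
                AlignedReadRecord.from_pysam(seg, multimap_mode, unique_mapq)
            )
    return records
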