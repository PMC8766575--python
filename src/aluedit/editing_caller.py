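"""Site-level editing calls from mismatch pileups.

The cascade after read filtering: (1) positional filter — a site dies
when more than half of its mismatch-carrying reads see the mismatch
within 5 nt of a read end; (2) major-allele rule — with multiple
alternative alleles, one must have >= 5 reads and more than twice the
reads of every other; (3) the major alternative allele needs >= 3 reads
and the position must be absent from the common-SNP catalog (records
flagged as cDNA-template discoveries are not excluded); (4) the variant
class is expressed on the transcribed strand inferred by majority vote
over the contributing reads, so a genomic T>C on a '-' transcript is an
A>G call. Calls are then consolidated across samples: a site survives
only with a consistent class and strand everywhere it was called, and
when seen in at least two patients.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from aluedit.read_filters import PileupColumn, PileupResult
from aluedit.simulate.genome import COMPLEMENT, GeneModel, RepeatInterval

logger = logging.getLogger(__name__)

VARIANT_CLASSES = (
    "A>C", "A>G", "A>T", "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T", "T>A", "T>C", "T>G",
)


@dataclass
class CandidateSite:
    """A mismatch position after pileup, before site-level filters."""

    chrom: str
    position: int
    ref_base: str
    counts: dict  # allele -> quality-passing reads
    n_mismatch_reads: int
    n_end_proximal_mismatch_reads: int
    transcribed_strand: str  # '+', '-' or 'ambiguous'
    major_alt_base: str | None = None

    @classmethod
    def from_column(
        cls, chrom: str, col: PileupColumn, end_distance: int = 5
    ) -> "CandidateSite":
        n_mismatch = sum(n for b, n in col.counts.items() if b != col.ref_base)
        n_proximal = sum(1 for d in col.end_distances if d <= end_distance)
        plus = col.strand_votes.get("+", 0)
        minus = col.strand_votes.get("-", 0)
        if plus > minus:
            strand = "+"
        elif minus > plus:
            strand = "-"
        else:
            strand = "ambiguous"
        return cls(
            chrom=chrom,
            position=col.genome_position,
            ref_base=col.ref_base,
            counts=dict(col.counts),
            n_mismatch_reads=n_mismatch,
            n_end_proximal_mismatch_reads=n_proximal,
            transcribed_strand=strand,
        )


@dataclass
class EditingCall:
    """A typed RNA variant in one sample, class on the transcribed strand."""

    chrom: str
    position: int
    variant_class: str
    transcribed_strand: str
    ref_reads: int
    alt_reads: int
    editing_level: float
    sample_id: str
    in_alu: bool | None = None
    in_intron: bool | None = None
    gene_id: str | None = None


@dataclass
class ConsolidatedSite:
    """A site retained across samples with consistent class and strand."""

    chrom: str
    position: int
    variant_class: str
    transcribed_strand: str
    calls: list = field(default_factory=list)
    n_patients_observed: int = 0
    in_alu: bool | None = None
    in_intron: bool | None = None
    gene_id: str | None = None


def positional_filter(site: CandidateSite) -> bool:
    """Pass unless mismatches sit within 5 nt of a read end in more than
    half of the mismatch-carrying reads (strict majority)."""
    if site.n_mismatch_reads < 1:
        raise ValueError("positional filter needs >= 1 mismatch read")
    return not (
        site.n_end_proximal_mismatch_reads * 2 > site.n_mismatch_reads
    )


def major_allele_filter(
    site: CandidateSite, min_reads: int = 5, ratio: float = 2.0
) -> tuple[bool, str | None]:
    """With multiple alternative alleles, require a major one with
    >= min_reads reads and more than ratio-fold the reads of every other
    alternative; with a single alternative the rule does not apply."""
    alts = {b: n for b, n in site.counts.items() if b != site.ref_base and n > 0}
    if not alts:
        raise ValueError("major-allele filter needs >= 1 alternative allele")
    if len(alts) == 1:
        ((base, _),) = alts.items()
        return True, base
    best = max(alts, key=lambda b: (alts[b], b))
    if alts[best] < min_reads:
        return False, None
    if all(alts[best] > ratio * n for b, n in alts.items() if b != best):
        return True, best
    return False, None


def assign_strand_and_class(
    ref_base: str, alt_base: str, transcribed_strand: str
) -> str | None:
    """Variant class on the transcribed strand; None when ambiguous."""
    if transcribed_strand == "ambiguous":
        return None
    if transcribed_strand == "-":
        ref_base = COMPLEMENT[ref_base]
        alt_base = COMPLEMENT[alt_base]
    return f"{ref_base}>{alt_base}"


def call_site(
    site: CandidateSite,
    snp_catalog: set[tuple[str, int]],
    sample_id: str,
    min_alt_reads: int = 3,
    major_allele_min: int = 5,
    major_allele_ratio: float = 2.0,
) -> EditingCall | None:
    """Full site-level cascade for one candidate in one sample."""
    if not isinstance(snp_catalog, (set, frozenset, dict)):
        raise TypeError("SNP catalog must be a position-indexed set")
    if not positional_filter(site):
        return None
    ok, major_alt = major_allele_filter(site, major_allele_min, major_allele_ratio)
    if not ok:
        return None
    site.major_alt_base = major_alt
    alt_reads = site.counts.get(major_alt, 0)
    if alt_reads < min_alt_reads:
        return None
    if (site.chrom, site.position) in snp_catalog:
        return None
    variant_class = assign_strand_and_class(
        site.ref_base, major_alt, site.transcribed_strand
    )
    if variant_class is None:
        logger.debug(
            "site %s:%d dropped: ambiguous transcribed strand", site.chrom, site.position
        )
        return None
    ref_reads = site.counts.get(site.ref_base, 0)
    return EditingCall(
        chrom=site.chrom,
        position=site.position,
        variant_class=variant_class,
        transcribed_strand=site.transcribed_strand,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
        editing_level=alt_reads / (ref_reads + alt_reads),
        sample_id=sample_id,
    )


def call_sample(
    pileup: PileupResult,
    chrom: str,
    snp_catalog: set[tuple[str, int]],
    sample_id: str,
    min_alt_reads: int = 3,
    end_distance: int = 5,
    major_allele_min: int = 5,
    major_allele_ratio: float = 2.0,
) -> list[EditingCall]:
    """All editing calls of one sample from its pileup."""
    calls = []
    for pos in sorted(pileup.columns):
        site = CandidateSite.from_column(chrom, pileup.columns[pos], end_distance)
        call = call_site(
            site, snp_catalog, sample_id,
            min_alt_reads, major_allele_min, major_allele_ratio,
        )
        if call is not None:
            calls.append(call)
    return calls


def consolidate(
    calls: list[EditingCall],
    sample_sheet: pd.DataFrame,
    min_patients: int = 2,
) -> list[ConsolidatedSite]:
    """Cross-sample consolidation.

    A position is retained iff every sample's call there agrees on class
    and strand, and the calls span >= min_patients distinct patients
    (tumor and normal tissue both qualify). Idempotent.
    """
    patient_of = dict(zip(sample_sheet.sample_id, sample_sheet.patient_id))
    flat: list[EditingCall] = []
    for item in calls:
        if isinstance(item, ConsolidatedSite):
            flat.extend(item.calls)
        else:
            flat.append(item)
    by_pos: dict[tuple[str, int], list[EditingCall]] = defaultdict(list)
    for call in flat:
        if call.sample_id not in patient_of:
            raise KeyError(f"sample {call.sample_id} missing from sample sheet")
        by_pos[(call.chrom, call.position)].append(call)

    sites = []
    for (chrom, pos), group in sorted(by_pos.items()):
        classes = {c.variant_class for c in group}
        strands = {c.transcribed_strand for c in group}
        if len(classes) > 1 or len(strands) > 1:
            logger.debug("site %s:%d dropped: inconsistent type/strand", chrom, pos)
            continue
        patients = {patient_of[c.sample_id] for c in group}
        if len(patients) < min_patients:
            continue
        sites.append(
            ConsolidatedSite(
                chrom=chrom,
                position=pos,
                variant_class=group[0].variant_class,
                transcribed_strand=group[0].transcribed_strand,
                calls=group,
                n_patients_observed=len(patients),
            )
        )
    return sites


def _check_sorted(intervals: list[tuple[int, int]], what: str) -> None:
    starts = [s for s, _ in intervals]
    if starts != sorted(starts):
        raise ValueError(f"{what} annotation is not coordinate-sorted")


def annotate_sites(
    sites: list,
    repeats: list[RepeatInterval],
    genes: list[GeneModel],
) -> list:
    """Set in_alu / in_intron / gene_id on calls or consolidated sites.

    in_alu: position inside a repeat whose subfamily name begins with
    "Alu"; in_intron: inside a gene body but in no exon of any
    transcript. Annotations must be coordinate-sorted.
    """
    _check_sorted([(r.start, r.end) for r in repeats], "repeat")
    _check_sorted([(g.start, g.end) for g in genes], "gene")
    alu = [(r.start, r.end) for r in repeats if r.name.startswith("Alu")]

    def in_alu(pos: int) -> bool:
        return any(s <= pos < e for s, e in alu)

    for site in sites:
        pos = site.position
        site.in_alu = in_alu(pos)
        site.gene_id = None
        site.in_intron = False
        for g in genes:
            if g.start <= pos < g.end:
                site.gene_id = g.gene_id
                site.in_intron = not any(s <= pos < e for s, e in g.exons)
                break
        for attr_call in getattr(site, "calls", []):
            attr_call.in_alu = site.in_alu
            attr_call.in_intron = site.in_intron
            attr_call.gene_id = site.gene_id
    return sites


def sites_per_million(calls: list[EditingCall], total_mapped_reads: int) -> float:
    """A>G sites per one million mapped reads for one sample."""
    if total_mapped_reads <= 0:
        raise ZeroDivisionError("total_mapped_reads must be > 0")
    n = sum(1 for c in calls if c.variant_class == "A>G")
    return n * 1e6 / total_mapped_reads


def calls_to_frame(calls: list[EditingCall]) -> pd.DataFrame:
    """Per-sample calls as a TSV-ready table (positions 1-based)."""
    rows = [
        {
            "chrom": c.chrom,
            "pos_1based": c.position + 1,
            "strand": c.transcribed_strand,
            "variant_class": c.variant_class,
            "ref_reads": c.ref_reads,
            "alt_reads": c.alt_reads,
            "editing_level": c.editing_level,
            "in_alu": c.in_alu,
            "in_intron": c.in_intron,
            "gene_id": c.gene_id,
            "sample_id": c.sample_id,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos_1based", "strand", "variant_class", "ref_reads",
            "alt_reads", "editing_level", "in_alu", "in_intron", "gene_id",
            "sample_id",
        ],
    )


def consolidated_to_frame(sites: list[ConsolidatedSite]) -> pd.DataFrame:
    """Site x sample long table of consolidated calls."""
    rows = []
    for s in sites:
        for c in s.calls:
            rows.append(
                {
                    "chrom": s.chrom,
                    "pos_1based": s.position + 1,
                    "strand": s.transcribed_strand,
                    "variant_class": s.variant_class,
                    "n_patients_observed": s.n_patients_observed,
                    "sample_id": c.sample_id,
                    "ref_reads": c.ref_reads,
                    "alt_reads": c.alt_reads,
                    "editing_level": c.editing_level,
                    "in_alu": s.in_alu,
                    "in_intron": s.in_intron,
                    "gene_id": s.gene_id,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos_1based", "strand", "variant_class",
            "n_patients_observed", "sample_id", "ref_reads", "alt_reads",
            "editing_level", "in_alu", "in_intron", "gene_id",
        ],
    )
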