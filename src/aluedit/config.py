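"""Configuration objects for the simulator and the analysis pipeline.

Defaults encode the study design the package emulates: 41 patients with
paired tumor and neurotypical tissue across six glioma pathologies, and
the thresholds of the editing-call filter cascade (base quality > 20,
alternate reads >= 3, end-distance 5 nt, major-allele 5 reads and 2x,
sites in >= 2 patients, FDR < 0.05, back-splice gate > 3 reads).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Patients per pathology in the emulated cohort design (41 total).
PATHOLOGY_PATIENT_COUNTS: dict[str, int] = {
    "O2": 6,
    "O3": 9,
    "A2": 4,
    "A3": 5,
    "A4": 2,
    "GBM": 15,
}

#: Default tumor-minus-normal shift of the A-to-I editing level per
#: pathology, on the raw [0,1] level scale. Values follow the reported
#: per-pathology mean differences; A4, untested in the source design
#: (n=2), is set between its neighboring astrocytoma grades.
DEFAULT_EDITING_DELTA: dict[str, float] = {
    "O2": 0.04,
    "O3": -0.08,
    "A2": -0.30,
    "A3": -0.19,
    "A4": -0.15,
    "GBM": -0.07,
}

#: Default tumor-minus-normal shift of the circular-RNA expression rate
#: (back-splice / total junction reads) per pathology.
DEFAULT_CIRC_DELTA: dict[str, float] = {
    "O2": -0.01,
    "O3": -0.02,
    "A2": -0.04,
    "A3": -0.04,
    "A4": -0.03,
    "GBM": -0.03,
}


def default_pathology_assignment(
    n_patients: int,
    counts: Mapping[str, int] = PATHOLOGY_PATIENT_COUNTS,
) -> list[str]:
    """Per-patient pathology labels.

    For the full design (``n_patients == sum(counts)``) the labels are
    exactly the design counts; for smaller cohorts labels are assigned
    round-robin over the pathologies so every label keeps appearing.
    """
    full = [lab for lab, k in counts.items() for _ in range(k)]
    if n_patients == len(full):
        return full
    labels = list(counts)
    return [labels[i % len(labels)] for i in range(n_patients)]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The generator plants A-to-I editing sites (concentrated in intronic
    Alu elements), germline SNPs, read pathologies (PCR duplicates,
    multi-mappers, clipped/indel/homopolymer reads) and per-gene
    back-splice / linear junction counts, all with a recorded truth
    table. Same seed, same config => byte-identical artifacts.
    """

    seed: int = 0
    n_patients: int = 41
    pathology_labels: list[str] | None = None  # per patient; default design
    n_genes: int = 12
    n_alu_per_gene: int = 2
    frac_alu_genes: float = 1.0  # fraction of genes carrying Alu intervals
    circ_prob_alu: float = 1.0   # P(circRNA signature | gene has Alu)
    circ_prob_no_alu: float = 0.25  # P(circRNA signature | no Alu)
    n_editing_sites: int = 120
    editing_level_normal: tuple[float, float] = (2.0, 6.0)  # Beta(a, b)
    editing_level_range: tuple[float, float] = (0.02, 0.98)  # truncation bounds
    editing_delta_tumor: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDITING_DELTA)
    )
    site_dispersion: float = 0.05  # intraclass correlation rho in [0, 1)
    coverage_mean: float = 50.0
    read_length: int = 101
    frac_duplicates: float = 0.10
    frac_multimap: float = 0.05
    frac_clipped: float = 0.05
    frac_indel: float = 0.03
    frac_homopolymer_reads: float = 0.02
    n_snps: int = 30
    base_error_rate: float = 0.001
    circ_rate_normal: float = 0.10
    circ_delta_tumor: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CIRC_DELTA)
    )
    junction_depth_mean: float = 100.0
    # genome layout (structural, rarely changed)
    exon_length: int = 250
    intron_length: int = 700
    intergenic_length: int = 300

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.pathology_labels is None:
            self.pathology_labels = default_pathology_assignment(self.n_patients)
        if len(self.pathology_labels) != self.n_patients:
            raise ValueError(
                "pathology_labels must have one label per patient "
                f"({len(self.pathology_labels)} != {self.n_patients})"
            )
        for name in (
            "frac_duplicates",
            "frac_multimap",
            "frac_clipped",
            "frac_indel",
            "frac_homopolymer_reads",
            "base_error_rate",
            "circ_rate_normal",
            "frac_alu_genes",
            "circ_prob_alu",
            "circ_prob_no_alu",
        ):
            _check_prob(name, getattr(self, name))
        if not 0.0 <= self.site_dispersion < 1.0:
            raise ValueError("site_dispersion must lie in [0, 1)")
        a, b = self.editing_level_normal
        if a <= 0 or b <= 0:
            raise ValueError("editing_level_normal Beta hyper-parameters must be > 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        unknown = set(self.pathology_labels) - set(self.editing_delta_tumor)
        if unknown:
            raise ValueError(f"no editing_delta_tumor for pathologies {sorted(unknown)}")
        unknown = set(self.pathology_labels) - set(self.circ_delta_tumor)
        if unknown:
            raise ValueError(f"no circ_delta_tumor for pathologies {sorted(unknown)}")

    @property
    def pathologies(self) -> list[str]:
        """Distinct pathology labels in cohort order."""
        seen: dict[str, None] = {}
        assert self.pathology_labels is not None
        for lab in self.pathology_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Thresholds and I/O paths of the editing/circRNA pipeline.

    Threshold defaults are the published filter cascade; any override is
    logged by the pipeline runner.
    """

    # inputs
    bam_dir: Path | None = None
    reference_fasta: Path | None = None
    snp_vcf: Path | None = None
    repeats_bed: Path | None = None
    genes_gtf: Path | None = None
    junctions_tsv: Path | None = None
    circ_coords_tsv: Path | None = None
    sample_sheet: Path | None = None
    output_dir: Path = Path("aluedit_out")
    # thresholds
    min_qual: int = 20            # base quality strictly greater than this
    min_alt_reads: int = 3        # alternate-allele reads >= this
    end_distance: int = 5         # proximal if within this many nt of a read end
    major_allele_min: int = 5
    major_allele_ratio: float = 2.0
    min_patients: int = 2         # consolidation: site in >= this many patients
    fdr: float = 0.05
    min_bsj: int = 3              # gene tested iff max back-splice reads > this
    min_patients_per_pathology: int = 3  # smaller pathologies skipped for testing
    include_small_pathologies: bool = False
    # conventions
    strandedness: str = "reverse"         # mate 2 on the transcribed strand
    multimap_mode: str = "either"         # "tag", "mapq", or "either"
    unique_mapq: int = 255                # aligner's unique-mapping MAPQ
    dedup_overlapping_mates: bool = False  # count overlapping mates once?
    cdna_info_flag: str = "CDNA"          # VCF INFO flag marking cDNA-derived SNPs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strandedness not in ("reverse", "forward"):
            raise ValueError("strandedness must be 'reverse' or 'forward'")
        if self.multimap_mode not in ("tag", "mapq", "either"):
            raise ValueError("multimap_mode must be 'tag', 'mapq' or 'either'")
        for name, value in self.threshold_dict().items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")

    def threshold_dict(self) -> dict[str, float]:
        return {
            "min_qual": self.min_qual,
            "min_alt_reads": self.min_alt_reads,
            "end_distance": self.end_distance,
            "major_allele_min": self.major_allele_min,
            "major_allele_ratio": self.major_allele_ratio,
            "min_patients": self.min_patients,
            "fdr": self.fdr,
            "min_bsj": self.min_bsj,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in raw:
            if key.endswith(("_dir", "_fasta", "_vcf", "_bed", "_gtf", "_tsv")) or key in (
                "sample_sheet",
                "output_dir",
            ):
                raw[key] = Path(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
            if v is not None
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def config_hash(self) -> str:
        import hashlib
        import json

        data = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def sequence_or_none(x: Sequence | None) -> list | None:
    return None if x is None else list(x)
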