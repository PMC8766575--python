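"""Shared fixtures: crafted read records and a small simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from aluedit.config import PipelineConfig, SimulationConfig

hypothesis_settings.register_profile("derandomized", derandomize=True, deadline=None)
hypothesis_settings.load_profile("derandomized")
from aluedit.read_filters import AlignedReadRecord
from aluedit.simulate import simulate_cohort


def make_record(
    sequence: str = "A" * 101,
    cigar: list[tuple[str, int]] | None = None,
    qualities: int | list[int] = 37,
    read_id: str = "r1",
    mate: int = 2,
    genome_strand: str = "+",
    duplicate: bool = False,
    multimap: bool = False,
    start: int = 0,
) -> AlignedReadRecord:
    """Build a read record; aligned_pairs derived from the CIGAR."""
    if cigar is None:
        cigar = [("M", len(sequence))]
    if isinstance(qualities, int):
        qualities = [qualities] * len(sequence)
    pairs = []
    qoff, gpos = 0, start
    for op, length in cigar:
        if op == "M":
            pairs.extend((qoff + i, gpos + i) for i in range(length))
            qoff += length
            gpos += length
        elif op in "IS":
            qoff += length
        elif op in "DN":
            gpos += length
    return AlignedReadRecord(
        read_id=read_id,
        mate=mate,
        genome_strand=genome_strand,
        duplicate_flag=duplicate,
        multimap_indicator=multimap,
        cigar=cigar,
        sequence=sequence,
        base_qualities=np.array(qualities),
        aligned_pairs=pairs,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Four-patient cohort with planted sites and SNPs, with BAMs."""
    config = SimulationConfig(
        seed=11,
        n_patients=4,
        pathology_labels=["O2", "O2", "A2", "A2"],
        n_genes=4,
        n_editing_sites=40,
        n_snps=12,
        coverage_mean=40.0,
        editing_level_range=(0.15, 0.9),
    )
    outdir = tmp_path_factory.mktemp("small_cohort")
    return simulate_cohort(config, outdir)


@pytest.fixture()
def pipeline_config():
    return PipelineConfig()
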