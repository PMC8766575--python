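"""Per-pathology differential-editing analysis and summary statistics.

A site enters a pathology's test set only when it was called in both
tissues of every patient of that pathology; each tested site gets a
beta-binomial likelihood-ratio test of tumor vs normal editing level
with the patient as covariate, FDR-corrected within the pathology.
The stage also computes the Alu Editing Index (the coverage-weighted
aggregate editing level over transcribed-strand adenosines inside Alu
intervals, as a percentage) and the cumulative distribution of
per-site tumor-minus-normal level differences with paired t and
Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from aluedit import bbstat
from aluedit.editing_caller import ConsolidatedSite
from aluedit.read_filters import BASE_INDEX, PileupResult
from aluedit.simulate.genome import RepeatInterval


@dataclass
class PathologyTestSet:
    """Sites testable in one pathology plus their count observations."""

    pathology: str
    site_ids: list[str]
    observations: pd.DataFrame  # unit_id, sample_id, k, n, condition, patient_id


@dataclass
class AeiResult:
    """Alu Editing Index of one sample."""

    sample_id: str
    edited_read_total: int
    informative_read_total: int
    aei: float | None  # percentage; None when no informative reads
    defined: bool


def select_test_sites(
    sites: list[ConsolidatedSite],
    sample_sheet: pd.DataFrame,
    pathology: str,
) -> PathologyTestSet:
    """Sites called in both tissues of every patient of the pathology."""
    cohort = sample_sheet[sample_sheet.pathology == pathology]
    if cohort.empty:
        raise KeyError(f"unknown pathology label: {pathology}")
    patients = cohort.patient_id.unique()
    if len(patients) < 2:
        raise ValueError(f"pathology {pathology} has fewer than 2 patients")
    needed = set(cohort.sample_id)
    patient_of = dict(zip(cohort.sample_id, cohort.patient_id))
    condition_of = dict(zip(cohort.sample_id, cohort.condition))

    rows = []
    site_ids = []
    for site in sites:
        have = {c.sample_id for c in site.calls}
        if not needed <= have:
            continue
        unit_id = f"{site.chrom}:{site.position}"
        site_ids.append(unit_id)
        for c in site.calls:
            if c.sample_id not in needed:
                continue
            rows.append(
                {
                    "unit_id": unit_id,
                    "sample_id": c.sample_id,
                    "k": c.alt_reads,
                    "n": c.ref_reads + c.alt_reads,
                    "condition": condition_of[c.sample_id],
                    "patient_id": patient_of[c.sample_id],
                }
            )
    obs = pd.DataFrame(
        rows, columns=["unit_id", "sample_id", "k", "n", "condition", "patient_id"]
    )
    return PathologyTestSet(pathology=pathology, site_ids=site_ids, observations=obs)


def diff_editing(test_set: PathologyTestSet, fdr: float = 0.05) -> pd.DataFrame:
    """Differential-editing results for one pathology's test set."""
    if test_set.observations.empty:
        raise ValueError(f"no testable sites for pathology {test_set.pathology}")
    result = bbstat.differential_test(test_set.observations, fdr=fdr)
    result.insert(0, "pathology", test_set.pathology)
    return result


def observed_deltas(test_set: PathologyTestSet) -> pd.DataFrame:
    """Per-site observed mean levels per condition, without model fits.

    Returns unit_id, mean_tumor, mean_normal, difference — the inputs of
    the delta-CDF summaries when no significance call is needed.
    """
    obs = test_set.observations.copy()
    obs["level"] = obs.k / obs.n.replace(0, np.nan)
    wide = obs.pivot_table(index="unit_id", columns="condition", values="level")
    out = pd.DataFrame(
        {
            "unit_id": wide.index,
            "mean_tumor": wide["tumor"].to_numpy(),
            "mean_normal": wide["normal"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["difference"] = out.mean_tumor - out.mean_normal
    return out


def aei_from_counts(counts: list[tuple[int, int]]) -> float:
    """AEI from (unedited, edited) read counts at adenosine positions:
    100 x sum(edited) / sum(unedited + edited)."""
    edited = sum(g for _, g in counts)
    informative = sum(a + g for a, g in counts)
    if informative == 0:
        raise ZeroDivisionError("no informative reads")
    return 100.0 * edited / informative


def compute_aei(
    pileup: PileupResult,
    repeats: list[RepeatInterval],
    reference: str,
    sample_id: str = "",
) -> AeiResult:
    """Alu Editing Index of one sample.

    Sums G-supporting over (A+G)-supporting quality-passing reads at
    every reference adenosine on the transcribed strand within Alu
    intervals; the transcribed strand per position comes from the
    majority vote of the covering reads (ties skipped). On the '-'
    strand the genomic bases are T (unedited) and C (edited).
    """
    edited = 0
    informative = 0
    a_idx, g_idx = BASE_INDEX["A"], BASE_INDEX["G"]
    t_idx, c_idx = BASE_INDEX["T"], BASE_INDEX["C"]
    for rep in repeats:
        if not rep.name.startswith("Alu"):
            continue
        for pos in range(rep.start, rep.end):
            counts = pileup.base_counts.get(pos)
            if counts is None:
                continue
            votes = pileup.strand_votes.get(pos)
            plus = votes.get("+", 0)
            minus = votes.get("-", 0)
            if plus == minus:
                continue
            strand = "+" if plus > minus else "-"
            ref_base = reference[pos]
            if strand == "+" and ref_base == "A":
                edited += int(counts[g_idx])
                informative += int(counts[a_idx] + counts[g_idx])
            elif strand == "-" and ref_base == "T":
                edited += int(counts[c_idx])
                informative += int(counts[t_idx] + counts[c_idx])
    if informative == 0:
        return AeiResult(sample_id, 0, 0, None, defined=False)
    return AeiResult(
        sample_id, edited, informative, 100.0 * edited / informative, defined=True
    )


@dataclass
class DeltaSummary:
    """Empirical CDF of per-unit tumor-normal differences + paired tests."""

    pathology: str
    n_units: int
    mean_difference: float
    t_p_value: float
    wilcoxon_p_value: float
    ecdf: pd.DataFrame  # columns: difference, cdf


def delta_summary(
    diffs: pd.DataFrame,
    pathology: str = "",
    significant_only: bool = False,
) -> DeltaSummary:
    """Summarize tumor-minus-normal differences over units.

    ``diffs`` must carry mean_tumor and mean_normal per unit (the
    differential-testing output qualifies); ``significant_only``
    restricts to FDR-significant units.
    """
    df = diffs
    if significant_only:
        df = df[df["significant"]]
    pairs = df[["mean_tumor", "mean_normal"]].dropna()
    if len(pairs) < 2:
        raise ValueError("need >= 2 paired values for a delta summary")
    delta = (pairs["mean_tumor"] - pairs["mean_normal"]).to_numpy()
    t_p = float(stats.ttest_rel(pairs["mean_tumor"], pairs["mean_normal"]).pvalue)
    if np.allclose(delta, 0.0):
        w_p = 1.0
    else:
        w_p = float(stats.wilcoxon(delta, alternative="two-sided").pvalue)
    xs = np.sort(delta)
    cdf = np.arange(1, len(xs) + 1) / len(xs)
    return DeltaSummary(
        pathology=pathology,
        n_units=len(delta),
        mean_difference=float(delta.mean()),
        t_p_value=t_p,
        wilcoxon_p_value=w_p,
        ecdf=pd.DataFrame({"difference": xs, "cdf": cdf}),
    )


def sign_test_centered(deltas: np.ndarray) -> float:
    """Two-sided sign test that differences are centered at zero."""
    deltas = np.asarray(deltas, dtype=float)
    nonzero = deltas[deltas != 0.0]
    if nonzero.size == 0:
        return 1.0
    n_pos = int((nonzero > 0).sum())
    return float(stats.binomtest(n_pos, nonzero.size, 0.5).pvalue)
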