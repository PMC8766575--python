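#!/usr/bin/env python
"""Summarize per-pathology differential editing and the AEI contrast.

Reads the pipeline outputs of 02: per-pathology mean editing-level
differences (tumor - normal), significant-site counts at FDR < 0.05,
paired t / Wilcoxon tests over per-site deltas, and the paired AEI
difference per pathology. Writes results/editing_summary.tsv and
results/aei_summary.tsv.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from aluedit.editing_analysis import delta_summary

ROOT = Path(__file__).resolve().parent.parent
PIPE = ROOT / "results" / "pipeline"


def main() -> None:
    diff = pd.read_csv(PIPE / "diff_editing.tsv", sep="\t")
    sheet = pd.read_csv(ROOT / "results" / "sample_sheet.tsv", sep="\t")

    rows = []
    for pathology, group in diff.groupby("pathology"):
        summary = delta_summary(group, pathology)
        rows.append(
            {
                "pathology": pathology,
                "n_sites_tested": len(group),
                "n_significant_fdr05": int(group.significant.sum()),
                "mean_level_delta": round(summary.mean_difference, 4),
                "paired_t_p": summary.t_p_value,
                "wilcoxon_p": summary.wilcoxon_p_value,
            }
        )
    summary_table = pd.DataFrame(rows).sort_values("pathology")
    summary_table.to_csv(ROOT / "results" / "editing_summary.tsv", sep="\t", index=False)
    print("differential editing per pathology:")
    print(summary_table.to_string(index=False))

    aei = pd.read_csv(PIPE / "aei.tsv", sep="\t").merge(sheet, on="sample_id")
    wide = aei.pivot_table(index=["patient_id", "pathology"],
                           columns="condition", values="aei_percent").reset_index()
    aei_rows = []
    for pathology, grp in wide.groupby("pathology"):
        delta = (grp.tumor - grp.normal).dropna()
        if len(delta) < 2:
            continue
        w_p = stats.wilcoxon(delta).pvalue if (delta != 0).any() else 1.0
        aei_rows.append(
            {
                "pathology": pathology,
                "n_patients": len(delta),
                "mean_aei_delta_percent": round(float(delta.mean()), 3),
                "wilcoxon_p": float(w_p),
            }
        )
    aei_table = pd.DataFrame(aei_rows).sort_values("pathology")
    aei_table.to_csv(ROOT / "results" / "aei_summary.tsv", sep="\t", index=False)
    print("\npaired AEI difference (tumor - normal) per pathology:")
    print(aei_table.to_string(index=False))


if __name__ == "__main__":
    main()
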