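#!/usr/bin/env python
"""Characterize the k=6 subgroups against the clinical table.

Chi-squared enrichment of pseudo cancer types per subgroup (BH-corrected
across all pairs), Kaplan-Meier / log-rank survival contrasts of each
enriched subgroup vs the remaining samples of the same type, and Fisher
tests of stage and grade distributions.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import netstrat as ns

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    clinical = ns.read_clinical(RESULTS / "cohort" / "clinical.tsv")
    assignment = pd.read_csv(RESULTS / "assignment_k6.tsv", sep="\t",
                             index_col=0)["subgroup"]

    enrichment = ns.enrichment_test(assignment, clinical["cancer_type"])
    enrichment.to_csv(RESULTS / "enrichment_k6.tsv", sep="\t", index=False)
    top = enrichment.nsmallest(6, "p_value")
    print("strongest subgroup enrichments (chi-squared, BH q):")
    for _, row in top.iterrows():
        print(f"  subgroup {row.subgroup} x {row.label}: "
              f"{row.count_in_subgroup}/{row.subgroup_size} samples, "
              f"q = {row.q_value:.2e} (display p {row.display_p:.1e})")

    scan = ns.survival_scan(clinical, assignment)
    scan.to_csv(RESULTS / "survival_scan_k6.tsv", sep="\t", index=False)
    sig = scan[scan.p_value < 0.05]
    print(f"\nlog-rank survival contrasts with p < 0.05: {len(sig)}/{len(scan)}")
    for _, row in sig.nsmallest(5, "p_value").iterrows():
        print(f"  subgroup {row.subgroup} within {row.cancer_type}: "
              f"p = {row.p_value:.2e} (n = {row.n_in} vs {row.n_rest})")

    rows = []
    for subgroup in sorted(assignment.unique()):
        for cancer_type in sorted(clinical["cancer_type"].dropna().unique()):
            for feature in ("stage", "grade"):
                try:
                    _, p, se = ns.stage_association(
                        clinical, assignment, subgroup, cancer_type, feature=feature
                    )
                except ValueError:
                    continue
                rows.append({"subgroup": subgroup, "cancer_type": cancer_type,
                             "feature": feature, "fisher_p": p, "mc_se": se})
    stage_grade = pd.DataFrame(rows)
    stage_grade.to_csv(RESULTS / "stage_grade_k6.tsv", sep="\t", index=False)
    n_sig = (stage_grade.fisher_p < 0.05).sum()
    print(f"\nstage/grade Fisher tests with p < 0.05: {n_sig}/{len(stage_grade)}")


if __name__ == "__main__":
    main()
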