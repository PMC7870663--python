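#!/usr/bin/env python
"""Cohort statistics battery on the simulated cohort.

Laterality tests with FDR correction across the canal measures, Pearson
correlations of the main measures with TIV, and the TIV-controlled sex
ANCOVA.  Writes ``results/statistics.json`` and a TIV-correlation scatter
figure to ``results/tiv_correlations.png``.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from innerear.phantom import CohortSpec, cohort_to_table, generate_cohort
from innerear.stats import gender_ancova, laterality_tests, tiv_correlations

RESULTS = Path(__file__).resolve().parents[1] / "results"

MAIN_MEASURES = ("inner_ear_length_total", "cochlea_height_oblique",
                 "scc_ant_radius", "scc_post_radius", "scc_lat_radius")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = cohort_to_table(generate_cohort(CohortSpec(n_subjects=30, seed=7)))
    scc_measures = [c for c in table.columns if c.startswith("scc_")]

    laterality = laterality_tests(table, scc_measures)
    n_significant = sum(r.significant for r in laterality)
    print(f"laterality: {n_significant} of {len(laterality)} measures "
          "significant after FDR")

    correlations = tiv_correlations(table, MAIN_MEASURES)
    for r in correlations:
        print(f"TIV vs {r.measure}: r = {r.statistic:.3f}, p = {r.pvalue:.2g}")

    ancova = gender_ancova(table, "inner_ear_length_total")
    print(f"sex ANCOVA (total length | TIV): "
          f"F(1,{ancova.df_residual}) = {ancova.F:.2f}, p = {ancova.pvalue:.3f}")

    report = {
        "laterality": [
            {"measure": r.measure, "test": r.test, "statistic": r.statistic,
             "p_raw": r.pvalue, "p_fdr": r.p_adjusted,
             "significant": bool(r.significant)}
            for r in laterality
        ],
        "tiv_correlations": [
            {"measure": r.measure, "r": r.statistic, "p": r.pvalue}
            for r in correlations
        ],
        "sex_ancova_total_length": {
            "F": ancova.F, "df_between": ancova.df_between,
            "df_residual": ancova.df_residual, "p": ancova.pvalue,
            "adjusted_means": ancova.adjusted_means,
        },
    }
    (RESULTS / "statistics.json").write_text(json.dumps(report, indent=2))

    per_subject = table.groupby("subject").agg(
        {**{m: "mean" for m in MAIN_MEASURES}, "tiv_cm3": "first"})
    fig, axes = plt.subplots(1, len(MAIN_MEASURES), figsize=(4 * len(MAIN_MEASURES), 3.5))
    for ax, corr in zip(axes, correlations):
        ax.scatter(per_subject["tiv_cm3"], per_subject[corr.measure], s=12)
        ax.set_xlabel("TIV (cm$^3$)")
        ax.set_ylabel(f"{corr.measure} (mm)")
        ax.set_title(f"r = {corr.statistic:.2f}, p = {corr.pvalue:.2g}")
    fig.tight_layout()
    fig.savefig(RESULTS / "tiv_correlations.png", dpi=120)
    print(f"wrote {RESULTS / 'statistics.json'} and tiv_correlations.png")


if __name__ == "__main__":
    main()
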