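#!/usr/bin/env python
"""Steady-state comparison track on every non-labeling preset.

Normalizes each cohort to sample mass and the d4-succinate internal
standard, computes fold changes against the preset's control group, runs
two-tailed Student's t-tests with Bonferroni correction across the panel,
and a PCA of the normalized profiles.  Prints which metabolites changed
significantly and how much PC1 separates the genotypes.
"""

from pathlib import Path

from midflux.io import read_sample_table
from midflux.simulate import SCENARIOS
from midflux.stats import (
    compare_to_control,
    fold_change_vs_control,
    normalize_table,
    pca_scores,
)

IN = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    for name, cfg in SCENARIOS.items():
        if cfg.flux_f:
            continue
        table_path = IN / name / "sample_table.csv"
        if not table_path.exists():
            raise SystemExit(f"{table_path} missing - run 01_simulate_cohorts.py first")
        normalized = normalize_table(read_sample_table(table_path))
        rel = fold_change_vs_control(normalized, cfg.control_group)
        rel.reset_index().to_csv(IN / name / "relative_abundance.csv", index=False)
        out = compare_to_control(normalized, cfg.control_group)
        out.to_csv(IN / name / "comparison.csv", index=False)
        pca = pca_scores(normalized)
        pca.scores.reset_index().to_csv(IN / name / "pca_scores.csv", index=False)
        hits = out[out["significant"]]
        print(f"\n{name} (control = {cfg.control_group}):")
        for _, row in hits.iterrows():
            print(
                f"  {row['metabolite']:>10}: fold change "
                f"{row['fold_change']:.2f}, p_adj = {row['p_adj']:.2e}"
            )
        if hits.empty:
            print("  no significant changes")
        print(
            f"  PC1 explains {pca.explained_variance_ratio[0] * 100:.1f}% "
            "of the metabolic-profile variance"
        )


if __name__ == "__main__":
    main()
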