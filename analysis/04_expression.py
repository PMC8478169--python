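#!/usr/bin/env python
"""Copper-induction expression profiling with the ddCT method.

Screens the reference gene for stability (SD of CT < 1), computes
per-gene log2 fold changes against the no-copper control for each copper
concentration and timepoint, applies the Shapiro-Wilk-gated Welch-t /
Mann-Whitney significance test, and compares estimates to the planted
effects.
"""

from pathlib import Path

import pandas as pd

from cuprome.qpcr import read_ct_table, reference_stability, run_expression_analysis

ROOT = Path(__file__).resolve().parent.parent / "results"
IN = ROOT / "inputs"
REFERENCE = "pfk"


def main() -> None:
    ct = read_ct_table(IN / "ct_table.csv")
    sd, stable = reference_stability(ct, REFERENCE)
    print(f"reference gene {REFERENCE}: SD of CT = {sd:.2f} -> {'stable' if stable else 'NOT stable'}")

    results = run_expression_analysis(ct, REFERENCE, control_condition="control")
    results.to_csv(ROOT / "expression_results.csv", index=False)

    truth = pd.read_csv(IN / "ct_truth.csv")
    merged = results.merge(truth, on=["gene", "condition", "timepoint"], suffixes=("", "_planted"))
    merged["abs_error"] = (merged["log2_fold_change"] - merged["log2_fold_change_planted"]).abs()
    print(f"\n{len(results)} gene x condition x timepoint contrasts; "
          f"{results['significant'].sum()} significant at p < 0.05")
    print(f"mean |log2FC error| vs planted truth: {merged['abs_error'].mean():.3f} "
          f"(max {merged['abs_error'].max():.3f})")
    print("\nlog2 fold changes (30min):")
    pivot = results[results["timepoint"] == "30min"].pivot(
        index="gene", columns="condition", values="log2_fold_change"
    )
    print(pivot.round(2).to_string())


if __name__ == "__main__":
    main()
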