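#!/usr/bin/env python
"""Compare the two arms across the derived phenotype panel.

Applies the normality-gated procedure (Student's t or Mann-Whitney per
variable), computes Cohen's d and percent differences, and the
within-patient imaging-agreement and mass-strength correlations.
Writes comparisons.csv, correlations.csv and a markdown report.
"""

import argparse
from pathlib import Path

import pandas as pd

from myoquant import correlation_report, group_report, report_markdown


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--derived", type=Path, default=Path("results/derived_measures.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    df = pd.read_csv(args.derived, index_col="id")
    comparisons = group_report(df)
    correlations = correlation_report(df)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    comparisons.to_csv(args.out_dir / "comparisons.csv")
    correlations.to_csv(args.out_dir / "correlations.csv", index=False)
    (args.out_dir / "report.md").write_text(report_markdown(comparisons, correlations))

    sig = comparisons[comparisons["significant"]]
    print(f"{len(sig)}/{len(comparisons)} variables differ between arms (p < 0.05):")
    for var, row in sig.iterrows():
        print(
            f"  {var:<20} {row['test_used']:<13} p={row['p_value']:.4g}  "
            f"d={row['cohens_d']:.2f}  diff={row['percent_diff']:+.1f}%"
        )
    print(f"report -> {args.out_dir / 'report.md'}")


if __name__ == "__main__":
    main()
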