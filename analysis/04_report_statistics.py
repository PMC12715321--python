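#!/usr/bin/env python
"""Group comparisons and LR-vs-micrographia correlations for the simulated study.

Runs the reporting layer on the metrics and classifier outputs: group summary
table, unpaired-t comparisons of consistent area and sequence effect between
groups, and Spearman correlations between the patient LR scores and both
micrographia measures (the expected signature is a negative LR-vs-sequence-
effect correlation: more shrinkage, higher impairment score).
"""

import pandas as pd

import common
from penstroke.pipeline import stage_report


def main() -> None:
    args = common.parser(__doc__).parse_args()
    config = common.build_config(args)
    out = config.out_dir
    report_dir = stage_report(
        config,
        out / "subject_metrics.csv",
        out / "patient_lr.csv",
        out / "pages" / "manifest.csv",
    )
    print(f"report tables: {report_dir}\n")
    comparisons = pd.read_csv(report_dir / "comparisons.csv")
    if not comparisons.empty:
        print(comparisons.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    correlations = pd.read_csv(report_dir / "correlations.csv")
    if not correlations.empty:
        print()
        print(correlations.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
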