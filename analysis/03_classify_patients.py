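#!/usr/bin/env python
"""Patient-disjoint 5-fold classification of row instances, then ROC analysis.

Crops every page into its ten row instances, trains the small convolutional
scorer on patient-disjoint folds, aggregates each subject's out-of-fold
instance probabilities into a likelihood-ratio score (LR in [0, 1], higher =
handwriting read as more impaired), and evaluates the patient-level ROC:
AUC, Youden index with its associated criterion, and the operating metrics at
the study prevalence.
"""

import json

import common
from penstroke.pipeline import stage_classify, stage_roc


def main() -> None:
    args = common.parser(__doc__).parse_args()
    config = common.build_config(args)
    manifest_path = config.out_dir / "pages" / "manifest.csv"
    scores_path = stage_classify(config, manifest_path)
    roc_path = stage_roc(config, scores_path)
    roc = json.loads(roc_path.read_text())
    print(f"patient LR scores: {scores_path}")
    print(
        f"{roc['comparison']}: AUC={roc['auc']:.2f}  J={roc['youden_j']:.2f} "
        f"at criterion {roc['associated_criterion']:.3f}\n"
        f"sens={roc['sensitivity']:.2f} spec={roc['specificity']:.2f} "
        f"PPV={roc['ppv']:.2f} NPV={roc['npv']:.2f} acc={roc['accuracy']:.2f} "
        f"({roc['n_pos']} positive vs {roc['n_neg']} negative subjects)"
    )


if __name__ == "__main__":
    main()
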