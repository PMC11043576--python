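#!/usr/bin/env python
"""Evaluate the final model and assemble the run report.

Computes ROC curves, Hanley-McNeil inference against chance, and confusion
tables with exact binomial intervals for the training and testing splits;
reruns the modeling chain on pathology-confirmed cases only (the sensitivity
analysis); and writes a single JSON report plus the testing-set ROC points.
An ROC plot is written when matplotlib is importable.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mirdiscover.cohort import TEST, TRAIN
from mirdiscover.config import RunConfig
from mirdiscover.evaluation import confusion_at_threshold, hanley_mcneil_test, roc_auc
from mirdiscover.mlp import MlpModel

from importlib import import_module
load_features = import_module("04_train_mlp_ensemble").load_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = RunConfig.load(args.data / "config.yaml")
    model = MlpModel.from_json((args.out / "final_model.json").read_text())
    features = load_features(args.data)
    feats = list(model.feature_names)

    report = {"threshold": cfg.evaluation.threshold, "splits": {}}
    for split in (TRAIN, TEST):
        X, y = features.X(feats, split), features.y(split)
        p = model.predict_proba(X)
        curve = roc_auc(p[y == 1], p[y == 0])
        hm = hanley_mcneil_test(curve.auc, int(y.sum()), int((1 - y).sum()))
        conf = confusion_at_threshold(p, y, cfg.evaluation.threshold,
                                      ci_level=cfg.evaluation.ci_level,
                                      ci_method=cfg.evaluation.ci_method)
        report["splits"][split] = {
            "auc": curve.auc,
            "hanley_mcneil": {"se": hm.se, "z": hm.z, "p": hm.p_two_sided,
                              "ci_95": list(hm.ci_95)},
            "confusion": conf.as_dict(),
        }
        print(f"{split}: AUC {curve.auc:.3f} "
              f"(p vs chance {hm.p_two_sided:.2g}), "
              f"sensitivity {100 * conf.sensitivity:.1f}%, "
              f"specificity {100 * conf.specificity:.1f}%")
        if split == TEST:
            pd.DataFrame(curve.points, columns=["fpr", "tpr"]).to_csv(
                args.out / "roc_testing.tsv", sep="\t", index=False)
            roc_points = curve.points

    (args.out / "evaluation_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(roc_points[:, 0], roc_points[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        auc = report["splits"][TEST]["auc"]
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"Testing-set ROC (AUC = {auc:.2f})")
        fig.tight_layout()
        fig.savefig(args.out / "roc_testing.png", dpi=150)
        print(f"wrote {args.out / 'roc_testing.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
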