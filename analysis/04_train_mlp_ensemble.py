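#!/usr/bin/env python
"""Train the MLP ensemble and pick the final model.

Samples random single-hidden-layer architectures (hidden size n/3..1.5n,
four activation families), trains each by BFGS on the training split,
ranks by training AUC, keeps the top 50, and selects the final model on
the testing split.  The full published sweep is 15,000 networks; this
driver defaults to 1,000 for a desk-scale run (--networks to change).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mirdiscover.cohort import TEST, TRAIN
from mirdiscover.config import RunConfig
from mirdiscover.mlp import ensemble_search, select_final
from mirdiscover.replication import FeatureTable


def load_features(data: Path) -> FeatureTable:
    frame = pd.read_csv(data / "replication_features.tsv", sep="\t",
                        index_col="sample_id")
    probes = tuple(c for c in frame.columns
                   if c not in ("hormone_use", "group", "split"))
    return FeatureTable(frame, probe_ids=probes)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--networks", type=int, default=1000)
    args = ap.parse_args()

    cfg = RunConfig.load(args.data / "config.yaml")
    seeds = cfg.sub_seeds()
    features = load_features(args.data)
    fs = json.loads((args.out / "feature_set.json").read_text())
    feats = fs["selected"] + fs["forced"]
    print(f"model inputs ({len(feats)}): {', '.join(feats)}")

    X_tr, y_tr = features.X(feats, TRAIN), features.y(TRAIN)
    X_te, y_te = features.X(feats, TEST), features.y(TEST)
    result = ensemble_search(X_tr, y_tr, n_networks=args.networks,
                             top_k=cfg.mlp.top_k, seed=seeds["ensemble"],
                             feature_names=feats, max_iter=cfg.mlp.max_iter,
                             l2=cfg.mlp.l2)
    final = select_final(result, X_te, y_te)

    final.manifest.to_csv(args.out / "ensemble_manifest.tsv", sep="\t",
                          index=False)
    (args.out / "final_model.json").write_text(final.model.to_json())
    arch = final.record.architecture
    print(f"trained {args.networks} networks; kept top {len(result.top_k)} "
          f"by training AUC")
    print(f"final model: {arch.n_hidden} hidden {arch.hidden_activation} units, "
          f"training AUC {final.record.train_auc:.3f}, "
          f"testing AUC {final.test_auc:.3f}")


if __name__ == "__main__":
    main()
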