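#!/usr/bin/env python
"""Replication-phase screen: univariate tests, PCA separation, and CFS.

Splits the replication cohort 2:1 (stratified on group and hormone use),
preprocesses the MFI panel (0.001 shift, log10), runs training-set t-tests
with Holm-Sidak correction, checks PCA/clustering separation, and selects
model inputs by CFS with the hormone covariate forced in.
"""

import argparse
import json
from pathlib import Path

from mirdiscover.cohort import read_sample_sheet, stratified_split, write_sample_sheet
from mirdiscover.config import RunConfig
from mirdiscover.replication import (
    HORMONE_COVARIATE,
    cfs_select,
    pca_separation,
    preprocess_mfi,
    univariate_tests,
)
from mirdiscover.simulate import read_mfi_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = RunConfig.load(args.data / "config.yaml")
    r = cfg.replication
    seeds = cfg.sub_seeds()
    cohort = read_sample_sheet(args.data / "replication_samples.csv")
    cohort = stratified_split(cohort, r.train_fraction, strata=r.split_strata,
                              seed=seeds["split"])
    write_sample_sheet(cohort, args.data / "replication_samples_split.csv")
    mfi = read_mfi_tsv(args.data / "replication_mfi.tsv")

    features = preprocess_mfi(mfi, cohort, r.shift_value, r.subtract_background)
    features.frame.to_csv(args.data / "replication_features.tsv", sep="\t",
                          index_label="sample_id")
    print(f"features: {len(features.probe_ids)} probes x {len(features.frame)} "
          f"samples; {features.n_negative_shifted} negative values shifted")

    uni = univariate_tests(features, training_only=True)
    uni.to_csv(args.out / "replication_univariate.tsv", sep="\t",
               index_label="probe_id")
    n_adj = int((uni["p_adjusted"] < 0.05).sum())
    print(f"univariate screen (training set): "
          f"{int((uni['p_raw'] <= r.p_gate).sum())} probes at raw p <= {r.p_gate}; "
          f"{n_adj} significant after Holm-Sidak correction")

    pca = pca_separation(features, seed=seeds["cfs"])
    print(f"PCA separation: PC1 AUC {pca.pc1_auc:.3f}, "
          f"2-cluster agreement {pca.cluster_agreement:.3f}")

    fs = cfs_select(features, forced=(HORMONE_COVARIATE,), folds=r.cfs_folds,
                    seed=seeds["cfs"], p_gate=r.p_gate,
                    min_fold_fraction=r.min_fold_fraction,
                    stall_limit=r.stall_limit, exhaustive_max=r.exhaustive_max,
                    locally_predictive=r.locally_predictive)
    print(f"CFS selected {len(fs.selected)} probes + forced {fs.forced}: "
          f"{', '.join(fs.features)}")
    (args.out / "feature_set.json").write_text(json.dumps({
        "selected": list(fs.selected),
        "forced": list(fs.forced),
        "candidate_pool": list(fs.candidate_pool),
        "fold_picks": [list(p) for p in fs.fold_picks],
        "fold_merits": list(fs.fold_merits),
        "frequencies": fs.frequencies,
        "pca": {"pc1_auc": pca.pc1_auc,
                "cluster_agreement": pca.cluster_agreement,
                "explained_variance_ratio":
                    pca.explained_variance_ratio.tolist()},
    }, indent=2))


if __name__ == "__main__":
    main()
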