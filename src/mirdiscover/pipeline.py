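"""End-to-end orchestration: simulate -> discovery -> replication -> model ->
evaluation, with the pathology-confirmed sensitivity rerun.

Every stage consumes a named sub-seed fanned out from the run seed, so a
full run is a pure function of its :class:`~mirdiscover.config.RunConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import discovery as disc
from . import replication as rep
from .cohort import CASE, TEST, TRAIN, CohortTable, stratified_split
from .config import RunConfig
from .evaluation import confusion_at_threshold, hanley_mcneil_test
from .mlp import EnsembleSearchResult, FinalSelection, ensemble_search, select_final
from .replication import HORMONE_COVARIATE, FeatureSet, FeatureTable
from .simulate import (
    RecoveryReport,
    recovery_report,
    simulate_cohort,
    simulate_ct_matrix,
    simulate_mfi_matrix,
)


@dataclass(frozen=True)
class ModelingResult:
    """Replication-phase modeling output for one case set."""

    feature_set: FeatureSet
    ensemble: EnsembleSearchResult
    final: FinalSelection
    univariate: pd.DataFrame
    pca_pc1_auc: float
    pca_cluster_agreement: float
    train_confusion: dict
    test_confusion: dict
    test_hanley: dict
    n_train_cases: int
    n_test_cases: int

    def summary(self) -> dict:
        return {
            "features": list(self.feature_set.features),
            "candidate_pool": list(self.feature_set.candidate_pool),
            "n_adjusted_significant": int((self.univariate["p_adjusted"] < 0.05).sum()),
            "pca_pc1_auc": self.pca_pc1_auc,
            "pca_cluster_agreement": self.pca_cluster_agreement,
            "final_architecture": vars(self.final.record.architecture),
            "final_train_auc": self.final.record.train_auc,
            "final_test_auc": self.final.test_auc,
            "train_confusion": self.train_confusion,
            "test_confusion": self.test_confusion,
            "test_hanley": self.test_hanley,
            "n_train_cases": self.n_train_cases,
            "n_test_cases": self.n_test_cases,
        }


@dataclass(frozen=True)
class PipelineResult:
    config: RunConfig
    seeds: dict
    discovery_selection: disc.StratifiedSelectionResult
    references: tuple[str, ...]
    panel: pd.DataFrame
    discovery_recovery: RecoveryReport
    replication_cohort: CohortTable
    features: FeatureTable
    main: ModelingResult
    cfs_recovery: RecoveryReport
    sensitivity: ModelingResult | None = None

    def report(self) -> dict:
        out = {
            "seeds": dict(self.seeds),
            "discovery": {
                "n_candidates": len(self.discovery_selection.selected_ids),
                "selected": list(self.discovery_selection.selected_ids),
                "references": list(self.references),
                "recovery": {
                    "recall": self.discovery_recovery.recall,
                    "n_false": self.discovery_recovery.n_false,
                },
            },
            "panel_size": int(len(self.panel)),
            "replication": self.main.summary(),
            "cfs_recovery": {
                "recall": self.cfs_recovery.recall,
                "n_false": self.cfs_recovery.n_false,
            },
        }
        if self.sensitivity is not None:
            out["sensitivity"] = self.sensitivity.summary()
        return out

    def to_json(self) -> str:
        return json.dumps(self.report(), sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _run_modeling(features: FeatureTable, cohort: CohortTable, config: RunConfig,
                  seeds: dict, case_ids: Sequence[str] | None = None
                  ) -> ModelingResult:
    """Univariate screen, PCA, CFS and the ensemble sweep on one case set.

    ``case_ids`` restricts the cases (sensitivity rerun); controls and the
    split assignment are untouched.
    """
    frame = features.frame
    if case_ids is not None:
        keep = (frame["group"] != CASE) | frame.index.isin(case_ids)
        features = FeatureTable(frame[keep], probe_ids=features.probe_ids,
                                qc_cv=features.qc_cv,
                                n_negative_shifted=features.n_negative_shifted)
    r = config.replication
    univariate = rep.univariate_tests(features, training_only=True,
                                      welch=config.discovery.welch)
    pca = rep.pca_separation(features, split=TRAIN, seed=seeds["cfs"])
    feature_set = rep.cfs_select(
        features, forced=(HORMONE_COVARIATE,), folds=r.cfs_folds,
        seed=seeds["cfs"], p_gate=r.p_gate,
        min_fold_fraction=r.min_fold_fraction, stall_limit=r.stall_limit,
        exhaustive_max=r.exhaustive_max,
        locally_predictive=r.locally_predictive,
    )
    feats = list(feature_set.features)
    X_train = features.X(feats, TRAIN)
    y_train = features.y(TRAIN)
    X_test = features.X(feats, TEST)
    y_test = features.y(TEST)
    ensemble = ensemble_search(
        X_train, y_train, n_networks=config.mlp.n_networks,
        top_k=config.mlp.top_k, seed=seeds["ensemble"], feature_names=feats,
        max_iter=config.mlp.max_iter, l2=config.mlp.l2,
    )
    final = select_final(ensemble, X_test, y_test)

    thr = config.evaluation.threshold
    kw = dict(ci_level=config.evaluation.ci_level,
              ci_method=config.evaluation.ci_method)
    train_conf = confusion_at_threshold(
        final.model.predict_proba(X_train), y_train, thr, **kw)
    test_conf = confusion_at_threshold(
        final.model.predict_proba(X_test), y_test, thr, **kw)
    hm = hanley_mcneil_test(final.test_auc, int(y_test.sum()),
                            int((1 - y_test).sum()))
    return ModelingResult(
        feature_set=feature_set, ensemble=ensemble, final=final,
        univariate=univariate, pca_pc1_auc=pca.pc1_auc,
        pca_cluster_agreement=pca.cluster_agreement,
        train_confusion=train_conf.as_dict(), test_confusion=test_conf.as_dict(),
        test_hanley={"auc": hm.auc, "se": hm.se, "z": hm.z, "p": hm.p_two_sided,
                     "ci_95": list(hm.ci_95)},
        n_train_cases=int(y_train.sum()), n_test_cases=int(y_test.sum()),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full discovery -> replication -> model -> evaluation chain on a
    simulated two-phase cohort, plus the sensitivity rerun when flagged."""
    seeds = config.sub_seeds()
    s = config.simulation
    truth = s.truth()

    # --- discovery phase -------------------------------------------------
    disc_cohort = simulate_cohort(
        s.n_cases_discovery, s.control_ratio_discovery,
        s.hormone_fraction_discovery, s.age_range,
        seed=seeds["discovery_cohort"], phase="discovery",
        pathology_confirmed_fraction=s.pathology_confirmed_fraction,
    )
    ct = simulate_ct_matrix(disc_cohort, truth, n_mirnas=s.n_mirnas,
                            seed=seeds["discovery_ct"])
    d = config.discovery
    collapsed = disc.collapse_duplicates(ct, d.max_duplicate_discordance)
    filtered, _qc = disc.qc_filter(collapsed, d.ct_max, d.max_missing_fraction)
    if d.outlier_flagging:
        filtered, _ = disc.flag_outliers(filtered, disc_cohort, d.outlier_alpha)
    imputed = disc.impute_missing(filtered, disc_cohort, d.impute_strategy)
    expr = disc.global_normalize(imputed)
    groups = {sid: disc_cohort.record(sid).group for sid in imputed.values.columns}
    ranking = disc.normfinder_stability(expr, groups,
                                        shrink_bias=d.normfinder_shrinkage)
    references = disc.select_references(ranking, d.k_references)
    expr = expr.with_references(references)
    selection = disc.stratified_ttests(expr, disc_cohort, p_strict=d.p_strict,
                                       p_both=d.p_both, welch=d.welch)
    selected = selection.selected_ids
    disc_recovery = recovery_report(selected, truth)

    # --- panel and replication cohort ------------------------------------
    literature = [f"lit-miR-{i:02d}" for i in range(1, s.n_literature_probes + 1)]
    positives = [f"pos-ctl-{i}" for i in range(1, s.n_positive_controls + 1)]
    negatives = [f"neg-ctl-{i}" for i in range(1, s.n_negative_controls + 1)]
    panel = disc.assemble_panel(selected, literature, positives, negatives)

    rep_cohort = simulate_cohort(
        s.n_cases_replication, s.control_ratio_replication,
        s.hormone_fraction_replication, s.age_range,
        seed=seeds["replication_cohort"], phase="replication",
        pathology_confirmed_fraction=s.pathology_confirmed_fraction,
    )
    rep_cohort = stratified_split(
        rep_cohort, config.replication.train_fraction,
        strata=config.replication.split_strata, seed=seeds["split"],
    )
    mfi = simulate_mfi_matrix(
        rep_cohort, truth, panel["probe_id"].tolist(), blank_wells=s.blank_wells,
        qc_fraction=s.qc_fraction, seed=seeds["replication_mfi"],
    )
    features = rep.preprocess_mfi(mfi, rep_cohort, config.replication.shift_value,
                                  config.replication.subtract_background)

    # --- modeling ---------------------------------------------------------
    main = _run_modeling(features, rep_cohort, config, seeds)
    cfs_recovery = recovery_report(main.feature_set.features, truth,
                                   ignore=(HORMONE_COVARIATE,))

    sensitivity = None
    if config.sensitivity_pathology_confirmed_only:
        confirmed = tuple(
            r.sample_id for r in rep_cohort.records
            if r.group == CASE and r.pathology_confirmed
        )
        sensitivity = _run_modeling(features, rep_cohort, config, seeds,
                                    case_ids=confirmed)

    return PipelineResult(
        config=config, seeds=seeds, discovery_selection=selection,
        references=references, panel=panel, discovery_recovery=disc_recovery,
        replication_cohort=rep_cohort, features=features, main=main,
        cfs_recovery=cfs_recovery, sensitivity=sensitivity,
    )
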