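"""Replication-phase preprocessing and feature selection.

Raw bead-panel fluorescence is shifted (values <= 0 become 0.001) and
log10-transformed; candidate probes are screened by pooled t-tests with
Holm-Sidak familywise correction and a PCA/clustering separation check; the
model's input set is chosen by correlation-based feature selection (CFS)
with stratified 10-fold cross-validation, a univariate p <= 0.15 gate, and
the hormone-use covariate forced into every evaluated subset.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .cohort import CASE, CohortTable, TRAIN, TEST
from .discovery import pooled_ttest, signed_fold_change
from .evaluation import roc_auc
from .simulate import MfiMatrix

HORMONE_COVARIATE = "hormone_use"


@dataclass(frozen=True)
class FeatureTable:
    """Samples x (probes + covariates) table of log10 MFI values.

    ``frame`` is indexed by sample id with one column per probe plus
    ``hormone_use`` (0/1), ``group`` and, when the cohort carries a split,
    ``split``.  Probe values are finite with no missing entries.
    """

    frame: pd.DataFrame
    probe_ids: tuple[str, ...]
    qc_cv: pd.Series | None = None
    n_negative_shifted: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        block = self.frame[list(self.probe_ids)].to_numpy(float)
        if not np.isfinite(block).all():
            raise ValueError("probe values must be finite with no missing entries")

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.frame
        if "split" not in self.frame.columns:
            raise ValueError("feature table has no split assignment")
        return self.frame[self.frame["split"] == split]

    def X(self, features: Sequence[str], split: str | None = None) -> np.ndarray:
        return self.rows(split)[list(features)].to_numpy(float)

    def y(self, split: str | None = None) -> np.ndarray:
        return (self.rows(split)["group"] == CASE).to_numpy(int)


def preprocess_mfi(mfi: MfiMatrix, cohort: CohortTable, shift_value: float = 0.001,
                   subtract_background: bool = False) -> FeatureTable:
    """Shift non-positive MFI values to ``shift_value``, log10-transform, and
    attach the hormone covariate and group labels.

    Background (blank-well) subtraction is off by default; blank and pooled
    QC wells never enter the study table — QC wells are summarized as a
    per-probe coefficient of variation.
    """
    study = mfi.wells("study")
    missing = set(cohort.sample_ids) - set(study)
    if missing:
        raise ValueError(f"cohort samples missing from matrix: {sorted(missing)}")
    vals = mfi.values[list(cohort.sample_ids)].astype(float)
    if subtract_background:
        blanks = mfi.wells("blank")
        if blanks:
            vals = vals.sub(mfi.values[blanks].mean(axis=1), axis=0)
    if not np.isfinite(vals.to_numpy()).all():
        raise ValueError("non-finite MFI values in study wells")
    n_shifted = int((vals.to_numpy() <= 0).sum())
    vals = vals.where(vals > 0, shift_value)
    log10 = np.log10(vals)

    qc = mfi.wells("qc_pool")
    qc_cv = None
    if qc:
        qv = mfi.values[qc]
        mean = qv.mean(axis=1)
        sd = qv.std(axis=1, ddof=1) if len(qc) > 1 else pd.Series(0.0, index=qv.index)
        qc_cv = (sd / mean.where(mean != 0, np.nan)).fillna(0.0).rename("qc_cv")

    frame = log10.T
    frame[HORMONE_COVARIATE] = [
        int(cohort.record(s).hormone_use) for s in frame.index
    ]
    frame["group"] = [cohort.record(s).group for s in frame.index]
    if cohort.split is not None:
        frame["split"] = [cohort.split[s] for s in frame.index]
    return FeatureTable(frame, probe_ids=tuple(log10.index), qc_cv=qc_cv,
                        n_negative_shifted=n_shifted)


# ---------------------------------------------------------------------------
# Univariate screening


def holm_sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sorted ascending, adjusted_(i) = 1 - (1 - p_(i))^(m - i + 1), monotonized
    by running maximum, returned in the input order and capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = 1.0 - np.power(1.0 - p[order], m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def univariate_tests(features: FeatureTable, training_only: bool = True,
                     welch: bool = False) -> pd.DataFrame:
    """Per-probe pooled t-tests of case vs control log10 MFI.

    Returns mean difference (log10 units), the signed 10^diff fold change,
    raw p, and Holm-Sidak adjusted p.  Probes with zero variance in both
    groups get t = 0, p = 1 and are flagged.
    """
    split = TRAIN if training_only else None
    frame = features.rows(split)
    y = (frame["group"] == CASE).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    X = frame[list(features.probe_ids)].to_numpy(float)
    xc, x0 = X[y], X[~y]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = pooled_ttest(xc, x0, axis=0, welch=welch)
    degenerate = ~np.isfinite(p)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    diff = xc.mean(axis=0) - x0.mean(axis=0)
    return pd.DataFrame(
        {
            "mean_diff": diff,
            "fold_change": signed_fold_change(np.power(10.0, diff)),
            "t": t,
            "p_raw": p,
            "p_adjusted": holm_sidak_adjust(p),
            "degenerate": degenerate,
        },
        index=list(features.probe_ids),
    )


# ---------------------------------------------------------------------------
# PCA / clustering separation


@dataclass(frozen=True)
class PcaReport:
    explained_variance_ratio: np.ndarray
    pc1_auc: float            # folded to >= 0.5 (PC sign is arbitrary)
    cluster_agreement: float  # 2-means label agreement, folded to >= 0.5
    scores: pd.DataFrame
    dropped: tuple[str, ...] = ()


def pca_separation(features: FeatureTable, split: str | None = TRAIN,
                   n_components: int = 5, seed: int = 0) -> PcaReport:
    """PCA on standardized probe columns plus an unsupervised 2-cluster check.

    Separation is summarized as the AUC of PC1 scores against case/control
    labels (0.5 = none); because a principal component's sign is arbitrary,
    both statistics are folded to >= 0.5.
    """
    frame = features.rows(split)
    if len(frame) < 3:
        raise ValueError("need at least 3 samples")
    X = frame[list(features.probe_ids)].to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = tuple(np.asarray(features.probe_ids)[~keep])
    if dropped:
        warnings.warn(f"dropping constant feature columns: {list(dropped)}",
                      stacklevel=2)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_components = min(n_components, Z.shape[1], len(frame) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    y = (frame["group"] == CASE).to_numpy()
    pc1 = scores[:, 0]
    auc = roc_auc(pc1[y], pc1[~y]).auc
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
    agree = float(np.mean(km.labels_ == y))
    return PcaReport(
        explained_variance_ratio=pca.explained_variance_ratio_,
        pc1_auc=max(auc, 1.0 - auc),
        cluster_agreement=max(agree, 1.0 - agree),
        scores=pd.DataFrame(
            scores, index=frame.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Correlation-based feature selection


def cfs_merit(class_corr: Mapping[str, float], feature_corr: pd.DataFrame,
              subset: Sequence[str]) -> float:
    """CFS merit of a feature subset:

        merit = k * mean|r_cf| / sqrt(k + k(k-1) * mean|r_ff|)

    favoring subsets highly correlated with the class but mutually
    uncorrelated.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    k = len(subset)
    rcf = float(np.mean([abs(class_corr[f]) for f in subset]))
    if k == 1:
        return rcf
    pairs = [
        abs(feature_corr.loc[a, b]) for a, b in itertools.combinations(subset, 2)
    ]
    rff = float(np.mean(pairs))
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


def _abs_correlations(frame: pd.DataFrame, feature_names: Sequence[str],
                      y: np.ndarray) -> tuple[dict[str, float], pd.DataFrame]:
    X = frame[list(feature_names)].to_numpy(float)
    yz = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        Xc = X - X.mean(axis=0)
        xn = np.linalg.norm(Xc, axis=0)
        yn = np.linalg.norm(yz)
        rcf = np.abs(Xc.T @ yz) / np.where(xn * yn > 0, xn * yn, np.inf)
        denom = np.outer(xn, xn)
        rff = np.abs(Xc.T @ Xc) / np.where(denom > 0, denom, np.inf)
    rff = pd.DataFrame(rff, index=list(feature_names), columns=list(feature_names))
    return dict(zip(feature_names, rcf)), rff


class _MeritEvaluator:
    """Array-backed CFS merit for the subset searches (identical to
    :func:`cfs_merit`, but indexed for speed)."""

    def __init__(self, class_corr, feature_corr, candidates, forced):
        names = list(forced) + list(candidates)
        self.pos = {f: i for i, f in enumerate(names)}
        self.rcf = np.array([abs(class_corr[f]) for f in names])
        self.rff = np.abs(feature_corr.loc[names, names].to_numpy(float))
        self.forced_idx = np.arange(len(forced))

    def __call__(self, additions: tuple[str, ...]) -> float:
        idx = np.concatenate(
            [self.forced_idx, [self.pos[a] for a in additions]]
        ).astype(int)
        k = idx.size
        if k == 0:
            return 0.0
        rcf = self.rcf[idx].mean()
        if k == 1:
            return float(rcf)
        rff = (self.rff[np.ix_(idx, idx)].sum() - k) / (k * (k - 1))
        return float(k * rcf / np.sqrt(k + k * (k - 1) * rff))


def best_first_search(class_corr: Mapping[str, float], feature_corr: pd.DataFrame,
                      candidates: Sequence[str], forced: Sequence[str] = (),
                      stall_limit: int = 5) -> tuple[tuple[str, ...], float]:
    """Best-first forward search over candidate subsets maximizing CFS merit.

    Forced covariates are part of every evaluated subset; the search stops
    after ``stall_limit`` consecutive non-improving node expansions.  Returns
    the winning candidate additions (excluding forced) and their merit.
    """
    forced = tuple(forced)
    candidates = tuple(sorted(candidates))
    merit_of = _MeritEvaluator(class_corr, feature_corr, candidates, forced)
    start: tuple[str, ...] = ()
    best_set, best_merit = start, merit_of(start)
    counter = itertools.count()
    heap = [(-best_merit, next(counter), start)]
    visited = {start}
    stall = 0
    while heap and stall < stall_limit:
        _, _, node = heapq.heappop(heap)
        improved = False
        for c in candidates:
            if c in node:
                continue
            child = tuple(sorted(node + (c,)))
            if child in visited:
                continue
            visited.add(child)
            m = merit_of(child)
            heapq.heappush(heap, (-m, next(counter), child))
            if m > best_merit + 1e-12:
                best_set, best_merit = child, m
                improved = True
        stall = 0 if improved else stall + 1
    return best_set, best_merit


def exhaustive_search(class_corr: Mapping[str, float], feature_corr: pd.DataFrame,
                      candidates: Sequence[str], forced: Sequence[str] = ()
                      ) -> tuple[tuple[str, ...], float]:
    """Enumerate every candidate subset; ties prefer smaller, then earlier."""
    forced = tuple(forced)
    candidates = tuple(sorted(candidates))
    merit_of = _MeritEvaluator(class_corr, feature_corr, candidates, forced)
    best: tuple[str, ...] = ()
    best_merit = merit_of(())
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            m = merit_of(combo)
            if m > best_merit + 1e-12:
                best, best_merit = combo, m
    return best, best_merit


@dataclass(frozen=True)
class FeatureSet:
    """CFS outcome: majority-vote probes, forced covariates, and per-fold
    provenance."""

    selected: tuple[str, ...]
    forced: tuple[str, ...]
    candidate_pool: tuple[str, ...]
    fold_picks: tuple[tuple[str, ...], ...]
    fold_merits: tuple[float, ...]

    @property
    def features(self) -> tuple[str, ...]:
        """Model inputs: selected probes plus forced covariates."""
        return self.selected + self.forced

    @property
    def frequencies(self) -> dict[str, float]:
        n = len(self.fold_picks)
        counts: dict[str, int] = {}
        for picks in self.fold_picks:
            for f in picks:
                counts[f] = counts.get(f, 0) + 1
        return {f: c / n for f, c in sorted(counts.items())}


def _locally_predictive(chosen: tuple[str, ...], candidates: Sequence[str],
                        class_corr: Mapping[str, float],
                        feature_corr: pd.DataFrame) -> tuple[str, ...]:
    """Hall's locally-predictive refinement: re-admit an unselected candidate
    when its class correlation exceeds its strongest correlation with the
    current subset (descending class-correlation order)."""
    if not chosen:
        return ()
    chosen = list(chosen)
    rest = sorted(
        (c for c in candidates if c not in chosen),
        key=lambda c: -abs(class_corr[c]),
    )
    for c in rest:
        max_ff = max(abs(feature_corr.loc[c, s]) for s in chosen)
        if abs(class_corr[c]) > max_ff:
            chosen.append(c)
    return tuple(sorted(chosen))


def cfs_select(features: FeatureTable, candidates: Sequence[str] | None = None,
               forced: Sequence[str] = (HORMONE_COVARIATE,), folds: int = 10,
               seed: int = 0, p_gate: float = 0.15,
               min_fold_fraction: float = 0.5, stall_limit: int = 5,
               exhaustive_max: int = 15,
               locally_predictive: bool = False) -> FeatureSet:
    """CFS with stratified cross-validation on the training split.

    Candidates are gated to training-set univariate raw p <= ``p_gate``;
    within each fold, correlations come from the fold's training portion and
    the search (exhaustive when the pool is small, best-first otherwise)
    always includes the forced covariates, followed by Hall's
    locally-predictive refinement.  Features chosen in at least
    ``min_fold_fraction`` of folds form the final set.
    """
    if candidates is None:
        candidates = features.probe_ids
    uni = univariate_tests(features, training_only=True)
    gated = tuple(
        c for c in candidates if c in uni.index and uni.loc[c, "p_raw"] <= p_gate
    )
    forced = tuple(forced)
    if not gated:
        warnings.warn("no candidate passed the univariate p-gate; "
                      "feature set is the forced covariates only", stacklevel=2)
        return FeatureSet((), forced, (), (), ())

    frame = features.rows(TRAIN)
    y = (frame["group"] == CASE).to_numpy(int)
    all_feats = list(gated) + list(forced)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    picks: list[tuple[str, ...]] = []
    merits: list[float] = []
    for train_idx, _ in skf.split(np.zeros(len(y)), y):
        sub = frame.iloc[train_idx]
        rcf, rff = _abs_correlations(sub, all_feats, y[train_idx])
        if len(gated) <= exhaustive_max:
            chosen, merit = exhaustive_search(rcf, rff, gated, forced)
        else:
            chosen, merit = best_first_search(rcf, rff, gated, forced,
                                             stall_limit=stall_limit)
        if locally_predictive:
            chosen = _locally_predictive(chosen, gated, rcf, rff)
        picks.append(tuple(sorted(chosen)))
        merits.append(merit)

    counts: dict[str, int] = {}
    for p in picks:
        for f in p:
            counts[f] = counts.get(f, 0) + 1
    selected = tuple(
        c for c in gated if counts.get(c, 0) / folds >= min_fold_fraction
    )
    return FeatureSet(selected, forced, gated, tuple(picks), tuple(merits))
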