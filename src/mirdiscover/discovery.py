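"""Discovery-phase qPCR statistics.

The chain mirrors a standard relative-quantification workflow: technical
duplicates are collapsed, high-Ct measurements removed, outliers flagged,
missing values imputed, every sample is centred on its global mean Ct
(removing per-sample loading artifacts), stable reference miRNAs are chosen
by the Normfinder variance decomposition, and fold changes are computed by
2^-ddCt.  Candidate selection runs pooled-variance t-tests separately within
hormone-use strata and applies a dual-threshold rule: p < 0.005 in either
stratum, or p <= 0.05 in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CASE, CONTROL, CohortTable
from .simulate import CtMatrix

REASON_NONE = "none"
REASON_EITHER = "either_stratum_p005"
REASON_BOTH = "both_strata_p05"


@dataclass(frozen=True)
class NormalizedExpr:
    """miRNA x sample dCt grid (cycles relative to the per-sample global mean)
    plus the reference miRNA set used for ddCt quantification."""

    values: pd.DataFrame
    reference_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_set", tuple(self.reference_set))
        missing = set(self.reference_set) - set(self.values.index)
        if missing:
            raise ValueError(f"reference miRNAs not in matrix: {sorted(missing)}")

    def with_references(self, reference_set: Sequence[str]) -> "NormalizedExpr":
        return NormalizedExpr(self.values, tuple(reference_set))

    def reference_adjusted(self) -> pd.DataFrame:
        """dCt minus the per-sample mean of the reference set.

        With an empty reference set the globally normalized values are
        returned unchanged.
        """
        if not self.reference_set:
            return self.values
        ref_mean = self.values.loc[list(self.reference_set)].mean(axis=0)
        return self.values.sub(ref_mean, axis=1)


@dataclass(frozen=True)
class QcReport:
    dropped_mirnas: tuple[str, ...]
    n_values_censored: int
    per_mirna_missing: pd.Series
    per_sample_missing: pd.Series


@dataclass(frozen=True)
class StabilityRanking:
    """Normfinder stability values: rho per miRNA (lower = more stable) with
    its group-bias (d) and sampling-error (se) components."""

    rho: pd.Series
    bias: pd.DataFrame
    se: pd.DataFrame


# ---------------------------------------------------------------------------
# Pre-processing


def collapse_duplicates(ct: CtMatrix, max_discordance: float = 1.0) -> CtMatrix:
    """Replace each technical-duplicate pair by its mean.

    Pairs differing by more than ``max_discordance`` cycles are set missing;
    if only one replicate is observed it passes through.
    """
    if ct.replicate_of is None:
        raise ValueError("replicate pairing is not defined on this matrix")
    by_sample: dict[str, list[str]] = {}
    for col in ct.values.columns:
        by_sample.setdefault(ct.replicate_of[col], []).append(col)
    for sid, cols in by_sample.items():
        if len(cols) > 2:
            raise ValueError(f"sample {sid!r} has {len(cols)} replicate columns")

    out = {}
    for sid, cols in by_sample.items():
        block = ct.values[cols].to_numpy(float)
        if block.shape[1] == 1:
            out[sid] = block[:, 0]
            continue
        a, b = block[:, 0], block[:, 1]
        both = np.isfinite(a) & np.isfinite(b)
        # singletons pass through; all-missing pairs stay missing
        mean = np.where(both, (a + b) / 2.0, np.where(np.isfinite(a), a, b))
        discordant = both & (np.abs(a - b) > max_discordance)
        mean[discordant] = np.nan
        out[sid] = mean
    values = pd.DataFrame(out, index=ct.values.index)
    values = values[[s for s in dict.fromkeys(by_sample)]]
    return CtMatrix(values, replicate_of=None)


def qc_filter(ct: CtMatrix, ct_max: float = 34.0,
              max_missing_fraction: float = 0.5) -> tuple[CtMatrix, QcReport]:
    """Censor measurements with Ct greater than ``ct_max`` (strictly) and drop
    miRNAs whose missing fraction then exceeds ``max_missing_fraction``."""
    if ct_max <= 0:
        raise ValueError("ct_max must be positive")
    v = ct.values.to_numpy(float).copy()
    censored = int(np.sum(v > ct_max))
    v[v > ct_max] = np.nan
    values = pd.DataFrame(v, index=ct.values.index, columns=ct.values.columns)
    frac = values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError("QC filter dropped every miRNA; nothing to analyze")
    report = QcReport(
        dropped_mirnas=tuple(values.index[~keep]),
        n_values_censored=censored,
        per_mirna_missing=frac,
        per_sample_missing=values.isna().mean(axis=0),
    )
    return CtMatrix(values.loc[keep], replicate_of=ct.replicate_of), report


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def flag_outliers(ct: CtMatrix, cohort: CohortTable, alpha: float = 0.05,
                  min_n: int = 5) -> tuple[CtMatrix, int]:
    """Grubbs-style outlier exclusion per miRNA within case/control group.

    Iteratively removes the most extreme value while the Grubbs statistic
    exceeds its two-sided critical value; excluded values become missing.
    """
    values = ct.values.copy()
    n_flagged = 0
    for group_ids in (cohort.case_ids, cohort.control_ids):
        cols = [c for c in group_ids if c in values.columns]
        if len(cols) < min_n:
            continue
        block = values[cols].to_numpy(float)
        for gi in range(block.shape[0]):
            row = block[gi]
            while True:
                obs = np.isfinite(row)
                n = int(obs.sum())
                if n < min_n:
                    break
                x = row[obs]
                sd = x.std(ddof=1)
                if sd == 0:
                    break
                dev = np.abs(x - x.mean())
                j = int(np.argmax(dev))
                if dev[j] / sd <= _grubbs_critical(n, alpha):
                    break
                row[np.flatnonzero(obs)[j]] = np.nan
                n_flagged += 1
        values[cols] = block
    return CtMatrix(values, replicate_of=ct.replicate_of), n_flagged


def impute_missing(ct: CtMatrix, cohort: CohortTable,
                   strategy: str = "cell_mean") -> CtMatrix:
    """Impute missing Ct values; observed values are never altered.

    The default replaces a missing value with the mean of its miRNA within
    the same (group, hormone stratum) cell, falling back to the miRNA grand
    mean (with a warning) when the cell has no observed value.
    """
    if strategy not in ("cell_mean", "grand_mean"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = ct.values.copy()
    if not values.isna().any().any():
        return CtMatrix(values, replicate_of=ct.replicate_of)
    if values.isna().all(axis=1).any():
        raise ValueError("a miRNA has no observed values; run qc_filter first")

    grand = values.mean(axis=1)
    cells = (
        [values.columns.tolist()]
        if strategy == "grand_mean"
        else [
            [c for c in cohort.ids(group=g, hormone_use=h) if c in values.columns]
            for g in (CASE, CONTROL)
            for h in (True, False)
        ]
    )
    fellback = False
    for cols in cells:
        if not cols:
            continue
        block = values[cols]
        cell_mean = block.mean(axis=1)
        empty = cell_mean.isna()
        if empty.any() and block.isna().any().any():
            fellback = True
        fill = cell_mean.where(~empty, grand)
        values[cols] = block.apply(lambda col: col.fillna(fill))
    if fellback:
        warnings.warn("empty imputation cell(s); fell back to miRNA grand mean",
                      stacklevel=2)
    return CtMatrix(values, replicate_of=ct.replicate_of)


def global_normalize(ct: CtMatrix) -> NormalizedExpr:
    """dCt = Ct minus the per-sample mean over the common detected miRNA set;
    every sample column of the result has mean exactly zero."""
    if ct.values.isna().any().any():
        raise ValueError("global normalization requires a complete matrix")
    values = ct.values.sub(ct.values.mean(axis=0), axis=1)
    return NormalizedExpr(values, reference_set=())


# ---------------------------------------------------------------------------
# Normfinder reference selection


def normfinder_stability(expr: NormalizedExpr, groups: Mapping[str, str] | pd.Series,
                         shrink_bias: bool = False) -> StabilityRanking:
    """Model-based stability value per miRNA.

    For gene i and group g with group mean a_ig and within-group variance
    v_ig, the group-bias term is the two-way interaction residual
    d_ig = a_ig - mean_g(a_ig) - mean_i(a_ig) + mean_ig(a_ig) and

        rho_i = (1/G) * sum_g ( |d_ig| + sqrt(v_ig / n_g) ).

    Lower rho means more stable.  ``shrink_bias`` applies a simple
    empirical-Bayes shrinkage of d toward zero (variance-ratio factor);
    the default is the plain estimator.
    """
    g = pd.Series(groups)
    v = expr.values
    g = g.loc[list(v.columns)]
    counts = g.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    a = v.T.groupby(g).mean().T          # genes x groups
    var = v.T.groupby(g).var(ddof=1).T
    d = a.sub(a.mean(axis=1), axis=0).sub(a.mean(axis=0), axis=1) + a.to_numpy().mean()
    if shrink_bias:
        se2 = (var / counts).mean(axis=0)            # per-group mean sampling var
        tau2 = (d**2).mean(axis=0) - se2
        factor = (tau2 / (tau2 + se2)).clip(lower=0.0, upper=1.0)
        d = d.mul(factor, axis=1)
    se = np.sqrt(var.div(counts, axis=1))
    rho = (d.abs() + se).mean(axis=1)
    return StabilityRanking(rho=rho, bias=d, se=se)


def select_references(ranking: StabilityRanking, k: int = 5) -> tuple[str, ...]:
    """The k most stable miRNAs (smallest rho, ties broken by id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking.rho):
        raise ValueError(f"k={k} exceeds number of ranked miRNAs ({len(ranking.rho)})")
    order = sorted(ranking.rho.index, key=lambda i: (ranking.rho[i], i))
    return tuple(order[:k])


# ---------------------------------------------------------------------------
# Fold changes and stratified selection


def signed_fold_change(ratio: float | np.ndarray) -> float | np.ndarray:
    """Display convention: ratios below 1 become the negative reciprocal,
    so |FC| >= 1 always (ratio 0.25 -> -4)."""
    r = np.asarray(ratio, float)
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def ddct_fold_change(expr: NormalizedExpr, case_ids: Sequence[str],
                     control_ids: Sequence[str]) -> pd.DataFrame:
    """2^-ddCt relative quantification, per miRNA.

    ddCt is the case-minus-control difference of reference-adjusted dCt
    means; the returned ``fold_change`` uses the signed convention.
    """
    if not case_ids or not control_ids:
        raise ValueError("both groups must be nonempty")
    adj = expr.reference_adjusted()
    ddct = adj[list(case_ids)].mean(axis=1) - adj[list(control_ids)].mean(axis=1)
    ratio = np.power(2.0, -ddct)
    return pd.DataFrame(
        {"ddct": ddct, "ratio": ratio, "fold_change": signed_fold_change(ratio.to_numpy())},
        index=adj.index,
    )


def pooled_ttest(x: np.ndarray, y: np.ndarray, axis: int = -1,
                 welch: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test (Student's pooled-variance by default)."""
    res = stats.ttest_ind(x, y, axis=axis, equal_var=not welch)
    return np.asarray(res.statistic, float), np.asarray(res.pvalue, float)


def discovery_selection_rule(p_hormone: float, p_nonhormone: float,
                             p_strict: float = 0.005,
                             p_both: float = 0.05) -> tuple[bool, str]:
    """Dual-threshold inclusion rule for replication-panel candidates.

    Included iff p < ``p_strict`` in either stratum, or p <= ``p_both`` in
    both; the strict clause takes precedence in the recorded reason.
    Missing p-values (NaN) fail the clause they appear in.
    """
    for p in (p_hormone, p_nonhormone):
        if np.isfinite(p) and not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of range: {p}")
    ph = p_hormone if np.isfinite(p_hormone) else np.inf
    pn = p_nonhormone if np.isfinite(p_nonhormone) else np.inf
    if ph < p_strict or pn < p_strict:
        return True, REASON_EITHER
    if ph <= p_both and pn <= p_both:
        return True, REASON_BOTH
    return False, REASON_NONE


@dataclass(frozen=True)
class StratifiedSelectionResult:
    """Per-miRNA fold changes and p-values within hormone strata plus the
    inclusion decision (the discovery candidate table)."""

    table: pd.DataFrame
    p_strict: float = 0.005
    p_both: float = 0.05

    @property
    def selected_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["included"]])


def stratified_ttests(expr: NormalizedExpr, cohort: CohortTable,
                      p_strict: float = 0.005, p_both: float = 0.05,
                      welch: bool = False) -> StratifiedSelectionResult:
    """Per-stratum Student's t-tests and 2^-ddCt fold changes.

    Tests run on reference-adjusted dCt, separately among hormone users and
    non-users; a stratum with fewer than two cases or two controls yields
    missing results for that stratum (flagged via NaN).
    """
    adj = expr.reference_adjusted()
    cols = set(adj.columns)
    out: dict[str, np.ndarray] = {}
    for label, hormone in (("hormone", True), ("nonhormone", False)):
        case_ids = [c for c in cohort.ids(group=CASE, hormone_use=hormone) if c in cols]
        ctrl_ids = [c for c in cohort.ids(group=CONTROL, hormone_use=hormone) if c in cols]
        if len(case_ids) < 2 or len(ctrl_ids) < 2:
            warnings.warn(
                f"{label} stratum degenerate ({len(case_ids)} cases, "
                f"{len(ctrl_ids)} controls); p set to missing", stacklevel=2,
            )
            nan = np.full(len(adj.index), np.nan)
            out[f"t_{label}"], out[f"p_{label}"] = nan, nan.copy()
            out[f"fold_change_{label}"] = nan.copy()
            continue
        t, p = pooled_ttest(
            adj[case_ids].to_numpy(), adj[ctrl_ids].to_numpy(), axis=1, welch=welch
        )
        fc = ddct_fold_change(expr, case_ids, ctrl_ids)["fold_change"].to_numpy()
        out[f"t_{label}"], out[f"p_{label}"] = t, p
        out[f"fold_change_{label}"] = fc

    table = pd.DataFrame(out, index=adj.index)
    decisions = [
        discovery_selection_rule(ph, pn, p_strict=p_strict, p_both=p_both)
        for ph, pn in zip(table["p_hormone"], table["p_nonhormone"])
    ]
    table["included"] = [d[0] for d in decisions]
    table["inclusion_reason"] = [d[1] for d in decisions]
    return StratifiedSelectionResult(table, p_strict=p_strict, p_both=p_both)


# ---------------------------------------------------------------------------
# Panel assembly


def assemble_panel(selected: Sequence[str], literature_additions: Sequence[str] = (),
                   positive_controls: Sequence[str] = (),
                   negative_controls: Sequence[str] = ()) -> pd.DataFrame:
    """Concatenate the replication probe panel, preserving category labels.

    Probes are de-duplicated within a category; a probe appearing in two
    categories is an error naming the probe.
    """
    cats = {
        "discovery": list(dict.fromkeys(selected)),
        "literature": list(dict.fromkeys(literature_additions)),
        "positive_control": list(dict.fromkeys(positive_controls)),
        "negative_control": list(dict.fromkeys(negative_controls)),
    }
    seen: dict[str, str] = {}
    rows = []
    for cat, probes in cats.items():
        for p in probes:
            if p in seen:
                raise ValueError(
                    f"probe {p!r} appears in both {seen[p]!r} and {cat!r}"
                )
            seen[p] = cat
            rows.append((p, cat))
    return pd.DataFrame(rows, columns=["probe_id", "category"])
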