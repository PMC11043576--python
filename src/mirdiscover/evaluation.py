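"""ROC/AUC machinery, Hanley-McNeil inference against chance, and threshold
classification metrics with exact binomial confidence intervals."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RocCurve:
    """AUC plus the (fpr, tpr) polyline from a full threshold sweep.

    The AUC is computed twice — as the tie-corrected rank statistic
    (probability a random case outscores a random control) and as the
    trapezoidal area under the sweep — and the two must agree to 1e-9.
    """

    auc: float
    points: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)


def roc_auc(scores_cases: Sequence[float], scores_controls: Sequence[float]) -> RocCurve:
    cases = np.asarray(scores_cases, float)
    controls = np.asarray(scores_controls, float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score lists must be nonempty")

    # Rank statistic: (# case>control pairs + 0.5 * ties) / (n1 * n0)
    combined = np.concatenate([cases, controls])
    ranks = stats.rankdata(combined)
    n1, n0 = cases.size, controls.size
    auc_rank = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # Threshold sweep: predicted positive iff score >= threshold, thresholds
    # descending over the distinct observed scores.
    labels = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
    order = np.argsort(-combined, kind="stable")
    sorted_scores = combined[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # keep only the last index of each tied block
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    points = np.column_stack([fpr, tpr])
    auc_trap = float(np.trapezoid(tpr, fpr))

    if abs(auc_rank - auc_trap) > 1e-9:
        raise RuntimeError(
            f"rank AUC {auc_rank!r} and trapezoidal AUC {auc_trap!r} disagree"
        )
    return RocCurve(auc=float(auc_rank), points=points)


@dataclass(frozen=True)
class HanleyMcNeilResult:
    auc: float
    se: float
    z: float
    p_two_sided: float
    ci_95: tuple[float, float]
    boundary: bool = False  # SE collapsed to zero (degenerate AUC at n=1)


def hanley_mcneil_test(auc: float, n_cases: int, n_controls: int,
                       null_auc: float = 0.5) -> HanleyMcNeilResult:
    """Analytic SE of an AUC and a two-sided z-test against ``null_auc``.

    Uses the exponential-approximation moments Q1 = A/(2-A) and
    Q2 = 2A^2/(1+A):

        SE^2 = [A(1-A) + (n1-1)(Q1-A^2) + (n0-1)(Q2-A^2)] / (n1 * n0)
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("group counts must be >= 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_cases - 1) * (q1 - a * a)
        + (n_controls - 1) * (q2 - a * a)
    ) / (n_cases * n_controls)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        return HanleyMcNeilResult(a, 0.0, np.inf if a != null_auc else 0.0,
                                  np.nan, (a, a), boundary=True)
    z = (a - null_auc) / se
    p = 2.0 * stats.norm.sf(abs(z))
    lo = max(0.0, a - 1.96 * se)
    hi = min(1.0, a + 1.96 * se)
    return HanleyMcNeilResult(a, se, float(z), float(p), (lo, hi))


def binomial_ci(successes: int, n: int, level: float = 0.95,
                method: str = "clopper-pearson") -> tuple[float, float]:
    """Binomial proportion confidence interval.

    ``clopper-pearson`` (exact, via beta quantiles) is the default;
    ``wilson`` is available for comparison.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lo = 0.0 if successes == 0 else float(
            stats.beta.ppf(alpha / 2, successes, n - successes + 1)
        )
        hi = 1.0 if successes == n else float(
            stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
        )
        return lo, hi
    if method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        p = successes / n
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    raise ValueError(f"unknown CI method {method!r}")


@dataclass(frozen=True)
class ConfusionReport:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float | None = None
    ci_level: float = 0.95
    ci_method: str = "clopper-pearson"

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_cases

    @property
    def specificity(self) -> float:
        return self.tn / self.n_controls

    @property
    def ci_sensitivity(self) -> tuple[float, float]:
        return binomial_ci(self.tp, self.n_cases, self.ci_level, self.ci_method)

    @property
    def ci_specificity(self) -> tuple[float, float]:
        return binomial_ci(self.tn, self.n_controls, self.ci_level, self.ci_method)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ci_sensitivity": list(self.ci_sensitivity),
            "ci_specificity": list(self.ci_specificity),
        }


def confusion_at_threshold(probabilities: Sequence[float], labels: Sequence[int],
                           threshold: float = 0.5, ci_level: float = 0.95,
                           ci_method: str = "clopper-pearson") -> ConfusionReport:
    """Classify positive iff probability >= threshold and tabulate counts."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = p >= threshold
    pos = y == 1
    return ConfusionReport(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        threshold=threshold, ci_level=ci_level, ci_method=ci_method,
    )
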