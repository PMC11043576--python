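"""Single-hidden-layer perceptron classifiers trained by BFGS, and the
random-architecture ensemble sweep.

The model construction procedure: architectures are sampled with hidden-layer
size uniform on [ceil(n_inputs/3), floor(1.5 * n_inputs)] and a hidden
activation drawn from {linear, logistic, tanh, exponential}; each network is
fit on the training split by quasi-Newton (BFGS) minimization of penalized
binomial cross-entropy; networks are ranked by training-set AUC, the top k
retained, and the final model is the one with the best testing-set AUC.  The
logistic output is the estimated probability of disease for a sample's
pattern of probe values plus the hormone-use covariate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .evaluation import RocCurve, roc_auc

ACTIVATIONS = ("exponential", "linear", "logistic", "tanh")


class TrainingFailure(RuntimeError):
    """BFGS diverged twice (non-finite loss) for one network."""


@dataclass(frozen=True)
class ArchitectureSpec:
    n_inputs: int
    n_hidden: int
    hidden_activation: str
    output_activation: str = "logistic"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown hidden activation {self.hidden_activation!r}")
        if self.output_activation not in ("logistic", "softmax"):
            raise ValueError(f"unknown output activation {self.output_activation!r}")


def hidden_size_range(n_inputs: int) -> tuple[int, int]:
    """Inclusive sweep bounds for the hidden layer: ceil(n/3) .. floor(1.5n),
    forced non-empty for tiny input counts."""
    lo = max(1, math.ceil(n_inputs / 3))
    hi = max(lo, math.floor(1.5 * n_inputs))
    return lo, hi


def sample_architecture(n_inputs: int, rng_seed: int) -> ArchitectureSpec:
    """Draw one architecture uniformly over the sweep (deterministic in seed)."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    lo, hi = hidden_size_range(n_inputs)
    n_hidden = int(rng.integers(lo, hi + 1))
    activation = ACTIVATIONS[int(rng.integers(len(ACTIVATIONS)))]
    init_seed = int(rng.integers(2**31))
    return ArchitectureSpec(n_inputs, n_hidden, activation, init_seed=init_seed)


def _act(name: str, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Activation value and derivative (as a function of u and/or value)."""
    if name == "linear":
        return u, np.ones_like(u)
    if name == "logistic":
        z = expit(u)
        return z, z * (1.0 - z)
    if name == "tanh":
        z = np.tanh(u)
        return z, 1.0 - z * z
    if name == "exponential":
        z = np.exp(np.clip(u, -30.0, 30.0))
        return z, z
    raise ValueError(name)


def _pack(W1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, d: int, h: int):
    W1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d : h * d + h]
    w2 = theta[h * d + h : h * d + 2 * h]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
               arch: ArchitectureSpec, l2: float) -> tuple[float, np.ndarray]:
    n, d = X.shape
    h = arch.n_hidden
    W1, b1, w2, b2 = _unpack(theta, d, h)
    u1 = X @ W1.T + b1
    z, dz = _act(arch.hidden_activation, u1)
    u2 = z @ w2 + b2
    p = expit(u2)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    loss += 0.5 * l2 * (np.sum(W1 * W1) + np.sum(w2 * w2))

    delta2 = (p - y) / n                       # dL/du2
    gw2 = z.T @ delta2 + l2 * w2
    gb2 = delta2.sum()
    delta1 = np.outer(delta2, w2) * dz         # dL/du1
    gW1 = delta1.T @ X + l2 * W1
    gb1 = delta1.sum(axis=0)
    return float(loss), _pack(gW1, gb1, gw2, gb2)


@dataclass(frozen=True)
class MlpModel:
    """A trained network: weights, input standardization (training data only),
    and training diagnostics."""

    architecture: ArchitectureSpec
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    feature_names: tuple[str, ...] | None = None
    diagnostics: dict | None = None

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Forward pass; output is the probability of case status in [0, 1]."""
        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None:
                X = X[list(self.feature_names)]
            X = X.to_numpy(float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.architecture.n_inputs:
            raise ValueError(
                f"expected {self.architecture.n_inputs} features, got {X.shape[1]}"
            )
        Z = (X - self.x_mean) / self.x_sd
        u1 = Z @ self.W1.T + self.b1
        z, _ = _act(self.architecture.hidden_activation, u1)
        return expit(z @ self.w2 + self.b2)

    # -- lossless JSON serialization (float64 round-trips via repr) --------

    def to_json(self) -> str:
        d = {
            "architecture": vars(self.architecture),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "diagnostics": self.diagnostics,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MlpModel":
        d = json.loads(text)
        return cls(
            architecture=ArchitectureSpec(**d["architecture"]),
            W1=np.asarray(d["W1"], float),
            b1=np.asarray(d["b1"], float),
            w2=np.asarray(d["w2"], float),
            b2=float(d["b2"]),
            x_mean=np.asarray(d["x_mean"], float),
            x_sd=np.asarray(d["x_sd"], float),
            feature_names=tuple(d["feature_names"]) if d["feature_names"] else None,
            diagnostics=d["diagnostics"],
        )


def _standardization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean/sd from training data; binary 0/1 columns pass
    through unstandardized, constant columns get sd 1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    binary = np.array([set(np.unique(col)) <= {0.0, 1.0} for col in X.T])
    mean[binary] = 0.0
    sd[binary] = 1.0
    sd[sd == 0] = 1.0
    return mean, sd


def train_bfgs(arch: ArchitectureSpec, X: np.ndarray, y: np.ndarray,
               feature_names: Sequence[str] | None = None, max_iter: int = 150,
               l2: float = 1e-4, init_scale: float | None = None,
               gtol: float = 1e-5) -> MlpModel:
    """Fit one network by BFGS from seeded small-random initialization.

    The loss is mean binomial cross-entropy with an L2 weight penalty
    (biases unpenalized).  On a non-finite result the fit restarts once with
    a 5x smaller initialization; a second failure raises
    :class:`TrainingFailure`.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("y must contain both binary classes")
    if X.shape[1] != arch.n_inputs:
        raise ValueError("X width does not match architecture")
    mean, sd = _standardization(X)
    Z = (X - mean) / sd

    d, h = arch.n_inputs, arch.n_hidden
    rng = np.random.default_rng(arch.init_seed)
    base1 = init_scale if init_scale is not None else 0.5 / np.sqrt(d)
    base2 = init_scale if init_scale is not None else 0.5 / np.sqrt(h)

    last_err = None
    for attempt, shrink in enumerate((1.0, 0.2)):
        W1 = rng.uniform(-base1 * shrink, base1 * shrink, size=(h, d))
        b1 = rng.uniform(-base1 * shrink, base1 * shrink, size=h)
        w2 = rng.uniform(-base2 * shrink, base2 * shrink, size=h)
        theta0 = _pack(W1, b1, w2, 0.0)
        try:
            res = minimize(
                _loss_grad, theta0, args=(Z, y, arch, l2), method="BFGS",
                jac=True, options={"maxiter": max_iter, "gtol": gtol},
            )
        except (FloatingPointError, np.linalg.LinAlgError) as err:  # pragma: no cover
            last_err = err
            continue
        if np.isfinite(res.fun) and np.isfinite(res.x).all():
            W1, b1, w2, b2 = _unpack(res.x, d, h)
            diag = {
                "final_loss": float(res.fun),
                "n_iter": int(res.nit),
                "converged": bool(res.success),
                "restarted": attempt > 0,
            }
            return MlpModel(arch, W1, b1, w2, float(b2), mean, sd,
                            tuple(feature_names) if feature_names else None, diag)
        last_err = RuntimeError(f"non-finite loss {res.fun!r}")
    raise TrainingFailure(str(last_err))


# ---------------------------------------------------------------------------
# Ensemble sweep


@dataclass(frozen=True)
class NetworkRecord:
    index: int
    seed: int
    architecture: ArchitectureSpec | None
    model: MlpModel | None
    train_auc: float
    failed: bool = False


@dataclass(frozen=True)
class EnsembleSearchResult:
    """All trained networks ranked by training AUC, with the retained top-k."""

    records: tuple[NetworkRecord, ...]
    top_k: tuple[NetworkRecord, ...]
    seed: int

    @property
    def ranking(self) -> tuple[NetworkRecord, ...]:
        ok = [r for r in self.records if not r.failed]
        return tuple(sorted(ok, key=lambda r: (-r.train_auc, r.index)))


def _auc_of(model: MlpModel, X: np.ndarray, y: np.ndarray) -> float:
    p = model.predict_proba(X)
    return roc_auc(p[y == 1], p[y == 0]).auc


def ensemble_search(X: np.ndarray, y: np.ndarray, n_networks: int = 15000,
                    top_k: int = 50, seed: int = 0,
                    feature_names: Sequence[str] | None = None,
                    max_iter: int = 150, l2: float = 1e-4) -> EnsembleSearchResult:
    """Sample, train and rank ``n_networks`` architectures on the training
    split only.

    Per-network seeds derive from ``seed``, so the sweep is bit-reproducible.
    More than 50% failed fits is treated as pathological input and raises.
    """
    if not n_networks >= top_k >= 1:
        raise ValueError("need n_networks >= top_k >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y, int).ravel()
    rng = np.random.default_rng(seed)
    net_seeds = rng.integers(2**31, size=n_networks)

    records: list[NetworkRecord] = []
    n_failed = 0
    for i in range(n_networks):
        arch = sample_architecture(X.shape[1], int(net_seeds[i]))
        try:
            model = train_bfgs(arch, X, y, feature_names=feature_names,
                               max_iter=max_iter, l2=l2)
        except TrainingFailure:
            n_failed += 1
            records.append(NetworkRecord(i, int(net_seeds[i]), arch, None,
                                         float("nan"), failed=True))
            continue
        records.append(
            NetworkRecord(i, int(net_seeds[i]), arch, model, _auc_of(model, X, y))
        )
    if n_failed > 0.5 * n_networks:
        raise RuntimeError(
            f"{n_failed}/{n_networks} networks failed training; inputs pathological"
        )
    result = EnsembleSearchResult(tuple(records), (), seed)
    ranked = result.ranking
    return EnsembleSearchResult(tuple(records), tuple(ranked[:top_k]), seed)


@dataclass(frozen=True)
class FinalSelection:
    model: MlpModel
    record: NetworkRecord
    test_auc: float
    test_roc: RocCurve
    manifest: pd.DataFrame  # network id, architecture, training and testing AUC


def select_final(result: EnsembleSearchResult, X_test: np.ndarray,
                 y_test: np.ndarray) -> FinalSelection:
    """Score the retained networks on the testing split and keep the best.

    Ties on testing AUC break toward higher training AUC, then lower network
    index.  (Selecting on the test set is optimistically biased; the sweep
    reports it as published rather than hiding it.)
    """
    if not result.top_k:
        raise ValueError("no candidate networks to select from")
    X_test = np.asarray(X_test, float)
    y_test = np.asarray(y_test, int).ravel()
    if len(y_test) == 0:
        raise ValueError("testing split is empty")

    rows = []
    scored = []
    for r in result.top_k:
        curve = roc_auc(
            r.model.predict_proba(X_test)[y_test == 1],
            r.model.predict_proba(X_test)[y_test == 0],
        )
        scored.append((r, curve))
        rows.append(
            {
                "network_id": r.index,
                "n_hidden": r.architecture.n_hidden,
                "hidden_activation": r.architecture.hidden_activation,
                "train_auc": r.train_auc,
                "test_auc": curve.auc,
            }
        )
    best, best_curve = max(
        scored, key=lambda rc: (rc[1].auc, rc[0].train_auc, -rc[0].index)
    )
    return FinalSelection(
        model=best.model, record=best,
        test_auc=best_curve.auc, test_roc=best_curve,
        manifest=pd.DataFrame(rows),
    )
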