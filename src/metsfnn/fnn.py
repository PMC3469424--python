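"""Fuzzy neural network: sigmoid memberships, product rules, weighted output.

Architecture, for k selected inputs (k ≤ 2 in the standard analysis): each
standardized input x feeds two sigmoid membership functions,

    f(x) = 1 / (1 + exp(-Wg·x + Wc)),

a "low" one (Wg < 0, non-increasing) and a "high" one (Wg > 0).  Every
low/high combination across the inputs forms one production rule; the rule
activation Π is the product of its membership grades, and the network output

    y* = Σ_r Wf_r · Π_r

is the rule-weighted sum.  A subject is called a case when y* > 0 and a
control when y* < 0; y* = 0 is counted as incorrect for either class.

Training minimizes the mean squared error against targets +1 (case) and
−1 (control) by full-batch gradient descent on Wf, Wc and Wg, with the
membership-sign constraints maintained by projection.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "MembershipPair",
    "FNNModel",
    "TrainingConfig",
    "membership",
    "forward",
    "predict_class",
    "train",
    "fit_fnn",
]

_WG_MIN = 1e-3  # smallest admissible |Wg|; keeps memberships monotone


def membership(x, wc: float, wg: float):
    """Sigmoid membership grade 1/(1+exp(-wg*x + wc)); strictly in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("membership input must be finite")
    out = 1.0 / (1.0 + np.exp(np.clip(-wg * x + wc, -500.0, 500.0)))
    return out if out.ndim else float(out)


@dataclass
class MembershipPair:
    """Low/high sigmoid parameters for one input (standardized scale)."""

    wc_low: float = 0.0
    wg_low: float = -2.0
    wc_high: float = 0.0
    wg_high: float = 2.0

    def __post_init__(self) -> None:
        if not self.wg_low < 0:
            raise ValueError("wg_low must be negative (f_low non-increasing)")
        if not self.wg_high > 0:
            raise ValueError("wg_high must be positive (f_high non-decreasing)")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.05
    epochs: int = 500
    seed: int = 0
    tol: float = 0.0          # stop early when the loss improves by less
    log_inputs: tuple = ()    # inputs to log-transform before standardizing

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class FNNModel:
    """A trained network: input names, memberships, rule weights, and the
    training-fold standardization constants.

    Rules are ordered by ``itertools.product((0, 1), repeat=k)`` over the
    inputs in order, 0 = low and 1 = high, so with two inputs the weight
    vector is [(low,low), (low,high), (high,low), (high,high)].
    """

    inputs: list[str]
    pairs: list[MembershipPair]
    rule_weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_inputs: tuple = ()
    loss_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.rule_weights = np.asarray(self.rule_weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.inputs)
        if len(self.pairs) != k:
            raise ValueError("one MembershipPair required per input")
        if self.rule_weights.shape != (2 ** k,):
            raise ValueError(f"expected {2 ** k} rule weights")
        if np.any(self.sds <= 0):
            raise ValueError("standardization sds must be positive")

    @property
    def rules(self) -> list[tuple[int, ...]]:
        return list(itertools.product((0, 1), repeat=len(self.inputs)))

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        for j, name in enumerate(self.inputs):
            if name in self.log_inputs:
                X = X.copy()
                X[:, j] = np.log(X[:, j])
        return (X - self.means) / self.sds

    def to_json(self) -> str:
        d = {
            "inputs": self.inputs,
            "pairs": [asdict(p) for p in self.pairs],
            "rule_weights": self.rule_weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "log_inputs": list(self.log_inputs),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FNNModel":
        d = json.loads(text)
        return cls(
            inputs=list(d["inputs"]),
            pairs=[MembershipPair(**p) for p in d["pairs"]],
            rule_weights=np.asarray(d["rule_weights"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            log_inputs=tuple(d.get("log_inputs", ())),
        )


def _grades(model: FNNModel, Z: np.ndarray) -> np.ndarray:
    """Membership grades, shape (n, k, 2) with axis 2 = (low, high)."""
    n, k = Z.shape
    G = np.empty((n, k, 2))
    for j, p in enumerate(model.pairs):
        G[:, j, 0] = membership(Z[:, j], p.wc_low, p.wg_low)
        G[:, j, 1] = membership(Z[:, j], p.wc_high, p.wg_high)
    return G


def _activations(model: FNNModel, G: np.ndarray) -> np.ndarray:
    """Rule activations Π, shape (n, 2^k)."""
    rules = model.rules
    n = G.shape[0]
    P = np.ones((n, len(rules)))
    for r, sides in enumerate(rules):
        for j, s in enumerate(sides):
            P[:, r] *= G[:, j, s]
    return P


def forward(model: FNNModel, X) -> np.ndarray:
    """Network output y* for raw inputs.

    ``X`` may be a DataFrame holding the model's input columns or an array
    of shape (n, k) in model input order.  Missing values are rejected:
    complete-case filtering belongs upstream.
    """
    if isinstance(X, pd.DataFrame):
        X = X[model.inputs].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.isnan(X).any():
        raise ValueError("forward requires complete cases")
    Z = model.standardize(X)
    P = _activations(model, _grades(model, Z))
    return P @ model.rule_weights


def predict_class(ystar) -> np.ndarray:
    """+1 (case) where y*>0, −1 (control) where y*<0, 0 (never correct) at
    exactly zero."""
    return np.sign(np.asarray(ystar, dtype=float)).astype(int)


def correct_mask(ystar, targets) -> np.ndarray:
    """Boolean: prediction strictly on the target side of zero."""
    y = np.asarray(ystar, dtype=float)
    t = np.asarray(targets, dtype=float)
    return ((y > 0) & (t > 0)) | ((y < 0) & (t < 0))


def train(Z: np.ndarray, targets: np.ndarray, model: FNNModel,
          config: TrainingConfig) -> FNNModel:
    """Gradient-descent training on pre-standardized inputs (in place).

    Minimizes mean((y* − t)²), t ∈ {+1, −1}; after each update Wg_high is
    projected back above +1e-3 and Wg_low below −1e-3.
    """
    n, k = Z.shape
    t = np.asarray(targets, dtype=float)
    rules = model.rules
    lr = config.learning_rate
    prev = np.inf
    for _ in range(config.epochs):
        G = _grades(model, Z)
        P = _activations(model, G)
        y = P @ model.rule_weights
        e = y - t
        loss = float(np.mean(e ** 2))
        model.loss_history.append(loss)
        if prev - loss < config.tol and np.isfinite(prev):
            break
        prev = loss

        grad_wf = 2.0 / n * (P.T @ e)
        # dL/df for each (input j, side s): sum over rules using that side of
        # Wf_r times the partial product excluding input j
        dwc = np.zeros((k, 2))
        dwg = np.zeros((k, 2))
        for j in range(k):
            for s in (0, 1):
                acc = np.zeros(n)
                for r, sides in enumerate(rules):
                    if sides[j] != s:
                        continue
                    partial = np.ones(n)
                    for j2, s2 in enumerate(sides):
                        if j2 != j:
                            partial *= G[:, j2, s2]
                    acc += model.rule_weights[r] * partial
                dL_df = 2.0 / n * e * acc
                f = G[:, j, s]
                fp = f * (1.0 - f)
                dwg[j, s] = float(np.sum(dL_df * fp * Z[:, j]))
                dwc[j, s] = float(np.sum(dL_df * -fp))

        model.rule_weights = model.rule_weights - lr * grad_wf
        for j, p in enumerate(model.pairs):
            p.wc_low -= lr * dwc[j, 0]
            p.wg_low -= lr * dwg[j, 0]
            p.wc_high -= lr * dwc[j, 1]
            p.wg_high -= lr * dwg[j, 1]
            p.wg_low = min(p.wg_low, -_WG_MIN)
            p.wg_high = max(p.wg_high, _WG_MIN)
    return model


def fit_fnn(data: pd.DataFrame, inputs: list[str], targets,
            config: TrainingConfig | None = None) -> FNNModel:
    """Standardize the named columns and train a fresh network.

    ``targets`` is a ±1 array (or anything coercible).  Initialization is
    deterministic: f_high centered at the standardized mean with gradient
    +2, f_low mirrored, all rule weights zero.
    """
    config = config or TrainingConfig()
    t = np.asarray(targets, dtype=float)
    if not set(np.unique(t)) <= {-1.0, 1.0}:
        raise ValueError("targets must be coded +1 / -1")
    if (t > 0).sum() < 2 or (t < 0).sum() < 2:
        raise ValueError("need at least two subjects per class")
    X = data[inputs].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training data must be complete-case")
    for j, name in enumerate(inputs):
        if name in config.log_inputs:
            X[:, j] = np.log(X[:, j])
    means, sds = X.mean(axis=0), X.std(axis=0)
    if np.any(sds <= 0):
        bad = [inputs[j] for j in np.where(sds <= 0)[0]]
        raise ValueError(f"zero-variance input(s): {bad}")
    k = len(inputs)
    model = FNNModel(
        inputs=list(inputs),
        pairs=[MembershipPair() for _ in range(k)],
        rule_weights=np.zeros(2 ** k),
        means=means,
        sds=sds,
        log_inputs=tuple(config.log_inputs),
    )
    Z = (X - means) / sds
    return train(Z, t, model, config)
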