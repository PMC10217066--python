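"""Restricted Boltzmann Machines and Deep Belief Network classifiers.

An RBM couples I binary visible units v to J binary hidden units h through
the energy

    E(v, h; θ) = − v'Wh − b'v − a'h,        θ = [W, b, a],

with joint p(v, h) = exp(−E)/Z and factorized logistic conditionals
p(h_j=1 | v) = δ(Σ_i w_ij v_i + a_j), p(v_i=1 | h) = δ(Σ_j w_ij h_j + b_i),
δ(x) = 1/(1 + e^(−x)).  Training uses one-step contrastive divergence
(CD-1) with momentum.  A DBN stacks RBMs — each trained on the previous
layer's hidden activation probabilities — then unrolls them into a
feed-forward network with a logistic classification layer fine-tuned by
mini-batch backpropagation on the cross-entropy.

For tiny models (I + J ≤ 20) :func:`exact_rbm_stats` enumerates every
joint state, giving the exact partition function, marginals and
log-likelihood gradient; it is the oracle the stochastic training rule is
validated against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "RBMParams",
    "DBNModel",
    "ExactRBMStatistics",
    "sigmoid",
    "rbm_energy",
    "hidden_conditional",
    "visible_conditional",
    "cd1_statistics",
    "cd1_update",
    "exact_rbm_stats",
    "exact_loglik_gradient",
    "init_rbm",
    "train_rbm",
    "pretrain_stack",
    "fine_tune",
    "predict_proba",
    "predict_labels",
]


def sigmoid(x):
    """Logistic function δ(x) = 1/(1 + e^(−x)), stable for large |x|."""
    return expit(x)


@dataclass(frozen=True)
class RBMParams:
    """One RBM's parameters: W (I × J), visible biases b (I), hidden biases a (J)."""

    W: np.ndarray
    b: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        b = np.asarray(self.b, dtype=float)
        a = np.asarray(self.a, dtype=float)
        if W.ndim != 2 or b.shape != (W.shape[0],) or a.shape != (W.shape[1],):
            raise ValueError("inconsistent RBM shapes")
        for arr in (W, b, a):
            if not np.isfinite(arr).all():
                raise ValueError("RBM parameters must be finite")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a", a)

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


def init_rbm(
    n_visible: int, n_hidden: int, seed: int, scale: float | None = None
) -> RBMParams:
    """Random weights at Glorot scale √(2/(I+J)) by default, zero biases.

    The Glorot scale keeps both the RBM's hidden activations and the
    gradients of the later fine-tuning stage away from the near-constant
    regime that tiny initial weights produce.
    """
    if scale is None:
        scale = float(np.sqrt(2.0 / (n_visible + n_hidden)))
    rng = np.random.default_rng(seed)
    return RBMParams(
        W=rng.normal(0.0, scale, size=(n_visible, n_hidden)),
        b=np.zeros(n_visible),
        a=np.zeros(n_hidden),
    )


def _check_binary(state: np.ndarray, name: str) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if not np.isin(state, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be a binary (0/1) state")
    return state


def rbm_energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h; θ) = −Σ_ij w_ij v_i h_j − Σ_i b_i v_i − Σ_j a_j h_j."""
    v = _check_binary(v, "v")
    h = _check_binary(h, "h")
    return float(-(v @ params.W @ h) - params.b @ v - params.a @ h)


def hidden_conditional(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = δ(Σ_i w_ij v_i + a_j); accepts probabilities for v."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError("visible dimension mismatch")
    return sigmoid(v @ params.W + params.a)


def visible_conditional(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) = δ(Σ_j w_ij h_j + b_i); accepts probabilities for h."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError("hidden dimension mismatch")
    return sigmoid(h @ params.W.T + params.b)


@dataclass(frozen=True)
class ExactRBMStatistics:
    """Exhaustive-enumeration quantities for a tiny RBM.

    ``joint`` is the 2^I × 2^J probability table over (v, h) states in
    binary counting order; model expectations are the exact sufficient
    statistics under p(v, h; θ).
    """

    Z: float
    joint: np.ndarray
    visible_states: np.ndarray
    hidden_states: np.ndarray
    model_expectation_W: np.ndarray
    model_expectation_b: np.ndarray
    model_expectation_a: np.ndarray


def _enumerate_states(n: int) -> np.ndarray:
    """All binary vectors of length n in counting order, shape (2^n, n)."""
    grid = np.indices((2,) * n).reshape(n, -1).T
    return grid.astype(float)


def exact_rbm_stats(params: RBMParams) -> ExactRBMStatistics:
    """Partition function and exact model expectations by state enumeration."""
    I, J = params.n_visible, params.n_hidden
    if I + J > 20:
        raise ValueError("enumeration limited to I + J <= 20 units")
    V = _enumerate_states(I)
    H = _enumerate_states(J)
    energy = -(V @ params.W @ H.T + (V @ params.b)[:, None] + (H @ params.a)[None, :])
    log_unnorm = -energy
    shift = log_unnorm.max()
    unnorm = np.exp(log_unnorm - shift)
    Z = float(unnorm.sum() * np.exp(shift))
    joint = unnorm / unnorm.sum()
    exp_W = V.T @ joint @ H
    exp_b = joint.sum(axis=1) @ V
    exp_a = joint.sum(axis=0) @ H
    return ExactRBMStatistics(
        Z=Z,
        joint=joint,
        visible_states=V,
        hidden_states=H,
        model_expectation_W=exp_W,
        model_expectation_b=exp_b,
        model_expectation_a=exp_a,
    )


def exact_loglik_gradient(
    params: RBMParams, data: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact ∂/∂θ of the mean log-likelihood of ``data`` (rows in [0,1]).

    Data expectations use the factorized p(h | v); model expectations come
    from the enumerated joint.
    """
    data = np.asarray(data, dtype=float)
    stats = exact_rbm_stats(params)
    ph = hidden_conditional(params, data)
    n = data.shape[0]
    grad_W = data.T @ ph / n - stats.model_expectation_W
    grad_b = data.mean(axis=0) - stats.model_expectation_b
    grad_a = ph.mean(axis=0) - stats.model_expectation_a
    return grad_W, grad_b, grad_a


def cd1_statistics(
    params: RBMParams, batch: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One CD-1 gradient estimate (positive − negative phase), batch-averaged.

    Positive phase: data and p(h | data).  Negative phase: sample h from
    its conditional, reconstruct visible probabilities, recompute hidden
    probabilities.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("batch must be non-empty")
    if ((batch < 0) | (batch > 1)).any():
        raise ValueError("batch values must lie in [0, 1]")
    n = batch.shape[0]
    ph_pos = hidden_conditional(params, batch)
    h_sample = (rng.random(ph_pos.shape) < ph_pos).astype(float)
    pv_neg = visible_conditional(params, h_sample)
    ph_neg = hidden_conditional(params, pv_neg)
    dW = (batch.T @ ph_pos - pv_neg.T @ ph_neg) / n
    db = (batch - pv_neg).mean(axis=0)
    da = (ph_pos - ph_neg).mean(axis=0)
    return dW, db, da


def cd1_update(
    params: RBMParams,
    batch: np.ndarray,
    lr: float,
    momentum: float,
    rng: np.random.Generator,
    velocity: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[RBMParams, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """One CD-1 parameter update with momentum.

    Δθ = lr · (positive − negative statistics) + momentum · previous Δθ.
    Returns the updated parameters and the new velocity (to be chained
    into the next call).
    """
    if lr < 0 or not 0 <= momentum < 1:
        raise ValueError("lr must be >= 0 and momentum in [0, 1)")
    dW, db, da = cd1_statistics(params, batch, rng)
    if velocity is None:
        vW = np.zeros_like(params.W)
        vb = np.zeros_like(params.b)
        va = np.zeros_like(params.a)
    else:
        vW, vb, va = velocity
    vW = lr * dW + momentum * vW
    vb = lr * db + momentum * vb
    va = lr * da + momentum * va
    new = RBMParams(W=params.W + vW, b=params.b + vb, a=params.a + va)
    return new, (vW, vb, va)


def reconstruction_error(params: RBMParams, X: np.ndarray) -> float:
    """Mean squared error of the one-step mean-field reconstruction of X."""
    ph = hidden_conditional(params, X)
    pv = visible_conditional(params, ph)
    return float(np.mean((np.asarray(X, dtype=float) - pv) ** 2))


def _minibatches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[k : k + batch_size] for k in range(0, n, batch_size)]


def train_rbm(
    params: RBMParams,
    X: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float = 0.1,
    momentum: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[RBMParams, list[float]]:
    """CD-1 training over shuffled mini-batches; returns per-epoch recon error."""
    X = np.asarray(X, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    if batch_size > X.shape[0]:
        warnings.warn(
            f"batch_size {batch_size} > {X.shape[0]} records; clamping",
            stacklevel=2,
        )
        batch_size = X.shape[0]
    velocity = None
    errors: list[float] = []
    for _ in range(epochs):
        for idx in _minibatches(X.shape[0], batch_size, rng):
            params, velocity = cd1_update(
                params, X[idx], lr, momentum, rng, velocity
            )
        errors.append(reconstruction_error(params, X))
    return params, errors


def pretrain_stack(
    layer_sizes: Sequence[int],
    X: np.ndarray,
    epochs: int = 200,
    batch_size: int = 100,
    lr: float = 0.1,
    momentum: float = 0.5,
    seed: int = 0,
) -> list[RBMParams]:
    """Greedy layer-wise pretraining.

    ``layer_sizes`` is (n_features, hidden_1, ..., hidden_L).  The first
    RBM trains on X; each later RBM trains on the previous layer's hidden
    activation probabilities.
    """
    X = np.asarray(X, dtype=float)
    if ((X < 0) | (X > 1)).any():
        raise ValueError("X must be scaled to [0, 1] for Bernoulli visibles")
    if len(layer_sizes) < 2 or any(s < 1 for s in layer_sizes):
        raise ValueError("layer_sizes must list >= 2 positive sizes")
    if layer_sizes[0] != X.shape[1]:
        raise ValueError("layer_sizes[0] must equal the input dimension")
    rng = np.random.default_rng(seed)
    stack: list[RBMParams] = []
    current = X
    for level, (n_vis, n_hid) in enumerate(zip(layer_sizes, layer_sizes[1:])):
        params = init_rbm(n_vis, n_hid, seed=int(rng.integers(2**31)))
        if epochs > 0:
            params, errors = train_rbm(
                params, current, epochs, batch_size, lr, momentum, rng
            )
            logger.debug(
                "pretrained RBM %d (%dx%d): recon %.5f -> %.5f",
                level,
                n_vis,
                n_hid,
                errors[0],
                errors[-1],
            )
        stack.append(params)
        current = hidden_conditional(params, current)
    return stack


@dataclass(frozen=True)
class DBNModel:
    """Unrolled feed-forward classifier: pretrained hidden layers + logistic top.

    ``layers`` holds (weight, bias) pairs for every layer including the
    classification layer; all use logistic activations.  A single output
    unit scores class 1; ``n_outputs = 2`` gives one unit per class.
    """

    layers: tuple[tuple[np.ndarray, np.ndarray], ...]
    n_outputs: int
    loss_history: tuple[float, ...] = ()
    config: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.layers[0][0].shape[0]

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        activations = [np.atleast_2d(np.asarray(X, dtype=float))]
        for W, c in self.layers:
            activations.append(sigmoid(activations[-1] @ W + c))
        return activations

    def to_jsonable(self) -> dict:
        return {
            "n_outputs": self.n_outputs,
            "layers": [
                {"W": W.tolist(), "bias": c.tolist()} for W, c in self.layers
            ],
            "config": self.config,
        }

    @classmethod
    def from_jsonable(cls, payload: dict) -> "DBNModel":
        layers = tuple(
            (np.asarray(d["W"], dtype=float), np.asarray(d["bias"], dtype=float))
            for d in payload["layers"]
        )
        return cls(
            layers=layers,
            n_outputs=payload["n_outputs"],
            config=payload.get("config", {}),
        )

    def loss_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.loss_history) + 1),
                "training_loss": self.loss_history,
            }
        ).to_csv(path, index=False)


def _cross_entropy(p: np.ndarray, t: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))


def fine_tune(
    stack: Sequence[RBMParams],
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 200,
    batch_size: int = 100,
    lr: float = 0.5,
    seed: int = 0,
    n_outputs: int = 1,
    momentum: float = 0.9,
) -> DBNModel:
    """Supervised backpropagation through the unrolled stack.

    Hidden layers start from the pretrained RBM weights (W, hidden biases);
    the logistic classification layer starts at Glorot scale.  Mini-batch
    gradient descent with momentum on the mean cross-entropy; per-epoch
    full-data loss is recorded.  Aborts with a diagnostic if the loss turns
    non-finite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    if n_outputs not in (1, 2):
        raise ValueError("n_outputs must be 1 or 2")
    if not 0 <= momentum < 1:
        raise ValueError("momentum must be in [0, 1)")
    rng = np.random.default_rng(seed)
    weights = [rbm.W.copy() for rbm in stack]
    biases = [rbm.a.copy() for rbm in stack]
    top_in = stack[-1].n_hidden if stack else X.shape[1]
    glorot = np.sqrt(2.0 / (top_in + n_outputs))
    weights.append(rng.normal(0.0, glorot, size=(top_in, n_outputs)))
    biases.append(np.zeros(n_outputs))
    if n_outputs == 1:
        targets = y.astype(float)[:, None]
    else:
        targets = np.column_stack([(y == 0), (y == 1)]).astype(float)
    if batch_size > X.shape[0]:
        batch_size = X.shape[0]
    vel_W = [np.zeros_like(W) for W in weights]
    vel_c = [np.zeros_like(c) for c in biases]
    losses: list[float] = []
    for epoch in range(epochs):
        for idx in _minibatches(X.shape[0], batch_size, rng):
            acts = [X[idx]]
            for W, c in zip(weights, biases):
                acts.append(sigmoid(acts[-1] @ W + c))
            # logistic output + cross-entropy -> delta = (p - t) at the top;
            # hidden layers propagate through the logistic derivative
            delta = (acts[-1] - targets[idx]) / idx.size
            for level in range(len(weights) - 1, -1, -1):
                grad_W = acts[level].T @ delta
                grad_c = delta.sum(axis=0)
                if level > 0:
                    delta = (delta @ weights[level].T) * acts[level] * (
                        1 - acts[level]
                    )
                vel_W[level] = momentum * vel_W[level] - lr * grad_W
                vel_c[level] = momentum * vel_c[level] - lr * grad_c
                weights[level] += vel_W[level]
                biases[level] += vel_c[level]
        out = X
        for W, c in zip(weights, biases):
            out = sigmoid(out @ W + c)
        loss = _cross_entropy(out, targets)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"fine-tuning diverged at epoch {epoch + 1}: loss={loss}"
            )
        losses.append(loss)
    return DBNModel(
        layers=tuple(zip((w.copy() for w in weights), (c.copy() for c in biases))),
        n_outputs=n_outputs,
        loss_history=tuple(losses),
        config={
            "epochs": epochs,
            "batch_size": batch_size,
            "lr": lr,
            "seed": seed,
        },
    )


def predict_proba(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Per-record class-1 probability in (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    out = model.forward(X)[-1]
    if model.n_outputs == 1:
        return out[:, 0]
    return out[:, 1] / (out[:, 0] + out[:, 1])


def predict_labels(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Probabilities thresholded at 0.5 (boundary goes to class 0)."""
    return (predict_proba(model, X) > 0.5).astype(int)
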