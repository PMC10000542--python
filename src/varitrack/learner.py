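"""From-scratch gated recurrent learner with a parametric-leak variance readout.

The cell is a gated recurrent unit with input gate ``i``, forget gate ``d``,
output gate ``b`` and an internal cell state ``c`` (theta is the logistic
function, ``o`` the elementwise product):

    d_t  = theta(W_fx x_t + W_fa a_{t-1} + W_fc c_{t-1} + b_f)
    i_t  = theta(W_ix x_t + W_ia a_{t-1} + W_ic c_{t-1} + b_i)
    ch_t = tanh (W_cx x_t + W_ca a_{t-1}                + b_c)
    c_t  = i_t o ch_t + d_t o c_{t-1}
    b_t  = theta(W_ox x_t + W_oa a_{t-1} + W_oc c_t     + b_o)
    a_t  = b_t o tanh(c_t)

Note the output gate peeks at the *current* cell state.  The hidden state is
passed through the *variance activation* — a parametric leaky rectifier with
a learned per-unit leak ``gamma``:

    F(a) = a           if a > 0
    F(a) = gamma * a   if a <= 0

equivalently ``G(a) = max(0, a) + gamma * min(0, a)``; the two forms are
asserted identical.  The abnormality score of a record is
``theta(u . F(a_t) + bias)``, trained against 0/1 normal/abnormal labels with
mean squared error (cross-entropy behind a switch).

All gradients — including dR/dgamma (zero on the positive branch, the
pre-activation itself on the negative branch) and the readout gradient dR/dU
— are derived by hand and propagated through time; the test suite checks
every parameter block against central finite differences.

Updates use heavy-ball momentum with an adaptive damping ratio: per
parameter block,

    m <- lambda_m * m + lr * g
    J <- beta * J + (1 - beta) * g^2
    p <- p - m * J / (c + J)

so steps are damped while the squared-gradient average ``J`` is small
relative to the damping constant ``c`` and approach the plain momentum step
once ``J >> c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

__all__ = [
    "ModelParams",
    "CellState",
    "ForwardCache",
    "TrainConfig",
    "GradOptState",
    "init_params",
    "variance_activation",
    "variance_layer",
    "cell_step",
    "forward_sequence",
    "forward_batch",
    "loss",
    "grad_gamma",
    "abnormality_gradient",
    "backward_batch",
    "backward_sequence",
    "update_parameters",
    "train",
    "pad_sequences",
    "RecurrentVarianceClassifier",
]

MODEL_FORMAT_VERSION = 1

#: Parameter-block names, in a fixed order used by the optimizer and serializer.
_BLOCKS = (
    "W_fx", "W_fa", "W_fc", "b_f",
    "W_ix", "W_ia", "W_ic", "b_i",
    "W_ox", "W_oa", "W_oc", "b_o",
    "W_cx", "W_ca", "b_c",
    "u", "b_out", "gamma",
)


@dataclass
class ModelParams:
    """All weights of the cell, the readout and the variance activation."""

    W_fx: np.ndarray
    W_fa: np.ndarray
    W_fc: np.ndarray
    b_f: np.ndarray
    W_ix: np.ndarray
    W_ia: np.ndarray
    W_ic: np.ndarray
    b_i: np.ndarray
    W_ox: np.ndarray
    W_oa: np.ndarray
    W_oc: np.ndarray
    b_o: np.ndarray
    W_cx: np.ndarray
    W_ca: np.ndarray
    b_c: np.ndarray
    u: np.ndarray
    b_out: np.ndarray  # scalar array, shape ()
    gamma: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_fx.shape[0]

    @property
    def n_features(self) -> int:
        return self.W_fx.shape[1]

    def blocks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _BLOCKS}

    def copy(self) -> "ModelParams":
        return ModelParams(**{name: getattr(self, name).copy() for name in _BLOCKS})

    def validate(self) -> None:
        H, F = self.hidden_size, self.n_features
        expected = {
            "W_fx": (H, F), "W_fa": (H, H), "W_fc": (H, H), "b_f": (H,),
            "W_ix": (H, F), "W_ia": (H, H), "W_ic": (H, H), "b_i": (H,),
            "W_ox": (H, F), "W_oa": (H, H), "W_oc": (H, H), "b_o": (H,),
            "W_cx": (H, F), "W_ca": (H, H), "b_c": (H,),
            "u": (H,), "b_out": (), "gamma": (H,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"parameter {name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in parameter {name}")

    def to_json(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "hidden_size": self.hidden_size,
            "n_features": self.n_features,
            "blocks": {
                name: {"shape": list(arr.shape), "data": arr.ravel().tolist()}
                for name, arr in self.blocks().items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def from_json(cls, payload: dict) -> "ModelParams":
        blocks = {
            name: np.array(b["data"], dtype=float).reshape(b["shape"])
            for name, b in payload["blocks"].items()
        }
        params = cls(**blocks)
        params.validate()
        return params

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_json(json.loads(Path(path).read_text()))


def init_params(
    n_features: int,
    hidden_size: int = 8,
    gamma_init: float = 0.25,
    rng: np.random.Generator | int | None = 0,
) -> ModelParams:
    """Small symmetric initialization: weights ~ U(-0.1, 0.1), biases 0, leak 0.25."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    H, F = hidden_size, n_features

    def w(*shape):
        return rng.uniform(-0.1, 0.1, size=shape)

    return ModelParams(
        W_fx=w(H, F), W_fa=w(H, H), W_fc=w(H, H), b_f=np.zeros(H),
        W_ix=w(H, F), W_ia=w(H, H), W_ic=w(H, H), b_i=np.zeros(H),
        W_ox=w(H, F), W_oa=w(H, H), W_oc=w(H, H), b_o=np.zeros(H),
        W_cx=w(H, F), W_ca=w(H, H), b_c=np.zeros(H),
        u=w(H), b_out=np.zeros(()), gamma=np.full(H, float(gamma_init)),
    )


def variance_activation(a: np.ndarray, gamma: np.ndarray | float) -> np.ndarray:
    """F(a): identity on the positive branch, leak ``gamma * a`` on ``a <= 0``.

    Continuous at 0 and monotone nondecreasing for ``gamma >= 0``; ``gamma``
    broadcasts over the trailing (unit) axis.
    """
    a = np.asarray(a, dtype=float)
    return np.where(a > 0, a, gamma * a)


def variance_layer(a: np.ndarray, gamma: np.ndarray | float) -> np.ndarray:
    """G(a) = max(0, a) + gamma * min(0, a); pointwise identical to F(a)."""
    a = np.asarray(a, dtype=float)
    return np.maximum(0.0, a) + gamma * np.minimum(0.0, a)


@dataclass
class CellState:
    """State after one cell step (gates kept for inspection)."""

    a: np.ndarray
    c: np.ndarray
    gate_i: np.ndarray | None = None
    gate_d: np.ndarray | None = None
    gate_b: np.ndarray | None = None
    candidate: np.ndarray | None = None

    @classmethod
    def zero(cls, hidden_size: int, batch_shape: tuple = ()) -> "CellState":
        shape = (*batch_shape, hidden_size)
        return cls(a=np.zeros(shape), c=np.zeros(shape))


def cell_step(params: ModelParams, x: np.ndarray, state: CellState) -> CellState:
    """Advance the gated cell one step; ``x`` is ``(F,)`` or ``(B, F)``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_features:
        raise ValueError(
            f"input has {x.shape[-1]} features, model expects {params.n_features}"
        )
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite input to cell_step")
    a_prev, c_prev = state.a, state.c
    d = expit(x @ params.W_fx.T + a_prev @ params.W_fa.T + c_prev @ params.W_fc.T + params.b_f)
    i = expit(x @ params.W_ix.T + a_prev @ params.W_ia.T + c_prev @ params.W_ic.T + params.b_i)
    ch = np.tanh(x @ params.W_cx.T + a_prev @ params.W_ca.T + params.b_c)
    c = i * ch + d * c_prev
    b = expit(x @ params.W_ox.T + a_prev @ params.W_oa.T + c @ params.W_oc.T + params.b_o)
    a = b * np.tanh(c)
    return CellState(a=a, c=c, gate_i=i, gate_d=d, gate_b=b, candidate=ch)


@dataclass
class ForwardCache:
    """Every intermediate of a batched forward pass, kept for backpropagation."""

    X: np.ndarray        # (B, T, F)
    mask: np.ndarray     # (B, T) validity mask
    D: np.ndarray        # forget gates   (B, T, H)
    I: np.ndarray        # input gates    (B, T, H)
    O: np.ndarray        # output gates   (B, T, H)
    Ch: np.ndarray       # candidates     (B, T, H)
    C: np.ndarray        # cell states    (B, T, H)
    A: np.ndarray        # hidden states  (B, T, H)
    Fh: np.ndarray       # F(A)           (B, T, H)
    scores: np.ndarray   # (B, T)


def forward_batch(
    params: ModelParams, X: np.ndarray, mask: np.ndarray | None = None
) -> ForwardCache:
    """Run the cell and readout over a padded batch ``X`` of shape (B, T, F)."""
    X = np.asarray(X, dtype=float)
    B, T, F = X.shape
    H = params.hidden_size
    if mask is None:
        mask = np.ones((B, T), dtype=bool)
    D = np.empty((B, T, H)); I = np.empty((B, T, H)); O = np.empty((B, T, H))
    Ch = np.empty((B, T, H)); C = np.empty((B, T, H)); A = np.empty((B, T, H))
    state = CellState.zero(H, (B,))
    for t in range(T):
        state = cell_step(params, X[:, t], state)
        D[:, t] = state.gate_d; I[:, t] = state.gate_i; O[:, t] = state.gate_b
        Ch[:, t] = state.candidate; C[:, t] = state.c; A[:, t] = state.a
    Fh = variance_activation(A, params.gamma)
    scores = expit(Fh @ params.u + params.b_out)
    return ForwardCache(X=X, mask=np.asarray(mask, bool), D=D, I=I, O=O, Ch=Ch, C=C, A=A,
                        Fh=Fh, scores=scores)


def forward_sequence(
    params: ModelParams, X: np.ndarray
) -> tuple[list[CellState], np.ndarray]:
    """Run one sequence ``(T, F)``; returns per-step states and scores in (0, 1)."""
    X = np.asarray(X, dtype=float)
    states: list[CellState] = []
    state = CellState.zero(params.hidden_size)
    scores = np.empty(len(X))
    for t, x in enumerate(X):
        state = cell_step(params, x, state)
        states.append(state)
        scores[t] = float(expit(variance_activation(state.a, params.gamma) @ params.u
                                + params.b_out))
    return states, scores


def loss(scores: np.ndarray, labels: np.ndarray, kind: str = "mse",
         mask: np.ndarray | None = None) -> float:
    """Training objective R over all (valid) records.

    ``mse``: mean of (score - label)^2.  ``xent``: mean binary cross-entropy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"scores shape {scores.shape} != labels shape {labels.shape}")
    if mask is None:
        mask = np.ones_like(scores, dtype=bool)
    s, y = scores[mask], labels[mask]
    if kind == "mse":
        return float(np.mean((s - y) ** 2))
    if kind == "xent":
        eps = 1e-12
        return float(-np.mean(y * np.log(s + eps) + (1 - y) * np.log(1 - s + eps)))
    raise ValueError(f"unknown loss kind {kind!r}")


def grad_gamma(cache: ForwardCache, upstream_dF: np.ndarray) -> np.ndarray:
    """dR/dgamma_i: sum over records and time of upstream * I(A_i).

    The negative-branch factor is the pre-activation itself,
    ``I(A) = A`` for ``A <= 0`` and 0 for ``A > 0``.
    """
    if cache is None:
        raise RuntimeError("forward cache required before computing gamma gradients")
    branch = np.where(cache.A > 0, 0.0, cache.A)
    m = cache.mask[..., None]
    return np.sum(np.asarray(upstream_dF) * branch * m, axis=tuple(range(cache.A.ndim - 1)))


def _score_grad(cache: ForwardCache, labels: np.ndarray, kind: str) -> np.ndarray:
    """dR/d(logit) per record, zero outside the mask."""
    S, Y, mask = cache.scores, np.asarray(labels, dtype=float), cache.mask
    n = mask.sum()
    if Y.shape != S.shape:
        raise ValueError(f"labels shape {Y.shape} != scores shape {S.shape}")
    if kind == "mse":
        dlogit = 2.0 * (S - Y) / n * S * (1.0 - S)
    elif kind == "xent":
        dlogit = (S - Y) / n
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    return np.where(mask, dlogit, 0.0)


def abnormality_gradient(
    cache: ForwardCache, labels: np.ndarray, kind: str = "mse"
) -> tuple[np.ndarray, float]:
    """Readout gradient dR/dU (and dR/dbias) from the forward cache."""
    dlogit = _score_grad(cache, labels, kind)
    du = np.einsum("bt,bth->h", dlogit, cache.Fh)
    return du, float(dlogit.sum())


def backward_batch(
    params: ModelParams, cache: ForwardCache, labels: np.ndarray, kind: str = "mse"
) -> dict[str, np.ndarray]:
    """Full backpropagation-through-time over a padded batch.

    Returns one gradient array per parameter block (same shapes as the
    parameters).  Padded steps carry zero upstream gradient and therefore
    contribute nothing.
    """
    X, A, C, D, I, O, Ch = cache.X, cache.A, cache.C, cache.D, cache.I, cache.O, cache.Ch
    B, T, F = X.shape
    H = params.hidden_size

    dlogit = _score_grad(cache, labels, kind)           # (B, T)
    du = np.einsum("bt,bth->h", dlogit, cache.Fh)
    db_out = np.array(dlogit.sum())
    dF = dlogit[..., None] * params.u                   # (B, T, H)
    dgamma = grad_gamma(cache, dF)
    dA_readout = dF * np.where(A > 0, 1.0, params.gamma)

    g = {name: np.zeros_like(arr) for name, arr in params.blocks().items()}
    g["u"], g["b_out"], g["gamma"] = du, db_out, dgamma

    dA_carry = np.zeros((B, H))
    dC_carry = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x = X[:, t]
        a_prev = A[:, t - 1] if t > 0 else np.zeros((B, H))
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H))
        o, i, d, ch, c_t = O[:, t], I[:, t], D[:, t], Ch[:, t], C[:, t]
        th = np.tanh(c_t)

        dA = dA_readout[:, t] + dA_carry
        dzo = dA * th * o * (1.0 - o)
        dC = dA * o * (1.0 - th ** 2) + dzo @ params.W_oc + dC_carry
        dzc = dC * i * (1.0 - ch ** 2)
        dzi = dC * ch * i * (1.0 - i)
        dzd = dC * c_prev * d * (1.0 - d)

        g["W_ox"] += dzo.T @ x; g["W_oa"] += dzo.T @ a_prev; g["W_oc"] += dzo.T @ c_t
        g["b_o"] += dzo.sum(0)
        g["W_fx"] += dzd.T @ x; g["W_fa"] += dzd.T @ a_prev; g["W_fc"] += dzd.T @ c_prev
        g["b_f"] += dzd.sum(0)
        g["W_ix"] += dzi.T @ x; g["W_ia"] += dzi.T @ a_prev; g["W_ic"] += dzi.T @ c_prev
        g["b_i"] += dzi.sum(0)
        g["W_cx"] += dzc.T @ x; g["W_ca"] += dzc.T @ a_prev; g["b_c"] += dzc.sum(0)

        dA_carry = dzo @ params.W_oa + dzd @ params.W_fa + dzi @ params.W_ia + dzc @ params.W_ca
        dC_carry = dC * d + dzd @ params.W_fc + dzi @ params.W_ic
    return g


def backward_sequence(
    params: ModelParams, cache: ForwardCache, labels: np.ndarray, kind: str = "mse"
) -> dict[str, np.ndarray]:
    """Gradients for a single cached sequence (batch of one)."""
    return backward_batch(params, cache, labels, kind)


@dataclass
class TrainConfig:
    """Optimizer and training hyperparameters (defaults as documented above)."""

    epochs: int = 300
    learning_rate: float = 0.5
    momentum: float = 0.9       # lambda_m, heavy-ball decay
    sq_decay: float = 0.9       # beta, decay of the squared-gradient average J
    damping: float = 1e-6       # c, damping constant in Z = c + J
    loss: str = "mse"

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0 <= self.sq_decay < 1:
            raise ValueError("sq_decay must lie in [0, 1)")
        if self.learning_rate <= 0 or self.damping <= 0:
            raise ValueError("learning_rate and damping must be positive")


@dataclass
class GradOptState:
    """Momentum and squared-gradient accumulators, one pair per parameter block."""

    m: dict[str, np.ndarray] = field(default_factory=dict)
    J: dict[str, np.ndarray] = field(default_factory=dict)


def update_parameters(
    params: ModelParams,
    grads: dict[str, np.ndarray],
    opt: GradOptState,
    config: TrainConfig,
) -> tuple[ModelParams, GradOptState]:
    """One damped-momentum step, in place on ``params`` (also returned).

    Per block: ``m <- lambda_m m + lr g``, ``J <- beta J + (1-beta) g^2``,
    ``Z = c + J``, ``p <- p - m J/Z``.  ``J >= 0`` and ``Z > 0`` always hold.
    """
    config.validate()
    for name in _BLOCKS:
        gr = np.asarray(grads[name], dtype=float)
        if not np.all(np.isfinite(gr)):
            raise FloatingPointError(f"non-finite gradient in parameter block {name!r}")
        p = getattr(params, name)
        m = opt.m.get(name)
        J = opt.J.get(name)
        if m is None:
            m = np.zeros_like(p)
            J = np.zeros_like(p)
        m = config.momentum * m + config.learning_rate * gr
        J = config.sq_decay * J + (1.0 - config.sq_decay) * gr ** 2
        Z = config.damping + J
        setattr(params, name, p - m * (J / Z))
        opt.m[name] = m
        opt.J[name] = J
    return params, opt


def pad_sequences(
    X: Sequence[np.ndarray], y: Sequence[np.ndarray] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Pad variable-length sequences into (B, T, F) plus a validity mask."""
    lengths = [len(x) for x in X]
    if not lengths or min(lengths) == 0:
        raise ValueError("training set must contain nonempty sequences")
    T = max(lengths)
    F = X[0].shape[1]
    Xp = np.zeros((len(X), T, F))
    mask = np.zeros((len(X), T), dtype=bool)
    Yp = np.zeros((len(X), T)) if y is not None else None
    for b, x in enumerate(X):
        Xp[b, : lengths[b]] = x
        mask[b, : lengths[b]] = True
        if y is not None:
            Yp[b, : lengths[b]] = y[b]
    return Xp, mask, Yp


def train(
    params: ModelParams,
    X: Sequence[np.ndarray],
    y: Sequence[np.ndarray],
    config: TrainConfig | None = None,
) -> tuple[ModelParams, list[float]]:
    """Full-batch training of the learner on labeled sequences.

    ``X`` is a list of normalized ``(T_b, F)`` arrays, ``y`` a matching list
    of 0/1 label arrays.  Returns the trained parameters and the per-epoch
    loss trace (evaluated before each update, plus the final loss).
    Deterministic: full-batch gradients, no sampling.
    """
    if config is None:
        config = TrainConfig()
    config.validate()
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    Xp, mask, Yp = pad_sequences(X, y)
    opt = GradOptState()
    trace: list[float] = []
    for _ in range(config.epochs):
        cache = forward_batch(params, Xp, mask)
        trace.append(loss(cache.scores, Yp, config.loss, mask))
        grads = backward_batch(params, cache, Yp, config.loss)
        params, opt = update_parameters(params, grads, opt, config)
    cache = forward_batch(params, Xp, mask)
    trace.append(loss(cache.scores, Yp, config.loss, mask))
    return params, trace


class RecurrentVarianceClassifier(BaseEstimator, ClassifierMixin):
    """Record-level abnormality classifier over normalized sequences.

    Wraps the gated cell, variance readout and damped-momentum training into
    a scikit-learn-style estimator.  ``X`` is a list of ``(T_b, F)`` arrays
    (one per subject), ``y`` a list of matching 0/1 label arrays.

    Parameters
    ----------
    hidden_size : int
        Number of recurrent units.
    epochs, learning_rate, momentum, sq_decay, damping, loss
        Training hyperparameters (see :class:`TrainConfig`).
    gamma_init : float
        Initial leak of the variance activation.
    threshold : float
        Score cut for :meth:`predict`.
    random_state : int
        Seed of the weight initialization.
    """

    def __init__(
        self,
        hidden_size: int = 8,
        epochs: int = 300,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        sq_decay: float = 0.9,
        damping: float = 1e-6,
        gamma_init: float = 0.25,
        loss: str = "mse",
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.sq_decay = sq_decay
        self.damping = damping
        self.gamma_init = gamma_init
        self.loss = loss
        self.threshold = threshold
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            sq_decay=self.sq_decay,
            damping=self.damping,
            loss=self.loss,
        )

    def fit(self, X: Sequence[np.ndarray], y: Sequence[np.ndarray]):
        X = [np.asarray(x, dtype=float) for x in X]
        y = [np.asarray(v, dtype=float) for v in y]
        params = init_params(
            X[0].shape[1],
            hidden_size=self.hidden_size,
            gamma_init=self.gamma_init,
            rng=self.random_state,
        )
        self.params_, self.loss_trace_ = train(params, X, y, self._config())
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise NotFittedError("RecurrentVarianceClassifier is not fitted yet")

    def predict_scores(self, X: Sequence[np.ndarray]) -> list[np.ndarray]:
        """Per-record abnormality scores in (0, 1), one array per sequence."""
        self._check_fitted()
        out = []
        for x in X:
            _, scores = forward_sequence(self.params_, np.asarray(x, dtype=float))
            out.append(scores)
        return out

    def predict(self, X: Sequence[np.ndarray]) -> list[np.ndarray]:
        """Thresholded 0/1 abnormality labels, one array per sequence."""
        return [(s > self.threshold).astype(int) for s in self.predict_scores(X)]
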