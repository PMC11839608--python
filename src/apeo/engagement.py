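"""Engagement modelling, gamification, social influence and the
from-scratch recurrent engagement predictor.

Engagement of participant i is driven by intrinsic motivation
M = enjoyment / perceived effort, social influence S = sum_j w_ij·E_j
(softmax attention weights over peer embeddings), and perceived
competency C = skill gain / skill requirement, combined by a pluggable
read-out (default: logistic-linear).  Gamified rewards, challenge
balancing, adaptive targets and geometric engagement decay close the
motivational loop.  The recurrent predictor is a plain tanh RNN with a
sigmoid output head trained by full-unroll backpropagation through time
and vanilla gradient descent, which keeps training bit-deterministic.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from apeo.errors import DomainError, ShapeError

__all__ = [
    "EngagementFactors",
    "GamificationParams",
    "RNNParams",
    "engagement_components",
    "influence_weights",
    "engagement_value",
    "compute_reward",
    "challenge_balance",
    "update_target",
    "decay_engagement",
    "init_rnn_params",
    "rnn_forward",
    "rnn_loss",
    "rnn_gradients",
    "rnn_train",
    "save_rnn_params",
    "load_rnn_params",
]


@dataclass(frozen=True)
class EngagementFactors:
    """Intrinsic motivation M, social influence S, competency C, noise."""

    intrinsic_M: float
    social_S: float
    competency_C: float
    noise_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.intrinsic_M < 0 or self.competency_C < 0:
            raise DomainError("M and C are ratios of positive quantities, >= 0")


@dataclass(frozen=True)
class GamificationParams:
    beta1: float = 1.0       # task-score reward weight
    beta2: float = 1.0       # engagement reward weight
    gamma_bonus: float = 1.0  # milestone-bonus weight
    T_threshold: float = 0.6  # task score needed for a bonus
    delta: float = 0.5       # reward -> perceived-challenge coupling
    eta_target: float = 0.1  # target adaptation rate
    alpha_decay: float = 0.9  # engagement decay rate

    def __post_init__(self) -> None:
        if min(self.beta1, self.beta2, self.gamma_bonus, self.delta) < 0:
            raise DomainError("reward weights must be >= 0")
        if not 0 < self.eta_target <= 1:
            raise DomainError(f"eta_target must be in (0,1], got {self.eta_target}")
        if not 0 <= self.alpha_decay <= 1:
            raise DomainError(f"alpha_decay must be in [0,1], got {self.alpha_decay}")


def engagement_components(
    enjoyment: float,
    effort: float,
    skill_gain: float,
    skill_req: float,
    peer_engagements: Sequence[float],
    weights: Sequence[float],
    noise_eps: float = 0.0,
) -> EngagementFactors:
    """Assemble the three engagement drivers for one participant.

    ``weights`` must be the participant's normalized peer-influence
    weights (sum to 1 within 1e-8).
    """
    if effort <= 0:
        raise DomainError(f"perceived effort must be > 0, got {effort}")
    if skill_req <= 0:
        raise DomainError(f"skill requirement must be > 0, got {skill_req}")
    w = np.asarray(weights, dtype=float)
    E = np.asarray(peer_engagements, dtype=float)
    if w.shape != E.shape:
        raise ShapeError(f"weights shape {w.shape} != peers shape {E.shape}")
    if w.size and abs(w.sum() - 1.0) > 1e-8:
        raise DomainError(f"influence weights must sum to 1, got {w.sum()!r}")
    return EngagementFactors(
        intrinsic_M=enjoyment / effort,
        social_S=float(w @ E) if w.size else 0.0,
        competency_C=skill_gain / skill_req,
        noise_eps=noise_eps,
    )


def influence_weights(theta_i: np.ndarray, phis: np.ndarray) -> np.ndarray:
    """Softmax attention weights w_ij = softmax_j(theta_i'·phi_j).

    Computed with max-subtraction so large dot products cannot overflow;
    weights are strictly positive and sum to 1 to machine precision.
    """
    theta_i = np.asarray(theta_i, dtype=float)
    phis = np.atleast_2d(np.asarray(phis, dtype=float))
    if phis.shape[0] < 1:
        raise DomainError("need at least one peer")
    if phis.shape[1] != theta_i.size:
        raise ShapeError(
            f"peer embedding dim {phis.shape[1]} != own dim {theta_i.size}")
    logits = phis @ theta_i
    logits = logits - logits.max()
    w = np.exp(logits)
    return w / w.sum()


def default_readout(M: float, S: float, C: float,
                    w: Sequence[float] = (1.0, 1.0, 1.0),
                    b: float = 0.0) -> float:
    """Logistic-linear engagement read-out sigma(w·[M,S,C] + b)."""
    z = float(np.asarray(w, float) @ np.array([M, S, C])) + b
    return float(1.0 / (1.0 + np.exp(-z)))


def engagement_value(
    factors: EngagementFactors,
    f: Callable[[float, float, float], float] | None = None,
) -> float:
    """Engagement E = f(M, S, C) + eps clamped to [0, 1].

    ``f`` defaults to the logistic-linear read-out; any callable of
    (M, S, C) may be plugged in.
    """
    fn = f if f is not None else default_readout
    e = fn(factors.intrinsic_M, factors.social_S, factors.competency_C)
    e += factors.noise_eps
    return min(max(float(e), 0.0), 1.0)


def compute_reward(T: float, E: float,
                   params: GamificationParams) -> tuple[float, float]:
    """Gamified reward R = beta1·T + beta2·E + gamma·B with milestone
    bonus B = max(0, T − T_threshold).  Returns (R, B)."""
    B = max(0.0, T - params.T_threshold)
    R = params.beta1 * T + params.beta2 * E + params.gamma_bonus * B
    return R, B


def challenge_balance(F_target, F_actual, R: float, delta: float) -> float:
    """Perceived challenge ||F_target − F_actual||² − delta·R (may be
    negative when rewards outweigh the performance gap)."""
    if delta < 0:
        raise DomainError(f"delta must be >= 0, got {delta}")
    F_target = np.atleast_1d(np.asarray(F_target, float))
    F_actual = np.atleast_1d(np.asarray(F_actual, float))
    if F_target.shape != F_actual.shape:
        raise ShapeError(
            f"target shape {F_target.shape} != actual shape {F_actual.shape}")
    diff = F_target - F_actual
    return float(diff @ diff) - delta * R


def update_target(F_target, F_actual, eta_target: float):
    """Adaptive difficulty: F_target ← F_target + eta·(F_actual − F_target)."""
    if not 0 < eta_target <= 1:
        raise DomainError(f"eta_target must be in (0,1], got {eta_target}")
    F_target = np.asarray(F_target, dtype=float)
    F_actual = np.asarray(F_actual, dtype=float)
    out = F_target + eta_target * (F_actual - F_target)
    return float(out) if out.ndim == 0 else out


def decay_engagement(E: float, R: float, alpha_decay: float) -> float:
    """Geometric engagement decay toward the reward level:
    E(t+1) = alpha·E(t) + (1 − alpha)·R."""
    if not 0 <= alpha_decay <= 1:
        raise DomainError(f"alpha_decay must be in [0,1], got {alpha_decay}")
    return alpha_decay * E + (1.0 - alpha_decay) * R


# --------------------------------------------------------------------------
# Recurrent engagement predictor (tanh RNN + sigmoid head, trained by BPTT)
# --------------------------------------------------------------------------

@dataclass
class RNNParams:
    """Weights of the engagement RNN.

    ``W_h`` (H, d), ``U_h`` (H, H), ``b_h`` (H,) define the hidden update
    h(t) = tanh(W_h·x(t) + U_h·h(t−1) + b_h); ``W_e`` (H,), ``b_e``
    the output head E(t+1) = sigma(W_e·h(t) + b_e).
    """

    W_h: np.ndarray
    U_h: np.ndarray
    b_h: np.ndarray
    W_e: np.ndarray
    b_e: float

    def __post_init__(self) -> None:
        self.W_h = np.atleast_2d(np.asarray(self.W_h, float))
        self.U_h = np.atleast_2d(np.asarray(self.U_h, float))
        self.b_h = np.atleast_1d(np.asarray(self.b_h, float))
        self.W_e = np.atleast_1d(np.asarray(self.W_e, float))
        H = self.W_h.shape[0]
        if self.U_h.shape != (H, H) or self.b_h.shape != (H,) \
                or self.W_e.shape != (H,):
            raise ShapeError("RNN parameter shapes are mutually inconsistent")
        for a in (self.W_h, self.U_h, self.b_h, self.W_e):
            if not np.all(np.isfinite(a)):
                raise DomainError("RNN parameters must be finite")

    @property
    def hidden_dim(self) -> int:
        return self.W_h.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_h.shape[1]

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.W_h.ravel(), self.U_h.ravel(), self.b_h,
            self.W_e, [self.b_e]])

    @classmethod
    def from_vector(cls, v: np.ndarray, hidden_dim: int,
                    input_dim: int) -> "RNNParams":
        v = np.asarray(v, dtype=float)
        H, d = hidden_dim, input_dim
        sizes = [H * d, H * H, H, H, 1]
        if v.size != sum(sizes):
            raise ShapeError(f"vector of size {v.size} cannot fill an RNN "
                             f"with H={H}, d={d}")
        parts = np.split(v, np.cumsum(sizes)[:-1])
        return cls(W_h=parts[0].reshape(H, d), U_h=parts[1].reshape(H, H),
                   b_h=parts[2], W_e=parts[3], b_e=float(parts[4][0]))


def init_rnn_params(input_dim: int, hidden_dim: int = 4,
                    seed: int | None = None,
                    scale: float = 0.5) -> RNNParams:
    """Small random initialization, deterministic per seed."""
    rng = np.random.default_rng(seed)
    return RNNParams(
        W_h=rng.normal(0, scale, (hidden_dim, input_dim)),
        U_h=rng.normal(0, scale / np.sqrt(hidden_dim), (hidden_dim, hidden_dim)),
        b_h=np.zeros(hidden_dim),
        W_e=rng.normal(0, scale, hidden_dim),
        b_e=0.0,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def rnn_forward(
    x_series: np.ndarray,
    params: RNNParams,
    h0: np.ndarray | None = None,
    return_hidden: bool = False,
):
    """Predicted engagement series, one value per input step, all in (0, 1)."""
    x = np.atleast_2d(np.asarray(x_series, dtype=float))
    if x.shape[0] < 1:
        raise DomainError("input series must be non-empty")
    if x.shape[1] != params.input_dim:
        raise ShapeError(
            f"input dim {x.shape[1]} != RNN input dim {params.input_dim}")
    H = params.hidden_dim
    h = np.zeros(H) if h0 is None else np.asarray(h0, dtype=float)
    if h.shape != (H,):
        raise ShapeError(f"h0 shape {h.shape} != ({H},)")
    hiddens, preds = [], []
    for t in range(x.shape[0]):
        h = np.tanh(params.W_h @ x[t] + params.U_h @ h + params.b_h)
        hiddens.append(h)
        preds.append(float(_sigmoid(np.array(params.W_e @ h + params.b_e))))
    preds = np.array(preds)
    if return_hidden:
        return preds, np.array(hiddens)
    return preds


def _as_batch(dataset):
    """Stack a dataset into (X, Y) arrays when all sequences share one
    length; returns None otherwise."""
    xs, ys = [], []
    for x_series, e_true in dataset:
        xs.append(np.atleast_2d(np.asarray(x_series, dtype=float)))
        ys.append(np.asarray(e_true, dtype=float))
        if ys[-1].shape != (xs[-1].shape[0],):
            raise ShapeError(
                f"target shape {ys[-1].shape} != sequence length "
                f"{xs[-1].shape[0]}")
    lengths = {x.shape[0] for x in xs}
    if len(lengths) != 1:
        return None
    return np.stack(xs), np.stack(ys)


def _batched_forward(X: np.ndarray, params: RNNParams):
    """Vectorized forward over a (n, T, d) batch; returns predictions
    (n, T) and hidden states (n, T, H)."""
    n, T, _ = X.shape
    H = params.hidden_dim
    h = np.zeros((n, H))
    hiddens = np.empty((n, T, H))
    preds = np.empty((n, T))
    for t in range(T):
        h = np.tanh(X[:, t] @ params.W_h.T + h @ params.U_h.T + params.b_h)
        hiddens[:, t] = h
        preds[:, t] = _sigmoid(h @ params.W_e + params.b_e)
    return preds, hiddens


def rnn_loss(dataset, params: RNNParams) -> float:
    """Sum of squared engagement prediction errors over all sequences."""
    batch = _as_batch(list(dataset))
    if batch is not None:
        X, Y = batch
        preds, _ = _batched_forward(X, params)
        return float(np.sum((Y - preds) ** 2))
    total = 0.0
    for x_series, e_true in dataset:
        pred = rnn_forward(x_series, params)
        e_true = np.asarray(e_true, dtype=float)
        if e_true.shape != pred.shape:
            raise ShapeError(
                f"target shape {e_true.shape} != prediction shape {pred.shape}")
        total += float(np.sum((e_true - pred) ** 2))
    return total


def rnn_gradients(dataset, params: RNNParams) -> RNNParams:
    """Analytic gradients of :func:`rnn_loss` via full-unroll BPTT."""
    dataset = list(dataset)
    batch = _as_batch(dataset)
    if batch is not None:
        return _batched_gradients(*batch, params)
    gW_h = np.zeros_like(params.W_h)
    gU_h = np.zeros_like(params.U_h)
    gb_h = np.zeros_like(params.b_h)
    gW_e = np.zeros_like(params.W_e)
    gb_e = 0.0
    for x_series, e_true in dataset:
        x = np.atleast_2d(np.asarray(x_series, dtype=float))
        e_true = np.asarray(e_true, dtype=float)
        preds, hiddens = rnn_forward(x, params, return_hidden=True)
        T = x.shape[0]
        dh_next = np.zeros(params.hidden_dim)
        for t in range(T - 1, -1, -1):
            y = preds[t]
            dz = 2.0 * (y - e_true[t]) * y * (1.0 - y)
            gW_e += dz * hiddens[t]
            gb_e += dz
            dh = dz * params.W_e + dh_next
            da = dh * (1.0 - hiddens[t] ** 2)
            gW_h += np.outer(da, x[t])
            h_prev = hiddens[t - 1] if t > 0 else np.zeros(params.hidden_dim)
            gU_h += np.outer(da, h_prev)
            gb_h += da
            dh_next = params.U_h.T @ da
    return RNNParams(W_h=gW_h, U_h=gU_h, b_h=gb_h, W_e=gW_e, b_e=gb_e)


def _batched_gradients(X: np.ndarray, Y: np.ndarray,
                       params: RNNParams) -> RNNParams:
    """BPTT vectorized over sequences of equal length."""
    n, T, _ = X.shape
    preds, hiddens = _batched_forward(X, params)
    gW_h = np.zeros_like(params.W_h)
    gU_h = np.zeros_like(params.U_h)
    gb_h = np.zeros_like(params.b_h)
    gW_e = np.zeros_like(params.W_e)
    gb_e = 0.0
    dh_next = np.zeros((n, params.hidden_dim))
    for t in range(T - 1, -1, -1):
        y = preds[:, t]
        dz = 2.0 * (y - Y[:, t]) * y * (1.0 - y)          # (n,)
        gW_e += dz @ hiddens[:, t]
        gb_e += float(dz.sum())
        dh = dz[:, None] * params.W_e[None, :] + dh_next
        da = dh * (1.0 - hiddens[:, t] ** 2)
        gW_h += da.T @ X[:, t]
        h_prev = (hiddens[:, t - 1] if t > 0
                  else np.zeros((n, params.hidden_dim)))
        gU_h += da.T @ h_prev
        gb_h += da.sum(axis=0)
        dh_next = da @ params.U_h
    return RNNParams(W_h=gW_h, U_h=gU_h, b_h=gb_h, W_e=gW_e, b_e=gb_e)


def rnn_train(
    dataset,
    init_params: RNNParams | None = None,
    lr: float = 5.0,
    epochs: int = 200,
    seed: int | None = None,
) -> tuple[RNNParams, list[float]]:
    """Full-batch gradient descent on the squared prediction error.

    Deterministic per seed (the seed only drives initialization when
    ``init_params`` is omitted).  Returns fitted parameters and the loss
    recorded before each epoch plus the final loss.
    """
    dataset = list(dataset)
    if not dataset:
        raise DomainError("dataset must contain at least one sequence")
    if lr <= 0:
        raise DomainError(f"lr must be > 0, got {lr}")
    if init_params is None:
        d = np.atleast_2d(np.asarray(dataset[0][0], float)).shape[1]
        init_params = init_rnn_params(d, seed=seed)
    p = RNNParams(W_h=init_params.W_h.copy(), U_h=init_params.U_h.copy(),
                  b_h=init_params.b_h.copy(), W_e=init_params.W_e.copy(),
                  b_e=init_params.b_e)
    # scale the step by the observation count so lr is a per-sample rate
    # and stability does not depend on dataset size
    n_obs = sum(np.asarray(e, dtype=float).size for _, e in dataset)
    step = lr / n_obs
    trace = [rnn_loss(dataset, p)]
    for _ in range(epochs):
        g = rnn_gradients(dataset, p)
        p = RNNParams(W_h=p.W_h - step * g.W_h, U_h=p.U_h - step * g.U_h,
                      b_h=p.b_h - step * g.b_h, W_e=p.W_e - step * g.W_e,
                      b_e=p.b_e - step * g.b_e)
        trace.append(rnn_loss(dataset, p))
    return p, trace


def save_rnn_params(params: RNNParams, path) -> None:
    payload = {
        "W_h": params.W_h.tolist(), "U_h": params.U_h.tolist(),
        "b_h": params.b_h.tolist(), "W_e": params.W_e.tolist(),
        "b_e": params.b_e,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_rnn_params(path) -> RNNParams:
    with open(path) as fh:
        d = json.load(fh)
    return RNNParams(W_h=np.array(d["W_h"]), U_h=np.array(d["U_h"]),
                     b_h=np.array(d["b_h"]), W_e=np.array(d["W_e"]),
                     b_e=float(d["b_e"]))
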