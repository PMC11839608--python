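"""Participant state dynamics and PID control.

The per-participant state S(t) = [fitness..., engagement, adherence]
evolves by a linear controlled update S(t+1) = S(t) + W_s·u + D_s·d with
engagement and adherence clamped to [0, 1] afterwards.  An autonomous
first-order relaxation toward a target state with a participant-specific
time constant is exposed in closed form and serves as the oracle for the
discrete Euler stepping.  The controller is a discrete PID with
rectangle-rule integral, backward-difference derivative, and optional
integral clamping (anti-windup) because real interventions are
box-constrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from apeo.errors import DomainError, ShapeError

__all__ = [
    "ParticipantState",
    "StateDynamics",
    "PIDGains",
    "evolve_state",
    "performance_error",
    "state_cost",
    "relax_towards_target",
    "pid_control",
    "PIDController",
]


@dataclass
class ParticipantState:
    """State vector [F..., E, A]; engagement/adherence live in [0, 1]."""

    fitness: np.ndarray
    engagement: float
    adherence: float
    t: int = 0
    clamped: bool = False  # set when the last update hit a [0,1] bound

    def __post_init__(self) -> None:
        self.fitness = np.atleast_1d(np.asarray(self.fitness, dtype=float))
        if not np.all(np.isfinite(self.fitness)):
            raise DomainError("fitness must be finite")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.fitness, [self.engagement, self.adherence]])

    @classmethod
    def from_vector(cls, v: np.ndarray, t: int = 0,
                    clamped: bool = False) -> "ParticipantState":
        v = np.asarray(v, dtype=float)
        return cls(fitness=v[:-2], engagement=float(v[-2]),
                   adherence=float(v[-1]), t=t, clamped=clamped)

    @property
    def dim(self) -> int:
        return self.fitness.size + 2


@dataclass(frozen=True)
class StateDynamics:
    """Linear maps from interventions (W_s) and disturbances (D_s) to
    state changes."""

    W_s: np.ndarray
    D_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "W_s", np.atleast_2d(np.asarray(self.W_s, float)))
        object.__setattr__(self, "D_s", np.atleast_2d(np.asarray(self.D_s, float)))
        if self.W_s.shape[0] != self.D_s.shape[0]:
            raise ShapeError(
                f"W_s maps to dim {self.W_s.shape[0]} but D_s to "
                f"{self.D_s.shape[0]}")


@dataclass(frozen=True)
class PIDGains:
    Kp: float = 1.0
    Ki: float = 0.0
    Kd: float = 0.0
    dt: float = 1.0
    integral_limit: float | None = None  # anti-windup clamp on |integral|

    def __post_init__(self) -> None:
        if min(self.Kp, self.Ki, self.Kd) < 0:
            raise DomainError("PID gains must be >= 0")
        if self.dt <= 0:
            raise DomainError(f"dt must be > 0, got {self.dt}")


def evolve_state(
    S: ParticipantState,
    u: np.ndarray,
    d: np.ndarray,
    dyn: StateDynamics,
) -> ParticipantState:
    """One controlled step: S + W_s·u + D_s·d, then clamp E, A to [0, 1]."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if dyn.W_s.shape != (S.dim, u.size):
        raise ShapeError(
            f"W_s shape {dyn.W_s.shape} incompatible with state dim {S.dim} "
            f"and intervention dim {u.size}")
    if dyn.D_s.shape != (S.dim, d.size):
        raise ShapeError(
            f"D_s shape {dyn.D_s.shape} incompatible with state dim {S.dim} "
            f"and disturbance dim {d.size}")
    v = S.as_vector() + dyn.W_s @ u + dyn.D_s @ d
    raw_e, raw_a = v[-2], v[-1]
    v[-2] = min(max(raw_e, 0.0), 1.0)
    v[-1] = min(max(raw_a, 0.0), 1.0)
    clamped = (raw_e != v[-2]) or (raw_a != v[-1])
    return ParticipantState.from_vector(v, t=S.t + 1, clamped=clamped)


def performance_error(F_target: np.ndarray, F_actual: np.ndarray) -> np.ndarray:
    """Tracking error e = F_target − F_actual (wearable-measured state)."""
    F_target = np.atleast_1d(np.asarray(F_target, dtype=float))
    F_actual = np.atleast_1d(np.asarray(F_actual, dtype=float))
    if F_target.shape != F_actual.shape:
        raise ShapeError(
            f"target shape {F_target.shape} != actual shape {F_actual.shape}")
    return F_target - F_actual


def state_cost(errors, interventions, lam: float = 0.0) -> float:
    """Cohort state cost: sum_i ||e_i||^2 + lambda·||u_i||^2.

    ``lam`` regularizes intervention magnitude so the controller does not
    buy tracking accuracy with arbitrarily large prescriptions.
    """
    if lam < 0:
        raise DomainError(f"lambda must be >= 0, got {lam}")
    errors = [np.atleast_1d(np.asarray(e, float)) for e in errors]
    interventions = [np.atleast_1d(np.asarray(u, float)) for u in interventions]
    if len(errors) != len(interventions):
        raise ShapeError(
            f"{len(errors)} error vectors vs {len(interventions)} interventions")
    total = 0.0
    for e, u in zip(errors, interventions):
        total += float(e @ e) + lam * float(u @ u)
    return total


def relax_towards_target(S0, S_target, tau: float, t) -> np.ndarray | float:
    """Closed-form first-order relaxation
    S(t) = S_target + (S0 − S_target)·exp(−t/tau)."""
    if tau <= 0:
        raise DomainError(f"tau must be > 0, got {tau}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("elapsed time must be >= 0")
    out = S_target + (np.asarray(S0, float) - S_target) * np.exp(-t / tau)
    return out if out.ndim else float(out)


def pid_control(error_history, gains: PIDGains) -> np.ndarray | float:
    """Stateless PID on an error history (most recent last).

    u = Kp·e(t) + Ki·(rectangle-rule integral) + Kd·(backward difference)/dt,
    applied component-wise for vector errors.  The integral is clamped to
    ``gains.integral_limit`` when set (anti-windup).
    """
    history = [np.atleast_1d(np.asarray(e, float)) for e in error_history]
    if not history:
        raise DomainError("error history must contain at least one error")
    e_now = history[-1]
    integral = gains.dt * np.sum(history, axis=0)
    if gains.integral_limit is not None:
        integral = np.clip(integral, -gains.integral_limit, gains.integral_limit)
    deriv = ((e_now - history[-2]) / gains.dt if len(history) > 1
             else np.zeros_like(e_now))
    u = gains.Kp * e_now + gains.Ki * integral + gains.Kd * deriv
    return u if e_now.size > 1 else float(u[0])


@dataclass
class PIDController:
    """Incremental PID that carries its own integral and previous error —
    O(1) per step, equivalent to :func:`pid_control` on the full history."""

    gains: PIDGains
    _integral: np.ndarray | None = field(default=None, repr=False)
    _prev: np.ndarray | None = field(default=None, repr=False)

    def reset(self) -> None:
        self._integral = None
        self._prev = None

    def step(self, e) -> np.ndarray | float:
        e = np.atleast_1d(np.asarray(e, float))
        g = self.gains
        if self._integral is None:
            self._integral = np.zeros_like(e)
        self._integral = self._integral + g.dt * e
        if g.integral_limit is not None:
            self._integral = np.clip(self._integral, -g.integral_limit,
                                     g.integral_limit)
        deriv = ((e - self._prev) / g.dt if self._prev is not None
                 else np.zeros_like(e))
        self._prev = e
        u = g.Kp * e + g.Ki * self._integral + g.Kd * deriv
        return u if e.size > 1 else float(u[0])
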