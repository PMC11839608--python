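"""Real-time feedback: goal adaptation, performance classification,
corrective/motivational signals, fatigue-risk scoring and intensity
gating.

Performance relative to a participant goal G partitions into four
classes: OPTIMAL within an epsilon band, UNDERPERFORMING below G − kappa,
OVEREXERTING above G + kappa, and MARGINAL in the gap between the epsilon
band and the kappa tolerance (left undefined by the threshold rule; made
explicit here and mapped to "monitor, no adjustment").  Fatigue risk
combines heart-rate variability and movement-velocity deviation against
cumulative rewards; when it crosses a threshold the prescribed intensity
is reduced proportionally to the performance deviation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from apeo.errors import DomainError

__all__ = [
    "FeedbackParams",
    "PerformanceClass",
    "update_goal",
    "classify_performance",
    "feedback_signals",
    "fatigue_risk",
    "adjust_intensity",
]


class PerformanceClass(enum.Enum):
    OPTIMAL = "optimal"
    UNDERPERFORMING = "underperforming"
    OVEREXERTING = "overexerting"
    MARGINAL = "marginal"


@dataclass(frozen=True)
class FeedbackParams:
    epsilon: float = 0.1       # optimal-band half-width
    kappa: float = 0.3         # under/over tolerance (>= epsilon)
    gamma1: float = 1.0        # corrective-signal scale
    gamma2: float = 1.0        # motivational-cue scale
    eta_goal: float = 0.2      # goal adjustment rate, (0, 1]
    alpha_H: float = 1.0       # HRV weight in fatigue risk
    beta_V: float = 1.0        # velocity-deviation weight
    zeta_R: float = 0.5        # reward (protective) weight
    tau_fatigue: float = 1.0   # risk threshold triggering gating
    rho: float = 0.2           # intensity adjustment rate
    I_min: float = 0.0
    I_max: float = 1.0
    history_window: int = 5    # points used for the motivational slope

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.kappa < 0:
            raise DomainError("epsilon and kappa must be >= 0")
        if self.epsilon > self.kappa:
            raise DomainError(
                f"epsilon ({self.epsilon}) must not exceed kappa "
                f"({self.kappa}): the optimal band lies inside the tolerance")
        if not 0 < self.eta_goal <= 1:
            raise DomainError(f"eta_goal must be in (0,1], got {self.eta_goal}")
        if min(self.gamma1, self.gamma2, self.alpha_H, self.beta_V,
               self.zeta_R, self.rho) < 0:
            raise DomainError("scale factors and weights must be >= 0")
        if self.I_min >= self.I_max:
            raise DomainError("I_min must be < I_max")


def update_goal(G: float, M: float, T_optimal: float,
                eta_goal: float) -> float:
    """Periodic goal adaptation G ← G + eta·(T_optimal − M)."""
    if not 0 < eta_goal <= 1:
        raise DomainError(f"eta_goal must be in (0,1], got {eta_goal}")
    return G + eta_goal * (T_optimal - M)


def classify_performance(M: float, G: float,
                         params: FeedbackParams) -> PerformanceClass:
    """Threshold classification of measurement M against goal G.

    Exactly one class for every input: OPTIMAL if |M−G| <= epsilon, then
    UNDERPERFORMING/OVEREXERTING outside the kappa tolerance, else
    MARGINAL.
    """
    dev = abs(M - G)
    if dev <= params.epsilon:
        return PerformanceClass.OPTIMAL
    if M < G - params.kappa:
        return PerformanceClass.UNDERPERFORMING
    if M > G + params.kappa:
        return PerformanceClass.OVEREXERTING
    return PerformanceClass.MARGINAL


def _recent_slope(history: np.ndarray) -> float:
    """Least-squares slope of performance vs step index."""
    t = np.arange(history.size, dtype=float)
    t -= t.mean()
    denom = float(t @ t)
    return float(t @ (history - history.mean()) / denom) if denom else 0.0


def feedback_signals(
    M: float,
    G: float,
    history,
    params: FeedbackParams,
) -> dict:
    """Corrective and motivational feedback for one step.

    Corrective signal C = gamma1·(G − M).  The motivational cue is
    gamma2·slope of the recent performance history (least-squares over the
    last ``history_window`` points): a positive slope yields reinforcement
    proportional to the improvement rate, a flat or declining slope sets
    the encourage-with-correction flag.  An empty history falls back to a
    cue from M alone, flagged accordingly.
    """
    corrective = params.gamma1 * (G - M)
    history = np.asarray(list(history), dtype=float)
    if history.size == 0:
        return {
            "corrective": corrective,
            "cue": params.gamma2 * M,
            "encourage": True,
            "no_history": True,
        }
    recent = history[-params.history_window:]
    slope = _recent_slope(recent)
    return {
        "corrective": corrective,
        "cue": params.gamma2 * slope,
        "encourage": slope <= 0,
        "no_history": False,
    }


def fatigue_risk(H: float, V: float, R: float,
                 params: FeedbackParams) -> float:
    """Fatigue risk alpha·H + beta·V − zeta·R.

    H and V should be z-scored against the participant's rolling baseline
    so the weights are scale-free; R is cumulative reward, which is
    protective (higher rewards signal engaged, non-fatigued activity).
    """
    return params.alpha_H * H + params.beta_V * V - params.zeta_R * R


def adjust_intensity(A: float, D: float, risk: float,
                     params: FeedbackParams) -> tuple[float, bool]:
    """Gated intensity reduction: when risk exceeds tau_fatigue,
    A ← A − rho·D clamped into [I_min, I_max].  Returns (intensity,
    clamped flag); below-threshold risk leaves A untouched."""
    if risk <= params.tau_fatigue:
        return A, False
    raw = A - params.rho * D
    new = min(max(raw, params.I_min), params.I_max)
    return new, new != raw
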