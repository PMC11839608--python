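"""Joint kinematics, inverse dynamics, energy accounting, and force
optimization.

Forces come from Newton's second law F = m·a per joint and time step;
torques from the standard rigid-body form tau = I·q̈ + C(q, q̇) + G(q);
mechanical energy is kinetic energy plus trapezoidal accumulation of the
work F·v.  Inefficient movement is corrected by gradient descent on the
squared deviation from an optimal force profile, with a hard per-joint
energy cap enforced by scaling the step (projection).
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass
import warnings

import numpy as np

from apeo.errors import DomainError, ShapeError

__all__ = [
    "JointTrajectory",
    "RigidJointModel",
    "EnergyBudget",
    "joint_kinetics",
    "inverse_dynamics",
    "mechanical_energy",
    "inefficiency_loss",
    "optimize_forces",
    "reference_force_profile",
    "pendulum_model",
]


@dataclass
class JointTrajectory:
    """Sampled motion of one joint: positions/velocities/accelerations are
    (T, 3) arrays in SI units; missing derivatives are filled by central
    differences."""

    positions: np.ndarray | None = None
    velocities: np.ndarray | None = None
    accelerations: np.ndarray | None = None
    mass: float = 1.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise DomainError(f"mass must be > 0, got {self.mass}")
        if self.dt <= 0:
            raise DomainError(f"dt must be > 0, got {self.dt}")
        arrays = {}
        for name in ("positions", "velocities", "accelerations"):
            a = getattr(self, name)
            if a is not None:
                a = np.atleast_2d(np.asarray(a, dtype=float))
                arrays[name] = a
                setattr(self, name, a)
        if not arrays:
            raise DomainError("trajectory needs at least one kinematic series")
        lengths = {a.shape[0] for a in arrays.values()}
        if len(lengths) > 1:
            raise ShapeError(f"kinematic series lengths differ: {lengths}")
        self._n = lengths.pop()

    def ensure_derivatives(self) -> None:
        """Fill velocities/accelerations by central differences."""
        if self.velocities is None:
            if self.positions is None or self._n < 3:
                raise DomainError(
                    "need positions with >= 3 samples to differentiate")
            self.velocities = np.gradient(self.positions, self.dt, axis=0)
        if self.accelerations is None:
            if self._n < 3:
                raise DomainError(
                    "need >= 3 samples to differentiate velocities")
            self.accelerations = np.gradient(self.velocities, self.dt, axis=0)


@dataclass(frozen=True)
class RigidJointModel:
    """1-DOF rigid joint: inertia plus Coriolis/centrifugal and gravity
    terms as callables of the joint coordinate(s)."""

    inertia: float
    coriolis_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    gravity_fn: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise DomainError(f"inertia must be > 0, got {self.inertia}")


@dataclass(frozen=True)
class EnergyBudget:
    """Permissible total mechanical energy across joints, J."""

    E_max: float

    def __post_init__(self) -> None:
        if self.E_max <= 0:
            raise DomainError(f"E_max must be > 0, got {self.E_max}")


def joint_kinetics(traj: JointTrajectory) -> np.ndarray:
    """Per-step joint forces F(t) = m·a(t), shape (T, 3)."""
    if traj.accelerations is None:
        traj.ensure_derivatives()
    return traj.mass * traj.accelerations


def integrate_positions(traj: JointTrajectory) -> np.ndarray:
    """Reconstruct positions from velocities by the trapezoid rule,
    anchored at the first recorded position (O(dt^2) accurate)."""
    if traj.velocities is None:
        raise DomainError("velocities required for position reconstruction")
    p0 = traj.positions[0] if traj.positions is not None else np.zeros(3)
    v = traj.velocities
    increments = 0.5 * (v[1:] + v[:-1]) * traj.dt
    return p0 + np.vstack([np.zeros(3), np.cumsum(increments, axis=0)])


def inverse_dynamics(q, qdot, qddot, model: RigidJointModel) -> np.ndarray | float:
    """Joint torque tau = I·q̈ + C(q, q̇) + G(q)."""
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    qddot = np.asarray(qddot, dtype=float)
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qdot))
            and np.all(np.isfinite(qddot))):
        raise DomainError("joint coordinates must be finite")
    tau = (model.inertia * qddot + np.asarray(model.coriolis_fn(q, qdot), float)
           + np.asarray(model.gravity_fn(q), float))
    return float(tau) if tau.ndim == 0 else tau


def mechanical_energy(traj: JointTrajectory, forces: np.ndarray) -> np.ndarray:
    """Energy series E(t) = ½·m·||v(t)||² + ∫ F·v dt (trapezoid)."""
    if traj.velocities is None:
        traj.ensure_derivatives()
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    v = traj.velocities
    if forces.shape != v.shape:
        raise ShapeError(
            f"forces shape {forces.shape} != velocities shape {v.shape}")
    kinetic = 0.5 * traj.mass * np.sum(v**2, axis=1)
    power = np.sum(forces * v, axis=1)
    work = np.concatenate([
        [0.0], np.cumsum(0.5 * (power[1:] + power[:-1]) * traj.dt)])
    return kinetic + work


def inefficiency_loss(F_actual: np.ndarray, F_optimal: np.ndarray) -> float:
    """Squared deviation of actual from optimal joint forces; 0 iff equal."""
    F_actual = np.asarray(F_actual, dtype=float)
    F_optimal = np.asarray(F_optimal, dtype=float)
    if F_actual.shape != F_optimal.shape:
        raise ShapeError(
            f"force shapes differ: {F_actual.shape} vs {F_optimal.shape}")
    return float(np.sum((F_actual - F_optimal) ** 2))


def optimize_forces(
    F_actual: np.ndarray,
    F_optimal: np.ndarray,
    eta: float,
    budget: EnergyBudget | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
    energy_fn: Callable[[np.ndarray], float] | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Gradient descent F ← F − eta·2(F − F_optimal) with an optional
    energy projection.

    When a ``budget`` and ``energy_fn`` (forces → total energy) are given,
    any step whose energy exceeds ``E_max`` is scaled back toward the
    previous iterate until feasible.  Returns the final forces and the
    loss trace (loss before each iterate plus the final loss).
    """
    if eta <= 0:
        raise DomainError(f"eta must be > 0, got {eta}")
    if eta >= 1:
        warnings.warn(f"eta={eta} >= 1 risks divergence of the quadratic "
                      "descent", stacklevel=2)
    F = np.array(F_actual, dtype=float)
    F_opt = np.asarray(F_optimal, dtype=float)
    if F.shape != F_opt.shape:
        raise ShapeError(f"force shapes differ: {F.shape} vs {F_opt.shape}")
    trace = [inefficiency_loss(F, F_opt)]
    for _ in range(max_iter):
        if trace[-1] < tol:
            break
        step = -eta * 2.0 * (F - F_opt)
        F_new = F + step
        if budget is not None and energy_fn is not None:
            scale = 1.0
            while scale > 1e-12 and energy_fn(F + scale * step) > budget.E_max:
                scale *= 0.5
            if energy_fn(F + scale * step) > budget.E_max:
                scale = 0.0  # stuck on the energy boundary: do not move
            F_new = F + scale * step
        F = F_new
        trace.append(inefficiency_loss(F, F_opt))
    return F, trace


def reference_force_profile(template: np.ndarray, body_mass: float,
                            reference_mass: float = 60.0) -> np.ndarray:
    """Synthetic stand-in for participant-specific optimal forces: a
    reference per-unit-mass force template scaled linearly by body mass.

    Real optimal forces would come from biomechanical norms and energy
    minimization; no such norm dataset ships with the package, so this
    helper only rescales an explicit template.
    """
    if body_mass <= 0:
        raise DomainError(f"body_mass must be > 0, got {body_mass}")
    return np.asarray(template, dtype=float) * (body_mass / reference_mass)


def pendulum_model(mass: float = 1.0, length: float = 1.0,
                   g: float = 9.81) -> RigidJointModel:
    """Point-mass 1-link pendulum; angle measured from the vertical.

    Potential energy V(theta) = −m·g·l·cos(theta), so the gravity torque is
    dV/dtheta = m·g·l·sin(theta); inertia I = m·l²; no Coriolis term for a
    single link.
    """
    if mass <= 0 or length <= 0:
        raise DomainError("mass and length must be > 0")
    return RigidJointModel(
        inertia=mass * length**2,
        coriolis_fn=lambda q, qd: np.zeros_like(np.asarray(q, float)),
        gravity_fn=lambda q: mass * g * length * np.sin(np.asarray(q, float)),
    )
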