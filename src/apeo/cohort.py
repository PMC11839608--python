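"""Synthetic participant cohorts and their ground-truth generators.

Every downstream module is exercised against cohorts produced here:
participant traits (body mass, baseline aerobic capacity, adaptation time
constant, enjoyment/effort/skill terms, social embeddings), the latent
physical-literacy forward model, the participation sigmoid, and the
external-disturbance streams that perturb state dynamics.

Reproducibility contract: a fixed ``(config, seed)`` pair yields a
bit-identical cohort, and each participant owns an RNG stream derived from
the master seed via ``SeedSequence`` spawn keys, so enlarging a cohort
never perturbs the streams of existing participants.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from apeo.errors import ConfigError, DomainError, ShapeError

__all__ = [
    "ParticipantProfile",
    "LiteracyModel",
    "ParticipationModel",
    "CohortConfig",
    "generate_profiles",
    "fitness_attributes",
    "literacy_score",
    "participation_probability",
    "generate_disturbances",
    "profiles_to_csv",
    "profiles_from_csv",
    "load_cohort_config",
]

#: trait name -> (distribution, parameters) used when a config leaves the
#: trait unspecified.  Values are desk-scale choices for an adolescent
#: school cohort; any trait may be fixed to a scalar in the config.
DEFAULT_TRAITS: dict[str, tuple[str, tuple[float, ...]]] = {
    "body_mass": ("normal", (58.0, 9.0)),          # kg
    "vo2_baseline": ("normal", (41.0, 5.0)),       # mL·kg⁻¹·min⁻¹
    "time_constant_tau": ("lognormal", (1.6, 0.3)),  # simulation steps
    "enjoyment": ("beta", (2.0, 2.0)),
    "perceived_effort": ("uniform", (0.3, 0.9)),
    "skill_requirement": ("uniform", (0.3, 0.9)),
}

_TRAIT_FLOORS = {
    "body_mass": 30.0,
    "vo2_baseline": 20.0,
    "time_constant_tau": 1.0,
    "enjoyment": 0.0,
    "perceived_effort": 0.05,
    "skill_requirement": 0.05,
}


@dataclass(frozen=True)
class ParticipantProfile:
    """Static traits of one synthetic participant."""

    id: int
    body_mass: float
    vo2_baseline: float
    time_constant_tau: float
    enjoyment: float
    perceived_effort: float
    skill_requirement: float
    embedding_theta: np.ndarray
    eeg_signature: Mapping[str, Mapping[str, float]] | None
    rng_seed: int

    def __post_init__(self) -> None:
        for name in ("body_mass", "time_constant_tau", "perceived_effort",
                     "skill_requirement"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")

    def rng(self) -> np.random.Generator:
        """Fresh generator for this participant's private stream."""
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class LiteracyModel:
    """Forward latent model L = W·X + eps for physical literacy."""

    loadings_W: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        W = np.asarray(self.loadings_W, dtype=float)
        object.__setattr__(self, "loadings_W", W)
        if not np.all(np.isfinite(W)):
            raise DomainError("loadings_W must be finite")
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class ParticipationModel:
    """Weights of the participation sigmoid P = sigma(E'w_E + C'w_C)."""

    w_E: np.ndarray
    w_C: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w_E", "w_C"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if not np.all(np.isfinite(v)):
                raise DomainError(f"{name} must be finite")


@dataclass
class CohortConfig:
    """Cohort-level settings; ``traits`` entries override DEFAULT_TRAITS.

    A trait override is either a scalar (fixed for every participant) or a
    mapping ``{"dist": name, "params": [...]}``.
    """

    n: int = 8
    seed: int = 0
    fitness_dim: int = 3
    embedding_dim: int = 4
    traits: dict = field(default_factory=dict)

    _KNOWN = {"n", "seed", "fitness_dim", "embedding_dim", "traits"}

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "CohortConfig":
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown cohort config key(s): {sorted(unknown)}")
        traits = dict(raw.get("traits", {}))
        bad = set(traits) - set(DEFAULT_TRAITS)
        if bad:
            raise ConfigError(f"unknown trait key(s): {sorted(bad)}")
        return cls(
            n=int(raw.get("n", 8)),
            seed=int(raw.get("seed", 0)),
            fitness_dim=int(raw.get("fitness_dim", 3)),
            embedding_dim=int(raw.get("embedding_dim", 4)),
            traits=traits,
        )


def load_cohort_config(path) -> CohortConfig:
    """Read a YAML file with a top-level ``cohort:`` block."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    block = raw.get("cohort", raw)
    if not isinstance(block, Mapping):
        raise ConfigError("cohort config must be a mapping")
    return CohortConfig.from_mapping(block)


def _draw_trait(rng: np.random.Generator, name: str, spec) -> float:
    if np.isscalar(spec):
        return float(spec)
    if isinstance(spec, Mapping):
        dist, params = spec.get("dist"), tuple(spec.get("params", ()))
    else:
        dist, params = spec
    if dist == "normal":
        value = rng.normal(*params)
    elif dist == "uniform":
        value = rng.uniform(*params)
    elif dist == "beta":
        value = rng.beta(*params)
    elif dist == "lognormal":
        value = rng.lognormal(*params)
    else:
        raise ConfigError(f"trait '{name}': unknown distribution '{dist}'")
    return float(max(value, _TRAIT_FLOORS[name]))


def generate_profiles(
    n: int,
    config: CohortConfig | Mapping | None = None,
    seed: int | None = None,
) -> list[ParticipantProfile]:
    """Generate ``n`` participant profiles, one independent RNG stream each.

    Parameters
    ----------
    n:
        Cohort size, at least 1.
    config:
        Optional :class:`CohortConfig` or mapping; trait overrides may fix
        a trait to a scalar or replace its distribution.
    seed:
        Master seed; falls back to ``config.seed``.
    """
    if n < 1:
        raise DomainError(f"cohort size must be >= 1, got {n}")
    if config is None:
        config = CohortConfig()
    elif isinstance(config, Mapping):
        config = CohortConfig.from_mapping(config)
    master = config.seed if seed is None else int(seed)

    profiles = []
    for i in range(n):
        ss = np.random.SeedSequence(entropy=master, spawn_key=(i,))
        child_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=master, spawn_key=(i, 0)))
        traits = {
            name: _draw_trait(rng, name, config.traits.get(name, default))
            for name, default in DEFAULT_TRAITS.items()
        }
        theta = rng.normal(0.0, 1.0, size=config.embedding_dim)
        profiles.append(ParticipantProfile(
            id=i,
            embedding_theta=theta,
            eeg_signature=None,  # eeg module default signatures apply
            rng_seed=child_seed,
            **traits,
        ))
    return profiles


def fitness_attributes(
    vo2max: float, vo2_baseline: float, w_max: float, w_body: float
) -> tuple[float, float]:
    """Endurance and strength fitness scores.

    F1 is the relative aerobic-capacity gain ``(VO2max - VO2baseline) /
    VO2baseline``; F2 is maximum force output normalized by body weight,
    ``W_max / W_body``.
    """
    if vo2_baseline <= 0:
        raise DomainError(f"vo2_baseline must be > 0, got {vo2_baseline}")
    if w_body <= 0:
        raise DomainError(f"w_body must be > 0, got {w_body}")
    f1 = (vo2max - vo2_baseline) / vo2_baseline
    f2 = w_max / w_body
    return f1, f2


def literacy_score(
    X: np.ndarray,
    model: LiteracyModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray | float:
    """Latent physical-literacy score(s) L = W·X + eps.

    ``X`` may be a single observable vector of length k or an (m, k) matrix
    of m observations; ``W`` a (k,) vector (scalar L) or (q, k) matrix.
    Deterministic when ``model.noise_sd == 0``.
    """
    X = np.asarray(X, dtype=float)
    W = model.loadings_W
    k = W.shape[-1]
    if X.shape[-1] != k:
        raise ShapeError(
            f"observable dimension {X.shape[-1]} does not match loadings "
            f"dimension {k}")
    L = X @ W.T if W.ndim > 1 else X @ W
    if model.noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        L = L + gen.normal(0.0, model.noise_sd, size=np.shape(L) or None)
    return L


def participation_probability(
    E: Sequence[float], C: Sequence[float], model: ParticipationModel
) -> float:
    """Probability of participation, sigma(E'w_E + C'w_C), in (0, 1)."""
    E = np.asarray(E, dtype=float)
    C = np.asarray(C, dtype=float)
    if E.shape != model.w_E.shape:
        raise ShapeError(f"engagement factors shape {E.shape} != w_E shape "
                         f"{model.w_E.shape}")
    if C.shape != model.w_C.shape:
        raise ShapeError(f"condition factors shape {C.shape} != w_C shape "
                         f"{model.w_C.shape}")
    logit = float(E @ model.w_E + C @ model.w_C)
    # numerically stable logistic
    if logit >= 0:
        return 1.0 / (1.0 + np.exp(-logit))
    z = np.exp(logit)
    return z / (1.0 + z)


def generate_disturbances(
    T: int,
    scale: float,
    seed: int | None = None,
    ar: float = 0.0,
    dim: int = 1,
) -> np.ndarray:
    """Zero-mean external-disturbance series of shape (T, dim).

    ``ar=0`` gives i.i.d. Gaussian noise; ``0 < ar < 1`` gives an AR(1)
    process with the same stationary standard deviation ``scale`` —
    serially correlated disturbances emulate fatigue-like carry-over.
    """
    if T < 1:
        raise DomainError(f"T must be >= 1, got {T}")
    if scale < 0:
        raise DomainError(f"scale must be >= 0, got {scale}")
    if not 0.0 <= ar < 1.0:
        raise DomainError(f"ar must be in [0, 1), got {ar}")
    if scale == 0:
        return np.zeros((T, dim))
    rng = np.random.default_rng(seed)
    if ar == 0.0:
        return rng.normal(0.0, scale, size=(T, dim))
    innov_sd = scale * np.sqrt(1.0 - ar**2)
    out = np.empty((T, dim))
    out[0] = rng.normal(0.0, scale, size=dim)
    for t in range(1, T):
        out[t] = ar * out[t - 1] + rng.normal(0.0, innov_sd, size=dim)
    return out


_CSV_COLUMNS = [
    "id", "body_mass", "vo2_baseline", "time_constant_tau", "enjoyment",
    "perceived_effort", "skill_requirement", "rng_seed", "embedding_theta",
]


def profiles_to_csv(profiles: Sequence[ParticipantProfile], path) -> None:
    """Write one row per participant; embeddings are ';'-joined floats."""
    rows = []
    for p in profiles:
        row = {c: getattr(p, c) for c in _CSV_COLUMNS[:-1]}
        row["embedding_theta"] = ";".join(repr(float(v))
                                          for v in p.embedding_theta)
        rows.append(row)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def profiles_from_csv(path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"cohort CSV missing column(s): {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        theta = np.array([float(v) for v in str(row["embedding_theta"]).split(";")])
        out.append(ParticipantProfile(
            id=int(row["id"]),
            body_mass=float(row["body_mass"]),
            vo2_baseline=float(row["vo2_baseline"]),
            time_constant_tau=float(row["time_constant_tau"]),
            enjoyment=float(row["enjoyment"]),
            perceived_effort=float(row["perceived_effort"]),
            skill_requirement=float(row["skill_requirement"]),
            embedding_theta=theta,
            eeg_signature=None,
            rng_seed=int(row["rng_seed"]),
        ))
    return out
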