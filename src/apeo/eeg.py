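"""Synthetic EEG, band-power features, and the emotion rule engine.

The rule engine maps spectral features to one of five emotional states and
each state to a prescribed activity adjustment:

====================  =======================  ======================
feature change        emotional state          activity adjustment
====================  =======================  ======================
beta power up         stress / anxiety         relaxation activities
alpha power up        relaxed, low engagement  team-based sports
theta/alpha down      overload / fatigue       lower intensity, rest
theta power up        focus                    structured skill tasks
beta and alpha down   lack of interest         high-energy activities
====================  =======================  ======================

"Up"/"down" are judged relative to a per-participant resting baseline
recording using configurable multipliers.  The synthetic generator plants
band-limited oscillations whose relative amplitudes encode each state, so
the full synthesize → filter → band-power → classify loop can be tested
end to end without any recorded EEG.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from apeo.errors import DomainError, ShapeError

__all__ = [
    "EmotionalState",
    "ActivityAdjustment",
    "EEGTrace",
    "EEGFeatures",
    "Thresholds",
    "DEFAULT_BANDS",
    "STATE_SIGNATURES",
    "ADJUSTMENT_TABLE",
    "synthesize_eeg",
    "bandpass_filter",
    "band_powers",
    "classify_emotion",
    "recommend_adjustment",
    "rule_table_json",
    "trace_to_csv",
    "trace_from_csv",
]


class EmotionalState(enum.Enum):
    STRESS_ANXIETY = "stress_anxiety"
    RELAX_LOW_ENGAGEMENT = "relax_low_engagement"
    OVERLOAD_FATIGUE = "overload_fatigue"
    FOCUS = "focus"
    LACK_OF_INTEREST = "lack_of_interest"
    #: sentinel returned when no rule fires; treated as focus-neutral
    NONE = "none"


class ActivityAdjustment(enum.Enum):
    RELAXATION = "relaxation"
    TEAM_SPORTS = "team_sports"
    LOWER_INTENSITY_REST = "lower_intensity_rest"
    STRUCTURED_SKILL = "structured_skill"
    HIGH_ENERGY = "high_energy"


#: emotional state -> (activity adjustment, target outcome)
ADJUSTMENT_TABLE: dict[EmotionalState, tuple[ActivityAdjustment, str]] = {
    EmotionalState.STRESS_ANXIETY: (ActivityAdjustment.RELAXATION, "Stress reduction"),
    EmotionalState.RELAX_LOW_ENGAGEMENT: (ActivityAdjustment.TEAM_SPORTS, "Improved engagement"),
    EmotionalState.OVERLOAD_FATIGUE: (ActivityAdjustment.LOWER_INTENSITY_REST, "Prevent burnout"),
    EmotionalState.FOCUS: (ActivityAdjustment.STRUCTURED_SKILL, "Maintain engagement"),
    EmotionalState.LACK_OF_INTEREST: (ActivityAdjustment.HIGH_ENERGY, "Stimulate interest"),
}

#: conventional EEG frequency bands, Hz (half-open [low, high))
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: oscillator carrier frequency per band, Hz (bin-centered for 2 s windows)
_BAND_TONES = {"theta": 6.0, "alpha": 10.0, "beta": 20.0}

#: per-state band amplitudes relative to a unit resting baseline.  The
#: alpha-dominant state carries a mild theta elevation so its theta/alpha
#: ratio stays above the fatigue cutoff (relaxed wakefulness raises theta
#: as well as alpha); amplitudes are sqrt of the intended power ratios.
STATE_SIGNATURES: dict[EmotionalState, dict[str, float]] = {
    EmotionalState.NONE: {"theta": 1.0, "alpha": 1.0, "beta": 1.0},
    EmotionalState.STRESS_ANXIETY: {"theta": 1.0, "alpha": 1.0, "beta": 1.6},
    EmotionalState.RELAX_LOW_ENGAGEMENT: {
        "theta": math.sqrt(1.4), "alpha": math.sqrt(2.0), "beta": 1.0},
    EmotionalState.OVERLOAD_FATIGUE: {"theta": 0.6, "alpha": 1.0, "beta": 1.0},
    EmotionalState.FOCUS: {"theta": 1.6, "alpha": 1.0, "beta": 1.0},
    EmotionalState.LACK_OF_INTEREST: {"theta": 1.0, "alpha": 0.5, "beta": 0.5},
}

#: base oscillation amplitude of a unit-baseline band, µV
_BASE_AMPLITUDE = 10.0


@dataclass(frozen=True)
class EEGTrace:
    """Multi-channel EEG segment: ``samples`` is (time, channels) in µV."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(self.samples).ndim == 1:
            x = x.T
        object.__setattr__(self, "samples", x)
        if self.fs <= 0:
            raise DomainError(f"sampling rate must be > 0, got {self.fs}")
        if not np.all(np.isfinite(x)):
            raise DomainError("EEG samples must be finite")
        if x.shape[1] < 1:
            raise ShapeError("EEG trace needs at least one channel")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class EEGFeatures:
    """Band powers (µV²) and the theta/alpha ratio.

    ``ta_ratio`` is ``None`` when alpha power is zero — undefined, never
    silently coerced to 0.
    """

    beta_power: float
    alpha_power: float
    theta_power: float
    ta_ratio: float | None

    def __post_init__(self) -> None:
        for name in ("beta_power", "alpha_power", "theta_power"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Thresholds:
    """Multipliers deciding 'up'/'down' relative to baseline."""

    up: float = 1.5
    down: float = 0.67

    def __post_init__(self) -> None:
        if not (0 < self.down < 1 < self.up):
            raise DomainError("thresholds require 0 < down < 1 < up")


def synthesize_eeg(
    state: EmotionalState,
    duration: float = 8.0,
    fs: float = 256.0,
    snr: float = math.inf,
    seed: int | None = None,
    n_channels: int = 4,
    signature: Mapping[str, float] | None = None,
) -> EEGTrace:
    """Synthesize a trace whose band-power profile encodes ``state``.

    Each band carries a sinusoid at its carrier frequency with a random
    phase per channel; broadband Gaussian noise is added at the requested
    signal-to-noise power ratio (``snr=inf`` means noiseless).
    """
    if fs <= 100:
        raise DomainError(
            f"fs={fs} Hz would alias the beta band; need fs > 100")
    if snr < 0:
        raise DomainError(f"snr must be >= 0, got {snr}")
    n = int(round(duration * fs))
    if n < 2:
        raise DomainError("duration*fs must give at least 2 samples")
    sig = dict(signature) if signature is not None else STATE_SIGNATURES[state]
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.zeros((n, n_channels))
    total_power = 0.0
    for band, freq in _BAND_TONES.items():
        amp = _BASE_AMPLITUDE * sig.get(band, 1.0)
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        x += amp * np.sin(2 * np.pi * freq * t[:, None] + phases[None, :])
        total_power += amp**2 / 2.0
    if np.isfinite(snr) and snr > 0:
        noise_sd = math.sqrt(total_power / snr)
        x += rng.normal(0.0, noise_sd, size=x.shape)
    elif snr == 0:
        raise DomainError("snr must be positive (use inf for noiseless)")
    return EEGTrace(samples=x, fs=fs)


def bandpass_filter(trace: EEGTrace, low: float, high: float,
                    order: int = 4) -> EEGTrace:
    """Zero-phase Butterworth band-pass (forward-backward, so band power
    is not phase-distorted and stopband attenuation is doubled)."""
    nyq = trace.fs / 2.0
    if not (0 < low < high < nyq):
        raise DomainError(
            f"band edges must satisfy 0 < low < high < fs/2; got "
            f"low={low}, high={high}, fs/2={nyq}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trace.fs,
                     output="sos")
    y = sps.sosfiltfilt(sos, trace.samples, axis=0)
    return EEGTrace(samples=y, fs=trace.fs)


def band_powers(
    trace: EEGTrace,
    bands: Mapping[str, tuple[float, float]] | None = None,
) -> EEGFeatures:
    """Integrated Welch PSD per band, averaged over channels.

    Welch uses 2 s Hann windows with 50 % overlap; bands are half-open
    ``[low, high)`` so adjacent bands never double-count a bin.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else dict(bands)
    if not bands:
        raise DomainError("band set must not be empty")
    if trace.duration < 2.0:
        raise DomainError(
            f"trace must be at least 2 s for spectral estimation, got "
            f"{trace.duration:.3f} s")
    nyq = trace.fs / 2.0
    for name, (lo, hi) in bands.items():
        if not (0 < lo < hi < nyq):
            raise DomainError(f"band '{name}'=({lo}, {hi}) outside (0, {nyq})")
    nperseg = int(round(2.0 * trace.fs))
    freqs, psd = sps.welch(trace.samples, fs=trace.fs, nperseg=nperseg,
                           noverlap=nperseg // 2, axis=0)
    df = freqs[1] - freqs[0]
    powers = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        powers[name] = float(np.mean(psd[mask].sum(axis=0) * df))
    alpha = powers.get("alpha", 0.0)
    theta = powers.get("theta", 0.0)
    ta = theta / alpha if alpha > 0 else None
    return EEGFeatures(
        beta_power=powers.get("beta", 0.0),
        alpha_power=alpha,
        theta_power=theta,
        ta_ratio=ta,
    )


def classify_emotion(
    features: EEGFeatures,
    baseline: EEGFeatures,
    thresholds: Thresholds = Thresholds(),
) -> EmotionalState:
    """Classify the emotional state from baseline-relative band powers.

    Rules fire in a fixed precedence order, fatigue first because it is
    the safety-critical rule:

    1. theta/alpha ratio below ``down``×baseline -> OVERLOAD_FATIGUE
    2. beta power above ``up``×baseline          -> STRESS_ANXIETY
    3. theta power above ``up``×baseline         -> FOCUS
    4. alpha power above ``up``×baseline         -> RELAX_LOW_ENGAGEMENT
    5. beta and alpha both below ``down``        -> LACK_OF_INTEREST

    If no rule fires the neutral sentinel ``EmotionalState.NONE`` is
    returned with a warning.
    """
    for name in ("beta_power", "alpha_power", "theta_power"):
        if getattr(baseline, name) <= 0:
            raise DomainError(f"baseline {name} must be > 0")
    beta_rel = features.beta_power / baseline.beta_power
    alpha_rel = features.alpha_power / baseline.alpha_power
    theta_rel = features.theta_power / baseline.theta_power
    if features.ta_ratio is not None and baseline.ta_ratio:
        ta_rel = features.ta_ratio / baseline.ta_ratio
        if ta_rel < thresholds.down:
            return EmotionalState.OVERLOAD_FATIGUE
    if beta_rel > thresholds.up:
        return EmotionalState.STRESS_ANXIETY
    if theta_rel > thresholds.up:
        return EmotionalState.FOCUS
    if alpha_rel > thresholds.up:
        return EmotionalState.RELAX_LOW_ENGAGEMENT
    if beta_rel < thresholds.down and alpha_rel < thresholds.down:
        return EmotionalState.LACK_OF_INTEREST
    warnings.warn("no emotion rule fired; returning neutral sentinel",
                  stacklevel=2)
    return EmotionalState.NONE


def recommend_adjustment(
    state: EmotionalState,
) -> tuple[ActivityAdjustment, str] | None:
    """Activity adjustment and target outcome for a state; ``None`` for the
    neutral sentinel (no recommendation, not an error)."""
    if state is EmotionalState.NONE:
        return None
    return ADJUSTMENT_TABLE[state]


def rule_table_json() -> str:
    """The classification/adjustment rule table as JSON, for audit."""
    rows = []
    feature_of = {
        EmotionalState.STRESS_ANXIETY: "beta up",
        EmotionalState.RELAX_LOW_ENGAGEMENT: "alpha up",
        EmotionalState.OVERLOAD_FATIGUE: "theta/alpha ratio down",
        EmotionalState.FOCUS: "theta up",
        EmotionalState.LACK_OF_INTEREST: "beta and alpha down",
    }
    for state, (adj, outcome) in ADJUSTMENT_TABLE.items():
        rows.append({
            "eeg_feature": feature_of[state],
            "emotional_state": state.value,
            "activity_adjustment": adj.value,
            "target_outcome": outcome,
        })
    return json.dumps(rows, indent=2)


def trace_to_csv(trace: EEGTrace, path) -> None:
    """CSV with one column per channel; first line records fs as a comment."""
    cols = [f"ch{j}" for j in range(trace.n_channels)]
    with open(path, "w") as fh:
        fh.write(f"# fs={trace.fs}\n")
        pd.DataFrame(trace.samples, columns=cols).to_csv(fh, index=False)


def trace_from_csv(path, fs: float | None = None) -> EEGTrace:
    """Read a trace written by :func:`trace_to_csv`; ``fs`` overrides the
    sidecar comment when given."""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# fs="):
            file_fs = float(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            file_fs = None
            df = pd.read_csv(fh)
    rate = fs if fs is not None else file_fs
    if rate is None:
        raise DomainError("sampling rate not in file; pass fs explicitly")
    return EEGTrace(samples=df.to_numpy(dtype=float), fs=rate)
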