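"""Simulated observers with known temporal templates.

Real observers tested with the same stimulus class share the *power*
spectrum of their temporal sensitivity profile while its *phase* spectrum is
idiosyncratic.  The generator instantiates that structure directly: each
class owns a prototype power profile over the basis frequencies, and each
observer's latent template is synthesized from that shared power with
observer-specific phases.  Responses follow a logistic rule on the inner
product between the template and the trial's (centered) sampling features,
with the intercept calibrated so mean accuracy sits at the staircase's ~50%
operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .sampling import BasisSpec, draw_sampling_batch
from .wavelets import morlet_tf_batch

__all__ = [
    "ObserverModel",
    "ExperimentLog",
    "simulate_dataset",
    "make_class_library",
    "default_class_power",
]

DEFAULT_GAIN = 6.0
DEFAULT_PHASE_JITTER = 2.0 * np.pi
DEFAULT_OBSERVERS_PER_CLASS = 12
DEFAULT_N_TRIALS = 1200
DEFAULT_CLASS_NAMES = ("words", "familiar_objects", "novel_objects", "faces")


@dataclass(frozen=True)
class ObserverModel:
    """Latent temporal template plus logistic response rule."""

    template: np.ndarray  # (n_frames,) for 'time', (n_freq, n_frames) for 'tf'
    domain: str = "time"
    gain: float = DEFAULT_GAIN
    intercept: float | None = None  # None -> calibrated at simulation time
    phase_jitter: float = 0.0
    participant_id: str = "sim"
    stimulus_class: str = "synthetic"

    def __post_init__(self) -> None:
        t = np.asarray(self.template, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("template must be finite")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.domain not in ("time", "tf"):
            raise ValueError("domain must be 'time' or 'tf'")
        object.__setattr__(self, "template", t)


@dataclass(frozen=True)
class ExperimentLog:
    """Per-participant trial table: sampling functions, accuracy, staircase."""

    participant_id: str
    stimulus_class: str
    values: np.ndarray  # (n_trials, n_frames) SNR series
    amplitudes: np.ndarray  # (n_trials, n_freq)
    phases: np.ndarray  # (n_trials, n_freq)
    accuracy: np.ndarray  # (n_trials,) in {0, 1}
    noise_level: np.ndarray  # (n_trials,) staircase level per trial
    spec: BasisSpec = field(default_factory=BasisSpec)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        acc = np.asarray(self.accuracy)
        if values.ndim != 2 or len(values) < 1:
            raise ValueError("log needs at least one trial")
        if values.shape[1] != self.spec.n_frames:
            raise ValueError("values width does not match spec.n_frames")
        if not np.isin(acc, (0, 1)).all():
            raise ValueError("accuracies must be binary")
        if len(acc) != len(values) or len(self.noise_level) != len(values):
            raise ValueError("per-trial arrays must share their length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "accuracy", acc.astype(np.int8))
        object.__setattr__(
            self, "noise_level", np.asarray(self.noise_level, dtype=int)
        )

    @property
    def n_trials(self) -> int:
        return len(self.values)


def _observer_features(
    values: np.ndarray, domain: str, spec: BasisSpec
) -> np.ndarray:
    if domain == "time":
        return values - values.mean(axis=1, keepdims=True)
    maps = morlet_tf_batch(values, spec)
    return maps.reshape(len(maps), -1)


def calibrate_intercept(
    scores: np.ndarray, gain: float, target: float
) -> float:
    """Intercept b solving mean(expit(b + gain * score)) = target."""
    if not (0.0 < target < 1.0):
        raise ValueError(
            f"target accuracy {target} unreachable; feasible range is (0, 1)"
        )
    g = lambda b: float(np.mean(expit(b + gain * scores))) - target
    return float(brentq(g, -50.0, 50.0, xtol=1e-10))


def simulate_dataset(
    model: ObserverModel,
    n_trials: int = DEFAULT_N_TRIALS,
    spec: BasisSpec | None = None,
    rng: np.random.Generator | None = None,
    calibrate_to: float = 0.5,
    noise_level: int = 64,
) -> ExperimentLog:
    """Simulate one observer's session at a fixed noise level.

    Per trial, a fresh sampling function is drawn; the probability of a
    correct response is logistic(intercept + gain * <template, features>),
    and accuracy is a Bernoulli draw.  When ``model.intercept`` is None it is
    calibrated on the session's own trials so mean accuracy ~= calibrate_to.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    spec = spec or BasisSpec()
    rng = rng if rng is not None else np.random.default_rng()
    values, amps, phases = draw_sampling_batch(n_trials, spec, rng)
    feats = _observer_features(values, model.domain, spec)
    scores = feats @ model.template.ravel()
    b = (
        calibrate_intercept(scores, model.gain, calibrate_to)
        if model.intercept is None
        else model.intercept
    )
    p = expit(b + model.gain * scores)
    acc = (rng.random(n_trials) < p).astype(np.int8)
    return ExperimentLog(
        participant_id=model.participant_id,
        stimulus_class=model.stimulus_class,
        values=values,
        amplitudes=amps,
        phases=phases,
        accuracy=acc,
        noise_level=np.full(n_trials, noise_level, dtype=int),
        spec=spec,
    )


def default_class_power(
    n_classes: int, spec: BasisSpec | None = None
) -> np.ndarray:
    """Distinct prototype power profiles: Gaussian bumps over the basis
    frequencies with class-specific centers spanning 5-55 Hz."""
    spec = spec or BasisSpec()
    f = np.asarray(spec.frequencies)
    centers = np.linspace(f[0] + 5.0, f[-1] - 5.0, n_classes)
    prof = np.exp(-0.5 * ((f[None, :] - centers[:, None]) / 6.0) ** 2)
    return prof + 0.02


def make_class_library(
    n_classes: int = 4,
    observers_per_class: int = DEFAULT_OBSERVERS_PER_CLASS,
    prototype_power: np.ndarray | None = None,
    phase_jitter: float = DEFAULT_PHASE_JITTER,
    rng: np.random.Generator | None = None,
    gain: float = DEFAULT_GAIN,
    spec: BasisSpec | None = None,
    class_names: tuple[str, ...] | None = None,
) -> list[ObserverModel]:
    """Build simulated observers sharing class power spectra.

    Each class draws one set of base phases; each observer adds Gaussian
    phase jitter (SD ``phase_jitter`` radians) before the template is
    synthesized as sum_k sqrt(power_k) sin(2 pi f_k t + phi_k) over the frame
    midpoints and normalized to unit Euclidean norm.
    """
    if n_classes < 2 or observers_per_class < 2:
        raise ValueError("need >= 2 classes and >= 2 observers per class")
    spec = spec or BasisSpec()
    rng = rng if rng is not None else np.random.default_rng()
    power = (
        default_class_power(n_classes, spec)
        if prototype_power is None
        else np.asarray(prototype_power, dtype=float)
    )
    if power.shape != (n_classes, len(spec.frequencies)):
        raise ValueError("prototype_power must be (n_classes, n_frequencies)")
    if len(np.unique(power.round(12), axis=0)) < n_classes:
        warnings.warn(
            "identical prototype power profiles across classes: class decoding "
            "will be at chance",
            stacklevel=2,
        )
    names = class_names or tuple(
        DEFAULT_CLASS_NAMES[i] if i < len(DEFAULT_CLASS_NAMES) else f"class_{i}"
        for i in range(n_classes)
    )
    t = spec.frame_times
    f = np.asarray(spec.frequencies)
    library = []
    for c in range(n_classes):
        base_phase = rng.uniform(0.0, 2.0 * np.pi, size=len(f))
        for o in range(observers_per_class):
            phi = base_phase + rng.normal(0.0, phase_jitter, size=len(f))
            tmpl = (np.sqrt(power[c]) * np.sin(2 * np.pi * np.outer(t, f) + phi)).sum(
                axis=1
            )
            tmpl = tmpl / np.linalg.norm(tmpl)
            library.append(
                ObserverModel(
                    template=tmpl,
                    domain="time",
                    gain=gain,
                    phase_jitter=phase_jitter,
                    participant_id=f"{names[c]}_{o + 1:02d}",
                    stimulus_class=names[c],
                )
            )
    return library
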