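"""Stimulus composition and the adaptive noise-contrast staircase.

Each displayed frame is a weighted sum of a *signal* component (the target
image blended with a contrast-scaled binary white-noise mask) and a *noise*
component (an independent maximal-contrast binary white-noise field).  The
per-frame signal weight is the trial's sampling-function value, so target
visibility oscillates over the 200 ms exposure.  A 1-up/1-down staircase on
the mask contrast (128 levels, step 16 halving on reversals to a floor of 1)
holds accuracy near 50% correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .sampling import SamplingFunction

__all__ = [
    "FrameSequence",
    "StaircaseState",
    "compose_frames",
    "staircase_update",
    "simulate_staircase_session",
    "N_NOISE_LEVELS",
]

N_NOISE_LEVELS = 128
START_LEVEL = 64  # midpoint of the 1..128 range under 1-based integer levels
INITIAL_STEP = 16
_ALLOWED_STEPS = (16, 8, 4, 2, 1)


@dataclass(frozen=True)
class FrameSequence:
    """Grayscale stimulus frames plus the sampling function that weighted them.

    Intensities are nominally in [0, 1]; per-frame luminance/contrast
    equalization can push single pixels marginally out of gamut, which is
    tolerated here and clipped only on export.
    """

    frames: np.ndarray  # (n_frames, h, w)
    sampling: SamplingFunction
    noise_level: int

    def frame_means(self) -> np.ndarray:
        return self.frames.mean(axis=(1, 2))

    def frame_rms(self) -> np.ndarray:
        return self.frames.std(axis=(1, 2))

    def to_uint8(self) -> np.ndarray:
        """Clipped 8-bit frames, ready for any standard image writer."""
        return (np.clip(self.frames, 0.0, 1.0) * 255).round().astype(np.uint8)


@dataclass(frozen=True)
class StaircaseState:
    """Current white-noise contrast level and step of the adaptive procedure."""

    level: int = START_LEVEL
    step: int = INITIAL_STEP
    last_direction: str = "none"  # {'up', 'down', 'none'}
    history: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (1 <= self.level <= N_NOISE_LEVELS):
            raise ValueError(f"level must lie in 1..{N_NOISE_LEVELS}")
        if self.step not in _ALLOWED_STEPS:
            raise ValueError(f"step must be one of {_ALLOWED_STEPS}")
        if self.last_direction not in ("up", "down", "none"):
            raise ValueError("last_direction must be 'up', 'down' or 'none'")


def mask_contrast(noise_level: int) -> float:
    """Contrast of the signal's noise mask: level 1 is a null (zero-contrast)
    mask, level 128 is full black/white."""
    if not (1 <= int(noise_level) <= N_NOISE_LEVELS):
        raise ValueError(f"noise_level must lie in 1..{N_NOISE_LEVELS}")
    return (int(noise_level) - 1) / (N_NOISE_LEVELS - 1)


def compose_frames(
    target: np.ndarray,
    noise_level: int,
    sf: SamplingFunction,
    rng: np.random.Generator | None = None,
) -> FrameSequence:
    """Compose the frame sequence for one trial.

    Frame k is ``w_k * signal + (1 - w_k) * noise`` with ``w_k`` the
    sampling-function value.  The signal is the target blended with a fresh
    binary white-noise mask at the staircase's contrast level (a zero-contrast
    mask leaves the target untouched); the noise is an independent
    maximal-contrast binary field.  Frames are then equalized to the first
    frame's mean luminance and RMS contrast.
    """
    rng = rng if rng is not None else np.random.default_rng()
    target = np.asarray(target, dtype=float)
    if target.ndim != 2:
        raise ValueError("target must be a 2-D grayscale image")
    if target.min() < 0.0 or target.max() > 1.0:
        raise ValueError("target intensities must lie in [0, 1]")
    c = mask_contrast(noise_level)
    mask = rng.integers(0, 2, size=target.shape).astype(float)
    noise = rng.integers(0, 2, size=target.shape).astype(float)
    signal = (1.0 - c) * target + c * mask
    w = sf.values[:, None, None]
    frames = w * signal[None] + (1.0 - w) * noise[None]
    # per-frame luminance / RMS-contrast matching to the first frame
    m = frames.mean(axis=(1, 2), keepdims=True)
    s = frames.std(axis=(1, 2), keepdims=True)
    if np.any(s <= 0):
        raise ValueError("degenerate frame with zero contrast")
    frames = (frames - m) * (s[0] / s) + m[0]
    return FrameSequence(frames=frames, sampling=sf, noise_level=int(noise_level))


def staircase_update(
    state: StaircaseState,
    trial_index: int,
    window: Sequence[int] | None,
) -> StaircaseState:
    """State for trial ``trial_index`` given the last ten accuracies.

    Trials 1-10 hold the level at the starting midpoint.  From trial 11 on,
    accuracy above 50% over the sliding ten-trial window raises the noise
    level by the current step, below 50% lowers it, exactly 50% leaves it.
    The step halves on each reversal of adjustment direction (floor 1) and
    the level is clamped to 1..128.  State persists across blocks.
    """
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    if trial_index <= 10:
        return state
    if window is None or len(window) == 0:
        raise ValueError("an accuracy window is required from trial 11 onward")
    acc = float(np.mean(window))
    if acc == 0.5:
        return state
    direction = "up" if acc > 0.5 else "down"
    step = state.step
    if state.last_direction not in ("none", direction):
        step = max(step // 2, 1)
    delta = step if direction == "up" else -step
    level = int(np.clip(state.level + delta, 1, N_NOISE_LEVELS))
    return replace(state, level=level, step=step, last_direction=direction)


def simulate_staircase_session(
    p_correct: Callable[[int], float],
    n_trials: int = 1200,
    rng: np.random.Generator | None = None,
    state: StaircaseState | None = None,
    trial_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray, StaircaseState]:
    """Run a staircase-driven session against a psychometric function.

    ``p_correct(level)`` maps a noise-contrast level to the probability of a
    correct response.  ``state``/``trial_offset`` let consecutive blocks
    continue a single staircase: the returned state carries the last ten
    accuracies so the sliding window spans block boundaries.  Returns
    (levels, accuracies, final_state).
    """
    rng = rng if rng is not None else np.random.default_rng()
    state = state or StaircaseState()
    recent = list(state.history)
    levels = np.empty(n_trials, dtype=int)
    acc = np.empty(n_trials, dtype=np.int8)
    for i in range(n_trials):
        t = trial_offset + i + 1
        if t > 10:
            state = staircase_update(state, t, recent[-10:])
        levels[i] = state.level
        acc[i] = rng.random() < p_correct(state.level)
        recent.append(int(acc[i]))
    state = replace(state, history=tuple(recent[-10:]))
    return levels, acc, state


def default_psychometric(level: int | np.ndarray) -> float | np.ndarray:
    """Reference simulated observer: accuracy strictly decreasing in noise
    contrast, spanning the 128 levels with the 50% point at level 80."""
    level = np.asarray(level, dtype=float)
    p = 0.02 + 0.96 / (1.0 + np.exp((level - 80.0) / 12.0))
    return float(p) if p.ndim == 0 else p
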