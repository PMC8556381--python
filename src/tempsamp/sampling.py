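"""Random temporal sampling functions.

A sampling function is the per-trial time course of signal-to-noise ratio
(SNR) across the frames of a briefly shown visual target.  It is built by
summing sine waves at a fixed set of temporal frequencies (by default 5-55 Hz
in 5 Hz steps) with random amplitudes and phases, range-normalizing the
result to [0, 0.5], and keeping only draws whose frame sum matches a common
target, so that every trial delivers the same total amount of signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BasisSpec",
    "SamplingFunction",
    "SpectralDescriptor",
    "make_sampling_function",
    "draw_sampling_batch",
    "fourier_descriptors",
    "range_normalize",
    "synthesize",
    "wrap_phase",
]

#: target frame sum of a normalized sampling function (the empirical mean of
#: frame sums of unconstrained range-normalized draws is n_frames * 0.25)
DEFAULT_SUM_TARGET = 6.0
#: half-width of the accepted band around the target sum
DEFAULT_SUM_TOL = 0.05
#: candidate redraws allowed per requested function before giving up
REDRAW_BUDGET = 10_000


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class BasisSpec:
    """Frequency basis and display timing of the sampling functions.

    Parameters
    ----------
    frequencies:
        Strictly increasing temporal frequencies in Hz, all positive and
        below the Nyquist limit of the refresh rate.
    duration:
        Stimulus duration in seconds.
    refresh_rate:
        Display refresh rate in Hz; one SNR value is shown per frame.
    """

    frequencies: tuple[float, ...] = tuple(float(f) for f in range(5, 60, 5))
    duration: float = 0.200
    refresh_rate: float = 120.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D sequence")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing and positive")
        if self.refresh_rate <= 0 or self.duration <= 0:
            raise ValueError("duration and refresh_rate must be positive")
        if f[-1] >= self.nyquist:
            raise ValueError(
                f"all frequencies must lie below the Nyquist limit "
                f"({self.nyquist:g} Hz)"
            )
        if self.n_frames < 2:
            raise ValueError("duration x refresh_rate must give at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.refresh_rate))

    @property
    def nyquist(self) -> float:
        return self.refresh_rate / 2.0

    @property
    def frame_times(self) -> np.ndarray:
        """Frame midpoints in seconds: a frame is displayed over a whole
        refresh interval, so its midpoint is the unbiased representative."""
        return (np.arange(self.n_frames) + 0.5) / self.refresh_rate

    def basis_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sin, cos) matrices of shape (n_frequencies, n_frames)."""
        arg = 2.0 * np.pi * np.outer(self.frequencies, self.frame_times)
        return np.sin(arg), np.cos(arg)


@dataclass(frozen=True)
class SamplingFunction:
    """One trial's SNR time course plus the spectral parameters that built it.

    ``values`` is the range-normalized series in [0, 0.5]; ``amplitudes`` and
    ``phases`` regenerate the pre-normalization waveform exactly through
    :func:`synthesize`.
    """

    values: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    spec: BasisSpec = dataclasses.field(default_factory=BasisSpec)
    trial_id: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))
        if self.values.shape != (self.spec.n_frames,):
            raise ValueError("values length does not match spec.n_frames")
        if self.amplitudes.shape != (len(self.spec.frequencies),) or (
            self.phases.shape != self.amplitudes.shape
        ):
            raise ValueError("amplitudes/phases must have one entry per frequency")


@dataclass(frozen=True)
class SpectralDescriptor:
    """Per-basis-frequency amplitude (>= 0) and phase in (-pi, pi]."""

    amplitudes: np.ndarray
    phases: np.ndarray
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        if a.shape != (len(self.frequencies),) or p.shape != a.shape:
            raise ValueError("descriptor length must equal the number of frequencies")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "phases", wrap_phase(p))


def synthesize(
    amplitudes: np.ndarray, phases: np.ndarray, spec: BasisSpec | None = None
) -> np.ndarray:
    """Raw (pre-normalization) waveform sum_k a_k sin(2 pi f_k t + phi_k)."""
    spec = spec or BasisSpec()
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    sin_m, cos_m = spec.basis_matrices()
    out = (amplitudes * np.cos(phases)) @ sin_m + (amplitudes * np.sin(phases)) @ cos_m
    return out[0] if out.shape[0] == 1 else out


def range_normalize(x: np.ndarray, lo: float = 0.0, hi: float = 0.5) -> np.ndarray:
    """Affinely map a series onto [lo, hi]; idempotent; degenerate input raises."""
    x = np.asarray(x, dtype=float)
    span = x.max(axis=-1, keepdims=True) - x.min(axis=-1, keepdims=True)
    if np.any(span <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("cannot range-normalize a flat or non-finite series")
    return lo + (hi - lo) * (x - x.min(axis=-1, keepdims=True)) / span


class _BatchBuffers:
    """Reusable scratch for the float32 candidate screen (allocation-free)."""

    def __init__(self, chunk: int, n_freq: int, n_frames: int) -> None:
        self.chunk = chunk
        self.u = np.empty((chunk, 2 * n_freq), dtype=np.float32)
        self.ac = np.empty((chunk, 2 * n_freq), dtype=np.float32)
        self.phase = np.empty((chunk, n_freq), dtype=np.float32)
        self.x = np.empty((chunk, n_frames), dtype=np.float32)


def draw_sampling_batch(
    n: int,
    spec: BasisSpec | None = None,
    rng: np.random.Generator | None = None,
    sum_target: float = DEFAULT_SUM_TARGET,
    sum_tol: float = DEFAULT_SUM_TOL,
    redraw_budget: int = REDRAW_BUDGET,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` accepted sampling functions.

    Amplitudes are i.i.d. uniform(0, 1) and phases i.i.d. uniform(0, 2 pi)
    per basis frequency.  Each candidate waveform is range-normalized to
    [0, 0.5] and accepted when its frame sum lies within ``sum_tol`` of
    ``sum_target`` (rejection sampling).  Candidates are screened in float32
    for speed; accepted rows are recomputed in float64 and re-checked against
    the exact acceptance rule, so the returned draws follow the float64 rule.

    Returns ``(values, amplitudes, phases)`` with shapes
    ``(n, n_frames)``, ``(n, n_freq)``, ``(n, n_freq)``.
    """
    spec = spec or BasisSpec()
    rng = rng if rng is not None else np.random.default_rng()
    n_freq = len(spec.frequencies)
    n_frames = spec.n_frames
    sin_m, cos_m = spec.basis_matrices()
    basis32 = np.vstack([sin_m, cos_m]).astype(np.float32)
    basis64 = np.vstack([sin_m, cos_m])
    two_pi = np.float32(2.0 * np.pi)
    # float32 round-off on the 24-term sum is ~1e-5; widen the screen so no
    # float64-acceptable candidate is lost, then re-check exactly.
    screen_tol = sum_tol + 1e-3

    chunk = max(4096, min(1 << 21, 32 * n))
    buf = _BatchBuffers(chunk, n_freq, n_frames)
    out_v = np.empty((n, n_frames))
    out_a = np.empty((n, n_freq))
    out_p = np.empty((n, n_freq))
    got = 0
    candidates = 0
    budget = redraw_budget * max(n, 1)
    while got < n:
        if candidates >= budget:
            raise RuntimeError(
                f"sampling-function redraw budget exhausted "
                f"({candidates} candidates for {got}/{n} accepted)"
            )
        rng.random(out=buf.u, dtype=np.float32)
        amp = buf.u[:, :n_freq]
        np.multiply(buf.u[:, n_freq:], two_pi, out=buf.phase)
        np.cos(buf.phase, out=buf.ac[:, :n_freq])
        np.sin(buf.phase, out=buf.ac[:, n_freq:])
        buf.ac[:, :n_freq] *= amp
        buf.ac[:, n_freq:] *= amp
        np.matmul(buf.ac, basis32, out=buf.x)
        lo = buf.x.min(axis=1)
        hi = buf.x.max(axis=1)
        span = hi - lo
        ok = span > 0
        # frame sum of the normalized series, straight from raw statistics
        s = np.where(ok, 0.5 * (buf.x.sum(axis=1) - n_frames * lo) / np.where(ok, span, 1.0), np.inf)
        keep = np.flatnonzero(ok & (np.abs(s - sum_target) <= screen_tol))
        candidates += chunk
        if keep.size == 0:
            continue
        a64 = amp[keep].astype(np.float64)
        p64 = buf.phase[keep].astype(np.float64)
        x64 = np.hstack([a64 * np.cos(p64), a64 * np.sin(p64)]) @ basis64
        lo64 = x64.min(axis=1, keepdims=True)
        span64 = x64.max(axis=1, keepdims=True) - lo64
        good = span64[:, 0] > 0
        v64 = 0.5 * (x64 - lo64) / np.where(span64 > 0, span64, 1.0)
        exact = good & (np.abs(v64.sum(axis=1) - sum_target) <= sum_tol)
        idx = np.flatnonzero(exact)[: n - got]
        m = idx.size
        out_v[got : got + m] = v64[idx]
        out_a[got : got + m] = a64[idx]
        out_p[got : got + m] = p64[idx]
        got += m
    return out_v, out_a, out_p


def make_sampling_function(
    spec: BasisSpec | None = None,
    rng: np.random.Generator | None = None,
    sum_target: float = DEFAULT_SUM_TARGET,
    sum_tol: float = DEFAULT_SUM_TOL,
    trial_id: int | None = None,
) -> SamplingFunction:
    """Draw one accepted sampling function (see :func:`draw_sampling_batch`)."""
    spec = spec or BasisSpec()
    v, a, p = draw_sampling_batch(1, spec, rng, sum_target, sum_tol)
    return SamplingFunction(v[0], a[0], p[0], spec=spec, trial_id=trial_id)


def fourier_descriptors(
    sf: SamplingFunction | np.ndarray,
    spec: BasisSpec | None = None,
    from_series: bool = False,
) -> SpectralDescriptor:
    """Amplitude and phase at each basis frequency.

    Given a :class:`SamplingFunction` (and ``from_series=False``) the stored
    synthesis parameters are returned directly.  Given a raw series (or
    ``from_series=True``) the discrete transform is evaluated at the basis
    frequencies using the frame midpoint times, with the convention
    ``x(t) = a sin(2 pi f t + phi)`` so that descriptors of a synthesized
    waveform round-trip exactly.
    """
    if isinstance(sf, SamplingFunction) and not from_series:
        return SpectralDescriptor(
            np.abs(sf.amplitudes), wrap_phase(sf.phases), sf.spec.frequencies
        )
    if isinstance(sf, SamplingFunction):
        series = sf.values
        spec = sf.spec
    else:
        series = np.asarray(sf, dtype=float)
        spec = spec or BasisSpec()
    if series.shape != (spec.n_frames,):
        raise ValueError(
            f"series length {series.shape} does not match spec.n_frames={spec.n_frames}"
        )
    f = np.asarray(spec.frequencies)
    proj = series @ np.exp(-2j * np.pi * np.outer(spec.frame_times, f))
    amplitudes = 2.0 * np.abs(proj) / spec.n_frames
    phases = wrap_phase(np.angle(proj) + np.pi / 2.0)
    # phase of a vanishing component is meaningless; pin it to zero
    phases = np.where(amplitudes < 1e-12, 0.0, phases)
    return SpectralDescriptor(amplitudes, phases, spec.frequencies)
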