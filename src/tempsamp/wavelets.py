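"""Complex Morlet time-frequency re-coding of sampling functions.

Each series is convolved with unit-energy complex Morlet kernels (three
cycles by default) centered on the basis frequencies; the modulus of the
convolution gives the instantaneous amplitude of SNR oscillation at each
frequency and frame.  A three-cycle kernel trades frequency precision for
temporal precision, so a pure-frequency input also responds at neighboring
frequency rows (spectral smearing is expected, not a defect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .sampling import BasisSpec

__all__ = ["TimeFrequencyMap", "morlet_kernel", "morlet_tf", "morlet_tf_batch"]


@dataclass(frozen=True)
class TimeFrequencyMap:
    """Non-negative amplitude (or power) on a frequency x frame grid."""

    values: np.ndarray
    frequencies: tuple[float, ...]
    times: np.ndarray
    n_cycles: float = 3.0
    output: str = "amplitude"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.frequencies), len(self.times)):
            raise ValueError("values must be (n_frequencies, n_frames)")
        if np.any(v < 0):
            raise ValueError("time-frequency magnitudes must be non-negative")
        object.__setattr__(self, "values", v)


def morlet_kernel(
    freq: float,
    refresh_rate: float,
    n_cycles: float = 3.0,
    truncate: float = 4.0,
) -> np.ndarray:
    """Unit-energy complex Morlet kernel sampled at the refresh rate.

    The Gaussian envelope has sigma_t = n_cycles / (2 pi f); the kernel is
    truncated at ``truncate`` sigma on each side (odd length, centered).
    """
    if freq <= 0 or n_cycles < 1:
        raise ValueError("freq must be positive and n_cycles >= 1")
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(truncate * sigma_t * refresh_rate))
    t = np.arange(-half, half + 1) / refresh_rate
    kern = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    return kern / np.sqrt(np.sum(np.abs(kern) ** 2))


def _kernel_stack(spec: BasisSpec, n_cycles: float) -> np.ndarray:
    kernels = [morlet_kernel(f, spec.refresh_rate, n_cycles) for f in spec.frequencies]
    width = max(k.size for k in kernels)
    stack = np.zeros((len(kernels), width), dtype=complex)
    for i, k in enumerate(kernels):
        pad = (width - k.size) // 2  # symmetric: keeps the kernel centered
        stack[i, pad : pad + k.size] = k
    return stack


def morlet_tf_batch(
    series: np.ndarray,
    spec: BasisSpec | None = None,
    n_cycles: float = 3.0,
    output: str = "amplitude",
) -> np.ndarray:
    """Time-frequency maps for many series at once.

    ``series`` has shape (n_series, n_frames); the result has shape
    (n_series, n_frequencies, n_frames).  The convolution implicitly
    zero-extends each series beyond its 200 ms window (no frame is cropped).
    """
    spec = spec or BasisSpec()
    x = np.atleast_2d(np.asarray(series, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if x.shape[1] != spec.n_frames:
        raise ValueError(f"series length {x.shape[1]} != n_frames {spec.n_frames}")
    if output not in ("amplitude", "power"):
        raise ValueError("output must be 'amplitude' or 'power'")
    kern = _kernel_stack(spec, n_cycles)
    tiled = np.repeat(x[:, None, :], kern.shape[0], axis=1)
    resp = fftconvolve(tiled, kern[None, :, :], mode="same", axes=2)
    mag = np.abs(resp)
    return mag**2 if output == "power" else mag


def morlet_tf(
    series: np.ndarray,
    spec: BasisSpec | None = None,
    n_cycles: float = 3.0,
    output: str = "amplitude",
) -> TimeFrequencyMap:
    """Time-frequency map of one series (see :func:`morlet_tf_batch`)."""
    spec = spec or BasisSpec()
    vals = morlet_tf_batch(np.asarray(series, dtype=float)[None, :], spec, n_cycles, output)
    return TimeFrequencyMap(
        vals[0], spec.frequencies, spec.frame_times, n_cycles=n_cycles, output=output
    )
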