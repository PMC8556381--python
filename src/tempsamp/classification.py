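"""Classification images in the time, Fourier and time-frequency domains.

A raw classification image is the difference between the mean temporal
features of the sampling functions on correct trials and on error trials
(weights 1/n_correct and 1/n_error - the only weighting whose null
expectation is zero under unequal counts).  It is converted to Z scores
against a bootstrap null in which sampling functions are resampled with
replacement and paired with the observed accuracy-label multiset.  Z images
from several observers are averaged, smoothed with a Gaussian kernel, and
thresholded by the two-way Pixel test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .observers import ExperimentLog
from .pixel import FieldGeometry, pixel_threshold
from .sampling import BasisSpec, wrap_phase
from .wavelets import morlet_tf_batch

__all__ = [
    "ClassificationImage",
    "GroupResult",
    "trial_features",
    "raw_classification_image",
    "bootstrap_z",
    "smooth_field",
    "group_pipeline",
    "contrast_classification_image",
    "DEFAULT_FWHM",
]

DOMAINS = ("time", "fourier", "tf")
#: Gaussian smoothing FWHM, in grid bins, used at the group stage
DEFAULT_FWHM = {"time": 0.6, "fourier": 0.6, "tf": 1.5}
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class ClassificationImage:
    """Raw or Z-scored efficiency map in one coding domain.

    Shapes: (n_frames,) for ``time``; (2 * n_freq,) for ``fourier``
    (amplitude block then phase block); (n_freq, n_frames) for ``tf``.
    """

    domain: str
    values: np.ndarray
    scale: str = "raw"  # {'raw', 'z'}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}")
        if self.scale not in ("raw", "z"):
            raise ValueError("scale must be 'raw' or 'z'")
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("classification image must be finite")
        if self.scale == "z" and "n_boot" not in self.meta:
            raise ValueError("z-scaled images must carry bootstrap metadata")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class GroupResult:
    """Smoothed group Z image with its Pixel-test critical value and mask.

    ``mask`` is +1 where values > z_crit, -1 where values < -z_crit, else 0.
    """

    domain: str
    values: np.ndarray
    z_crit: float
    mask: np.ndarray
    alpha: float
    fwhm: float
    n_images: int
    meta: dict = field(default_factory=dict)

    def n_significant(self) -> tuple[int, int]:
        return int(np.sum(self.mask > 0)), int(np.sum(self.mask < 0))


def _domain_shape(domain: str, spec: BasisSpec) -> tuple[int, ...]:
    n_freq = len(spec.frequencies)
    return {
        "time": (spec.n_frames,),
        "fourier": (2 * n_freq,),
        "tf": (n_freq, spec.n_frames),
    }[domain]


def trial_features(log: ExperimentLog, domain: str, n_cycles: float = 3.0) -> np.ndarray:
    """Per-trial feature matrix (n_trials, n_features) for one coding domain.

    time: the SNR series itself; fourier: amplitudes then wrapped phases of
    the basis sinusoids; tf: the flattened Morlet amplitude map.
    """
    if domain == "time":
        return np.array(log.values, dtype=float)
    if domain == "fourier":
        return np.hstack([log.amplitudes, wrap_phase(log.phases)])
    if domain == "tf":
        maps = morlet_tf_batch(log.values, log.spec, n_cycles=n_cycles)
        return maps.reshape(len(maps), -1)
    raise ValueError(f"domain must be one of {DOMAINS}")


def _split_counts(log: ExperimentLog) -> tuple[np.ndarray, int, int]:
    acc = np.asarray(log.accuracy, dtype=int)
    n_c = int(acc.sum())
    n_e = int(len(acc) - n_c)
    if n_c == 0 or n_e == 0:
        raise ValueError("log must contain at least one correct and one error trial")
    return acc, n_c, n_e


def raw_classification_image(
    log: ExperimentLog, domain: str, n_cycles: float = 3.0
) -> ClassificationImage:
    """mean(features | correct) - mean(features | error)."""
    acc, n_c, n_e = _split_counts(log)
    x = trial_features(log, domain, n_cycles)
    values = x[acc == 1].mean(axis=0) - x[acc == 0].mean(axis=0)
    return ClassificationImage(
        domain,
        values.reshape(_domain_shape(domain, log.spec)),
        scale="raw",
        meta={
            "participant": log.participant_id,
            "stimulus_class": log.stimulus_class,
            "n_correct": n_c,
            "n_error": n_e,
        },
    )


def _bootstrap_stats(
    x: np.ndarray,
    n_correct: int,
    n_error: int,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap mean and SD of the raw image under label/function decoupling.

    Each iteration draws n_correct + n_error functions with replacement from
    the log and pairs them with the observed accuracy multiset; the weighted
    subtraction then gives one random classification image.
    """
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    off = (np.arange(n_boot) * n)[:, None]
    c_counts = np.bincount(
        (idx[:, :n_correct] + off).ravel(), minlength=n_boot * n
    ).reshape(n_boot, n)
    e_counts = np.bincount(
        (idx[:, n_correct:] + off).ravel(), minlength=n_boot * n
    ).reshape(n_boot, n)
    w = c_counts * (1.0 / n_correct)
    w -= e_counts * (1.0 / n_error)
    boots = w @ x
    return boots.mean(axis=0), boots.std(axis=0, ddof=1)


def bootstrap_z(
    log: ExperimentLog,
    domain: str,
    n_boot: int = DEFAULT_N_BOOT,
    rng: np.random.Generator | None = None,
    n_cycles: float = 3.0,
) -> ClassificationImage:
    """Z-scored classification image against the bootstrap null."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    acc, n_c, n_e = _split_counts(log)
    x = trial_features(log, domain, n_cycles)
    raw = x[acc == 1].mean(axis=0) - x[acc == 0].mean(axis=0)
    mean, sd = _bootstrap_stats(x, n_c, n_e, n_boot, rng)
    # constant features only produce round-off scatter across bootstraps
    bad = np.flatnonzero(sd <= 1e-10 * max(1.0, float(np.abs(x).max())))
    if bad.size:
        raise ValueError(f"bootstrap SD is zero at feature indices {bad.tolist()}")
    z = (raw - mean) / sd
    return ClassificationImage(
        domain,
        z.reshape(_domain_shape(domain, log.spec)),
        scale="z",
        meta={
            "participant": log.participant_id,
            "stimulus_class": log.stimulus_class,
            "n_correct": n_c,
            "n_error": n_e,
            "n_boot": n_boot,
        },
    )


def _sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_field(values: np.ndarray, fwhm: float, domain: str) -> np.ndarray:
    """Mean-preserving Gaussian smoothing (reflective boundary).

    time: 1-D over frames; tf: isotropic 2-D; fourier: the amplitude and
    phase blocks are smoothed separately (they are distinct fields).
    """
    v = np.asarray(values, dtype=float)
    s = _sigma(fwhm)
    if domain in ("time",):
        return gaussian_filter1d(v, s, mode="reflect")
    if domain == "tf":
        out = gaussian_filter1d(v, s, axis=0, mode="reflect")
        return gaussian_filter1d(out, s, axis=1, mode="reflect")
    if domain == "fourier":
        half = v.size // 2
        return np.concatenate(
            [
                gaussian_filter1d(v[:half], s, mode="reflect"),
                gaussian_filter1d(v[half:], s, mode="reflect"),
            ]
        )
    raise ValueError(f"domain must be one of {DOMAINS}")


def _smoothing_sd(shape: tuple[int, ...], fwhm: float, domain: str) -> np.ndarray:
    """Pointwise SD of a smoothed field whose input is unit white noise.

    Computed exactly from the smoothing operator (including the reflective
    boundary), per axis for separable kernels.
    """
    s = _sigma(fwhm)

    def axis_sd(n: int) -> np.ndarray:
        op = gaussian_filter1d(np.eye(n), s, axis=0, mode="reflect")
        return np.sqrt((op**2).sum(axis=1))

    if domain == "time":
        return axis_sd(shape[0])
    if domain == "tf":
        return np.outer(axis_sd(shape[0]), axis_sd(shape[1]))
    if domain == "fourier":
        half = shape[0] // 2
        block = axis_sd(half)
        return np.concatenate([block, block])
    raise ValueError(f"domain must be one of {DOMAINS}")


def _geometry(domain: str, shape: tuple[int, ...], fwhm: float) -> FieldGeometry:
    if domain == "fourier":
        return FieldGeometry(shape=(shape[0] // 2,), fwhm=fwhm, n_fields=2)
    return FieldGeometry(shape=shape, fwhm=fwhm)


def _check_group(cis: Sequence[ClassificationImage]) -> tuple[str, tuple[int, ...]]:
    if len(cis) == 0:
        raise ValueError("need at least one classification image")
    domain = cis[0].domain
    shape = cis[0].values.shape
    for ci in cis:
        if ci.domain != domain or ci.values.shape != shape:
            raise ValueError("classification images mix domains or shapes")
    return domain, shape


def group_pipeline(
    cis: Sequence[ClassificationImage],
    fwhm: float | None = None,
    alpha: float = 0.05,
) -> GroupResult:
    """Average Z images, smooth, and apply the two-way Pixel test.

    The participant average is rescaled by sqrt(n) and, after smoothing, by
    the exact pointwise SD of the smoothing operator, so the displayed field
    is unit-variance under the null hypothesis and the Pixel threshold
    applies directly.
    """
    domain, shape = _check_group(cis)
    fwhm = DEFAULT_FWHM[domain] if fwhm is None else float(fwhm)
    n = len(cis)
    mean_z = np.mean([ci.values for ci in cis], axis=0)
    fld = smooth_field(mean_z * np.sqrt(n), fwhm, domain) / _smoothing_sd(
        shape, fwhm, domain
    )
    z_crit = pixel_threshold(_geometry(domain, shape, fwhm), alpha, tails="two")
    mask = np.where(fld > z_crit, 1, np.where(fld < -z_crit, -1, 0)).astype(np.int8)
    return GroupResult(
        domain=domain,
        values=fld,
        z_crit=z_crit,
        mask=mask,
        alpha=alpha,
        fwhm=fwhm,
        n_images=n,
        meta={"kind": "group-mean"},
    )


def contrast_classification_image(
    group_a: Sequence[ClassificationImage],
    group_b: Sequence[ClassificationImage],
    fwhm: float | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    n_boot: int = DEFAULT_N_BOOT,
) -> GroupResult:
    """Z-scored difference between two groups of classification images.

    The observed difference of group means is standardized against a
    bootstrap null that resamples participants with replacement from the
    pooled set (group labels exchanged under the null).  The bootstrap set is
    symmetrized (each draw enters with both signs), which centers the null at
    zero and makes the contrast exactly antisymmetric in its arguments; the
    pooled participants are resampled in a canonical order so the null is
    invariant to argument order.
    """
    rng = rng if rng is not None else np.random.default_rng()
    domain, shape = _check_group(list(group_a) + list(group_b))
    fwhm = DEFAULT_FWHM[domain] if fwhm is None else float(fwhm)
    a = np.array([ci.values.ravel() for ci in group_a])
    b = np.array([ci.values.ravel() for ci in group_b])
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("participant resampling needs at least 2 images per group")
    diff = a.mean(axis=0) - b.mean(axis=0)
    pool = np.vstack([a, b])
    pool = pool[np.lexsort(pool.T[::-1])]  # canonical order: argument-order invariant
    ia = rng.integers(0, len(pool), size=(n_boot, n_a))
    ib = rng.integers(0, len(pool), size=(n_boot, n_b))
    d = pool[ia].mean(axis=1) - pool[ib].mean(axis=1)
    sd = np.sqrt((d**2).mean(axis=0))  # symmetrized null: mean 0 by construction
    bad = np.flatnonzero(sd <= 1e-10 * max(1.0, float(np.abs(pool).max())))
    if bad.size:
        raise ValueError(f"contrast bootstrap SD is zero at feature indices {bad.tolist()}")
    z = (diff / sd).reshape(shape)
    fld = smooth_field(z, fwhm, domain) / _smoothing_sd(shape, fwhm, domain)
    z_crit = pixel_threshold(_geometry(domain, shape, fwhm), alpha, tails="two")
    mask = np.where(fld > z_crit, 1, np.where(fld < -z_crit, -1, 0)).astype(np.int8)
    return GroupResult(
        domain=domain,
        values=fld,
        z_crit=z_crit,
        mask=mask,
        alpha=alpha,
        fwhm=fwhm,
        n_images=n_a + n_b,
        meta={"kind": "contrast", "n_a": n_a, "n_b": n_b, "n_boot": n_boot,
              "unsmoothed_z": z},
    )
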