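"""Spectral decomposition of classification images, between-subject
agreement, and stimulus-class decoding.

Although time-domain and time-frequency classification images vary widely
across observers, their power spectra are expected to be highly consistent;
the intraclass correlation coefficient quantifies that agreement, and a
linear SVM with leave-one-out cross-validation tests whether the power
spectra are diagnostic of the stimulus class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classification import ClassificationImage
from .sampling import wrap_phase

__all__ = ["CISpectrum", "AgreementReport", "DecodingResult", "ci_power_phase", "icc", "decode_loo"]


@dataclass(frozen=True)
class CISpectrum:
    """Power and phase per classification-image frequency.

    ``power``/``phase`` have shape (n_rows, n_bins): one row for a
    time-domain image, one row per stimulus sampling frequency for a
    time-frequency image.
    """

    power: np.ndarray
    phase: np.ndarray
    frequencies: np.ndarray  # classification-image frequencies, Hz
    row_frequencies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "phase", np.atleast_2d(np.asarray(self.phase, dtype=float)))


@dataclass(frozen=True)
class AgreementReport:
    """Intraclass correlation with its 95% interval (upper bound 1, no lower
    bound for the consistency / average-measures form)."""

    icc: float
    ci_low: float
    ci_high: float
    n_raters: int
    n_targets: int
    form: str = "icc3k"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc <= self.ci_high <= 1.0 + 1e-12):
            raise ValueError("interval must satisfy ci_low <= icc <= ci_high <= 1")


@dataclass(frozen=True)
class DecodingResult:
    accuracy: float
    confusion: np.ndarray  # (n_classes, n_classes), rows = true class
    classes: tuple
    chi2: float
    df: int
    p_value: float


def ci_power_phase(ci: ClassificationImage) -> CISpectrum:
    """Discrete Fourier power/phase of a classification image over time.

    Time-domain images give a single spectrum; time-frequency images give
    one spectrum per stimulus sampling frequency (row).  Fourier-domain
    images carry no time axis to transform and are rejected.
    """
    if ci.domain == "fourier":
        raise ValueError("a Fourier-domain classification image has no time axis")
    rows = np.atleast_2d(ci.values)
    n = rows.shape[1]
    spec_rows = np.fft.rfft(rows, axis=1)
    power = np.abs(spec_rows) ** 2
    phase = wrap_phase(np.angle(spec_rows))
    refresh = float(ci.meta.get("refresh_rate", 120.0))
    freqs = np.fft.rfftfreq(n, d=1.0 / refresh)
    row_freqs = tuple(np.arange(5.0, 60.0, 5.0)) if ci.domain == "tf" else None
    return CISpectrum(power=power, phase=phase, frequencies=freqs, row_frequencies=row_freqs)


def _anova_ms(data: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way (targets x raters) mean squares from a raters-by-targets matrix."""
    y = np.asarray(data, dtype=float)
    k, n = y.shape  # k raters, n targets
    grand = y.mean()
    ss_t = k * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_r = n * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_e = np.sum((y - y.mean(axis=0)[None, :] - y.mean(axis=1)[:, None] + grand) ** 2)
    ms_t = ss_t / (n - 1)
    ms_r = ss_r / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    return ms_t, ms_r, ms_e, n, k


def icc(
    data: np.ndarray, form: str = "icc3k", alpha: float = 0.05
) -> AgreementReport:
    """Average-measures intraclass correlation of a raters x targets matrix.

    Rows are raters (participants), columns are targets (classification-image
    points, or spectrum bins).  ``icc3k`` is the two-way consistency
    average-measures form (MS_T - MS_E) / MS_T - bounded above by 1 with no
    lower bound; ``icc2k`` is the absolute-agreement variant.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 3:
        raise ValueError("need a 2-D matrix with >= 2 raters and >= 3 targets")
    if not np.all(np.isfinite(y)):
        raise ValueError("entries must be finite")
    if form not in ("icc3k", "icc2k"):
        raise ValueError("form must be 'icc3k' or 'icc2k'")
    ms_t, ms_r, ms_e, n, k = _anova_ms(y)
    if ms_t == 0:
        raise ValueError("zero variance across targets: ICC undefined")
    if ms_e == 0:  # perfectly consistent raters
        return AgreementReport(1.0, 1.0, 1.0, k, n, form)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if form == "icc3k":
        value = (ms_t - ms_e) / ms_t
        f_obs = ms_t / ms_e
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo, hi = 1 - 1 / f_l, 1 - 1 / f_u
    else:
        value = (ms_t - ms_e) / (ms_t + (ms_r - ms_e) / n)
        # Shrout-Fleiss interval for ICC(2,1), then the Spearman-Brown step up
        icc2 = (ms_t - ms_e) / (ms_t + (k - 1) * ms_e + k * (ms_r - ms_e) / n)
        a = k * icc2 / (n * (1 - icc2))
        b = 1 + k * icc2 * (n - 1) / (n * (1 - icc2))
        v = (a * ms_r + b * ms_e) ** 2 / (
            (a * ms_r) ** 2 / (k - 1) + (b * ms_e) ** 2 / df2
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        l1 = n * (ms_t - f1 * ms_e) / (
            f1 * (k * ms_r + (k * n - k - n) * ms_e) + n * ms_t
        )
        u1 = n * (f2 * ms_t - ms_e) / (
            k * ms_r + (k * n - k - n) * ms_e + n * f2 * ms_t
        )
        step = lambda r: k * r / (1 + (k - 1) * r)
        lo, hi = step(l1), step(u1)
    return AgreementReport(float(value), float(min(lo, value)), float(min(max(hi, value), 1.0)), k, n, form)


def decode_loo(
    features: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator | None = None,
    C: float = 1.0,
) -> DecodingResult:
    """Leave-one-out linear-SVM decoding of stimulus class.

    Each left-out participant is predicted by a linear maximum-margin
    classifier (one-vs-one multiclass) trained on all others, with features
    standardized inside the training fold only.  The chi-square statistic
    tests the predicted-vs-true contingency table against independence
    (chance), df = (n_classes - 1)^2.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise ValueError(
            f"classes {small} have a single member: the LOO training set would "
            "lose the class"
        )
    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    pred = cross_val_predict(clf, x, y, cv=LeaveOneOut())
    conf = confusion_matrix(y, pred, labels=classes)
    accuracy = float(np.trace(conf) / conf.sum())
    expected = np.outer(conf.sum(axis=1), conf.sum(axis=0)) / conf.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (conf - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    df = (len(classes) - 1) ** 2
    p = float(stats.chi2.sf(chi2, df))
    return DecodingResult(
        accuracy=accuracy,
        confusion=conf,
        classes=tuple(classes.tolist()),
        chi2=chi2,
        df=df,
        p_value=p,
    )
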