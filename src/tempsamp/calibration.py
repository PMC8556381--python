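"""End-to-end calibration experiments for the analysis chain.

Two simulation studies validate the pipeline against its own nominal rates:

* the family-wise false-positive rate of the two-way Pixel test on fully
  null group classification images (accuracy labels independent of the
  sampling functions), run through the complete bootstrap-Z + average +
  smooth + threshold chain;
* the asymptotic accuracy of a simulated observer driven by the adaptive
  noise-contrast staircase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .classification import bootstrap_z, group_pipeline
from .observers import ExperimentLog
from .sampling import BasisSpec, draw_sampling_batch
from .stimulus import default_psychometric, simulate_staircase_session

__all__ = ["NullCalibration", "null_group_fwer", "staircase_convergence"]


@dataclass(frozen=True)
class NullCalibration:
    """Empirical family-wise error rates over simulated null experiments."""

    any_rate: float  # either tail (the two-way test's overall FWER)
    pos_rate: float  # positive tail only
    neg_rate: float  # negative tail only
    n_experiments: int
    alpha: float


def null_group_fwer(
    n_experiments: int,
    n_participants: int = 12,
    n_trials: int = 300,
    domain: str = "time",
    fwhm: float = 0.6,
    alpha: float = 0.05,
    n_boot: int = 1000,
    spec: BasisSpec | None = None,
    rng: np.random.Generator | None = None,
) -> NullCalibration:
    """Family-wise false-positive rate of the full group pipeline under the null.

    Each experiment simulates ``n_participants`` observers whose accuracy
    labels are Bernoulli(1/2) draws independent of the sampling functions,
    Z-scores every observer's classification image by bootstrap, averages,
    smooths, applies the two-way Pixel threshold, and records whether any
    point is suprathreshold in either tail.
    """
    spec = spec or BasisSpec()
    rng = rng if rng is not None else np.random.default_rng()
    n_any = n_pos = n_neg = 0
    for _ in range(n_experiments):
        values, amps, phases = draw_sampling_batch(
            n_participants * n_trials, spec, rng
        )
        cis = []
        for p in range(n_participants):
            sl = slice(p * n_trials, (p + 1) * n_trials)
            while True:  # labels independent of functions; degenerate splits redrawn
                acc = (rng.random(n_trials) < 0.5).astype(np.int8)
                if 0 < acc.sum() < n_trials:
                    break
            log = ExperimentLog(
                participant_id=f"null_{p}",
                stimulus_class="null",
                values=values[sl],
                amplitudes=amps[sl],
                phases=phases[sl],
                accuracy=acc,
                noise_level=np.full(n_trials, 64),
                spec=spec,
            )
            cis.append(bootstrap_z(log, domain, n_boot=n_boot, rng=rng))
        res = group_pipeline(cis, fwhm=fwhm, alpha=alpha)
        pos, neg = res.n_significant()
        n_pos += pos > 0
        n_neg += neg > 0
        n_any += (pos > 0) or (neg > 0)
    return NullCalibration(
        any_rate=n_any / n_experiments,
        pos_rate=n_pos / n_experiments,
        neg_rate=n_neg / n_experiments,
        n_experiments=n_experiments,
        alpha=alpha,
    )


def staircase_convergence(
    n_sessions: int = 50,
    n_trials: int = 1200,
    psychometric: Callable[[int], float] = default_psychometric,
    rng: np.random.Generator | None = None,
    tail_fraction: float = 1.0 / 3.0,
) -> float:
    """Mean accuracy over the final third of staircase-driven sessions.

    Returns the across-session mean accuracy (fraction correct) over the last
    ``tail_fraction`` of trials, once the staircase has converged to the
    50%-correct noise-contrast level.
    """
    rng = rng if rng is not None else np.random.default_rng()
    tail = int(round(n_trials * tail_fraction))
    accs = []
    for _ in range(n_sessions):
        _, acc, _ = simulate_staircase_session(psychometric, n_trials, rng)
        accs.append(acc[-tail:].mean())
    return float(np.mean(accs))
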