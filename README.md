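# tempsamp

**Random temporal sampling for probing oscillatory visual mechanisms.**

`tempsamp` is a Python toolbox for psychophysicists who study whether visual
processing efficiency oscillates over the brief exposure of a target.  In a
random-temporal-sampling experiment, a target is shown for 200 ms while its
visibility — the signal-to-noise ratio (SNR) of a target/noise mixture —
oscillates according to a random function regenerated on every trial.
Relating these per-trial visibility profiles to response accuracy yields
*classification images* of processing efficiency over time, over static
oscillation frequency, and over a time–frequency plane.

The package covers the complete workflow:

- **Stimulus generation** — per-trial SNR sampling functions built from
  5–55 Hz sinusoids (5 Hz steps) with random amplitudes and phases,
  range-normalized to [0, 0.5] and sum-matched across trials; frame
  composition (signal + maximal-contrast noise) with per-frame luminance and
  RMS-contrast equalization; the 128-level adaptive noise-contrast staircase
  that holds accuracy near 50 %.
- **Simulated observers** — a synthetic-data generator whose observers carry
  latent temporal templates that share a class-specific *power* spectrum but
  have idiosyncratic *phase* spectra, with a logistic response rule
  calibrated to the staircase's operating point.  Every analysis stage is
  testable against this known ground truth.
- **Analysis** — classification images in three coding domains (time,
  Fourier descriptors, Morlet time–frequency), bootstrap Z-scoring, group
  averaging, Gaussian smoothing, random-field-theory thresholding (the
  two-way Pixel test), spectral decomposition of classification images,
  between-subject agreement (intraclass correlation), and leave-one-out
  linear-SVM decoding of stimulus class.

## The statistics at the core

For trial features `x_i` (the SNR series, its Fourier descriptors, or its
three-cycle complex Morlet amplitude map) and binary accuracies, the raw
classification image is the weighted subtraction

```
CI = mean(x_i | correct) − mean(x_i | error)
```

It is standardized elementwise, `Z = (CI − μ*) / σ*`, where `μ*` and `σ*`
are the mean and SD of 1000 bootstrap classification images in which the
sampling functions are resampled with replacement and paired with the
observed accuracy multiset.  Individual Z images are averaged, smoothed with
a Gaussian kernel (FWHM 0.6 bins in the time domain, 1.5 bins in the
time–frequency domain), restandardized to unit null variance, and
thresholded at ±z_crit from the Pixel test: z_crit solves

```
α/2 = Σ_d R_d ρ_d(z)
```

the expected-Euler-characteristic bound for the maximum of a smooth
unit-variance Gaussian field (resel counts `R_d` from extent/FWHM, EC
densities `ρ_d` for d = 0, 1, 2), taken jointly with the lattice Bonferroni
bound — whichever is sharper.  Classification images are further decomposed
by FFT into power/phase spectra; agreement across observers uses the
two-way consistency average-measures ICC, `(MS_targets − MS_error) /
MS_targets` (upper bound 1, no lower bound).

## Worked example

Simulate the default four-class observer library (scaled down to 4 observers
per class and 600 trials for a quick demonstration), analyze, contrast,
decode, and report:

```python
from tempsamp.io import RunConfig, run_pipeline

cfg = RunConfig(n_classes=4, observers_per_class=4, n_trials=600,
                n_boot=500, seed=7)
for stage in ("simulate", "analyze", "contrast", "decode", "report"):
    run_pipeline(cfg, stage, "ts_example")
print(open("ts_example/report.txt").read())
```

which prints (abridged):

```
tempsamp run report  (config 9e4722a371560774, seed 7)

group_faces_tf: domain=tf z_crit=3.733 +points=12 -points=1
group_faces_time: domain=time z_crit=3.078 +points=3 -points=2
group_words_fourier: domain=fourier z_crit=3.052 +points=2 -points=0
group_words_tf: domain=tf z_crit=3.733 +points=17 -points=22
group_words_time: domain=time z_crit=3.078 +points=3 -points=4

decoding[time]: accuracy=0.938 (chance 0.250), chi2(9)=41.6, p=3.89e-06
decoding[tf]: accuracy=0.562 (chance 0.250), chi2(9)=16.8, p=5.26e-02
```

Each `group_*` line is one stimulus class in one coding domain: `z_crit` is
the two-way Pixel threshold for that domain's geometry, and `±points` count
grid points where group processing efficiency differs significantly from
zero (positive: the visibility pattern at that moment/frequency helped
recognition; negative: it interfered).  The decoding lines show
leave-one-out accuracy of predicting an observer's stimulus class from the
power spectrum of their classification image, with the chi-square test
against chance — time-domain power spectra are strongly diagnostic of the
task, the time–frequency spectra less so.

The same workflow is available from the shell:

```bash
tempsamp simulate --seed 7 --out run1
tempsamp analyze  --seed 7 --out run1
tempsamp decode   --seed 7 --out run1
tempsamp report   --seed 7 --out run1
```

## Layout

- `src/tempsamp/sampling.py` — sampling functions and Fourier descriptors
- `src/tempsamp/wavelets.py` — complex Morlet time–frequency maps
- `src/tempsamp/stimulus.py` — frame composition and the staircase
- `src/tempsamp/observers.py` — the simulated-observer generator
- `src/tempsamp/classification.py` — classification images, bootstrap Z,
  group and contrast pipelines
- `src/tempsamp/pixel.py` — random-field-theory (Pixel test) thresholds
- `src/tempsamp/spectra.py` — spectra, ICC, SVM decoding
- `src/tempsamp/calibration.py` — end-to-end null/staircase calibration
- `src/tempsamp/io.py`, `src/tempsamp/cli.py` — formats, config, workflow

See `docs/methods.md` for the modeling and numerical choices.
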