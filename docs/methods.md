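# Methods notes

This note records the models, parameter choices and numerical decisions
behind `tempsamp`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where the design was genuinely open.

## Sampling functions

A sampling function is the SNR time course of one trial:
`x(t) = Σ_k a_k sin(2π f_k t + φ_k)` over the basis frequencies
`f_k ∈ {5, 10, …, 55}` Hz, evaluated at the midpoints `t = (j + ½)/120` s of
the 24 display frames of a 200 ms exposure at 120 Hz.  A frame is shown for
its whole refresh interval, so the midpoint is the unbiased representative;
it also makes the basis exactly orthogonal on the frame grid (each `f_k`
falls on an integer DFT bin), which gives exact round-trips between
waveforms and their amplitude/phase descriptors.

Amplitudes are i.i.d. uniform(0, 1) and phases i.i.d. uniform(0, 2π) — the
maximal-entropy reading of "random amplitudes and phases".  Each draw is
range-normalized to [0, 0.5] *first* and then kept only if its frame sum
lies within ε = 0.05 of the target S\* = 6.0 (rejection sampling, budget
10 000 candidates per accepted function, acceptance rate ≈ 4.3 %).
Normalize-then-reject preserves the exact [0, 0.5] range; S\* = 6.0 is the
analytic and empirical mean of the frame sums of unconstrained normalized
draws (24 frames × 0.25), so the sum constraint removes trial-to-trial
energy differences without biasing the accepted shapes.  Flat (degenerate)
candidates are redrawn, never clamped — a flat function carries no sampling
information.

For throughput, candidates are screened in float32 (with the acceptance
band widened by 10⁻³) and the surviving draws are recomputed in float64 and
re-tested against the exact rule, so the accepted set follows the float64
acceptance rule; parameters are stored and the pre-normalization waveform
regenerates from them exactly.

## Time–frequency coding

Maps use three-cycle complex Morlet kernels, `σ_t = n_cycles/(2πf)`, at the
same 5–55 Hz frequencies, normalized to unit energy so magnitudes are
comparable across rows.  Three cycles buys temporal precision at the price
of frequency smearing; a pure-frequency input also drives neighboring rows,
which is expected and untreated.  The 24-sample series is implicitly
zero-extended (the 5 Hz kernel spans 600 ms, three times the window), no
frame is cropped, and there is no cone-of-influence masking.  The output is
the convolution modulus (amplitude) by default — classification-image
subtraction is linear in the coded feature and amplitude keeps units
interpretable — with squared magnitude available behind a flag.

## Stimulus frames and the staircase

Frame `k` is `w_k · signal + (1 − w_k) · noise`, where `w_k` is the
sampling-function value ("SNR" is read as the signal *weight*, bounded by
0.5, which keeps images in gamut and preserves the intended ordering), the
signal is the target blended with a binary white-noise mask of contrast
`(level − 1)/127` (level 1 is a null mask, level 128 full black/white), and
the noise is an independent maximal-contrast binary field; both fields are
fresh per trial.  Frames are then equalized to the first frame's mean
luminance and RMS contrast — the simplest operators satisfying the matching
requirement.  Equalization can push isolated pixels marginally outside
[0, 1]; values are left untouched in memory and clipped only on export.

The staircase spans 128 integer contrast levels, starts at the midpoint
(level 64) for ten trials, and from trial 11 compares mean accuracy over
the ten immediately preceding trials (a sliding window, recomputed every
trial and carried across block boundaries) with 50 %: above raises the
level by the current step, below lowers it, exactly 50 % holds.  The step
starts at 16 and halves at each reversal of adjustment direction down to 1;
the level is clamped to [1, 128].

## Simulated observers

Real observers are emulated by latent unit-norm temporal templates.  Each
class owns a prototype power profile over the 11 basis frequencies (default:
Gaussian bumps, width 6 Hz, centers spread over 10–50 Hz, floor 0.02); an
observer's template is `Σ_k √(power_k) sin(2π f_k t + φ_k)` with phases
drawn as a class base phase plus observer jitter.  The default jitter SD is
2π — a wrapped normal this wide is indistinguishable from uniform — so
observers share power exactly and phases not at all, the structure the
pipeline is designed to detect.  Setting the jitter to zero makes a class's
observers identical.

Responses follow `P(correct) = logistic(b + g · ⟨template, x − x̄⟩)` on the
mean-centered SNR series (or the Morlet map for time–frequency observers).
The paper of record needed no response model — its observers were human —
so the logistic rule is the package's own choice: the simplest monotone
link with a calibratable operating point.  The intercept `b` is solved by
root-finding on the session's own trials so that mean accuracy hits the
staircase's ~50 % target.  The default gain of 6 was fixed during
development as the smallest round value at which a single observer's
1200-trial classification image recovers its template at r ≈ 0.9; parameter
recovery, the power/phase dissociation (ICC of power spectra > 0.9, of raw
images ≈ 0) and four-class decodability all hold at this operating point.
Observer simulation runs at a fixed noise level by default; the staircase
is exercised and calibrated separately, which keeps the two mechanisms
independently testable.

What the generator does *not* emulate: image-computable responses (features
are sampling functions, not pixels), reaction times, learning or fatigue
drifts, and any between-observer variation in power spectra within a class.
Passing tests therefore certify the analysis chain on data with exactly the
assumed structure, not the behavior of human observers.

## Classification images and bootstrap Z

The raw image is `mean(features | correct) − mean(features | error)` — the
only weighting whose null expectation is zero under unequal counts.
Fourier-domain features are the 11 amplitudes followed by the 11 phases
wrapped to (−π, π]; phases are averaged arithmetically, a deliberate linear
reading of a circular quantity that mirrors how such images are usually
displayed.  The bootstrap null resamples sampling functions with
replacement and pairs them with the *fixed* observed label multiset
(preserving the observed accuracy rate), 1000 iterations by default; the
raw image is standardized by the bootstrap mean and SD.  Bootstrap SDs that
are zero up to round-off (constant features) raise an error naming the
offending points.

At the group stage the participant average is multiplied by √n — under the
null each participant's Z image is pointwise ≈ N(0, 1), so the average
alone would be 1/√n too small for a unit-variance threshold — smoothed
with a mean-preserving Gaussian kernel (reflective boundary), and divided
by the exact pointwise SD of the smoothing operator applied to white noise
(computed from the operator matrix, so edge effects are handled exactly).
The displayed field is therefore unit variance under the null and the
Pixel threshold applies directly; the family-wise error of the whole chain
is verified empirically (below).  Fourier-domain images are smoothed and
thresholded as two disjoint 1-D fields (amplitude block, phase block).

Class contrasts standardize the difference of group means against a
bootstrap null that resamples participants with replacement from the pooled
set (group labels exchanged under the null).  The bootstrap set is
symmetrized — each draw enters with both signs — which centers the null at
zero exactly, and the pool is resampled in a canonical (lexicographic)
order, making `contrast(A, B) = −contrast(B, A)` an exact identity rather
than an approximation.

## The Pixel test on small discrete fields

The critical Z solves `α_tail = Σ_d R_d ρ_d(z)` with resel counts
`R_1 = (n−1)/FWHM` (1-D) and `R_1 = L_1 + L_2`, `R_2 = L_1 L_2` (2-D,
boundary terms included — they are not negligible on a 24-bin field),
solved by bracketed root-finding; the bound is monotone on the bracket.
Smoothness is passed explicitly as the applied kernel's FWHM — the pipeline
knows its own filter — never estimated from residuals.

At the smoothing widths used here (0.6 bins in time, 1.5 bins in
time–frequency) the lattice is *under-smoothed* relative to the continuum:
the EC bound counts more resels than there are grid points and becomes
conservative.  The returned threshold is therefore the smaller of the EC
solution and the Bonferroni threshold over lattice points — both are valid
family-wise bounds, so their minimum is too.  Monte-Carlo simulation of
≥20 000 smoothed null lattice fields at both study geometries puts the
empirical family-wise rate within ±0.01 of the nominal 0.05 (two-way) and
0.025 (per tail), and the full null pipeline (sampling functions, bootstrap
Z, averaging, smoothing, thresholding) reproduces α ≈ 0.05 over 5000
simulated experiments.  The two-way test uses α/2 per tail and keeps the
sign: `|Z| > z_crit`.

## Spectra, agreement, decoding

Power/phase spectra of classification images are plain FFTs over the
24-point time axis (13 non-negative bins at 5 Hz spacing, 0–60 Hz), one
spectrum per time–frequency row.  Agreement uses the two-way *consistency*
average-measures ICC — the form that is bounded above by 1 with no lower
bound; the absolute-agreement variant is exposed alongside, and both match
`pingouin` to 10 significant digits in the cross-check tests.  Raters are
participants, targets are image points (or spectrum bins), and confidence
intervals use the F-distribution forms.

Decoding trains a linear SVC (one-vs-one, C = 1) with leave-one-out
cross-validation; features are standardized inside the training folds only.
Significance versus chance uses the chi-square statistic of the
predicted-vs-true contingency table against independence, df =
(n_classes − 1)², computed directly from the margins (robust to never-
predicted classes) and equal to `scipy.stats.chi2_contingency` whenever the
table is non-degenerate.  Time–frequency features concatenate all 11 row
spectra.

A caveat surfaced by the simulations: because Fourier-domain features read
wrapped phases linearly, a *template* observer can produce genuinely
non-zero Fourier-domain classification-image points (the template induces a
preferred phase).  The null behavior of the Fourier domain is therefore
certified with template-free observers, where the clean rate matches the
nominal 95 %.

## Problem sizes and reproducibility

The calibration studies run at 5000 null experiments (12 × 300 trials,
1000 bootstrap iterations) for the family-wise rate and 50 sessions × 1200
trials for the staircase, chosen so that Monte-Carlo standard errors
(≈ 0.003 on the rate, ≈ 0.2 pp on accuracy) are well inside the tolerances
being checked.  Test-suite simulations use the same generator defaults at
smaller trial counts.  All randomness flows through explicit
`numpy.random.Generator` objects; the staged workflow derives one seed per
stage from the master seed via `SeedSequence([master, stage_constant])`,
and repeated runs with the same configuration hash produce identical
numeric artifacts.

## Known limitations

- Phase averaging and phase-spectrum ICC treat circular quantities
  linearly; near ±π this wraps and attenuates agreement.
- The EC ∧ Bonferroni threshold is (mildly) conservative between the
  under-smoothed and smooth regimes; exactness is claimed only as verified
  by simulation at the study geometries.
- The contrast bootstrap resamples participants, so it needs at least two
  images per group and its null reflects between-participant variance only.
- Luminance/contrast equalization matches first and second moments; it does
  not equate higher-order statistics across frames.
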