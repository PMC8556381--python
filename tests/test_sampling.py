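"""Sampling-function generation and spectral re-coding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempsamp import (
    BasisSpec,
    SamplingFunction,
    draw_sampling_batch,
    fourier_descriptors,
    make_sampling_function,
    range_normalize,
    synthesize,
)
from tempsamp.sampling import DEFAULT_SUM_TARGET, DEFAULT_SUM_TOL, wrap_phase


class TestBasisSpec:
    def test_default_timing(self, spec):
        assert spec.n_frames == 24
        assert spec.nyquist == 60.0
        assert spec.frequencies == tuple(range(5, 60, 5))
        # frame midpoints: a frame shown over [k, k+1)/rate is represented at its middle
        assert np.allclose(spec.frame_times, (np.arange(24) + 0.5) / 120.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frequencies": (10.0, 5.0)},  # not increasing
            {"frequencies": (0.0, 5.0)},  # non-positive
            {"frequencies": (5.0, 65.0)},  # above Nyquist
            {"duration": 0.0},
            {"refresh_rate": -1.0},
            {"duration": 0.005},  # fewer than 2 frames
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BasisSpec(**kwargs)


class TestDraws:
    def test_single_draw_satisfies_invariants(self, spec, rng):
        sf = make_sampling_function(spec, rng)
        assert sf.values.shape == (24,)
        assert sf.values.min() == 0.0
        assert sf.values.max() == 0.5
        assert abs(sf.values.sum() - DEFAULT_SUM_TARGET) <= DEFAULT_SUM_TOL

    def test_many_draws_sum_matched_and_unbiased(self, spec, rng):
        v, a, p = draw_sampling_batch(10_000, spec, rng)
        assert np.all(np.abs(v.sum(axis=1) - DEFAULT_SUM_TARGET) <= DEFAULT_SUM_TOL)
        assert v.min(axis=1).max() == 0.0 and v.max(axis=1).min() == 0.5
        # per-frame mean SNR sits at the middle of the normalized range
        assert np.allclose(v.mean(axis=0), 0.25, atol=0.01)
        assert np.all(a >= 0) and np.all(a <= 1)

    def test_sum_target_matches_unconstrained_mean(self, spec, rng):
        # oracle: without sum matching, range-normalized draws average to
        # n_frames/4 per trial, which motivates the 6.0 target
        amps = rng.uniform(0, 1, (20_000, 11))
        phases = rng.uniform(0, 2 * np.pi, (20_000, 11))
        raw = synthesize(amps, phases, spec)
        sums = range_normalize(raw).sum(axis=1)
        assert abs(sums.mean() - spec.n_frames * 0.25) < 0.03

    def test_independent_draws_differ(self, spec, rng):
        v, _, _ = draw_sampling_batch(2, spec, rng)
        assert not np.allclose(v[0], v[1])

    def test_redraw_budget_exhaustion_raises(self, spec, rng):
        with pytest.raises(RuntimeError, match="budget"):
            # a frame sum of 11.9 is essentially unreachable
            draw_sampling_batch(1, spec, rng, sum_target=11.9, redraw_budget=100)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_range_normalization_idempotent(self, seed):
        x = np.random.default_rng(seed).standard_normal(24)
        once = range_normalize(x)
        assert np.allclose(range_normalize(once), once, atol=1e-12)
        assert once.min() == 0.0 and once.max() == 0.5


class TestFourierDescriptors:
    def test_stored_parameters_round_trip_exactly(self, spec, rng):
        sf = make_sampling_function(spec, rng)
        d = fourier_descriptors(sf)
        assert np.array_equal(d.amplitudes, sf.amplitudes)
        assert np.allclose(d.phases, wrap_phase(sf.phases))

    def test_series_descriptors_recover_synthesis(self, spec, rng):
        amps = rng.uniform(0.1, 1.0, 11)
        phases = rng.uniform(0, 2 * np.pi, 11)
        raw = synthesize(amps, phases, spec)
        d = fourier_descriptors(raw, spec, from_series=True)
        assert np.allclose(d.amplitudes, amps, atol=1e-10)
        assert np.allclose(wrap_phase(d.phases - phases), 0.0, atol=1e-10)

    def test_constant_series_has_no_oscillatory_content(self, spec):
        d = fourier_descriptors(np.full(24, 0.3), spec, from_series=True)
        assert np.allclose(d.amplitudes, 0.0, atol=1e-12)

    def test_single_sinusoid_closed_form(self, spec):
        # closed-form DFT of an integer-cycle sinusoid sampled at midpoints
        a, phi = 0.37, 1.2
        series = a * np.sin(2 * np.pi * 10.0 * spec.frame_times + phi)
        d = fourier_descriptors(series, spec, from_series=True)
        k = spec.frequencies.index(10.0)
        assert abs(d.amplitudes[k] - a) < 1e-12
        assert abs(d.phases[k] - phi) < 1e-12
        others = np.delete(d.amplitudes, k)
        assert np.all(others < 1e-12)

    def test_energy_matches_series_variance(self, spec, rng):
        # Parseval under the amplitude convention: var(x) = sum(a^2) / 2
        amps = rng.uniform(0, 1, 11)
        phases = rng.uniform(0, 2 * np.pi, 11)
        raw = synthesize(amps, phases, spec)
        d = fourier_descriptors(raw, spec, from_series=True)
        assert abs(raw.var() - np.sum(d.amplitudes**2) / 2.0) < 1e-12

    def test_length_mismatch_rejected(self, spec):
        with pytest.raises(ValueError, match="length"):
            fourier_descriptors(np.zeros(23), spec, from_series=True)

    def test_round_trip_through_waveform(self, spec, rng):
        sf = make_sampling_function(spec, rng)
        d1 = fourier_descriptors(sf)
        wave = synthesize(d1.amplitudes, d1.phases, spec)
        d2 = fourier_descriptors(wave, spec, from_series=True)
        assert np.allclose(d2.amplitudes, d1.amplitudes, atol=1e-10)
        assert np.allclose(wrap_phase(d2.phases - d1.phases), 0.0, atol=1e-10)


def test_sampling_function_validation(spec):
    with pytest.raises(ValueError):
        SamplingFunction(np.zeros(23), np.zeros(11), np.zeros(11), spec=spec)
    with pytest.raises(ValueError):
        SamplingFunction(np.zeros(24), np.zeros(10), np.zeros(10), spec=spec)
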