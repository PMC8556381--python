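"""Classification images: raw subtraction, bootstrap Z, group and contrast."""

import numpy as np
import pytest

from tempsamp import (
    ClassificationImage,
    ExperimentLog,
    bootstrap_z,
    contrast_classification_image,
    group_pipeline,
    make_class_library,
    raw_classification_image,
    simulate_dataset,
    smooth_field,
    trial_features,
)
from tempsamp.observers import ObserverModel


def make_log(values, accuracy, spec, pid="p", cls="c"):
    n, k = values.shape
    rng = np.random.default_rng(0)
    return ExperimentLog(
        pid, cls, values,
        rng.random((n, 11)), rng.random((n, 11)),
        np.asarray(accuracy), np.full(n, 64), spec,
    )


def bruteforce_mean_difference(x, acc):
    """Independent oracle: elementwise loops, no vectorized reuse."""
    nc = sum(int(a) for a in acc)
    ne = len(acc) - nc
    out = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        sc = sum(x[i, j] for i in range(len(acc)) if acc[i] == 1)
        se = sum(x[i, j] for i in range(len(acc)) if acc[i] == 0)
        out[j] = sc / nc - se / ne
    return out


class TestRawImage:
    def test_identical_correct_and_error_sets_cancel(self, spec, rng):
        v = rng.random((6, 24)) * 0.5
        values = np.vstack([v, v])
        log = make_log(values, [1] * 6 + [0] * 6, spec)
        assert np.allclose(raw_classification_image(log, "time").values, 0.0)

    def test_singleton_difference(self, spec, rng):
        values = rng.random((2, 24)) * 0.5
        log = make_log(values, [1, 0], spec)
        ci = raw_classification_image(log, "time")
        assert np.allclose(ci.values, values[0] - values[1], atol=1e-15)

    @pytest.mark.parametrize("domain", ["time", "fourier", "tf"])
    def test_matches_bruteforce_oracle(self, spec, rng, domain):
        values = rng.random((40, 24)) * 0.5
        acc = rng.integers(0, 2, 40)
        acc[:2] = [0, 1]
        log = make_log(values, acc, spec)
        ci = raw_classification_image(log, domain)
        oracle = bruteforce_mean_difference(trial_features(log, domain), acc)
        assert np.allclose(ci.values.ravel(), oracle, atol=1e-12)

    def test_one_sided_log_rejected(self, spec, rng):
        log = make_log(rng.random((5, 24)), [1] * 5, spec)
        with pytest.raises(ValueError, match="correct and .* error"):
            raw_classification_image(log, "time")


class TestBootstrapZ:
    def test_reproducible_given_seed(self, spec, rng):
        log = make_log(rng.random((50, 24)) * 0.5, rng.integers(0, 2, 50), spec)
        a = bootstrap_z(log, "time", 200, np.random.default_rng(1))
        b = bootstrap_z(log, "time", 200, np.random.default_rng(1))
        assert np.array_equal(a.values, b.values)

    def test_carries_bootstrap_metadata(self, spec, rng):
        log = make_log(rng.random((30, 24)) * 0.5, rng.integers(0, 2, 30), spec)
        z = bootstrap_z(log, "time", 150, rng)
        assert z.scale == "z" and z.meta["n_boot"] == 150

    def test_degenerate_feature_reported(self, spec, rng):
        values = rng.random((30, 24)) * 0.5
        values[:, 7] = 0.3  # constant column: no bootstrap variance
        log = make_log(values, rng.integers(0, 2, 30), spec)
        with pytest.raises(ValueError, match=r"\[7\]"):
            bootstrap_z(log, "time", 100, rng)

    def test_small_n_boot_rejected(self, spec, rng):
        log = make_log(rng.random((10, 24)), [1] * 5 + [0] * 5, spec)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_z(log, "time", 1, rng)


class TestSmoothing:
    @pytest.mark.parametrize("domain,shape", [("time", (24,)), ("fourier", (22,)), ("tf", (11, 24))])
    def test_mean_preserved(self, domain, shape, rng):
        x = rng.standard_normal(shape)
        for fwhm in (0.6, 1.5, 3.0):
            assert abs(smooth_field(x, fwhm, domain).mean() - x.mean()) < 1e-10


class TestGroupPipeline:
    def test_planted_template_detected_with_correct_sign(self, spec):
        rng = np.random.default_rng(42)
        tmpl = np.zeros(24)
        tmpl[6:10] = 1.0
        tmpl /= np.linalg.norm(tmpl)
        models = [
            ObserverModel(template=tmpl, gain=12.0, participant_id=f"o{i}")
            for i in range(8)
        ]
        cis = [
            bootstrap_z(simulate_dataset(m, 600, spec, rng), "time", 500, rng)
            for m in models
        ]
        res = group_pipeline(cis)
        pos = np.flatnonzero(res.mask > 0)
        assert pos.size > 0
        assert set(pos) <= set(range(5, 11))  # at the template's support
        assert np.all(res.mask[np.abs(tmpl) < 1e-12][2:-2] <= 0)

    def test_mixed_domains_rejected(self, spec, rng):
        a = ClassificationImage("time", np.zeros(24))
        b = ClassificationImage("fourier", np.zeros(22))
        with pytest.raises(ValueError, match="mix"):
            group_pipeline([a, b])

    def test_mask_matches_threshold_rule(self, spec, rng):
        log = make_log(rng.random((60, 24)) * 0.5, rng.integers(0, 2, 60), spec)
        res = group_pipeline([bootstrap_z(log, "time", 200, rng)])
        assert np.array_equal(res.mask == 1, res.values > res.z_crit)
        assert np.array_equal(res.mask == -1, res.values < -res.z_crit)


class TestContrast:
    def _zimages(self, spec, rng, template, n_obs, cls):
        models = [
            ObserverModel(template=template, gain=12.0,
                          participant_id=f"{cls}{i}", stimulus_class=cls)
            for i in range(n_obs)
        ]
        return [
            bootstrap_z(simulate_dataset(m, 400, spec, rng), "time", 300, rng)
            for m in models
        ]

    def test_identical_groups_give_no_signal(self, spec, rng):
        log = make_log(rng.random((60, 24)) * 0.5, rng.integers(0, 2, 60), spec)
        cis = [bootstrap_z(log, "time", 200, rng) for _ in range(3)]
        res = contrast_classification_image(cis, cis, rng=rng, n_boot=200)
        assert np.allclose(res.values, 0.0)
        assert res.n_significant() == (0, 0)

    def test_exact_antisymmetry(self, spec, rng):
        a = self._zimages(spec, rng, np.ones(24) / np.sqrt(24), 3, "a")
        b = self._zimages(spec, rng, -np.ones(24) / np.sqrt(24), 3, "b")
        r1 = contrast_classification_image(a, b, rng=np.random.default_rng(7), n_boot=200)
        r2 = contrast_classification_image(b, a, rng=np.random.default_rng(7), n_boot=200)
        assert np.array_equal(r1.values, -r2.values)
        assert np.array_equal(r1.mask, -r2.mask)
        assert np.array_equal(
            r1.meta["unsmoothed_z"], -r2.meta["unsmoothed_z"]
        )

    def test_disjoint_template_supports_localize_differences(self, spec):
        rng = np.random.default_rng(17)
        ta = np.zeros(24); ta[4:8] = 1.0; ta /= np.linalg.norm(ta)
        tb = np.zeros(24); tb[16:20] = 1.0; tb /= np.linalg.norm(tb)
        a = self._zimages(spec, rng, ta, 6, "a")
        b = self._zimages(spec, rng, tb, 6, "b")
        res = contrast_classification_image(a, b, rng=rng, n_boot=500)
        pos, neg = np.flatnonzero(res.mask > 0), np.flatnonzero(res.mask < 0)
        assert pos.size > 0 and neg.size > 0
        assert set(pos) <= set(range(3, 9))
        assert set(neg) <= set(range(15, 21))

    def test_single_member_group_rejected(self, spec, rng):
        log = make_log(rng.random((30, 24)) * 0.5, rng.integers(0, 2, 30), spec)
        ci = bootstrap_z(log, "time", 100, rng)
        with pytest.raises(ValueError, match="2 images"):
            contrast_classification_image([ci], [ci, ci], rng=rng)
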