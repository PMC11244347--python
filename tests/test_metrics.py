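"""Fusion-quality indicators: analytic cases, oracles, bounds, determinism."""

import warnings

import numpy as np
import pytest

from medfuse import metrics as M


@pytest.fixture(scope="module")
def images():
    rng = np.random.default_rng(42)
    f = rng.uniform(0, 1, (128, 128))
    near = np.clip(f + 0.08 * rng.normal(size=f.shape), 0, 1)
    indep = rng.uniform(0, 1, f.shape)
    return f, near, indep


class TestEntropy:
    def test_constant_image_has_zero_entropy(self):
        assert M.en(np.full((16, 16), 0.5)) == 0.0

    def test_uniform_256_level_image_has_eight_bits(self):
        img = np.arange(256).repeat(4).reshape(32, 32) / 255.0
        assert abs(M.en(img) - 8.0) < 1e-12

    def test_balanced_two_level_image_has_one_bit(self):
        img = np.zeros((16, 16))
        img[:8] = 1.0
        assert abs(M.en(img) - 1.0) < 1e-12

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            M.en(np.zeros((0, 0)))


class TestMutualInformation:
    def test_identical_triple_scores_two(self, images):
        f = images[0]
        assert abs(M.mi(f, f, f) - 2.0) < 1e-12

    def test_independent_images_score_near_zero(self):
        # coarse binning keeps the finite-sample MI bias negligible
        rng = np.random.default_rng(3)
        f = rng.uniform(0, 1, (256, 256))
        a = rng.uniform(0, 1, (256, 256))
        b = rng.uniform(0, 1, (256, 256))
        assert M.mi(f, a, b, bins=32) < 0.05

    def test_symmetric_in_source_swap(self, images):
        f, a, b = images
        assert abs(M.mi(f, a, b) - M.mi(f, b, a)) < 1e-12

    def test_degenerate_image_warns_and_contributes_zero(self, images):
        const = np.full((128, 128), 0.5)
        with pytest.warns(UserWarning):
            v = M.mi(const, const, const)
        assert v == 0.0


class TestSCD:
    def test_sum_of_orthogonal_components_scores_two(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(64, 64))
        b = rng.normal(size=(64, 64))
        a -= a.mean()
        b -= b.mean()
        b -= (a.ravel() @ b.ravel()) / (a.ravel() @ a.ravel()) * a  # exact orthogonality
        assert abs(M.scd(a + b, a, b) - 2.0) < 1e-9

    def test_fused_equal_to_one_source_uses_zero_convention(self, images):
        f, _, b = images
        expected = np.corrcoef((f - b).ravel(), f.ravel())[0, 1]
        assert abs(M.scd(f, f, b) - expected) < 1e-9

    def test_bounded_on_random_triples(self):
        for seed in range(30):
            r = np.random.default_rng(seed)
            v = M.scd(r.uniform(0, 1, (32, 32)), r.uniform(0, 1, (32, 32)),
                      r.uniform(0, 1, (32, 32)))
            assert -2.0 <= v <= 2.0


class TestMSSSIM:
    def test_identical_triple_scores_one(self, images):
        f = images[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert abs(M.ms_ssim_metric(f, f, f) - 1.0) < 1e-9

    def test_small_image_reduces_scales_with_warning(self, images):
        f = images[0][:32, :32]
        with pytest.warns(UserWarning, match="scales"):
            v = M.ms_ssim_metric(f, f, f)
        assert abs(v - 1.0) < 1e-9

    def test_bounded_above_by_one(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = M.ms_ssim_metric(r.uniform(0, 1, (64, 64)),
                                     r.uniform(0, 1, (64, 64)),
                                     r.uniform(0, 1, (64, 64)))
            assert v <= 1.0


class TestEdgeMetrics:
    @pytest.mark.parametrize("metric", [M.qabf, M.qg])
    def test_identical_triple_scores_one(self, images, metric):
        f = images[0]
        assert abs(metric(f, f, f) - 1.0) < 1e-9

    @pytest.mark.parametrize("metric", [M.qabf, M.qg])
    def test_constant_fused_image_scores_near_zero(self, images, metric):
        f = images[0]
        assert metric(np.full_like(f, 0.5), f, f) < 0.05

    def test_edge_free_sources_warn_and_score_zero(self):
        flat = np.full((32, 32), 0.25)
        with pytest.warns(UserWarning):
            assert M.qabf(np.full((32, 32), 0.5), flat, flat) == 0.0

    def test_swap_invariance(self, images):
        f, a, b = images
        assert abs(M.qabf(f, a, b) - M.qabf(f, b, a)) < 1e-12

    def test_qg_decreases_as_fused_blends_toward_noise(self):
        rng = np.random.default_rng(9)
        src = rng.uniform(0, 1, (64, 64))
        noise = rng.uniform(0, 1, (64, 64))
        scores = [M.qg((1 - t) * src + t * noise, src, src) for t in (0.0, 0.3, 0.7)]
        assert scores[0] > scores[1] > scores[2]

    @pytest.mark.parametrize("metric", [M.qabf, M.qg])
    def test_bounded_in_unit_interval(self, images, metric):
        f, a, b = images
        assert 0.0 <= metric(f, a, b) <= 1.0


class TestNCIE:
    def test_independent_triple_sits_at_theoretical_floor(self):
        rng = np.random.default_rng(1)
        imgs = [rng.uniform(0, 1, (128, 128)) for _ in range(3)]
        floor = 1.0 - np.log(3) / np.log(16)
        assert abs(M.ncie(*imgs, bins=16) - floor) < 0.02

    def test_correlation_raises_the_score(self, images):
        f, near, indep = images
        assert M.ncie(f, near, near) > M.ncie(f, indep, np.roll(indep, 1000))

    def test_bounded_in_unit_interval(self, images):
        f, a, b = images
        assert 0.0 <= M.ncie(f, a, b) <= 1.0


class TestVIF:
    def test_identical_signal_has_unit_fidelity(self, images):
        f = images[0]
        assert abs(M.vif(f, f, f) - 1.0) < 1e-6

    def test_noisy_fused_image_loses_fidelity(self, images):
        f, near, _ = images
        assert M.vif(near, f, f) < 1.0

    def test_nonnegative(self, images):
        f, a, b = images
        assert M.vif(f, a, b) >= 0.0


class TestQTE:
    def test_tsallis_limit_brackets_shannon_value(self, images):
        f, near, _ = images
        lo = M.tsallis_mi(f, near, 0.999, bins=64)
        hi = M.tsallis_mi(f, near, 1.001, bins=64)
        sh = M.shannon_mi(f, near, bins=64, base=np.e)
        assert min(lo, hi) <= sh <= max(lo, hi)
        assert abs(lo - sh) < 0.01 and abs(hi - sh) < 0.01

    def test_exact_q_equal_one_falls_back_to_shannon(self, images):
        f, near, _ = images
        assert abs(M.tsallis_mi(f, near, 1.0) - M.shannon_mi(f, near, base=np.e)) < 1e-12

    def test_independent_images_score_near_zero_nonnegative(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (128, 128))
        b = rng.uniform(0, 1, (128, 128))
        v = M.tsallis_mi(a, b, 1.85, bins=16)
        assert 0.0 <= v < 0.05


class TestEvaluateAll:
    def test_report_has_exactly_nine_metric_fields(self, images):
        f, a, b = images
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = M.evaluate_all(f, a, b)
        assert len(M.MetricReport.METRIC_FIELDS) == 9
        assert set(r.values()) == set(M.MetricReport.METRIC_FIELDS)
        assert all(np.isfinite(v) for v in r.values().values())

    def test_identical_triple_hits_ideal_values(self, images):
        f = images[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = M.evaluate_all(f, f, f)
        assert abs(r.ms_ssim - 1.0) < 1e-6
        assert abs(r.qabf - 1.0) < 1e-6
        assert abs(r.qg - 1.0) < 1e-6

    def test_deterministic_across_calls(self, images):
        f, a, b = images
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = M.evaluate_all(f, a, b)
            r2 = M.evaluate_all(f, a, b)
        assert r1.values() == r2.values()

    def test_shape_mismatch_raises(self, images):
        f, a, _ = images
        with pytest.raises(ValueError):
            M.evaluate_all(f, a, a[:64, :64])

    def test_config_is_echoed(self, images):
        f, a, b = images
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = M.evaluate_all(f, a, b, M.MetricConfig(tsallis_q=1.5))
        assert r.config["tsallis_q"] == 1.5
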