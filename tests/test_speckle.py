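import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter, rotate

from speckgen.speckle import (
    AttentionParams,
    PolarGridSpec,
    SpeckleBankParams,
    apply_speckle,
    cartesian_to_polar,
    channel_attention,
    estimate_speckle_size,
    init_attention_params,
    make_spectral_window,
    polar_to_cartesian,
    sample_phase_field,
    speckle_bank_forward,
    speckle_conv_oracle,
    spectral_window_profile,
)


class TestSpectralWindow:
    def test_full_spectrum_is_all_ones(self):
        win = make_spectral_window(32, 32, 32, softness=0.0)
        assert np.array_equal(win.mask, np.ones((32, 32)))

    def test_d_one_keeps_only_dc(self):
        win = make_spectral_window(1, 32, 32, softness=0.0)
        expected = np.zeros((32, 32))
        expected[16, 16] = 1.0
        assert np.array_equal(win.mask, expected)

    def test_soft_window_matches_per_bin_evaluation(self):
        d, softness = 8.5, 0.5
        win = make_spectral_window(d, 32, 32, softness)
        # brute-force: product of per-axis logistic edges at every bin
        for i in range(32):
            for j in range(32):
                ki, kj = i - 16, j - 16
                ref = (1 / (1 + np.exp(-(d / 2 - abs(ki)) / softness))) * (
                    1 / (1 + np.exp(-(d / 2 - abs(kj)) / softness))
                )
                assert win.mask[i, j] == pytest.approx(ref, abs=1e-12)

    def test_rotation_symmetry_about_dc(self):
        for d, soft in [(7, 0.0), (12, 0.0), (9.3, 0.7)]:
            win = make_spectral_window(d, 32, 32, soft)
            native = np.fft.ifftshift(win.mask)
            rotated = native[(-np.arange(32)) % 32][:, (-np.arange(32)) % 32]
            assert np.allclose(native, rotated)

    def test_soft_limit_recovers_hard_window(self):
        hard = spectral_window_profile(8.0, np.arange(-8, 8, dtype=float), 0.0)
        soft = spectral_window_profile(8.0, np.arange(-8, 8, dtype=float), 1e-6)
        off_edge = np.abs(np.arange(-8, 8)) != 4
        assert np.allclose(hard[off_edge], soft[off_edge], atol=1e-9)

    @pytest.mark.parametrize("d", [0.0, -1.0, 33.0])
    def test_invalid_d_rejected(self, d):
        with pytest.raises(ValueError):
            make_spectral_window(d, 32, 32)

    def test_negative_softness_rejected(self):
        with pytest.raises(ValueError):
            make_spectral_window(8, 32, 32, softness=-0.1)


class TestPhaseField:
    def test_deterministic(self):
        a = sample_phase_field(32, 32, seed=7)
        b = sample_phase_field(32, 32, seed=7)
        assert np.array_equal(a, b)

    def test_range(self):
        p = sample_phase_field(2, 2, seed=0)
        assert np.all((p >= 0) & (p < 2 * np.pi))

    def test_uniformity_cos_mean(self):
        p = sample_phase_field(64, 64, seed=1)
        # mean of cos(U[0,2pi)) is 0 with variance 1/2 per sample
        se = np.sqrt(0.5 / p.size)
        assert abs(np.cos(p).mean()) < 3 * se

    def test_bad_dims(self):
        with pytest.raises(ValueError):
            sample_phase_field(0, 4, seed=0)


class TestApplySpeckle:
    def test_zero_image_zero_output(self):
        win = make_spectral_window(8, 32, 32)
        out = apply_speckle(np.zeros((32, 32)), win, sample_phase_field(32, 32, 1))
        assert np.allclose(out, 0.0)

    def test_full_spectrum_identity(self, rng):
        img = rng.random((32, 32))
        win = make_spectral_window(32, 32, 32, softness=0.0)
        out = apply_speckle(img, win, sample_phase_field(32, 32, 3))
        assert np.allclose(out, img, atol=1e-12)

    def test_matches_conv_oracle(self, rng):
        img = rng.random((16, 16))
        win = make_spectral_window(8, 16, 16)
        phases = sample_phase_field(16, 16, 5)
        fast = apply_speckle(img, win, phases)
        slow = speckle_conv_oracle(img, win, phases)
        assert np.allclose(fast, slow, rtol=1e-6, atol=1e-9)

    def test_nonnegative_output(self, rng):
        img = rng.standard_normal((16, 16))
        win = make_spectral_window(6, 16, 16, softness=0.3)
        out = apply_speckle(img, win, sample_phase_field(16, 16, 2))
        assert np.all(out >= 0)

    def test_shape_mismatch(self, rng):
        win = make_spectral_window(8, 16, 16)
        with pytest.raises(ValueError):
            apply_speckle(rng.random((8, 8)), win, sample_phase_field(16, 16, 1))


class TestConvOracle:
    def test_zero_image(self):
        win = make_spectral_window(4, 8, 8)
        out = speckle_conv_oracle(
            np.zeros((8, 8)), win, sample_phase_field(8, 8, 0)
        )
        assert np.allclose(out, 0.0)

    def test_delta_image_reproduces_kernel(self):
        # a unit impulse picks out the (shifted) window kernel magnitude
        img = np.zeros((8, 8))
        img[3, 5] = 1.0
        win = make_spectral_window(4, 8, 8)
        phases = np.zeros((8, 8))
        out = speckle_conv_oracle(img, win, phases)
        mask = np.fft.ifftshift(win.mask)
        idft_mat = np.exp(2j * np.pi * np.outer(np.arange(8), np.arange(8)) / 8) / 8
        kernel = idft_mat @ mask.astype(complex) @ idft_mat.T
        expected = np.abs(np.roll(np.roll(kernel, 3, axis=0), 5, axis=1))
        assert np.allclose(out, expected, atol=1e-12)

    def test_refuses_large_images(self):
        win = make_spectral_window(8, 128, 128)
        with pytest.raises(ValueError, match="oracle"):
            speckle_conv_oracle(
                np.ones((128, 128)), win, np.zeros((128, 128))
            )

    @settings(max_examples=10, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        d=st.floats(1.0, 12.0),
        soft=st.sampled_from([0.0, 0.3, 1.0]),
    )
    def test_fft_equivalence_property(self, seed, d, soft):
        rng = np.random.default_rng(seed)
        img = rng.random((12, 12))
        win = make_spectral_window(d, 12, 12, soft)
        phases = sample_phase_field(12, 12, seed)
        assert np.allclose(
            apply_speckle(img, win, phases),
            speckle_conv_oracle(img, win, phases),
            rtol=1e-6,
            atol=1e-9,
        )


class TestPolarWarp:
    def test_constant_image_constant_polar(self):
        spec = PolarGridSpec.default(64, 64)
        pol = cartesian_to_polar(np.full((64, 64), 0.7), spec)
        # outermost ring touches the grid border where samples fall outside
        assert np.allclose(pol[:-1], 0.7, atol=1e-9)

    def test_rotation_becomes_angular_shift(self, rng):
        im = gaussian_filter(rng.random((128, 128)), 3)
        spec = PolarGridSpec.default(128, 128)
        p0 = cartesian_to_polar(im, spec)
        deg = 40.0
        p1 = cartesian_to_polar(rotate(im, deg, reshape=False, order=1), spec)
        scores = [
            np.sum(p0 * np.roll(p1, s, axis=1)) for s in range(spec.n_angles)
        ]
        best = int(np.argmax(scores))
        expected = deg / 360.0 * spec.n_angles
        assert abs(best - expected) <= 2

    def test_bright_pixel_lands_in_expected_bin(self):
        im = np.zeros((65, 65))
        spec = PolarGridSpec.default(65, 65)
        radius, angle = 20.0, np.pi / 4
        r = int(round(spec.center_row + radius * np.sin(angle)))
        c = int(round(spec.center_col + radius * np.cos(angle)))
        im[r, c] = 1.0
        pol = cartesian_to_polar(im, spec)
        pr, pa = np.unravel_index(np.argmax(pol), pol.shape)
        assert abs(pr - radius * (spec.n_radii - 1) / spec.max_radius) <= 2
        assert abs(pa - angle * spec.n_angles / (2 * np.pi)) <= 2

    def test_constant_polar_fills_disc(self):
        spec = PolarGridSpec.default(64, 64)
        cart = polar_to_cartesian(np.ones((64, 64)), spec, 64, 64)
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        rho = np.hypot(rr - spec.center_row, cc - spec.center_col)
        assert np.allclose(cart[rho <= spec.max_radius - 1.0], 1.0, atol=1e-9)
        assert np.allclose(cart[rho > spec.max_radius], 0.0)

    def test_round_trip_psnr(self, rng):
        im = gaussian_filter(rng.random((64, 64)), 4)
        spec = PolarGridSpec.default(64, 64)
        back = polar_to_cartesian(cartesian_to_polar(im, spec), spec, 64, 64)
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        inside = np.hypot(rr - spec.center_row, cc - spec.center_col) <= (
            0.9 * spec.max_radius
        )
        mse = np.mean((back[inside] - im[inside]) ** 2)
        assert 10 * np.log10(1.0 / mse) >= 30.0

    def test_radial_function_gives_radial_symmetry(self):
        spec = PolarGridSpec.default(64, 64)
        polar = np.repeat(
            np.linspace(0, 1, spec.n_radii)[:, None], spec.n_angles, axis=1
        )
        cart = polar_to_cartesian(polar, spec, 64, 64)
        assert np.allclose(cart, cart[::-1, :], atol=0.05)
        assert np.allclose(cart, cart[:, ::-1], atol=0.05)

    def test_max_radius_bound_enforced(self):
        spec = PolarGridSpec(31.5, 31.5, 64, 64, max_radius=60.0)
        with pytest.raises(ValueError):
            cartesian_to_polar(np.zeros((64, 64)), spec)


class TestChannelAttention:
    def test_zero_params_give_half(self, rng):
        params = AttentionParams(
            w1=np.zeros((8, 8)), b1=np.zeros(8), w2=np.zeros((8, 32)), b2=np.zeros(32)
        )
        coeff = channel_attention(rng.random((3, 8, 4, 4)), params)
        assert np.allclose(coeff, 0.5)

    def test_matches_hand_composition(self, rng):
        params = init_attention_params(seed=3)
        x = rng.random((1, 8, 2, 2))
        pooled = x.sum(axis=(2, 3))
        hidden = np.maximum(pooled @ params.w1 + params.b1, 0.0)
        expected = 1.0 / (1.0 + np.exp(-(hidden @ params.w2 + params.b2)))
        assert np.allclose(channel_attention(x, params), expected)

    def test_open_interval(self, rng):
        params = init_attention_params(seed=1)
        coeff = channel_attention(10 * rng.standard_normal((4, 8, 3, 3)), params)
        assert np.all((coeff > 0) & (coeff < 1))

    def test_wrong_channel_count(self, rng):
        with pytest.raises(ValueError):
            channel_attention(rng.random((1, 4, 2, 2)), init_attention_params())


class TestSpeckleBank:
    @pytest.fixture
    def params(self):
        return SpeckleBankParams(
            window_sizes=[6.0, 8.0, 12.0, 16.0],
            attention=init_attention_params(seed=0),
            softness=0.0,
        )

    def test_zero_input_zero_output(self, params):
        out = speckle_bank_forward(np.zeros((2, 8, 16, 16)), params, seed=0)
        assert out.shape == (2, 32, 16, 16)
        assert np.allclose(out, 0.0)

    def test_unit_attention_recovers_apply_speckle(self, params, rng):
        x = np.zeros((1, 8, 16, 16))
        x[0, 3] = rng.random((16, 16))
        coeff = np.ones((1, 32))
        out = speckle_bank_forward(x, params, seed=42, attention_override=coeff)
        # reproduce the bank's internal phase stream
        stream = np.random.default_rng(42)
        for c in range(8):
            for s, d in enumerate(params.window_sizes):
                phases = stream.uniform(0, 2 * np.pi, (16, 16))
                win = make_spectral_window(d, 16, 16, params.softness)
                expected = apply_speckle(x[0, c], win, phases)
                assert np.allclose(out[0, c * 4 + s], expected)

    def test_seeded_reproducible_fresh_differs(self, params, rng):
        x = rng.random((1, 8, 16, 16))
        a = speckle_bank_forward(x, params, seed=5)
        b = speckle_bank_forward(x, params, seed=5)
        c = speckle_bank_forward(x, params, seed=6)
        assert np.array_equal(a, b)
        assert np.mean(a != c) > 0.5

    def test_channel_count_mismatch(self, params, rng):
        with pytest.raises(ValueError):
            speckle_bank_forward(rng.random((1, 4, 16, 16)), params)

    def test_polar_pipeline_runs(self, params, rng):
        params.polar_spec = PolarGridSpec.default(16, 16)
        out = speckle_bank_forward(rng.random((1, 8, 16, 16)), params, seed=1)
        assert out.shape == (1, 32, 16, 16)
        assert np.all(np.isfinite(out))


class TestSpeckleSize:
    def test_white_noise_is_narrow(self, rng):
        fwhm = estimate_speckle_size(rng.random((256, 256)))
        assert 1.0 <= fwhm <= 2.0

    def test_smaller_window_larger_speckle(self):
        means = {}
        for d in (8, 32):
            vals = []
            for s in range(10):
                win = make_spectral_window(d, 256, 256)
                img = apply_speckle(
                    np.ones((256, 256)), win, sample_phase_field(256, 256, 50 + s)
                )
                vals.append(estimate_speckle_size(img))
            means[d] = np.mean(vals)
        assert means[8] > means[32]

    def test_smoothing_widens(self, rng):
        img = rng.random((128, 128))
        assert estimate_speckle_size(gaussian_filter(img, 3)) > estimate_speckle_size(
            img
        )

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_speckle_size(np.full((32, 32), 0.5))
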