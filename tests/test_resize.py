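import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scintiresize import (
    CountImage,
    apply_global_scale,
    downsample_linear,
    downsample_window_sum,
    thin_poisson,
    upsample_corrected,
    upsample_linear,
)


def bilinear_oracle(values: np.ndarray, out_shape):
    """Brute-force separable bilinear sampling at half-pixel-centre coords."""
    M, N = values.shape
    out = np.zeros(out_shape)
    for i in range(out_shape[0]):
        for j in range(out_shape[1]):
            r = min(max((i + 0.5) * M / out_shape[0] - 0.5, 0.0), M - 1.0)
            c = min(max((j + 0.5) * N / out_shape[1] - 0.5, 0.0), N - 1.0)
            r0 = min(int(np.floor(r)), M - 2) if M > 1 else 0
            c0 = min(int(np.floor(c)), N - 2) if N > 1 else 0
            r1, c1 = min(r0 + 1, M - 1), min(c0 + 1, N - 1)
            dr, dc = r - r0, c - c0
            out[i, j] = (
                values[r0, c0] * (1 - dr) * (1 - dc)
                + values[r1, c0] * dr * (1 - dc)
                + values[r0, c1] * (1 - dr) * dc
                + values[r1, c1] * dr * dc
            )
    return out


class TestThinning:
    def test_p_one_is_identity(self, rng):
        img = CountImage(rng.poisson(20, (8, 8)))
        out = thin_poisson(img, 1.0, rng)
        assert np.array_equal(out.pixels, img.pixels)

    def test_p_zero_gives_empty_image(self, rng):
        img = CountImage(rng.poisson(20, (8, 8)))
        assert thin_poisson(img, 0.0, rng).total_counts == 0

    def test_output_never_exceeds_input(self, rng):
        img = CountImage(rng.poisson(9, (16, 16)))
        out = thin_poisson(img, 0.3, rng)
        assert np.all(out.pixels <= img.pixels)

    def test_binomial_moments(self, rng):
        # 1e5 independent pixels with n=100, p=0.25: mean ~ np, var ~ np(1-p)
        n_draws, n, p = 100_000, 100, 0.25
        img = CountImage(np.full((250, 400), n))
        draws = thin_poisson(img, p, rng).pixels.astype(float)
        mean, var = n * p, n * p * (1 - p)
        se_mean = np.sqrt(var / n_draws)
        # SE of the sample variance of a binomial: sqrt((mu4 - var^2)/n)
        q = 1 - p
        mu4 = n * p * q * (1 + (3 * n - 6) * p * q)
        se_var = np.sqrt((mu4 - var**2) / n_draws)
        assert abs(draws.mean() - mean) < 5 * se_mean
        assert abs(draws.var() - var) < 5 * se_var

    def test_thinning_composes_multiplicatively(self, rng):
        # thin(thin(x, p), q) ~ thin(x, p*q): compare moments over 1e5 draws
        n_draws, n, p, q = 100_000, 60, 0.6, 0.5
        img = CountImage(np.full((250, 400), n))
        two_step = thin_poisson(thin_poisson(img, p, rng), q, rng).pixels.astype(float)
        pq = p * q
        mean, var = n * pq, n * pq * (1 - pq)
        assert abs(two_step.mean() - mean) < 5 * np.sqrt(var / n_draws)
        mu4 = n * pq * (1 - pq) * (1 + (3 * n - 6) * pq * (1 - pq))
        assert abs(two_step.var() - var) < 5 * np.sqrt((mu4 - var**2) / n_draws)

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_invalid_probability_rejected(self, rng, p):
        with pytest.raises(ValueError):
            thin_poisson(CountImage(np.ones((2, 2), int)), p, rng)


class TestUpsampleLinear:
    def test_worked_example_total_quadruples(self):
        # a 2x2 image totaling 134 upsamples (f=2) to a 4x4 totaling exactly 536
        img = CountImage(np.array([[50, 30], [24, 30]]))
        assert img.total_counts == 134
        up = upsample_linear(img, 2)
        assert up.shape == (4, 4)
        assert up.total == 536.0

    @pytest.mark.parametrize("f", [2, 4])
    def test_constant_image_stays_constant(self, f):
        up = upsample_linear(CountImage(np.full((3, 3), 7)), f)
        assert np.allclose(up.values, 7.0)

    @pytest.mark.parametrize("f", [2, 4])
    def test_matches_separable_oracle_on_ramp(self, f):
        ramp = np.arange(9).reshape(3, 3).astype(np.int64)
        up = upsample_linear(CountImage(ramp), f)
        assert np.allclose(up.values, bilinear_oracle(ramp, (3 * f, 3 * f)), atol=1e-12)

    def test_spacing_divided_by_factor(self):
        up = upsample_linear(CountImage(np.ones((2, 2), int), 6.59), 4)
        assert up.pixel_spacing_mm == pytest.approx(6.59 / 4)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.integers(2, 8),
        st.integers(2, 8),
        st.sampled_from([2, 4]),
        st.integers(0, 2**31 - 1),
    )
    def test_total_scales_by_exactly_f_squared(self, m, n, f, seed):
        px = np.random.default_rng(seed).poisson(15, (m, n))
        up = upsample_linear(CountImage(px), f)
        assert up.total == pytest.approx(px.sum() * f * f, rel=1e-12)


class TestGlobalScale:
    def test_one_sixteenth_restores_total_after_4x_upsampling(self, rng):
        img = CountImage(rng.poisson(30, (8, 8)))
        up = apply_global_scale(upsample_linear(img, 4), 1 / 16)
        assert up.total == pytest.approx(img.total_counts, rel=1e-12)

    def test_identity_and_linearity(self, rng):
        from scintiresize import RealImage

        img = RealImage(rng.random((5, 5)))
        assert np.array_equal(apply_global_scale(img, 1.0).values, img.values)
        assert apply_global_scale(img, 0.3).total == pytest.approx(
            0.3 * img.total, rel=1e-12
        )

    def test_nonpositive_scale_rejected(self, rng):
        from scintiresize import RealImage

        with pytest.raises(ValueError):
            apply_global_scale(RealImage(rng.random((2, 2))), 0.0)


class TestUpsampleCorrected:
    def test_zero_image_maps_to_zero(self, rng):
        out = upsample_corrected(CountImage(np.zeros((4, 4), int)), 2, rng)
        assert out.total_counts == 0 and out.shape == (8, 8)

    def test_expected_total_preserved_within_one_percent(self, rng):
        # thinning with p = 1/f**2 undoes the f**2 count inflation on average
        img = CountImage(np.random.default_rng(42).poisson(40, (16, 16)))
        totals = [
            upsample_corrected(img, 4, rng).total_counts for _ in range(1000)
        ]
        assert abs(np.mean(totals) - img.total_counts) < 0.01 * img.total_counts

    def test_binomial_dispersion_of_output_pixels(self, rng):
        # repeat-dispersion (var/mean) of each output pixel ~ 1 - p = 15/16
        img = CountImage(np.random.default_rng(7).poisson(200, (8, 8)))
        reps = np.stack(
            [upsample_corrected(img, 4, rng).pixels for _ in range(2000)]
        ).astype(float)
        mean = reps.mean(axis=0)
        keep = mean > 1.0  # dispersion ill-estimated on near-empty pixels
        disp = reps.var(axis=0)[keep] / mean[keep]
        # SE of var/mean ratio for binomial repeats ~ sqrt(2/n) to first order
        assert abs(disp.mean() - 15 / 16) < 5 * np.sqrt(2 / 2000 / keep.sum())

    def test_output_is_integer_count_image(self, rng):
        out = upsample_corrected(CountImage(rng.poisson(25, (6, 6))), 2, rng)
        assert np.issubdtype(out.pixels.dtype, np.integer)
        assert out.pixels.min() >= 0


class TestDownsampleLinear:
    def test_worked_example_total_quartered(self):
        # 4x4 totaling 318 -> 2x2 with total exactly 79.5 (reported ~80)
        px = np.array(
            [[35, 28, 11, 7], [30, 31, 9, 12], [25, 22, 14, 10], [24, 36, 12, 12]]
        )
        img = CountImage(px)
        assert img.total_counts == 318
        down = downsample_linear(img, 2)
        assert down.total == 79.5

    def test_rescale_restores_source_total_for_factor_two(self, rng):
        img = CountImage(rng.poisson(20, (8, 8)))
        down = downsample_linear(img, 2, rescale=True)
        assert down.total == pytest.approx(img.total_counts, rel=1e-12)

    def test_factor_two_is_exact_block_mean(self, rng):
        img = CountImage(rng.poisson(14, (6, 6)))
        down = downsample_linear(img, 2)
        blocks = img.pixels.reshape(3, 2, 3, 2).mean(axis=(1, 3))
        assert np.array_equal(down.values, blocks)

    def test_factor_four_matches_bilinear_oracle(self, rng):
        px = rng.poisson(22, (8, 8))
        down = downsample_linear(CountImage(px), 4)
        assert np.allclose(down.values, bilinear_oracle(px, (2, 2)), atol=1e-12)

    def test_factor_four_uses_central_window_only(self):
        # pixels outside the central 2x2 of each 4x4 block are ignored
        px = np.zeros((4, 4), dtype=np.int64)
        px[0, 0] = 1000  # corner pixel, outside the central window
        assert downsample_linear(CountImage(px), 4).values[0, 0] == 0.0
        px2 = np.zeros((4, 4), dtype=np.int64)
        px2[1, 1] = 100  # central pixel, fully weighted
        assert downsample_linear(CountImage(px2), 4).values[0, 0] == 25.0

    def test_nondivisible_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            downsample_linear(CountImage(rng.poisson(5, (6, 6))), 4)


class TestDownsampleWindowSum:
    def test_constant_blocks_sum_exactly(self):
        down = downsample_window_sum(CountImage(np.ones((4, 4), int)), 2)
        assert np.array_equal(down.pixels, np.full((2, 2), 4))
        assert down.total_counts == 16

    def test_matches_double_loop_block_sum(self, rng):
        px = rng.integers(0, 50, (8, 8))
        down = downsample_window_sum(CountImage(px), 4)
        oracle = np.zeros((2, 2), dtype=np.int64)
        for i in range(2):
            for j in range(2):
                for a in range(4):
                    for b in range(4):
                        oracle[i, j] += px[4 * i + a, 4 * j + b]
        assert np.array_equal(down.pixels, oracle)

    def test_spacing_multiplied_by_factor(self, rng):
        down = downsample_window_sum(CountImage(rng.poisson(5, (4, 4)), 1.64), 2)
        assert down.pixel_spacing_mm == pytest.approx(3.28)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_conserves_total_counts_exactly(self, m, n, seed):
        px = np.random.default_rng(seed).integers(0, 200, (4 * m, 4 * n))
        img = CountImage(px)
        assert downsample_window_sum(img, 2).total_counts == img.total_counts
        assert downsample_window_sum(img, 4).total_counts == img.total_counts

    def test_factor_four_equals_nested_factor_two(self, rng):
        img = CountImage(rng.integers(0, 99, (16, 16)))
        once = downsample_window_sum(img, 4)
        twice = downsample_window_sum(downsample_window_sum(img, 2), 2)
        assert np.array_equal(once.pixels, twice.pixels)

    def test_factor_two_equals_rescaled_linear_downsample(self, rng):
        # the stated equivalence: f^2 * bilinear(f=2) == 2x2 block sum, exactly
        img = CountImage(rng.integers(0, 99, (10, 10)))
        lin = downsample_linear(img, 2, rescale=True)
        ws = downsample_window_sum(img, 2)
        assert np.array_equal(lin.values, ws.pixels.astype(float))
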