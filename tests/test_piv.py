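import numpy as np
import pytest

from aaapiv.geometry import IdealizedAAAGeometry, bulge_radius, lumen_mask
from aaapiv.piv import (
    PreprocessConfig,
    SegmentationError,
    ValidationConfig,
    VectorField,
    delta_deformation,
    piv_multipass,
    preprocess,
    segment_wall,
    validate_vectors,
    window_grid,
)
from aaapiv.synth import BackgroundModel, CameraModel, IlluminationConfig, render_pair, seed_particles

SHAPE = (256, 320)
SCALE = 24.6
WINDOW = (0.0, SHAPE[1] / SCALE)
CAMERA = CameraModel(shape=SHAPE, scale=SCALE)
QUIET = BackgroundModel(offset=0.0, gradient=0.0, read_noise_sd=0.0,
                        poisson=False)


def shifted_pair(shift_px=(0.0, 0.0), seed=1, shape=SHAPE, noise=False):
    """Rigid-shift double exposure of a random tracer pattern."""
    u = shift_px[0] / SCALE * 1e-3 / 400e-6
    v = shift_px[1] / SCALE * 1e-3 / 400e-6

    def sampler(x, y, z, t):
        x = np.asarray(x, float)
        return np.full_like(x, u), np.full_like(x, v)

    mask = np.ones(shape, bool)
    particles = seed_particles(mask, WINDOW, SCALE, 8.0, seed=seed)
    pair = render_pair(
        particles, CameraModel(shape=shape, scale=SCALE),
        IlluminationConfig.from_label("C4"), sampler, 0.0, WINDOW, shape,
        background=None if noise else QUIET, seed=seed,
    )
    return pair.frame_a.astype(float), pair.frame_b.astype(float)


def synthetic_field(rng, shape=(20, 30), base=5.0, noise=0.05):
    u = base + rng.normal(0, noise, shape)
    v = rng.normal(0, noise, shape)
    return VectorField(
        x_px=np.arange(shape[1]) * 16.0 + 16,
        y_px=np.arange(shape[0]) * 16.0 + 16,
        u_px=u, v_px=v, snr=np.full(shape, 10.0),
        in_domain=np.ones(shape, bool),
    )


class TestPreprocess:
    def test_identical_frames_background_equals_frame(self, rng):
        frame = rng.uniform(0, 1000, SHAPE)
        stack = np.stack([frame] * 4)
        with pytest.raises(ValueError, match="rescale"):
            preprocess(stack)  # zero-variance residual cannot be rescaled
        # the background estimate itself is the frame
        assert np.allclose(stack.mean(axis=0), frame)

    def test_constant_offset_removed_by_background_subtraction(self):
        a, b = shifted_pair((3.0, 0.0))
        plain, _ = preprocess(np.stack([a, b]))
        offset, bg = preprocess(np.stack([a + 500.0, b + 500.0]))
        assert np.allclose(plain, offset, atol=1e-6)
        assert bg.mean() == pytest.approx((a + b).mean() / 2 + 500.0, rel=1e-6)

    def test_gradient_background_contrast_improves(self):
        # particle-to-background contrast after the pipeline beats the raw
        # frame carrying a strong smooth gradient
        a, _ = shifted_pair((0.0, 0.0), seed=1)
        b, _ = shifted_pair((0.0, 0.0), seed=2)  # independent tracer pattern
        gradient = np.linspace(0, 1500, SHAPE[0])[:, None]
        raw_a, raw_b = a + gradient, b + gradient
        filtered, _ = preprocess(np.stack([raw_a, raw_b]))
        spots = a > 200  # true particle cores of frame A

        def contrast(img):
            return (img[spots].mean() - img[~spots].mean()) / (img.std() + 1e-12)

        assert contrast(filtered[0]) > contrast(raw_a)

    def test_output_range_and_shapes(self):
        a, b = shifted_pair((2.0, 1.0), noise=True)
        out, bg = preprocess(np.stack([a, b]))
        assert out.shape == (2, *SHAPE)
        assert bg.shape == SHAPE
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(p_low=99.0, p_high=20.0)


class TestPivMultipass:
    def test_uniform_shift_recovered(self):
        a, b = shifted_pair((5.0, 0.0))
        f = piv_multipass(a, b, passes=(64, 32))
        assert np.all(np.abs(f.u_px - 5.0) < 0.1)
        assert np.all(np.abs(f.v_px) < 0.1)

    def test_zero_shift_noise_free(self):
        a, b = shifted_pair((0.0, 0.0))
        f = piv_multipass(a, b, passes=(64, 32))
        assert np.all(np.abs(f.u_px) < 0.02)
        assert np.all(np.abs(f.v_px) < 0.02)

    def test_final_grid_spacing_matches_overlap(self):
        a, b = shifted_pair((1.0, 0.0))
        f = piv_multipass(a, b, passes=(64, 32), overlap=0.5)
        assert np.all(np.diff(f.x_px) == 16)
        assert np.all(np.diff(f.y_px) == 16)
        assert f.window_px == 32

    @pytest.mark.parametrize("shift", [(12.4, -5.3), (20.0, 7.7), (31.0, 0.0)])
    def test_large_shift_rms_below_tenth_pixel(self, shift):
        # up to 1/4 of the first-pass window (128 px); windows whose
        # pattern has left the frame carry no signal and are excluded
        a, b = shifted_pair(shift, seed=4)
        f = piv_multipass(a, b, passes=(128, 64, 32))
        half = f.window_px / 2
        keep = (
            (f.x_px[None, :] + half + max(shift[0], 0) <= a.shape[1])
            & (f.x_px[None, :] - half + min(shift[0], 0) >= 0)
            & (f.y_px[:, None] + half + max(shift[1], 0) <= a.shape[0])
            & (f.y_px[:, None] - half + min(shift[1], 0) >= 0)
        )
        err2 = (f.u_px - shift[0]) ** 2 + (f.v_px - shift[1]) ** 2
        rms = np.sqrt(np.mean(err2[keep]))
        assert rms < 0.1

    def test_velocity_conversion(self):
        a, b = shifted_pair((5.0, 0.0))
        f = piv_multipass(a, b, passes=(64, 32), scale=SCALE, dt_s=400e-6)
        # 5 px / 24.6 px/mm / 400 us = 0.508 m/s
        assert np.median(f.u_ms) == pytest.approx(0.508, abs=0.01)

    def test_masked_windows_emit_no_vectors(self):
        a, b = shifted_pair((3.0, 0.0))
        mask = np.ones(SHAPE, bool)
        mask[:, :160] = False
        f = piv_multipass(a, b, mask=mask, passes=(64, 32))
        cover = np.array([
            mask[:, x - 16 : x + 16].mean() for x in f.x_px
        ])
        expected_cols = cover >= 0.5
        assert np.array_equal(f.in_domain.all(axis=0), expected_cols)
        assert f.in_domain.sum() == expected_cols.sum() * f.y_px.size

    def test_boundary_windows_flagged(self):
        a, b = shifted_pair((3.0, 0.0))
        mask = np.ones(SHAPE, bool)
        mask[:, :150] = False
        f = piv_multipass(a, b, mask=mask, passes=(64, 32))
        assert f.boundary.sum() > 0
        assert np.all(f.in_domain[f.boundary])

    def test_window_larger_than_image_rejected(self):
        a, b = shifted_pair((1.0, 0.0))
        with pytest.raises(ValueError, match="larger than image"):
            piv_multipass(a, b, passes=(512, 256))

    def test_mismatched_shapes_rejected(self):
        a, b = shifted_pair((1.0, 0.0))
        with pytest.raises(ValueError):
            piv_multipass(a, b[:-10], passes=(64, 32))


class TestValidateVectors:
    def test_single_outlier_flagged_and_replaced(self, rng):
        f = synthetic_field(rng)
        sd = np.std(f.u_px)
        f.u_px[10, 10] += 20 * sd
        out, rate = validate_vectors(f)
        assert rate == pytest.approx(1 / f.u_px.size)
        assert out.replaced[10, 10]
        assert out.replaced.sum() == 1
        neighbors = [f.u_px[i, j] for i in (9, 10, 11) for j in (9, 10, 11)
                     if (i, j) != (10, 10)]
        assert out.u_px[10, 10] == pytest.approx(np.mean(neighbors))

    def test_all_low_snr_invalid_rate_100(self, rng):
        f = synthetic_field(rng)
        f.snr = np.full_like(f.snr, 1.0)
        out, rate = validate_vectors(f)
        assert rate == 1.0
        assert not out.valid.any()  # nobody has a valid donor

    def test_snr_just_above_threshold_kept(self, rng):
        f = synthetic_field(rng)
        f.snr = np.full_like(f.snr, 1.26)
        _, rate = validate_vectors(f)
        assert rate == 0.0

    def test_idempotent(self, rng):
        f = synthetic_field(rng)
        f.u_px[4, 7] += 3.0
        f.snr[12, 3] = 1.0
        once, _ = validate_vectors(f)
        twice, rate2 = validate_vectors(once)
        assert rate2 == 0.0
        assert np.array_equal(once.u_px, twice.u_px)
        assert np.array_equal(once.replaced, twice.replaced)

    def test_neighborhood_must_be_at_least_3(self):
        with pytest.raises(ValueError):
            ValidationConfig(neighborhood=1)

    def test_empty_domain_passthrough(self, rng):
        f = synthetic_field(rng)
        f.in_domain[:] = False
        out, rate = validate_vectors(f)
        assert rate == 0.0


class TestSegmentWall:
    SEG_SHAPE = (1040, 400)
    SEG_WINDOW = (-8.13, -8.13 + 400 / SCALE)

    @pytest.fixture(scope="class")
    def wall_frame(self):
        """Bright lumen against dark exterior around the aneurysm bulge."""
        geom = IdealizedAAAGeometry()
        mask = lumen_mask(geom, self.SEG_WINDOW, SCALE, self.SEG_SHAPE)
        frame = np.where(mask, 900.0, 60.0)
        return geom, frame

    def _tube_init(self, geom, offset_px=5.0, jitter=0.0, seed=0, n_side=120):
        rng = np.random.default_rng(seed)
        cy = self.SEG_SHAPE[0] / 2
        cols = np.linspace(2.0, self.SEG_SHAPE[1] - 3.0, n_side)
        x_mm = self.SEG_WINDOW[0] + (cols + 0.5) / SCALE
        r_px = bulge_radius(geom, x_mm) * SCALE - offset_px
        top = np.stack(
            [cy - r_px + rng.normal(0, jitter, n_side), cols], axis=1
        )
        bot = np.stack(
            [cy + r_px[::-1] - rng.normal(0, jitter, n_side), cols[::-1]],
            axis=1,
        )
        for chain in (top, bot):  # pinned endpoints stay on the init wall
            chain[0, 0] = chain[0, 0]
        return np.concatenate([top, bot])

    def _analytic_width(self, geom, cols):
        x_mm = self.SEG_WINDOW[0] + (np.asarray(cols) + 0.5) / SCALE
        return 2 * bulge_radius(geom, x_mm) * SCALE

    def test_converges_to_analytic_boundary(self, wall_frame):
        geom, frame = wall_frame
        init = self._tube_init(geom, offset_px=5.0, jitter=2.0)
        contour = segment_wall(frame, init)
        cols = np.arange(40, 360, 20, dtype=float)
        widths = contour.width_at(cols)
        err = np.abs(widths - self._analytic_width(geom, cols))
        assert np.median(err) < 3.0  # px; includes snake + rasterization bias

    def test_initialization_at_truth_is_stable(self, wall_frame):
        geom, frame = wall_frame
        init = self._tube_init(geom, offset_px=0.0)
        contour = segment_wall(frame, init)
        drift = np.abs(contour.width_at(np.arange(40, 360, 40, dtype=float))
                       - self._analytic_width(geom, np.arange(40, 360, 40)))
        assert np.median(drift) < 3.0

    def test_nonconvergence_carries_last_contour(self, wall_frame):
        geom, frame = wall_frame
        init = self._tube_init(geom, offset_px=30.0)
        with pytest.raises(SegmentationError) as err:
            segment_wall(frame, init, max_num_iter=1, convergence_tol=1e-3)
        assert err.value.contour.vertices.shape[0] > 0

    def test_width_at_bulge_center(self, wall_frame):
        geom, frame = wall_frame
        init = self._tube_init(geom, offset_px=4.0, jitter=1.0, seed=3)
        contour = segment_wall(frame, init)
        col = (0.0 - self.SEG_WINDOW[0]) * SCALE  # x = 0, the bulge center
        # 2 * 19 mm * 24.6 px/mm = 935 px
        assert contour.width_at(col) == pytest.approx(935.0, abs=6.0)


class TestDeltaDeformation:
    def test_zero_at_reference_time(self, rng):
        y = 492.0 + rng.uniform(-2, 2, (3, 10))
        delta = delta_deformation(y, t0_index=4)
        assert np.all(delta[:, 4] == 0.0)

    def test_normalized_percentage(self):
        y = np.array([[492.0, 502.0]])
        delta = delta_deformation(y, t0_index=0)
        assert delta[0, 1] == pytest.approx(10 / 492 * 100, rel=1e-9)
        assert delta[0, 1] == pytest.approx(2.0, abs=0.05)

    def test_unnormalized_in_input_units(self):
        y = np.array([[492.0, 502.0]])
        delta = delta_deformation(y, t0_index=0, normalize=False)
        assert delta[0, 1] == pytest.approx(10.0)

    def test_rigid_sequence_stays_below_segmentation_noise(self, rng):
        # +-0.4 px jitter on a 492 px diameter: delta < 0.2%
        y = 492.0 + rng.uniform(-0.4, 0.4, (3, 25))
        y[:, 0] = 492.0
        delta = delta_deformation(y, t0_index=0)
        assert np.max(np.abs(delta)) < 0.2

    def test_missing_station_rejected(self):
        y = np.array([[492.0, np.nan]])
        with pytest.raises(ValueError):
            delta_deformation(y, t0_index=0)


class TestWindowGrid:
    def test_half_overlap_spacing(self):
        g = window_grid(256, 32, 0.5)
        assert g[0] == 16
        assert np.all(np.diff(g) == 16)
        assert g[-1] <= 256 - 16

    def test_excessive_overlap_rejected(self):
        with pytest.raises(ValueError):
            window_grid(256, 32, 0.999)
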