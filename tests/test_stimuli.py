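"""Stimulus-pipeline unit and property tests.

The Monte-Carlo oracles here re-derive expected image statistics with
independent code paths (vectorised rasterisation, explicit kernels) rather
than re-using the generator's internals.
"""

import numpy as np
import pytest

from facepriors import (StimulusSpec, ValidationError, adjust_contrast,
                        apply_speckle, apply_stage3, embed_face,
                        generate_noise_pattern, generate_stimulus_set,
                        make_face_template, stimulus_manifest)
from facepriors.stimuli import (STAGE_BLUR, STAGE_CIRCLES, STAGE_CONTRAST,
                                STAGE_FACE, STAGE_SPECKLE, StimulusImage)


def oracle_coverage_fraction(spec, n_rep, seed):
    """Independent rasteriser: expected black-pixel fraction with border clipping.

    Vectorised all-circles-at-once membership test, unlike the generator's
    per-circle bounding-box loop.
    """
    rng = np.random.default_rng(seed)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    lo, hi = spec.circle_diameter_range
    fracs = []
    for _ in range(n_rep):
        centers = rng.uniform(0, n, size=(spec.n_circles, 2))
        radii = rng.integers(lo, hi + 1, size=spec.n_circles) / 2.0
        covered = np.zeros((n, n), dtype=bool)
        d2 = ((yy[None] - centers[:, 0, None, None]) ** 2
              + (xx[None] - centers[:, 1, None, None]) ** 2)
        covered = (d2 <= (radii**2)[:, None, None]).any(axis=0)
        fracs.append(covered.mean())
    return np.mean(fracs), np.std(fracs)


class TestNoisePattern:
    def test_no_circles_gives_white_canvas(self, rng):
        spec = StimulusSpec(image_size=64, n_circles=0, face_size=32)
        img = generate_noise_pattern(spec, rng)
        assert np.all(img.pixels == 1.0)

    def test_deterministic_given_seed(self, small_spec):
        a = generate_noise_pattern(small_spec, np.random.default_rng(3))
        b = generate_noise_pattern(small_spec, np.random.default_rng(3))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_black_fraction_matches_monte_carlo_oracle(self):
        spec = StimulusSpec(image_size=96, n_circles=120, face_size=48)
        mean, sd = oracle_coverage_fraction(spec, n_rep=60, seed=99)
        rng = np.random.default_rng(2024)
        fracs = [(generate_noise_pattern(spec, rng).pixels == 0.0).mean()
                 for _ in range(30)]
        # generator's mean coverage within the oracle's sampling band
        assert abs(np.mean(fracs) - mean) < 4 * sd / np.sqrt(30) + 4 * sd / np.sqrt(60)

    def test_invalid_spec_rejected(self, rng):
        with pytest.raises(ValidationError):
            generate_noise_pattern(StimulusSpec(n_circles=-1), rng)
        with pytest.raises(ValidationError):
            generate_noise_pattern(StimulusSpec(circle_diameter_range=(5, 2)), rng)


class TestSpeckle:
    def test_zero_variance_is_identity(self, rng):
        img = StimulusImage(pixels=np.linspace(0, 1, 64).reshape(8, 8))
        out = apply_speckle(img, 0.0, rng)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_black_image_is_fixed_point(self, rng):
        img = StimulusImage(pixels=np.zeros((16, 16)))
        out = apply_speckle(img, 2.0, rng)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_noise_moments_match_simulation_oracle(self):
        # constant image I = 0.5: pre-clipping Var(J - I) = I^2 * v; the oracle
        # simulates the clipped uniform multiplicative process directly
        intensity, v = 0.5, 2.0
        half = np.sqrt(3 * v)
        noise = intensity * np.random.default_rng(8).uniform(-half, half, 200_000)
        oracle_var = np.var(np.clip(intensity + noise, 0, 1) - intensity)
        img = StimulusImage(pixels=np.full((450, 450), intensity))
        out = apply_speckle(img, v, np.random.default_rng(9))
        assert abs((out.pixels - intensity).var() - oracle_var) < 0.005
        # and the unclipped theory value I^2 v = 0.5 shows up before clipping
        assert np.var(noise) == pytest.approx(intensity**2 * v, rel=0.02)

    def test_negative_variance_rejected(self, rng):
        img = StimulusImage(pixels=np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            apply_speckle(img, -1.0, rng)


class TestStage3:
    def test_blur_preserves_constant_image(self, rng):
        spec = StimulusSpec(stage3_mode="blur")
        img = StimulusImage(pixels=np.full((64, 64), 0.37))
        out = apply_stage3(img, spec, rng)
        np.testing.assert_allclose(out.pixels, 0.37, atol=1e-12)

    def test_blur_preserves_global_mean(self, rng):
        spec = StimulusSpec(stage3_mode="blur")
        img = generate_noise_pattern(StimulusSpec(image_size=96, n_circles=60, face_size=48),
                                     np.random.default_rng(5))
        out = apply_stage3(img, spec, rng)
        assert abs(out.pixels.mean() - img.pixels.mean()) < 1e-3

    def test_impulse_response_matches_explicit_kernel(self, rng):
        # independent oracle: construct the truncated discrete Gaussian kernel
        var = 10.0
        sigma = np.sqrt(var)
        radius = int(4 * sigma + 0.5)  # scipy's default truncation
        x = np.arange(-radius, radius + 1)
        w = np.exp(-x**2 / (2 * var))
        w /= w.sum()
        central = w[radius] ** 2  # separable 2-D kernel centre
        n = 2 * radius + 31
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = apply_stage3(StimulusImage(pixels=img), StimulusSpec(stage3_variance=var), rng)
        assert out.pixels[n // 2, n // 2] == pytest.approx(central, rel=1e-10)

    def test_additive_noise_mode_deterministic_and_clipped(self):
        spec = StimulusSpec(stage3_mode="additive_noise", stage3_variance=0.04)
        img = StimulusImage(pixels=np.full((32, 32), 0.5))
        a = apply_stage3(img, spec, np.random.default_rng(1))
        b = apply_stage3(img, spec, np.random.default_rng(1))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0 and a.pixels.max() <= 1
        assert not np.array_equal(a.pixels, img.pixels)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValidationError):
            StimulusSpec(stage3_mode="median").validate()


class TestContrast:
    @pytest.mark.parametrize("value,expected", [(0.0, 0.1), (1.0, 0.9), (0.5, 0.5)])
    def test_default_endpoint_and_midpoint_mapping(self, value, expected):
        img = StimulusImage(pixels=np.full((4, 4), value))
        out = adjust_contrast(img, (0.1, 0.9))
        np.testing.assert_allclose(out.pixels, expected)

    def test_full_range_is_identity(self):
        img = StimulusImage(pixels=np.linspace(0, 1, 16).reshape(4, 4))
        out = adjust_contrast(img, (0.0, 1.0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_degenerate_range_rejected(self):
        img = StimulusImage(pixels=np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            adjust_contrast(img, (0.5, 0.5))


class TestFaceTemplate:
    def test_deterministic(self):
        np.testing.assert_array_equal(make_face_template(4, 64),
                                      make_face_template(4, 64))

    def test_distinct_ids_differ(self):
        for i in range(5):
            a, b = make_face_template(i, 64), make_face_template(i + 1, 64)
            assert (np.abs(a - b) > 1 / 255).mean() >= 0.01

    def test_range_and_minimum_size(self):
        t = make_face_template(0, 64)
        assert t.min() >= 0 and t.max() <= 1
        with pytest.raises(ValidationError):
            make_face_template(0, 16)


class TestStimulusSet:
    def test_counts_range_and_positions(self, small_spec):
        stimuli = generate_stimulus_set(small_spec)
        assert sum(s.has_face for s in stimuli) == small_spec.n_targets
        assert sum(not s.has_face for s in stimuli) == small_spec.n_noise
        lo, hi = small_spec.contrast_out_range
        limit = small_spec.image_size - small_spec.face_size
        for s in stimuli:
            assert s.pixels.min() >= lo - 1e-12 and s.pixels.max() <= hi + 1e-12
            if s.has_face:
                r, c = s.face_position
                assert 0 <= r <= limit and 0 <= c <= limit

    def test_pipeline_stage_order_recorded(self, small_spec):
        stimuli = generate_stimulus_set(small_spec)
        target = next(s for s in stimuli if s.has_face)
        noise = next(s for s in stimuli if not s.has_face)
        assert target.provenance == [STAGE_CIRCLES, STAGE_SPECKLE, STAGE_FACE,
                                     STAGE_BLUR, STAGE_CONTRAST]
        assert noise.provenance == [STAGE_CIRCLES, STAGE_SPECKLE, STAGE_BLUR,
                                    STAGE_CONTRAST]

    def test_end_to_end_identity_chain(self):
        # no circles, no speckle, no blur: target is the contrast-mapped template
        spec = StimulusSpec(image_size=96, face_size=48, n_circles=0,
                            speckle_variance=0.0, stage3_variance=0.0,
                            n_targets=1, n_noise=0, n_distinct_faces=1, seed=11)
        s = generate_stimulus_set(spec)[0]
        r, c = s.face_position
        fs = spec.face_size
        lo, hi = spec.contrast_out_range
        expected = lo + (hi - lo) * make_face_template(s.face_id, fs)
        np.testing.assert_allclose(s.pixels[r:r + fs, c:c + fs], expected, atol=1e-12)
        background = s.pixels.copy()
        background[r:r + fs, c:c + fs] = hi
        np.testing.assert_allclose(background, hi, atol=1e-12)

    def test_face_must_fit_canvas(self, rng):
        with pytest.raises(ValidationError):
            StimulusSpec(image_size=100, face_size=100).validate()
        img = StimulusImage(pixels=np.ones((64, 64)))
        with pytest.raises(ValidationError):
            embed_face(img, make_face_template(0, 32), (40, 0), 0)

    def test_manifest_shape(self, small_spec):
        stimuli = generate_stimulus_set(small_spec)
        m = stimulus_manifest(stimuli, seed=small_spec.seed)
        assert list(m.columns) == ["stimulus_id", "has_face", "face_id",
                                   "face_row", "face_col", "seed"]
        assert m["has_face"].sum() == small_spec.n_targets
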