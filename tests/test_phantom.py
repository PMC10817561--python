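"""Synthetic phantom generator: geometry, beam, sensor model."""

import numpy as np
import pytest

from biodecomp import (
    PhantomSpec,
    Region,
    decompose_stack,
    gaussian_beam,
    generate,
    log_inverse_transmittance,
    make_thickness_maps,
    preset,
    render_stack,
    transmittance_stack,
)


class TestThicknessMapConstruction:
    def test_rectangle_covers_left_half(self):
        spec = PhantomSpec(
            frame_shape=(8, 8),
            regions=(Region("meat", "rectangle", (0, 0, 4, 8), 0.5),),
        )
        maps = make_thickness_maps(spec)
        meat = maps.map_for("meat")
        assert (meat[:, :4] == 0.5).all() and (meat[:, 4:] == 0.0).all()
        assert (maps.map_for("bone") == 0).all()
        assert (maps.map_for("skin") == 0).all()

    def test_overlay_adds_to_region(self):
        spec = PhantomSpec(
            frame_shape=(8, 8),
            regions=(Region("skin", "rectangle", (0, 0, 4, 8), 0.2),),
            overlay_layers=(("skin", 0.1),),
        )
        skin = make_thickness_maps(spec).map_for("skin")
        assert (skin[:, :4] == pytest.approx(0.3)) and (
            skin[:, 4:] == pytest.approx(0.1)
        )

    def test_empty_spec_is_all_zero(self):
        maps = make_thickness_maps(PhantomSpec(frame_shape=(4, 4)))
        assert (maps.values == 0).all()

    def test_unknown_tissue_rejected(self):
        with pytest.raises(ValueError, match="unknown tissue"):
            PhantomSpec(
                frame_shape=(4, 4),
                regions=(Region("gristle", "rectangle", (0, 0, 2, 2), 0.1),),
            )

    def test_ellipse_contains_center_not_corner(self):
        spec = PhantomSpec(
            frame_shape=(9, 9),
            regions=(Region("bone", "ellipse", (4, 4, 3, 2), 0.4),),
        )
        bone = make_thickness_maps(spec).map_for("bone")
        assert bone[4, 4] == 0.4
        assert bone[0, 0] == 0.0


class TestGaussianBeam:
    def test_peak_at_center(self):
        b = gaussian_beam((9, 9), 1000.0, (4.0, 4.0), 2.0)
        assert b[4, 4] == pytest.approx(1000.0)

    def test_one_sigma_falloff(self):
        b = gaussian_beam((9, 9), 1000.0, (4.0, 4.0), 2.0)
        assert b[4, 6] == pytest.approx(1000.0 * np.exp(-0.5), rel=1e-12)

    def test_radial_symmetry(self):
        b = gaussian_beam((9, 11), 500.0, (5.0, 4.0), 3.0)
        assert b[4, 5 + 3] == pytest.approx(b[4, 5 - 3], rel=1e-12)
        assert b[4 + 2, 5] == pytest.approx(b[4 - 2, 5], rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_beam((4, 4), 1.0, (2.0, 2.0), 0.0)


class TestRenderStack:
    def test_zero_thickness_object_equals_reference(self, table_matrix):
        spec = PhantomSpec(
            frame_shape=(8, 8), speckle_sigma=0.0, read_sigma=0.0, quantize=False
        )
        out = render_stack(make_thickness_maps(spec), table_matrix, spec)
        for ref, obj in zip(out.reference_images, out.object_images):
            np.testing.assert_array_equal(ref.pixels, obj.pixels)

    def test_single_layer_quantized_counts(self):
        # oracle: 1000 * exp(-2 * 0.5) = 367.879, rounds to 368
        from biodecomp import AttenuationMatrix

        m = AttenuationMatrix(np.array([[2.0]]), (808.0,), ("meat",))
        spec = PhantomSpec(
            frame_shape=(1, 1),
            tissue_labels=("meat",),
            overlay_layers=(("meat", 0.5),),
            beam_amplitude=1000.0,
            beam_sigma=1e9,  # effectively flat over one pixel
            speckle_sigma=0.0,
            read_sigma=0.0,
            bit_depth=16,
        )
        out = render_stack(make_thickness_maps(spec), m, spec)
        assert out.object_images[0].pixels[0, 0] == 368

    def test_saturation_clips_to_plateau(self, table_matrix):
        spec = PhantomSpec(
            frame_shape=(16, 16),
            beam_amplitude=80000.0,
            saturation_level=40000.0,
            beam_sigma=6.0,
            speckle_sigma=0.0,
            read_sigma=0.0,
        )
        out = render_stack(make_thickness_maps(spec), table_matrix, spec)
        ref = out.reference_images[0].pixels
        assert ref.max() == 40000.0
        assert (ref == 40000.0).sum() > 1  # a flat-topped plateau, not a peak

    def test_tissue_order_mismatch_rejected(self, table_matrix):
        spec = PhantomSpec(frame_shape=(4, 4))
        maps = make_thickness_maps(spec)
        reordered = type(maps)(
            maps.values, ("bone", "meat", "skin"), maps.valid_mask
        )
        with pytest.raises(ValueError, match="tissue order"):
            render_stack(reordered, table_matrix, spec)

    def test_determinism_for_fixed_seed(self, table_matrix):
        spec = preset("blocks", frame_shape=(32, 32), seed=7)
        a = generate(spec, table_matrix)
        b = generate(preset("blocks", frame_shape=(32, 32), seed=7), table_matrix)
        for ia, ib in zip(a.object_images, b.object_images):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)
        for ia, ib in zip(a.reference_images, b.reference_images):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)


class TestLoopClosure:
    def test_noise_free_transmittance_recovers_forward_model(
        self, clean_blocks, table_matrix
    ):
        """transmittance(render(...)) equals exp(-mu . d) to 1e-12."""
        stack, _ = transmittance_stack(
            clean_blocks.object_images, clean_blocks.reference_images
        )
        depth = np.tensordot(
            table_matrix.values, clean_blocks.ground_truth.values, axes=(1, 0)
        )
        expected = np.exp(-depth)
        valid = stack.valid_mask
        assert valid.all()
        np.testing.assert_allclose(
            stack.values[:, valid], expected[:, valid], rtol=1e-12
        )

    def test_speckle_increases_recovery_variance(self, table_matrix):
        """Recovered-map variance grows strictly with speckle sigma."""
        variances = []
        for sigma in (0.005, 0.02, 0.1):
            spec = preset("blocks", frame_shape=(48, 48), seed=11)
            spec.speckle_sigma = sigma
            spec.read_sigma = 0.0
            out = generate(spec, table_matrix)
            stack, _ = transmittance_stack(
                out.object_images, out.reference_images
            )
            res = decompose_stack(
                log_inverse_transmittance(stack), table_matrix, policy="keep_raw"
            )
            err = res.thickness_maps.raw_values - out.ground_truth.values
            variances.append(float(np.nanvar(err)))
        assert variances[0] < variances[1] < variances[2]

    def test_quantization_error_within_analytic_bound(self, table_matrix):
        """Thickness error from rounding to integer counts stays below
        the bound implied by +/- half a count at each valid pixel."""
        m, n = 16, 32
        ramp = np.zeros((3, m, n))
        ramp[0] = np.linspace(0.0, 0.5, n)[None, :]  # meat wedge
        spec = PhantomSpec(
            frame_shape=(m, n),
            speckle_sigma=0.0,
            read_sigma=0.0,
            quantize=True,
            beam_sigma=1e6,  # near-flat illumination
            beam_amplitude=52000.0,
        )
        maps = type(make_thickness_maps(spec))(
            ramp, spec.tissue_labels, np.ones((m, n), bool)
        )
        out = render_stack(maps, table_matrix, spec)
        stack, _ = transmittance_stack(out.object_images, out.reference_images)
        res = decompose_stack(log_inverse_transmittance(stack), table_matrix,
                              policy="keep_raw")
        err = np.abs(res.thickness_maps.raw_values - ramp)

        inv_norm = np.linalg.norm(
            np.linalg.inv(table_matrix.values), ord=np.inf
        )
        obj = np.stack([im.pixels for im in out.object_images]).astype(float)
        ref = np.stack([im.pixels for im in out.reference_images]).astype(float)
        # |ln(I_true / I_q)| <= -ln(1 - 0.5 / I_q), per frame, worst wavelength
        per_pixel = (-np.log1p(-0.5 / obj) - np.log1p(-0.5 / ref)).max(axis=0)
        bound = inv_norm * per_pixel
        valid = stack.valid_mask
        assert (err[:, valid] <= bound[valid][None, :]).all()
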