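"""Vector-field sampling, tensor fitting, resampling and helical angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fiberpath as fp
from fiberpath.fields import (
    Image,
    sample_field_trilinear_batch,
)


def _random_smooth_field(rng, shape=(5, 5, 5)):
    vals = rng.normal(size=shape + (3,)) + np.array([2.0, 0.5, 0.0])
    return fp.VectorField(values=vals, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


class TestTrilinearSampling:
    def test_voxel_center_identity(self, rng):
        field = _random_smooth_field(rng)
        for idx in [(1, 1, 1), (2, 3, 1), (3, 3, 3)]:
            v = field.values[idx]
            got = fp.sample_field_trilinear(field, field.voxel_to_world(idx), v)
            assert np.allclose(got, v / np.linalg.norm(v), atol=1e-12)

    def test_sign_coherence_at_midpoint(self):
        # Two antiparallel voxel vectors: a naive blend would cancel to zero;
        # pre-flipping against the reference recovers the common direction.
        vals = np.zeros((2, 2, 2, 3))
        vals[..., 0] = 1.0
        vals[1, :, :, 0] = -1.0
        field = fp.VectorField(values=vals)
        got = fp.sample_field_trilinear(field, (0.5, 0.5, 0.5), (1.0, 0.0, 0.0))
        assert np.allclose(got, (1, 0, 0), atol=1e-12)

    def test_matches_hand_computed_trilinear_formula(self, rng):
        field = _random_smooth_field(rng)
        ref = np.array([1.0, 0.0, 0.0])
        p = np.array([1.25, 2.5, 0.75])
        fx, fy, fz = 0.25, 0.5, 0.75
        base = np.array([1, 2, 0])
        acc = np.zeros(3)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    v = field.values[tuple(base + [dx, dy, dz])]
                    if v @ ref < 0:
                        v = -v
                    w = ((fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                         * (fz if dz else 1 - fz))
                    acc += w * v
        expected = acc / np.linalg.norm(acc)
        got = fp.sample_field_trilinear(field, p, ref)
        assert np.allclose(got, expected, atol=1e-12)

    def test_out_of_bounds_raises(self, rng):
        field = _random_smooth_field(rng)
        with pytest.raises(fp.OutOfBoundsError):
            fp.sample_field_trilinear(field, (-3.0, 0.0, 0.0), (1, 0, 0))

    def test_support_boundary_returns_zero(self):
        field = fp.VectorField(values=np.zeros((3, 3, 3, 3)))
        got = fp.sample_field_trilinear(field, (1.0, 1.0, 1.0), (1, 0, 0))
        assert np.allclose(got, 0.0)

    def test_batch_flags_in_and_out_of_bounds(self, rng):
        field = _random_smooth_field(rng)
        pts = np.array([[1.5, 1.5, 1.5], [-5.0, 0.0, 0.0]])
        vecs, valid = sample_field_trilinear_batch(field, pts, np.array([[1.0, 0, 0]] * 2))
        assert valid.tolist() == [True, False]
        assert np.allclose(vecs[1], 0.0)


class TestTensorFit:
    def _stack(self, tensors_grid, bval=1200.0, s0=1000.0):
        tf = fp.TensorField(tensors=tensors_grid, s0=np.full(tensors_grid.shape[:3], s0))
        bvals = np.concatenate([[0.0], np.full(6, bval)])
        bvecs = np.vstack([[0.0, 0.0, 0.0], fp.SIX_DIRECTIONS])
        return fp.synthesize_dwi(tf, bvals, bvecs, s0=s0)

    def test_isotropic_voxel_recovers_scaled_identity(self):
        d = 0.7e-3
        grid = np.tile(np.eye(3) * d, (2, 2, 2, 1, 1))
        dwi = self._stack(grid)
        mask = fp.VoxelMask(np.ones((2, 2, 2), bool))
        tf = fp.fit_diffusion_tensors(dwi, mask)
        assert np.allclose(tf.tensors, grid, atol=1e-9)
        assert np.allclose(tf.s0, 1000.0, rtol=1e-9)

    def test_noiseless_round_trip_anisotropic(self):
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        grid = np.tile(D, (3, 3, 3, 1, 1))
        dwi = self._stack(grid)
        mask = fp.VoxelMask(np.ones((3, 3, 3), bool))
        tf = fp.fit_diffusion_tensors(dwi, mask)
        rel = np.abs(tf.tensors - grid).max() / np.abs(D).max()
        assert rel < 1e-6

    def test_unmasked_voxels_zeroed(self):
        grid = np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1))
        dwi = self._stack(grid)
        flags = np.zeros((2, 2, 2), bool)
        flags[0, 0, 0] = True
        tf = fp.fit_diffusion_tensors(dwi, fp.VoxelMask(flags))
        assert np.all(tf.tensors[~flags] == 0)

    def test_b0_only_rejected(self):
        sig = np.ones((2, 2, 2, 3)) * 100
        dwi = fp.DWIStack(signals=sig, bvals=[0, 0, 0], bvecs=np.zeros((3, 3)))
        with pytest.raises(fp.InsufficientGradientScheme):
            fp.fit_diffusion_tensors(dwi, fp.VoxelMask(np.ones((2, 2, 2), bool)))

    def test_degenerate_direction_scheme_rejected(self):
        # six repeats of the same direction cannot span the tensor space
        bvecs = np.vstack([[0, 0, 0], np.tile([1.0, 0, 0], (6, 1))])
        sig = np.ones((2, 2, 2, 7)) * 100
        dwi = fp.DWIStack(signals=sig, bvals=[0] + [1000] * 6, bvecs=bvecs)
        with pytest.raises(fp.InsufficientGradientScheme):
            fp.fit_diffusion_tensors(dwi, fp.VoxelMask(np.ones((2, 2, 2), bool)))


class TestPrincipalDirection:
    def test_diagonal_tensor(self):
        grid = np.tile(np.diag([1.5e-3, 0.3e-3, 0.3e-3]), (2, 2, 2, 1, 1))
        tf = fp.TensorField(tensors=grid, s0=np.ones((2, 2, 2)))
        field = fp.principal_direction_field(tf, fp.VoxelMask(np.ones((2, 2, 2), bool)))
        v = field.values[0, 0, 0]
        assert np.allclose(np.abs(v), [1, 0, 0], atol=1e-12)

    def test_rotated_tensor_recovers_rotated_axis(self):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0],
                      [0, 0, 1.0]])
        D = R @ np.diag([2e-3, 1e-3, 1e-3]) @ R.T
        grid = np.tile(D, (2, 2, 2, 1, 1))
        tf = fp.TensorField(tensors=grid, s0=np.ones((2, 2, 2)))
        field = fp.principal_direction_field(tf, fp.VoxelMask(np.ones((2, 2, 2), bool)))
        v = field.values[0, 0, 0]
        expected = R[:, 0]
        assert min(np.linalg.norm(v - expected), np.linalg.norm(v + expected)) < 1e-9

    def test_isotropic_tensor_marked_degenerate(self):
        grid = np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1))
        tf = fp.TensorField(tensors=grid, s0=np.ones((2, 2, 2)))
        field = fp.principal_direction_field(tf, fp.VoxelMask(np.ones((2, 2, 2), bool)))
        assert np.all(field.values == 0)

    def test_nonsymmetric_rejected(self):
        grid = np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1))
        grid[..., 0, 1] = 5e-4  # asymmetric perturbation
        tf = fp.TensorField(tensors=grid, s0=np.ones((2, 2, 2)))
        with pytest.raises(fp.FieldError):
            fp.principal_direction_field(tf, fp.VoxelMask(np.ones((2, 2, 2), bool)))


class TestResampleAndScale:
    def test_anisotropic_to_isotropic_spacing(self, rng):
        img = Image(data=rng.normal(size=(8, 8, 4)), spacing=(1.875, 1.875, 4.0))
        out = fp.resample_and_scale(img, 0.8, 1.0)
        assert np.allclose(out.spacing, 0.8)

    def test_quarter_scale_shrinks_world_only(self, rng):
        img = Image(data=rng.normal(size=(6, 6, 6)), spacing=(0.8, 0.8, 0.8))
        out = fp.resample_and_scale(img, 0.8, 0.25)
        assert np.allclose(out.spacing, 0.2)
        assert out.data.shape == img.data.shape
        # values are untouched by the scaling step
        assert np.allclose(out.data, img.data, atol=1e-12)

    def test_identity_is_noop(self, rng):
        field = _random_smooth_field(rng)
        out = fp.resample_and_scale(field, field.spacing, 1.0)
        assert np.allclose(out.values, field.values, atol=1e-12)
        assert np.allclose(out.origin, field.origin)

    def test_mask_resampling_is_nearest(self):
        flags = np.zeros((4, 4, 4), bool)
        flags[:2] = True
        mask = fp.VoxelMask(flags, spacing=(1, 1, 1))
        out = fp.resample_and_scale(mask, 0.5, 1.0)
        assert out.flags.dtype == bool
        assert out.flags.shape == (8, 8, 8)
        assert out.flags[:3].all() and not out.flags[5:].any()

    def test_invalid_spacing_rejected(self, rng):
        with pytest.raises(fp.FieldError):
            fp.resample_and_scale(_random_smooth_field(rng), -1.0, 1.0)


class TestResidualMap:
    def test_zero_and_signed_differences(self):
        a = np.full((3, 3, 3), 5.0)
        assert np.all(fp.residual_map(a, a) == 0)
        assert np.allclose(fp.residual_map(a + 2, a), 2.0)
        # negative differences fall under the absolute value
        assert np.allclose(fp.residual_map(a - 2, a), 2.0)

    def test_shape_mismatch(self):
        with pytest.raises(fp.FieldError):
            fp.residual_map(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestHelicalAngle:
    AXIS = (0.0, 0.0, 1.0)
    ORIGIN = (0.0, 0.0, 0.0)

    def test_circumferential_longitudinal_and_diagonal(self):
        pos = (5.0, 0.0, 1.0)
        c_hat = np.array([0.0, 1.0, 0.0])  # z x r_hat at +x
        assert fp.helical_angle(c_hat, pos, self.AXIS, self.ORIGIN) == pytest.approx(0.0)
        assert fp.helical_angle((0, 0, 1), pos, self.AXIS, self.ORIGIN) == pytest.approx(90.0)
        diag = (c_hat + np.array([0, 0, 1.0])) / np.sqrt(2)
        assert fp.helical_angle(diag, pos, self.AXIS, self.ORIGIN) == pytest.approx(45.0, abs=1e-9)

    def test_position_on_axis_rejected(self):
        with pytest.raises(fp.FieldError):
            fp.helical_angle((1, 0, 0), (0, 0, 3.0), self.AXIS, self.ORIGIN)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
        scale=st.floats(0.01, 100),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_axial_and_scale_invariance(self, d, scale, sign):
        d = np.asarray(d)
        if np.linalg.norm(d) < 1e-3:
            return
        pos = (3.0, -2.0, 1.0)
        base = fp.helical_angle(d, pos, self.AXIS, self.ORIGIN)
        other = fp.helical_angle(sign * scale * d, pos, self.AXIS, self.ORIGIN)
        assert other == pytest.approx(base, abs=1e-9)
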