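"""Analytic fields, the helical-ventricle phantom, and the DWI simulator."""

import numpy as np
import pytest

import fiberpath as fp
from fiberpath.synth import SynthError


class TestAnalyticFields:
    def test_uniform_field_is_constant(self):
        field, mask = fp.make_analytic_field("uniform", (4, 4, 4), 1.0,
                                             {"direction": (0, 1, 0)})
        assert np.allclose(field.values, [0, 1, 0])
        assert mask.flags[1:-1, 1:-1, 1:-1].all()
        assert not mask.flags[0].any()

    def test_vortex_tangent_direction(self):
        field, _ = fp.make_analytic_field("vortex", (9, 9, 3), 1.0)
        center = field.voxel_to_world((4, 4, 1))
        # voxel at (r, 0, z) relative to the axis points along +y
        v = field.values[7, 4, 1]
        assert np.allclose(v, (0, 1, 0), atol=1e-12)

    def test_helix_pitch_sets_helical_angle(self):
        field, mask = fp.make_analytic_field("helix", (9, 9, 5), 1.0,
                                             {"pitch_angle_deg": 45.0})
        center = field.voxel_to_world((4, 4, 2))
        pts = field.voxel_centers()[mask.flags]
        vecs = field.values[mask.flags]
        off_axis = np.linalg.norm(pts[:, :2] - center[:2], axis=1) > 1e-9
        angles = fp.helical_angle_batch(vecs[off_axis], pts[off_axis],
                                        (0, 0, 1), center)
        assert np.allclose(angles, 45.0, atol=1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(SynthError):
            fp.make_analytic_field("spiral", (4, 4, 4), 1.0)


class TestPhantom:
    def test_field_is_unit_and_tangent(self, small_phantom):
        spec, field, mask, depth = small_phantom
        pts = field.voxel_centers()[mask.flags]
        vecs = field.values[mask.flags]
        assert np.allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-12)
        t = depth[mask.flags]
        radii = np.asarray(spec.inner_radii) + t[:, None] * (
            np.asarray(spec.outer_radii) - np.asarray(spec.inner_radii)
        )
        normals = pts / radii**2
        normals /= np.linalg.norm(normals, axis=1)[:, None]
        assert np.abs(np.einsum("ij,ij->i", vecs, normals)).max() < 1e-6

    def test_helical_angle_profile(self, small_phantom):
        spec, field, mask, depth = small_phantom
        pts = field.voxel_centers()[mask.flags]
        vecs = field.values[mask.flags]
        t = depth[mask.flags]
        ha = fp.helical_angle_batch(vecs, pts, (0, 0, 1), (0, 0, 0))
        mid = np.abs(t - 0.5) < 0.02
        assert np.abs(ha[mid]).max() < 0.5 + 120 * 0.02
        endo = t < 0.05
        epi = t > 0.95
        if endo.any():
            assert np.all(np.abs(ha[endo] - 60.0) < 2.0 + 120 * 0.05)
        assert epi.any()
        assert np.all(np.abs(ha[epi] + 60.0) < 2.0 + 120 * 0.05)

    def test_wall_depth_roundtrip(self, small_phantom):
        spec, field, mask, depth = small_phantom
        pts = field.voxel_centers()[mask.flags]
        t = fp.phantom_wall_depth(spec, pts)
        assert np.allclose(t, depth[mask.flags], atol=1e-9)
        assert t.min() >= 0 and t.max() <= 1

    def test_empty_shell_rejected(self):
        with pytest.raises(SynthError):
            fp.lv_phantom(fp.PhantomSpec(outer_radii=(1.0, 1.0, 1.0),
                                         inner_radii=(0.9, 0.9, 0.9),
                                         spacing=2.0))

    def test_streamline_helical_angle_grades_across_wall(self, small_phantom):
        """Tractography on the phantom reproduces the transmural progression."""
        spec, field, mask, _ = small_phantom
        params = fp.TractographyParams(n_seed=1, delta_s=0.25, l_max=6.0)
        streamlines = fp.run_tractography(field, mask, params)
        mean_ha, mean_t = [], []
        for s in streamlines[::7]:
            segs = np.diff(s.points, axis=0)
            mids = 0.5 * (s.points[:-1] + s.points[1:])
            ok = np.linalg.norm(mids[:, :2], axis=1) > 1e-6
            if not ok.any():
                continue
            ha = fp.helical_angle_batch(segs[ok], mids[ok], (0, 0, 1), (0, 0, 0))
            mean_ha.append(ha.mean())
            mean_t.append(fp.phantom_wall_depth(spec, mids[ok]).mean())
        mean_ha, mean_t = np.asarray(mean_ha), np.asarray(mean_t)
        edges = np.quantile(mean_t, np.linspace(0, 1, 7))
        bins = np.clip(np.digitize(mean_t, edges[1:-1]), 0, 5)
        means = np.array([mean_ha[bins == b].mean() for b in range(6)])
        assert np.all(np.diff(means) < 1.0)  # monotone decreasing
        assert means[0] - means[-1] > 90.0


class TestSynthesizeDwi:
    def test_b0_returns_s0_exactly(self):
        grid = np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1))
        tf = fp.TensorField(tensors=grid, s0=np.ones((2, 2, 2)))
        dwi = fp.synthesize_dwi(tf, [0.0], np.zeros((1, 3)), s0=123.0)
        assert np.allclose(dwi.signals, 123.0)

    def test_isotropic_signal_is_direction_independent(self):
        grid = np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1))
        tf = fp.TensorField(tensors=grid, s0=np.ones((2, 2, 2)))
        bvals = np.concatenate([[0.0], np.full(6, 1000.0)])
        bvecs = np.vstack([[0, 0, 0], fp.SIX_DIRECTIONS])
        dwi = fp.synthesize_dwi(tf, bvals, bvecs, s0=500.0)
        directional = dwi.signals[0, 0, 0, 1:]
        assert np.allclose(directional, directional[0])

    def test_round_trip_with_random_rotations(self, rng):
        from scipy.spatial.transform import Rotation

        shape = (4, 4, 4)
        R = Rotation.random(int(np.prod(shape)), random_state=7).as_matrix()
        base = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        tensors = np.einsum("nij,jk,nlk->nil", R, base, R).reshape(shape + (3, 3))
        tf = fp.TensorField(tensors=tensors, s0=np.full(shape, 1000.0))
        bvals = np.concatenate([[0.0], np.full(6, 1200.0)])
        bvecs = np.vstack([[0, 0, 0], fp.SIX_DIRECTIONS])
        dwi = fp.synthesize_dwi(tf, bvals, bvecs, s0=1000.0)
        fit = fp.fit_diffusion_tensors(dwi, fp.VoxelMask(np.ones(shape, bool)))
        rel = np.abs(fit.tensors - tensors).max() / np.abs(tensors).max()
        assert rel < 1e-6

    def test_noise_is_seeded(self):
        grid = np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1))
        tf = fp.TensorField(tensors=grid, s0=np.ones((2, 2, 2)))
        a = fp.synthesize_dwi(tf, [0.0], np.zeros((1, 3)), s0=100.0,
                              noise_sd=5.0, seed=3)
        b = fp.synthesize_dwi(tf, [0.0], np.zeros((1, 3)), s0=100.0,
                              noise_sd=5.0, seed=3)
        assert np.array_equal(a.signals, b.signals)

    def test_negative_bval_rejected(self):
        grid = np.tile(np.eye(3) * 1e-3, (1, 1, 1, 1, 1))
        tf = fp.TensorField(tensors=grid, s0=np.ones((1, 1, 1)))
        with pytest.raises(SynthError):
            fp.synthesize_dwi(tf, [-5.0], np.array([[1.0, 0, 0]]))
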