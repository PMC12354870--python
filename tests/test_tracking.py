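"""Seed layout and RK4 streamline integration."""

import numpy as np
import pytest

import fiberpath as fp
from fiberpath.tracking import TrackingError, _trace_batch


class TestSeeds:
    def test_single_seed_per_voxel_sits_at_centers(self):
        mask = fp.VoxelMask(np.ones((2, 2, 2), bool), spacing=(1, 1, 1))
        seeds = fp.generate_seeds(mask, 1)
        expected = mask.origin + np.stack(
            np.meshgrid(*[np.arange(2)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        assert np.allclose(seeds, expected)

    def test_eight_seeds_form_half_spaced_subgrid(self):
        mask = fp.VoxelMask(np.ones((1, 1, 1), bool), spacing=(1, 1, 1))
        seeds = fp.generate_seeds(mask, 8)
        assert len(seeds) == 8
        assert np.allclose(sorted(set(seeds[:, 0])), [-0.25, 0.25])
        diffs = np.diff(np.unique(seeds[:, 2]))
        assert np.allclose(diffs, 0.5)

    def test_masked_voxels_only_in_lexicographic_order(self):
        flags = np.zeros((3, 1, 1), bool)
        flags[0] = flags[2] = True
        mask = fp.VoxelMask(flags, spacing=(1, 1, 1))
        seeds = fp.generate_seeds(mask, 1)
        assert np.allclose(seeds[:, 0], [0, 2])

    def test_seed_density_identity_across_resolutions(self):
        # 64 seeds per (0.8 mm)^3 voxel and 1 seed per (0.2 mm)^3 voxel both
        # give 125 seeds per mm^3.
        coarse = fp.VoxelMask(np.ones((4, 4, 4), bool), spacing=(0.8,) * 3)
        fine = fp.VoxelMask(np.ones((16, 16, 16), bool), spacing=(0.2,) * 3)
        d_coarse = len(fp.generate_seeds(coarse, 64)) / (coarse.n_true * 0.8**3)
        d_fine = len(fp.generate_seeds(fine, 1)) / (fine.n_true * 0.2**3)
        assert d_coarse == pytest.approx(125.0)
        assert d_fine == pytest.approx(125.0)

    def test_non_cube_count_rejected_naming_nearest(self):
        mask = fp.VoxelMask(np.ones((2, 2, 2), bool))
        with pytest.raises(TrackingError, match="8 and 27"):
            fp.generate_seeds(mask, 10)


class TestIntegration:
    def test_straight_line_field(self):
        field, mask = fp.make_analytic_field("uniform", (12, 8, 8), 1.0,
                                             {"direction": (1, 0, 0)})
        params = fp.TractographyParams(delta_s=0.5, l_max=2.0)
        s = fp.integrate_streamline(field, mask, (2.0, 3.0, 3.0), +1, params)
        assert np.allclose(s.points, [(2 + 0.5 * k, 3, 3) for k in range(5)], atol=1e-12)

    def test_vortex_circle_radial_drift(self):
        field = fp.analytic_vortex()
        r = 5.0
        params = fp.TractographyParams(delta_s=r / 50, l_max=2 * np.pi * r + r / 100)
        pts = _trace_batch(field, None, np.array([[r, 0, 0]]),
                           np.array([1.0]), params)[0]
        radii = np.linalg.norm(pts[:, :2], axis=1)
        assert np.abs(radii - r).max() < 1e-3

    def test_fourth_order_convergence_on_vortex(self):
        field = fp.analytic_vortex()
        r = 5.0

        def endpoint_error(ds):
            n = round(2 * np.pi * r / ds)
            params = fp.TractographyParams(delta_s=ds, l_max=n * ds + ds / 2)
            pts = _trace_batch(field, None, np.array([[r, 0, 0]]),
                               np.array([1.0]), params)[0]
            steps = len(pts) - 1
            assert steps == n
            t = steps * ds
            exact = np.array([r * np.cos(t / r), r * np.sin(t / r), 0.0])
            return np.linalg.norm(pts[-1] - exact)

        e1, e2 = endpoint_error(r / 50), endpoint_error(r / 100)
        assert 10.0 < e1 / e2 < 24.0  # ~16x contraction per halving

    def test_sign_flip_invariance(self, rng):
        field, mask = fp.make_analytic_field("helix", (10, 10, 10), 1.0,
                                             {"pitch_angle_deg": 30.0})
        params = fp.TractographyParams(n_seed=1, delta_s=0.4, l_max=6.0)
        base = fp.run_tractography(field, mask, params)
        flips = np.where(rng.random(field.shape) < 0.5, 1.0, -1.0)
        flipped_field = fp.VectorField(values=field.values * flips[..., None],
                                       spacing=field.spacing, origin=field.origin)
        other = fp.run_tractography(flipped_field, mask, params)

        by_seed_base = {}
        by_seed_other = {}
        for s in base:
            by_seed_base.setdefault(s.seed_index, []).append(s.points)
        for s in other:
            by_seed_other.setdefault(s.seed_index, []).append(s.points)
        assert set(by_seed_base) == set(by_seed_other)
        for seed in by_seed_base:
            a, b = by_seed_base[seed], by_seed_other[seed]
            assert len(a) == len(b)
            # flipping the seed voxel's vector swaps the two branches
            direct = all(x.shape == y.shape and np.allclose(x, y, atol=1e-9)
                         for x, y in zip(a, b))
            swapped = len(a) == 2 and all(
                x.shape == y.shape and np.allclose(x, y, atol=1e-9)
                for x, y in zip(a, b[::-1])
            )
            assert direct or swapped

    def test_seed_outside_mask_rejected(self):
        field, mask = fp.make_analytic_field("uniform", (8, 8, 8), 1.0)
        with pytest.raises(TrackingError):
            fp.integrate_streamline(field, mask, (-10.0, 0, 0), +1,
                                    fp.TractographyParams(delta_s=0.5, l_max=2))


class TestRunTractography:
    def test_two_streamlines_per_interior_seed(self):
        field, mask = fp.make_analytic_field("uniform", (20, 6, 6), 1.0)
        params = fp.TractographyParams(n_seed=1, delta_s=0.5, l_max=3.0)
        out = fp.run_tractography(field, mask, params)
        seeds = fp.generate_seeds(mask, 1)
        counts = {}
        for s in out:
            counts[s.seed_index] = counts.get(s.seed_index, 0) + 1
        # seeds well inside the slab propagate both ways
        interior = [i for i, p in enumerate(seeds) if 5 < p[0] < 14]
        assert all(counts[i] == 2 for i in interior)

    def test_boundary_termination_stays_in_mask(self):
        field, mask = fp.make_analytic_field("uniform", (10, 6, 6), 1.0)
        params = fp.TractographyParams(delta_s=0.5, l_max=50.0)
        s = fp.integrate_streamline(field, mask, (2.0, 3.0, 3.0), -1, params)
        assert mask.contains_points(s.points).all()
        # backward branch walks to the -x mask face and stops there
        assert s.points[-1, 0] <= 2.0
        assert s.points[-1, 0] >= 0.5

    def test_length_and_spacing_invariants(self, small_phantom):
        _, field, mask, _ = small_phantom
        params = fp.TractographyParams(n_seed=1, delta_s=0.25, l_max=5.0)
        out = fp.run_tractography(field, mask, params)
        assert len(out) > 0
        for s in out[::25]:
            steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert np.all(steps <= params.delta_s * (1 + 1e-6))
            assert s.arc_length <= params.l_max + params.delta_s
            assert mask.contains_points(s.points).all()

    def test_deterministic_across_runs(self):
        field, mask = fp.make_analytic_field("vortex", (10, 10, 6), 1.0)
        params = fp.TractographyParams(n_seed=1, delta_s=0.3, l_max=4.0)
        a = fp.run_tractography(field, mask, params)
        b = fp.run_tractography(field, mask, params)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.points, y.points)
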