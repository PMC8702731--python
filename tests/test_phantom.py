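"""Phantom generator: rasterization against a brute-force oracle, label
precedence, class imbalance, and cohort reproducibility."""

from __future__ import annotations

import numpy as np
import pytest

import neuroseg3d as ns
from neuroseg3d.phantom import rasterize_tube

from conftest import brute_force_tube_mask


class TestRasterizeTube:
    def test_straight_tube_volume_matches_capsule(self):
        # radius 3 mm, segment length 20 mm on a 1 mm grid. Point-to-segment
        # distance sweeps a capsule: cylinder pi*r^2*L plus two hemispherical
        # end caps (4/3)*pi*r^3; voxelization over-counts by < 15%.
        tube = ns.TubeSpec([(16.0, 16.0, 6.0), (16.0, 16.0, 26.0)], 3.0)
        mask = rasterize_tube(tube, (32, 32, 32), (1.0, 1.0, 1.0))
        expected = np.pi * 3.0 ** 2 * 20.0 + (4.0 / 3.0) * np.pi * 3.0 ** 3
        assert abs(mask.sum() - expected) / expected < 0.15
        assert np.array_equal(mask, brute_force_tube_mask(
            tube, (32, 32, 32), (1.0, 1.0, 1.0)))

    def test_thin_tube_keeps_only_on_axis_voxels(self):
        # radius below half the voxel pitch along a line of voxel centers
        tube = ns.TubeSpec([(8.5, 8.5, 0.5), (8.5, 8.5, 15.5)], 0.4)
        mask = rasterize_tube(tube, (16, 16, 16), (1.0, 1.0, 1.0))
        zs, hs, ws = np.nonzero(mask)
        assert mask.sum() == 16
        assert set(zip(zs, hs)) == {(8, 8)}

    def test_degenerate_polyline_is_rejected(self):
        with pytest.raises(ValueError, match="stub"):
            ns.TubeSpec([(1.0, 1.0, 1.0), (1.0, 1.0, 1.0)], 1.0, name="stub")

    @pytest.mark.parametrize("seed", range(6))
    def test_fast_rasterization_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        npts = int(rng.integers(2, 5))
        pts = [tuple(rng.uniform(2, 14, 3)) for _ in range(npts)]
        tube = ns.TubeSpec(pts, float(rng.uniform(0.6, 3.0)))
        grid = (16, 16, 16)
        spacing = (1.0, 1.0, 1.0)
        fast = rasterize_tube(tube, grid, spacing)
        slow = brute_force_tube_mask(tube, grid, spacing)
        assert np.array_equal(fast, slow)

    def test_tapered_radius_changes_width_along_axis(self):
        tube = ns.TubeSpec([(8.5, 8.5, 2.0), (8.5, 8.5, 14.0)], [0.6, 3.0])
        mask = rasterize_tube(tube, (16, 16, 16), (1.0, 1.0, 1.0))
        slow = brute_force_tube_mask(tube, (16, 16, 16), (1.0, 1.0, 1.0))
        assert np.array_equal(mask, slow)
        assert mask[:, :, 3].sum() < mask[:, :, 13].sum()

    def test_oversized_radius_is_rejected(self):
        tube = ns.TubeSpec([(4.0, 4.0, 1.0), (4.0, 4.0, 7.0)], 5.0)
        with pytest.raises(ValueError, match="radius"):
            rasterize_tube(tube, (8, 8, 8), (1.0, 1.0, 1.0))


class TestGeneratePhantom:
    def test_default_phantom_contains_all_classes(self, default_phantom):
        img, lab = default_phantom
        assert lab.shape == (32, 96, 96)
        assert img.shape == lab.shape
        assert set(np.unique(lab.values)) == {0, 1, 2, 3}

    def test_nerve_confined_to_few_axial_slices(self, default_phantom):
        _, lab = default_phantom
        nerve_slices = np.unique(np.nonzero(lab.values == 3)[0])
        assert len(nerve_slices) <= 4
        assert np.all(np.diff(nerve_slices) == 1)  # consecutive

    def test_class_imbalance_of_default_spec(self, default_phantom):
        _, lab = default_phantom
        counts = lab.class_counts()
        total = lab.values.size
        assert counts["trigeminal_nerve"] / total < 0.01
        assert counts["brainstem"] / total > 0.05

    def test_same_seed_is_bit_identical(self):
        spec = ns.PhantomSpec.default(seed=7)
        i1, l1 = ns.generate_phantom(spec)
        i2, l2 = ns.generate_phantom(spec)
        assert np.array_equal(i1.values, i2.values)
        assert np.array_equal(l1.values, l2.values)

    def test_nerve_overrides_brainstem_at_overlap(self, default_phantom):
        # the nerve root starts inside the brainstem ellipsoid; precedence
        # must assign those voxels to the nerve class only
        _, lab = default_phantom
        spec = ns.PhantomSpec.default(seed=0)
        nerve_mask = rasterize_tube(spec.nerve, spec.grid_shape, spec.spacing_mm)
        assert np.all(lab.values[nerve_mask] == 3)

    def test_nerve_slice_limit_enforced(self):
        spec = ns.PhantomSpec.default(seed=0)
        steep = ns.TubeSpec([(4.0, 40.0, 58.0), (28.0, 36.0, 72.0)], 1.2,
                            intensity_mean=140.0, name="steep")
        bad = ns.PhantomSpec(**{**spec.__dict__, "nerve": steep})
        with pytest.raises(ValueError, match="slices"):
            ns.generate_phantom(bad)

    def test_foreground_brighter_than_background_required(self):
        spec = ns.PhantomSpec.default()
        dim = ns.EllipsoidSpec(center_mm=(16, 48, 48), semi_axes_mm=(5, 5, 5),
                               intensity_mean=10.0)
        with pytest.raises(ValueError, match="brighter"):
            ns.PhantomSpec(**{**spec.__dict__, "brainstem": dim})

    def test_contact_geometry_brings_vessel_near_nerve(self):
        spec = ns.PhantomSpec.default(seed=0, contact=True)
        img, lab = ns.generate_phantom(spec)
        nerve = np.argwhere(lab.values == 3).astype(float)
        vessel = np.argwhere(lab.values == 2).astype(float)
        dmin = np.sqrt(((nerve[:, None, :] - vessel[None, :, :]) ** 2).sum(-1)).min()
        assert dmin <= 2.0  # voxel-adjacent contact


class TestMakeDataset:
    def test_cohort_size_and_manifest(self, tmp_path):
        cases, manifest = ns.make_dataset(5, seed=1, out_dir=tmp_path)
        assert len(cases) == 5
        assert manifest["n"] == 5
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "case000_img.nii.gz").exists()
        assert (tmp_path / "case004_lab.nii.gz").exists()

    def test_different_seeds_differ(self):
        c1, _ = ns.make_dataset(1, seed=1)
        c2, _ = ns.make_dataset(1, seed=2)
        assert not np.array_equal(c1[0][1].values, c2[0][1].values)

    def test_same_seed_reproduces_manifest_and_voxels(self):
        c1, m1 = ns.make_dataset(3, seed=9)
        c2, m2 = ns.make_dataset(3, seed=9)
        assert m1 == m2
        for (i1, l1, _), (i2, l2, _) in zip(c1, c2):
            assert np.array_equal(i1.values, i2.values)
            assert np.array_equal(l1.values, l2.values)

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            ns.make_dataset(0)


def test_imbalance_property_over_cohort():
    """Over >= 20 jittered phantoms: median nerve fraction < 1% and nerve
    axial extent <= 4 slices in every case."""
    spec = ns.PhantomSpec.default(grid_shape=(16, 48, 48))
    cases, _ = ns.make_dataset(20, base_spec=spec, seed=42)
    fractions = []
    for _, lab, _ in cases:
        counts = lab.class_counts()
        fractions.append(counts["trigeminal_nerve"] / lab.values.size)
        nerve_slices = np.unique(np.nonzero(lab.values == 3)[0])
        assert len(nerve_slices) <= 4
    assert np.median(fractions) < 0.01
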