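"""Area profiles, compression detection, and volume metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cordbold import synth
from cordbold.morphometry import (
    AreaProfile,
    CompressionRegion,
    CordMask,
    analyze_mask,
    compression_volume,
    compute_area_profile,
    detect_compression,
    smooth_profile,
)


def lattice_disk_count(radius_voxels: float) -> int:
    """Independent oracle: centre-of-voxel lattice points with x²+y² ≤ r²."""
    r = int(np.ceil(radius_voxels))
    count = 0
    for x in range(-r, r + 1):
        for y in range(-r, r + 1):
            if x * x + y * y <= radius_voxels**2:
                count += 1
    return count


class TestAreaProfile:
    def test_digital_disk_area_matches_lattice_count(self):
        # radius 4 voxels at 0.9 mm in-plane: 49 voxels -> 39.69 mm² per slice
        assert lattice_disk_count(4.0) == 49
        grid = np.zeros((11, 11, 3), dtype=bool)
        xs, ys = np.meshgrid(np.arange(11) - 5, np.arange(11) - 5, indexing="ij")
        grid[(xs**2 + ys**2 <= 16)] = True
        mask = CordMask(voxels=grid, voxel_dims=(0.9, 0.9, 0.9))
        profile = compute_area_profile(mask)
        assert np.allclose(profile.areas, 49 * 0.81)
        assert np.isclose(profile.areas[0], 39.69)

    def test_empty_slice_has_zero_area_and_length_matches(self):
        grid = np.zeros((5, 5, 7), dtype=bool)
        grid[2, 2, 3] = True
        profile = compute_area_profile(CordMask(voxels=grid, voxel_dims=(1, 1, 2)))
        assert len(profile) == 7
        assert profile.areas[0] == 0
        assert profile.areas[3] == 1.0

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            CordMask(voxels=np.full((3, 3, 3), 0.5), voxel_dims=(1, 1, 1))

    def test_anisotropic_inplane_warns(self):
        grid = np.ones((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning, match="anisotropic"):
            compute_area_profile(CordMask(voxels=grid, voxel_dims=(0.5, 1.0, 1.0)))

    def test_volume_conservation_exact(self, box_phantom):
        # sum of slice areas × thickness equals voxel count × voxel volume
        _, mask, _ = box_phantom
        profile = compute_area_profile(mask)
        total = profile.areas.sum() * profile.slice_thickness
        dx, dy, dz = mask.voxel_dims
        assert total == pytest.approx(mask.voxels.sum() * dx * dy * dz, rel=1e-12)

    @given(k=st.floats(min_value=0.5, max_value=3.0))
    def test_inplane_scaling_covariance(self, k):
        grid = np.zeros((9, 9, 4), dtype=bool)
        grid[2:7, 2:7, :] = True
        base = compute_area_profile(CordMask(voxels=grid, voxel_dims=(1, 1, 1)))
        scaled = compute_area_profile(CordMask(voxels=grid, voxel_dims=(k, k, 1)))
        assert np.allclose(scaled.areas, k**2 * base.areas)


class TestSmoothing:
    def test_window_one_is_identity(self):
        p = AreaProfile(areas=np.array([1.0, 5.0, 2.0, 8.0]), slice_thickness=1.0)
        assert np.array_equal(smooth_profile(p, 1).smoothed_areas, p.areas)

    def test_constant_profile_unchanged(self):
        p = AreaProfile(areas=np.full(20, 7.0), slice_thickness=1.0)
        assert np.allclose(smooth_profile(p, 5).smoothed_areas, 7.0)

    def test_triangular_profile_matches_hand_average(self):
        p = AreaProfile(areas=np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0]), slice_thickness=1.0)
        sm = smooth_profile(p, 3).smoothed_areas
        # interior: mean of 3 neighbours; edges: shrinking window
        assert np.allclose(sm[1:-1], [1.0, 2.0, 7 / 3, 2.0, 1.0])
        assert sm[0] == pytest.approx(0.5)

    def test_even_window_rejected(self):
        p = AreaProfile(areas=np.ones(5), slice_thickness=1.0)
        with pytest.raises(ValueError, match="odd"):
            smooth_profile(p, 2)


class TestDetection:
    def test_constant_profile_yields_no_regions(self):
        p = smooth_profile(AreaProfile(areas=np.full(30, 50.0), slice_thickness=1.0), 3)
        assert detect_compression(p) == []

    def test_all_zero_profile_rejected(self):
        p = AreaProfile(areas=np.zeros(30), slice_thickness=1.0)
        with pytest.raises(ValueError, match="nonzero"):
            detect_compression(p)

    def test_box_notch_limits_within_one_slice(self, box_phantom):
        _, mask, truth = box_phantom
        _, regions = analyze_mask(mask)
        assert len(regions) == 1
        assert abs(regions[0].z_lo - truth[0].z_lo) <= 1
        assert abs(regions[0].z_hi - truth[0].z_hi) <= 1

    def test_two_disjoint_notches_returned_in_order(self):
        spec = synth.CordPhantomSpec(
            n_slices=80,
            compressions=(
                synth.CompressionSpec(center_slice=20, extent_slices=5, max_area_reduction=0.4),
                synth.CompressionSpec(center_slice=55, extent_slices=7, max_area_reduction=0.3),
            ),
        )
        mask, truth = synth.make_cord_phantom(spec)
        _, regions = analyze_mask(mask)
        assert len(regions) == 2
        assert regions[0].z_hi < regions[1].z_lo
        for det, tr in zip(regions, truth):
            assert abs(det.z_lo - tr.z_lo) <= 1 and abs(det.z_hi - tr.z_hi) <= 1

    @pytest.mark.parametrize("extent", [3, 7, 15])
    @pytest.mark.parametrize("reduction", [0.2, 0.6])
    def test_noiseless_grid_deficit_within_5pct(self, extent, reduction):
        spec = synth.CordPhantomSpec(
            n_slices=60,
            compressions=(
                synth.CompressionSpec(
                    center_slice=30, extent_slices=extent, max_area_reduction=reduction
                ),
            ),
        )
        mask, truth = synth.make_cord_phantom(spec)
        _, regions = analyze_mask(mask)
        assert len(regions) == 1
        assert regions[0].volume_deficit == pytest.approx(
            truth[0].volume_deficit, rel=0.05
        )

    def test_gaussian_notch_detected_around_center(self):
        spec = synth.CordPhantomSpec(
            n_slices=60,
            compressions=(
                synth.CompressionSpec(
                    center_slice=30, extent_slices=7, max_area_reduction=0.4, shape="gaussian"
                ),
            ),
        )
        mask, _ = synth.make_cord_phantom(spec)
        _, regions = analyze_mask(mask)
        assert len(regions) == 1
        assert regions[0].z_lo <= 30 <= regions[0].z_hi

    def test_noise_robustness_cv_below_10pct(self):
        # mirrors the high rater reliability of the metric on real cords
        deficits = []
        for seed in range(20):
            spec = synth.CordPhantomSpec(
                n_slices=60,
                surface_noise_sd=0.2,
                seed=seed,
                compressions=(
                    synth.CompressionSpec(
                        center_slice=30, extent_slices=7, max_area_reduction=0.4
                    ),
                ),
            )
            mask, _ = synth.make_cord_phantom(spec)
            _, regions = analyze_mask(mask)
            deficits.append(sum(r.volume_deficit for r in regions))
        deficits = np.array(deficits)
        assert (deficits > 0).all()
        assert deficits.std() / deficits.mean() < 0.10


class TestVolumes:
    def test_cord_volume_sums_areas_times_thickness(self):
        p = AreaProfile(areas=np.array([50.0, 40.0, 50.0]), slice_thickness=0.9)
        region = CompressionRegion(z_lo=0, z_hi=2, baseline_area=60.0)
        filled = compression_volume(p, region)
        assert filled.cord_volume_in_region == pytest.approx(126.0)
        assert filled.volume_deficit == pytest.approx(36.0)

    def test_region_at_baseline_has_zero_deficit(self):
        p = AreaProfile(areas=np.full(5, 60.0), slice_thickness=0.9)
        filled = compression_volume(p, CompressionRegion(z_lo=1, z_hi=3, baseline_area=60.0))
        assert filled.volume_deficit == 0.0

    def test_region_outside_profile_rejected(self):
        p = AreaProfile(areas=np.ones(5), slice_thickness=1.0)
        with pytest.raises(ValueError, match="outside"):
            compression_volume(p, CompressionRegion(z_lo=3, z_hi=7, baseline_area=1.0))

    def test_inverted_limits_rejected(self):
        with pytest.raises(ValueError):
            CompressionRegion(z_lo=5, z_hi=2, baseline_area=1.0)
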