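"""Shape synthesis, voxelization, mask union and margin metrics."""

import numpy as np
import pytest
from scipy import ndimage

from ablashape.profiles import AblationProfile, ProfileSegment
from ablashape.shape_margin import (
    AblationShape,
    EmptyShapeError,
    RasterMask,
    margin_metrics,
    rasterize,
    synthesize_shape,
    union_masks,
)
from ablashape.width_model import width_mean


def make_sphere(radius_vox: int, n: int = 56) -> np.ndarray:
    g = np.arange(n) - n / 2 + 0.5
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    return X**2 + Y**2 + Z**2 <= radius_vox**2


def euclidean_dilate(mask: np.ndarray, k: int) -> np.ndarray:
    """Isotropic k-voxel dilation via the Euclidean distance transform."""
    return ndimage.distance_transform_edt(~mask) <= k


class TestSynthesizeShape:
    def test_constant_pass_with_caps(self, coeffs):
        """A 55 mm travel producing 20 mm width yields a 75 mm shape."""
        from ablashape.planner import invert_width

        v = invert_width(coeffs, 20.0, 100.0)
        profile = AblationProfile([ProfileSegment(0.0, 55.0, 100.0, v)])
        shape = synthesize_shape(profile, coeffs)
        assert shape.total_length == pytest.approx(75.0, abs=1e-6)
        assert np.allclose(shape.width, 20.0, atol=1e-9)

    def test_pause_regions_contribute_nothing(self, coeffs):
        profile = AblationProfile(
            [
                ProfileSegment(0.0, 10.0, 100.0, 0.1),
                ProfileSegment(10.0, 20.0, 0.0, 0.1),
                ProfileSegment(20.0, 30.0, 100.0, 0.1),
            ]
        )
        shape = synthesize_shape(profile, coeffs, grid_mm=0.5)
        inside_pause = (shape.x > 10.4) & (shape.x < 19.6)
        # pause region keeps zero width and is excluded from the active span
        assert not inside_pause.any() or np.all(shape.width[inside_pause] == 0)

    def test_matches_dense_per_position_lookup(self, coeffs):
        profile = AblationProfile(
            [
                ProfileSegment(0.0, 12.0, 140.0, 0.2),
                ProfileSegment(12.0, 30.0, 80.0, 0.05),
                ProfileSegment(30.0, 42.0, 60.0, 0.1),
            ]
        )
        shape = synthesize_shape(profile, coeffs, grid_mm=0.1)
        for x, w in zip(shape.x[::17], shape.width[::17]):
            seg = next(
                s for s in profile.segments
                if s.x_start - 1e-12 <= x <= s.x_end + 1e-12
                and width_mean(coeffs, s.power, s.velocity) >= w - 1e-9
            )
            assert w == pytest.approx(
                width_mean(coeffs, seg.power, seg.velocity), abs=1e-9
            )

    def test_all_pause_profile_rejected(self, coeffs):
        profile = AblationProfile([ProfileSegment(0.0, 10.0, 0.0, 0.1)])
        with pytest.raises(EmptyShapeError):
            synthesize_shape(profile, coeffs)

    def test_envelope_is_pointwise_maximum_over_passes(self, coeffs):
        # overlapping passes: wide slow pass then a narrow fast pass
        profile = AblationProfile(
            [
                ProfileSegment(0.0, 20.0, 140.0, 0.05),
                ProfileSegment(20.0, 40.0, 60.0, 0.5),
            ]
        )
        shape = synthesize_shape(profile, coeffs, grid_mm=0.5)
        w_wide = width_mean(coeffs, 140.0, 0.05)
        sel = shape.x <= 20.0
        assert np.allclose(shape.width[sel], w_wide, atol=1e-9)


class TestRasterize:
    def test_cylinder_volume_matches_analytic(self):
        xs = np.linspace(0.0, 55.0, 111)
        shape = AblationShape(xs, np.full_like(xs, 20.0), np.zeros_like(xs))
        mask = rasterize(shape, spacing=0.5)
        analytic = np.pi * 10.0**2 * 55.0 + 4.0 / 3.0 * np.pi * 10.0**3
        assert mask.voxel_volume_mm3 == pytest.approx(analytic, rel=0.02)

    def test_rotational_symmetry_under_axis_flips(self):
        xs = np.linspace(0.0, 30.0, 61)
        shape = AblationShape(xs, 14.0 + 4.0 * np.sin(xs / 5.0), np.zeros_like(xs))
        mask = rasterize(shape, spacing=0.5)
        np.testing.assert_array_equal(mask.volume, mask.volume[:, ::-1, :])
        np.testing.assert_array_equal(mask.volume, mask.volume[:, :, ::-1])
        np.testing.assert_array_equal(mask.volume, mask.volume.transpose(0, 2, 1))

    def test_slice_is_midplane_of_volume(self):
        xs = np.linspace(0.0, 20.0, 41)
        shape = AblationShape(xs, np.full_like(xs, 10.0), np.zeros_like(xs))
        mask = rasterize(shape, spacing=0.5)
        np.testing.assert_array_equal(
            mask.slice2d, mask.volume[:, :, mask.volume.shape[2] // 2]
        )

    def test_coarse_spacing_warns(self):
        xs = np.linspace(0.0, 20.0, 41)
        shape = AblationShape(xs, np.full_like(xs, 3.0), np.zeros_like(xs))
        with pytest.warns(UserWarning, match="spacing"):
            rasterize(shape, spacing=2.0)


class TestUnionMasks:
    def _mask(self, vol):
        return RasterMask(volume=vol, spacing=1.0, origin=(0.0, 0.0, 0.0))

    def test_idempotent_and_identity(self):
        rng = np.random.default_rng(0)
        a = self._mask(rng.random((8, 8, 8)) > 0.5)
        empty = self._mask(np.zeros((8, 8, 8), dtype=bool))
        np.testing.assert_array_equal(union_masks([a, a]).volume, a.volume)
        np.testing.assert_array_equal(union_masks([a, empty]).volume, a.volume)

    def test_cardinality_subadditive(self):
        rng = np.random.default_rng(1)
        a = self._mask(rng.random((8, 8, 8)) > 0.6)
        b = self._mask(rng.random((8, 8, 8)) > 0.6)
        u = union_masks([a, b]).volume.sum()
        assert u <= a.volume.sum() + b.volume.sum()
        disjoint = self._mask(a.volume.copy())
        disjoint.volume[:] = False
        disjoint.volume[0, 0, 0] = not a.volume[0, 0, 0]
        # equality iff disjoint
        c = self._mask(~a.volume)
        assert union_masks([a, c]).volume.sum() == a.volume.sum() + c.volume.sum()

    def test_grid_mismatch_rejected(self):
        a = self._mask(np.zeros((8, 8, 8), dtype=bool))
        b = RasterMask(np.zeros((9, 8, 8), dtype=bool), 1.0, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            union_masks([a, b])


class TestMarginMetrics:
    def test_identical_masks(self):
        tumor = make_sphere(10)
        rep = margin_metrics(tumor, tumor, spacing=0.5)
        assert rep.minimal_margin_mm == pytest.approx(0.0)
        assert rep.coverage == 1.0
        assert rep.dice == pytest.approx(1.0)
        assert rep.over_ablation_ratio == 0.0

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_dilated_ablation_margin(self, k):
        spacing = 0.5
        tumor = make_sphere(10)
        ablation = euclidean_dilate(tumor, k)
        rep = margin_metrics(ablation, tumor, spacing=spacing)
        assert rep.coverage == 1.0
        assert abs(rep.minimal_margin_mm - k * spacing) <= spacing

    def test_disjoint_masks(self):
        tumor = np.zeros((20, 20, 20), dtype=bool)
        tumor[2:5, 2:5, 2:5] = True
        ablation = np.zeros_like(tumor)
        ablation[14:18, 14:18, 14:18] = True
        rep = margin_metrics(ablation, tumor, spacing=1.0)
        assert rep.coverage == 0.0
        assert rep.minimal_margin_mm < 0

    def test_empty_tumor_rejected(self):
        with pytest.raises(ValueError):
            margin_metrics(make_sphere(5), np.zeros((56, 56, 56), dtype=bool), spacing=1.0)

    def test_empty_ablation_reports_worst_case(self):
        tumor = make_sphere(5)
        rep = margin_metrics(np.zeros_like(tumor), tumor, spacing=1.0)
        assert rep.coverage == 0.0
        assert rep.minimal_margin_mm < 0

    def test_growing_ablation_never_hurts(self):
        tumor = make_sphere(8)
        a1 = euclidean_dilate(tumor, 1)
        a2 = euclidean_dilate(tumor, 3)
        r1 = margin_metrics(a1, tumor, spacing=0.5)
        r2 = margin_metrics(a2, tumor, spacing=0.5)
        assert r2.minimal_margin_mm >= r1.minimal_margin_mm
        assert r2.coverage >= r1.coverage

    def test_invariant_to_grid_rotation(self):
        rng = np.random.default_rng(3)
        tumor = np.zeros((24, 24, 24), dtype=bool)
        tumor[6:14, 8:18, 5:12] = True
        ablation = euclidean_dilate(tumor, 2)
        ablation[20:, :, :] = rng.random((4, 24, 24)) > 0.8
        r0 = margin_metrics(ablation, tumor, spacing=1.0)
        rt = margin_metrics(np.rot90(ablation, axes=(0, 1)),
                            np.rot90(tumor, axes=(0, 1)), spacing=1.0)
        assert rt.minimal_margin_mm == pytest.approx(r0.minimal_margin_mm)
        assert rt.coverage == pytest.approx(r0.coverage)
        assert rt.dice == pytest.approx(r0.dice)

    def test_coverage_one_iff_nonnegative_margin(self):
        tumor = make_sphere(8)
        # ablation missing a chunk of the tumor
        ablation = euclidean_dilate(tumor, 2)
        ablation[: ablation.shape[0] // 2] = False
        rep = margin_metrics(ablation, tumor, spacing=0.5)
        assert rep.coverage < 1.0
        assert rep.minimal_margin_mm < 0

    def test_required_margin_enters_over_ablation_and_dice(self):
        tumor = make_sphere(8)
        ablation = euclidean_dilate(tumor, 4)
        strict = margin_metrics(ablation, tumor, spacing=0.5, required_margin=0.0)
        lenient = margin_metrics(ablation, tumor, spacing=0.5, required_margin=2.0)
        assert lenient.over_ablation_ratio < strict.over_ablation_ratio
        assert lenient.dice > strict.dice


class TestEndToEnd:
    def test_planned_archetypes_cover_their_targets(self, coeffs, device):
        """Plan -> synthesize -> rasterize covers the target's own
        rasterization with coverage >= 0.95 for all four archetypes."""
        from ablashape.scenarios import RunConfig, run_scenario

        for name in ("cylinder", "dumbbell", "teardrop", "spheres"):
            bundle = run_scenario(name, RunConfig(seed=0))
            assert bundle["margin_report"].coverage >= 0.95, name
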