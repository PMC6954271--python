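"""Tissue masking, areas, mesh surface area and case summaries."""

import numpy as np
import pytest
import trimesh

from circumscan import geometry
from circumscan.coverage import (
    CaseRecord,
    SurfaceMesh,
    area_from_mask,
    coverage_percent,
    load_reference_cases,
    mesh_surface_area,
    otsu_tissue_mask,
    pathology_sampling_fraction_pct,
    summarize_cases,
)


def brute_force_otsu(image: np.ndarray) -> int:
    """Exhaustive between-class-variance maximizer over all 256 8-bit levels.

    Independent oracle: tries every possible threshold level on the exact
    integer histogram and returns the level whose split maximizes
    ``w0*w1*(mu0-mu1)^2`` (mask = pixels strictly above it).
    """
    counts = np.bincount(np.asarray(image, dtype=np.uint8).ravel(),
                         minlength=256).astype(float)
    levels = np.arange(256, dtype=float)
    total = counts.sum()
    best_t, best_v = 0, -1.0
    for k in range(1, 256):
        w0, w1 = counts[:k].sum(), total - counts[:k].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * levels[:k]).sum() / w0
        mu1 = (counts[k:] * levels[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, k - 1
    return best_t


class TestOtsuMask:
    def test_two_gaussian_mixture_separated(self):
        rng = np.random.default_rng(0)
        labels = rng.uniform(size=(200, 200)) < 0.5
        img = np.where(labels, rng.normal(0.8, 0.05, labels.shape),
                       rng.normal(0.2, 0.05, labels.shape))
        mask = otsu_tissue_mask(img)
        assert (mask != labels).mean() < 0.01

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_threshold_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = np.concatenate([rng.normal(60, 15, 4000),
                              rng.normal(180, 25, 3000)])
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        mask = otsu_tissue_mask(img)
        oracle_mask = img > brute_force_otsu(img)
        np.testing.assert_array_equal(mask, oracle_mask)

    def test_constant_image_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = otsu_tissue_mask(np.full((5, 5), 3.0))
        assert not mask.any()


class TestAreas:
    def test_pixel_area_conversion(self):
        mask = np.ones((1000, 1000), dtype=bool)
        assert area_from_mask(mask, 0.645) == pytest.approx(1e6 * 0.645**2 * 1e-8)

    def test_full_frame_area(self):
        mask = np.ones((2048, 2048), dtype=bool)
        assert area_from_mask(mask, 0.645) == pytest.approx(0.01745, abs=2e-5)

    def test_empty_mask(self):
        assert area_from_mask(np.zeros((4, 4), bool), 0.645) == 0.0


class TestMeshArea:
    def test_unit_right_triangle(self):
        mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        assert mesh_surface_area(mesh) == pytest.approx(0.005)  # 0.5 mm^2

    def test_unit_cube(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        mesh = SurfaceMesh(box.vertices, box.faces)
        assert mesh_surface_area(mesh) == pytest.approx(0.06)  # 6 mm^2

    def test_icosphere_approaches_analytic_sphere(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
        mesh = SurfaceMesh(ico.vertices, ico.faces)
        analytic = 4 * np.pi * 400 / 100  # 50.27 cm^2
        assert mesh_surface_area(mesh) == pytest.approx(analytic, rel=0.005)
        # independent cross-check against trimesh's own area
        assert mesh_surface_area(mesh) == pytest.approx(ico.area / 100, rel=1e-9)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError):
            mesh_surface_area(SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3))))


class TestCoveragePercent:
    @pytest.mark.parametrize("sim, surface, expected", [
        (26.63, 67.556, 39.42),
        (30.64, 67.556, 45.35),
        (0.0, 10.0, 0.0),
    ])
    def test_values(self, sim, surface, expected):
        assert round(coverage_percent(sim, surface), 2) == expected

    def test_zero_surface_rejected(self):
        with pytest.raises(ValueError):
            coverage_percent(1.0, 0.0)


class TestCaseSummaries:
    def test_reference_manual_statistics(self):
        report = summarize_cases(load_reference_cases())
        manual = report.stats["manual"]
        assert manual["sim_area_cm2"] == (21.95, 5.18)
        assert manual["surface_area_cm2"] == (67.56, 11.49)
        assert manual["coverage_pct"] == (33.27, 9.56)
        assert manual["elapsed_min"] == (43, 6)

    def test_reference_automated_statistics(self):
        report = summarize_cases(load_reference_cases())
        apps = report.stats["apps"]
        assert apps["sim_area_cm2"] == (28.64, 2.01)
        assert apps["coverage_pct"] == (42.39, 2.97)
        assert apps["elapsed_min"] == (36, 4)

    def test_throughputs_and_ratio(self):
        report = summarize_cases(load_reference_cases())
        assert report.throughput_cm2_per_min == {"manual": 0.5, "apps": 0.8}
        assert report.throughput_ratio == 1.6

    def test_population_sd_is_the_discriminator(self):
        # sample SD (N-1) does NOT reproduce the printed 5.18
        areas = [r.sim_area_cm2 for r in load_reference_cases()
                 if r.method == "manual"]
        assert round(float(np.std(areas, ddof=1)), 2) != 5.18
        assert round(float(np.std(areas, ddof=0)), 2) == 5.18

    def test_single_record_sd_zero(self):
        rec = CaseRecord("x", "manual", 10.0, 50.0, elapsed_min=20.0)
        report = summarize_cases([rec])
        assert report.stats["manual"]["sim_area_cm2"] == (10.0, 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_cases([])


class TestPathologyComparison:
    def test_sampling_fraction(self):
        assert pathology_sampling_fraction_pct() == pytest.approx(0.1333, abs=5e-4)

    def test_coverage_improvement_factor(self):
        report = summarize_cases(load_reference_cases())
        apps_cov = report.stats["apps"]["coverage_pct"][0]
        factor = apps_cov / pathology_sampling_fraction_pct()
        assert round(factor) == 318


class TestPhantomCoverage:
    def test_measured_fraction_matches_geometric_model(self, plain_panorama):
        _, roll = plain_panorama
        mask = otsu_tissue_mask(roll.image)
        measured = float(mask.mean())
        predicted = geometry.polygonal_coverage(0.2, 10).coverage_fraction
        assert abs(measured - predicted) * 100 < 2.0
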