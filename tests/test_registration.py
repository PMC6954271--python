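"""Fiducial detection, panel alignment, slippage and duplicate handling."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from circumscan import mosaic, phantom, registration
from circumscan.registration import (
    MarkerSet,
    align_panels,
    apply_alignment,
    detect_duplicate_overlap,
    detect_fiducials,
    measure_hash_spacing,
)
from tests.conftest import PHANTOM_MM_PER_PX, PHANTOM_OVERLAP


def _stitched(surf, plan, organ, slippage=()):
    acq = phantom.simulate_acquisition(surf, plan, organ, slippage=slippage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        panels, _ = mosaic.stitch_acquisition(acq, PHANTOM_OVERLAP)
    return panels


class TestDetectFiducials:
    def test_positions_match_ground_truth(self, marked_phantom):
        surf, _, _ = marked_phantom
        truth = surf.feature_log[-1]
        ms = detect_fiducials(surf.image)
        assert ms.central_line_y_px == pytest.approx(
            truth["central_line_y_px"], abs=2
        )
        # hashes away from the wrap seam are all recovered within 2 px
        interior = [x for x in truth["hash_x_px"] if x > 5]
        for x in interior:
            assert np.min(np.abs(ms.hash_x_positions_px - x)) <= 2

    def test_detection_on_reconstructed_panels(self, marked_phantom,
                                               marked_panels):
        surf, _, _ = marked_phantom
        truth_y = surf.feature_log[-1]["central_line_y_px"]
        found = [detect_fiducials(p) for p in marked_panels]
        assert all(m.central_line_y_px is not None for m in found)
        for m in found:
            assert m.central_line_y_px == pytest.approx(truth_y, abs=2)

    def test_unmarked_panel_yields_empty_set(self, plain_panorama):
        panels, _ = plain_panorama
        with pytest.warns(UserWarning, match="no fiducial"):
            ms = detect_fiducials(panels[0])
        assert ms.central_line_y_px is None
        assert ms.n_hashes == 0 and ms.confidence == 0.0

    def test_hash_count_matches_circumference(self):
        # d = 40 mm, spacing 10 mm -> floor(125.66 / 10) = 12 marks
        surf = phantom.generate_surface(40, 4, 0.05, feature_params={
            "nerve": {"density_per_mm2": 0}, "adipose": {"density_per_mm2": 0},
            "nucleus": {"density_per_mm2": 0}}, seed=0)
        marked = phantom.apply_fiducials(surf)
        ms = detect_fiducials(marked.image)
        # the mark at the wrap seam (x = 0) has no left flank; allow it missed
        assert ms.n_hashes in (11, 12)


class TestHashSpacing:
    def test_phantom_spacing_recovered(self, marked_phantom):
        surf, _, _ = marked_phantom
        ms = detect_fiducials(surf.image)
        assert ms.n_hashes >= 2
        spacing = measure_hash_spacing(ms, surf.mm_per_px)
        assert spacing == pytest.approx(10.0, abs=0.1)

    def test_synthetic_positions(self):
        ms = MarkerSet(0.0, np.array([0.0, 100.0, 200.0]), 1.0)
        assert measure_hash_spacing(ms, 0.1) == pytest.approx(10.0)

    def test_too_few_hashes_rejected(self):
        with pytest.raises(ValueError):
            measure_hash_spacing(MarkerSet(0.0, np.array([5.0]), 1.0), 0.1)


class TestDuplicateOverlap:
    def test_identical_panels(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(0).uniform(size=(120, 90)), 1.0)
        res = detect_duplicate_overlap(img, img)
        assert res["overlap_fraction"] == pytest.approx(1.0, abs=0.02)
        assert res["is_repeat"]

    def test_unrelated_textures(self):
        a = np.random.default_rng(1).uniform(size=(100, 80))
        b = np.random.default_rng(2).uniform(size=(100, 80))
        res = detect_duplicate_overlap(a, b)
        assert res["overlap_fraction"] == pytest.approx(0.0, abs=0.05)
        assert not res["is_repeat"]

    def test_ninety_percent_duplicate(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(3).uniform(size=(150, 400)), 1.0)
        a, b = img[:, :200], img[:, 20:220]  # 90% shared content
        res = detect_duplicate_overlap(a, b)
        assert res["overlap_fraction"] == pytest.approx(0.9, abs=0.05)
        assert res["is_repeat"]

    def test_symmetric_in_arguments(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(4).uniform(size=(100, 300)), 1.0)
        a, b = img[:, :160], img[:, 120:280]
        r1 = detect_duplicate_overlap(a, b)
        r2 = detect_duplicate_overlap(b, a)
        assert r1["overlap_fraction"] == pytest.approx(
            r2["overlap_fraction"], abs=1 / 160
        )


class TestAlignment:
    def test_no_slippage_gives_zero_offsets(self, marked_panels):
        result = align_panels(marked_panels)
        np.testing.assert_allclose(result.axial_offsets_px, 0.0, atol=1)

    def test_alignment_idempotent(self, marked_panels):
        result = align_panels(marked_panels)
        corrected = apply_alignment(marked_panels, result)
        again = align_panels(corrected)
        np.testing.assert_allclose(again.axial_offsets_px, 0.0, atol=1)

    def test_axial_slippage_recovered(self, marked_phantom):
        surf, plan, organ = marked_phantom
        slip_mm = 1.5  # 25% of the 6 mm panel length
        panels = _stitched(surf, plan, organ,
                           [phantom.SlippageEvent(4, axial_mm=slip_mm)])
        result = align_panels(panels)
        slip_px = slip_mm / PHANTOM_MM_PER_PX
        assert result.axial_offsets_px[4] == pytest.approx(-slip_px, abs=2)
        others = [o for i, o in enumerate(result.axial_offsets_px) if i != 4]
        np.testing.assert_allclose(others, 0.0, atol=1)

    def test_axial_correction_restores_continuity(self, marked_phantom):
        surf, plan, organ = marked_phantom
        panels = _stitched(surf, plan, organ,
                           [phantom.SlippageEvent(4, axial_mm=1.5)])
        reference = _stitched(surf, plan, organ)
        corrected = apply_alignment(panels, align_panels(panels))
        img = corrected[4].image
        ref = reference[4].image
        h = int(img.shape[0] * 0.6)  # central rows unaffected by fill
        a = img[:h][ref[:h] > 0] - np.mean(img[:h][ref[:h] > 0])
        b = ref[:h][ref[:h] > 0] - np.mean(ref[:h][ref[:h] > 0])
        ncc = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert ncc > 0.95

    def test_rotational_slippage_flagged_and_trimmed(self, marked_phantom):
        surf, plan, organ = marked_phantom
        panels = _stitched(surf, plan, organ,
                           [phantom.SlippageEvent(2, rotational_deg=-36.0)])
        result = align_panels(panels)
        flag = result.duplicate_flags[1]  # pair (panel 1, panel 2)
        assert flag["is_repeat"] and flag["overlap_fraction"] > 0.9
        corrected = apply_alignment(panels, result, repeat_policy="trim")
        assert (len(corrected) < len(panels)
                or corrected[2].image.shape[1] < panels[2].image.shape[1] * 0.2)
        dropped = apply_alignment(panels, result, repeat_policy="drop")
        assert len(dropped) == len(panels) - 1
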