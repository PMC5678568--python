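"""Pore measurement: both paths, Eq 1-2 identities, gates, recovery properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk, ellipse

from stomapore.geometry import EllipseParams, ellipse_mask, ellipse_points
from stomapore.morphometry import (
    EllipseFitError,
    PoreConfig,
    axes_from_area_ecc,
    binarize_roi,
    find_regions,
    fit_ellipse,
    mask_and_measure,
    measure_pore,
    measure_region,
    prune_spurs,
    select_pore_region,
    select_skeleton,
    skeletonize_regions,
)
from stomapore.synth import GroundTruthStoma, SceneSpec, render_scene, render_stoma


def _roi_config(box_side: float) -> PoreConfig:
    w = box_side
    return PoreConfig(
        area_min_px=int(0.08 * w * w),
        area_max_px=int(0.45 * w * w),
        skeleton_length_bounds=(0.6 * w, 2.6 * w),
    )


def _ground_truth_rois(spec: SceneSpec):
    """Yield (roi, config, gt) for every planted stoma of a scene."""
    micrograph, truths = render_scene(spec)
    for gt in truths:
        w = 3.2 * gt.pore.semi_major_px
        half = int(round(0.65 * w))
        r, c = int(round(gt.center[0])), int(round(gt.center[1]))
        roi = micrograph.pixels[
            max(0, r - half) : r + half, max(0, c - half) : c + half
        ]
        yield roi, _roi_config(w), gt, micrograph.pixel_scale


class TestBinarize:
    def test_constant_all_background(self):
        binary = binarize_roi(np.full((32, 32), 0.5))
        assert not binary.any()

    def test_two_level_partition(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        binary = binarize_roi(img, PoreConfig(sharpen_amount=0.0))
        assert binary[:, :10].all()
        assert not binary[:, 10:].any()

    def test_complete_stoma_interior_connected(self):
        canvas = np.full((120, 120), 0.72)
        gt = GroundTruthStoma(
            center=(60.0, 60.0),
            pore=EllipseParams((60.0, 60.0), 20.0, 12.0, 0.0),
            completeness=1.0,
            orientation_deg=0.0,
        )
        binary = binarize_roi(render_stoma(gt, canvas))
        regions = find_regions(binary)
        big = max(regions, key=lambda r: r.area_px)
        expected = np.pi * 20.0 * 12.0
        assert abs(big.area_px - expected) / expected < 0.05


class TestFindRegions:
    def test_empty(self):
        assert find_regions(np.zeros((10, 10), bool)) == []

    def test_two_squares(self):
        img = np.zeros((10, 20), bool)
        img[2:5, 2:5] = True
        img[2:5, 12:15] = True
        regions = find_regions(img)
        assert sorted(r.area_px for r in regions) == [9, 9]

    def test_diagonal_connectivity(self):
        img = np.zeros((4, 4), bool)
        img[1, 1] = img[2, 2] = True
        assert len(find_regions(img, connectivity=8)) == 1
        assert len(find_regions(img, connectivity=4)) == 2


class TestSelectPoreRegion:
    CENTER = (50.0, 50.0)

    def _make(self, shape_fn):
        img = np.zeros((100, 100), bool)
        shape_fn(img)
        return find_regions(img)

    def test_no_regions_none(self):
        cfg = PoreConfig(area_max_px=500)
        assert select_pore_region([], self.CENTER, cfg) is None

    def test_single_centered_region(self):
        regions = self._make(lambda im: im.__setitem__(disk((50, 50), 10), True))
        cfg = PoreConfig(area_max_px=500)
        assert select_pore_region(regions, self.CENTER, cfg) is not None

    def test_area_filter_precedes_distance(self):
        def draw(im):
            im[disk((50, 50), 20)] = True  # big centered, above max
            im[disk((80, 80), 6)] = True  # small off-center
        regions = self._make(draw)
        cfg = PoreConfig(area_max_px=500, area_min_px=10)
        chosen = select_pore_region(regions, self.CENTER, cfg)
        assert chosen is not None
        assert chosen.area_px < 500

    def test_thin_arc_rejected_by_fill_ratio(self):
        def draw(im):
            e = EllipseParams((50.0, 50.0), 25.0, 15.0, 0.0)
            pts = np.round(ellipse_points(e, 300, t0=0.0, t1=1.4 * np.pi)).astype(int)
            im[pts[:, 0], pts[:, 1]] = True
        regions = self._make(draw)
        cfg = PoreConfig(area_max_px=5000, area_min_px=10)
        assert select_pore_region(regions, self.CENTER, cfg) is None

    def test_unresolved_config_errors(self):
        with pytest.raises(ValueError):
            select_pore_region([], self.CENTER, PoreConfig())


class TestMeasureRegion:
    def test_single_pixel(self):
        region = find_regions(np.eye(1, 3, 1, dtype=bool))[0]
        m = measure_region(region, pixel_scale=1.0)
        assert m.area_px2 == 1.0
        assert m.eccentricity == 0.0
        assert m.major_axis_px == pytest.approx(np.sqrt(1 / np.pi))
        assert m.minor_axis_px == pytest.approx(np.sqrt(1 / np.pi))

    def test_disc(self):
        img = np.zeros((60, 60), bool)
        img[disk((30, 30), 20)] = True
        m = measure_region(find_regions(img)[0], pixel_scale=1.0)
        assert abs(m.area_px2 - 400 * np.pi) / (400 * np.pi) < 0.02
        assert m.eccentricity <= 0.1

    def test_ellipse_eccentricity(self):
        img = np.zeros((120, 120), bool)
        rr, cc = ellipse(60, 60, 20, 40)
        img[rr, cc] = True
        m = measure_region(find_regions(img)[0], pixel_scale=1.0)
        assert abs(m.eccentricity - np.sqrt(1 - 0.25)) < 0.03

    def test_pixel_scale_conversion(self):
        img = np.zeros((30, 30), bool)
        img[disk((15, 15), 8)] = True
        m = measure_region(find_regions(img)[0], pixel_scale=2.0)
        assert m.area_um2 == pytest.approx(m.area_px2 / 4.0)

    def test_boundary_traced(self):
        img = np.zeros((40, 40), bool)
        img[disk((20, 20), 10)] = True
        m = measure_region(find_regions(img)[0], pixel_scale=1.0)
        assert m.boundary is not None and len(m.boundary) > 0
        # boundary pixels lie on the region and roughly at radius 10
        d = np.hypot(m.boundary[:, 0] - 20, m.boundary[:, 1] - 20)
        assert d.min() > 7 and d.max() < 11.5


class TestAxesFromAreaEcc:
    def test_unit_circle(self):
        assert axes_from_area_ecc(np.pi, 0.0) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_worked_example(self):
        a, b = axes_from_area_ecc(np.pi, np.sqrt(3) / 2)
        assert a == pytest.approx(np.sqrt(2), rel=1e-9)
        assert b == pytest.approx(np.sqrt(2) / 2, rel=1e-9)

    @pytest.mark.parametrize("A,E", [(0.0, 0.5), (-1.0, 0.5), (1.0, 1.0), (1.0, 1.5)])
    def test_domain_errors(self, A, E):
        with pytest.raises(ValueError):
            axes_from_area_ecc(A, E)

    @given(
        A=st.floats(1e-6, 1e8),
        E=st.floats(0.0, 0.999999),
    )
    @settings(max_examples=200, deadline=None)
    def test_identities(self, A, E):
        a, b = axes_from_area_ecc(A, E)
        assert np.pi * a * b == pytest.approx(A, rel=1e-9)
        assert b / a == pytest.approx(np.sqrt(1 - E * E), rel=1e-9)


class TestSkeletonize:
    def test_empty(self):
        assert skeletonize_regions(np.zeros((10, 10), bool)) == []

    def test_idempotent_on_thin_curve(self):
        img = np.zeros((30, 30), bool)
        rr = np.arange(5, 25)
        cc = (10 + 3 * np.sin(rr / 4)).astype(int)
        img[rr, cc] = True
        skeletons = skeletonize_regions(img)
        assert len(skeletons) == 1
        assert skeletons[0].length_px == img.sum()
        got = {tuple(p) for p in skeletons[0].coords}
        assert got == {tuple(p) for p in np.argwhere(img)}

    def test_rectangle_medial_axis(self):
        for w, h in [(40, 12), (30, 7), (50, 15)]:
            img = np.zeros((h + 10, w + 10), bool)
            img[5 : 5 + h, 5 : 5 + w] = True
            skeleton = prune_spurs(skeletonize_regions(img)[0])
            assert abs(skeleton.length_px - (w - h + 1)) <= 2

    def test_prune_leaves_open_curve(self):
        img = np.zeros((20, 40), bool)
        img[10, 5:35] = True
        s = skeletonize_regions(img)[0]
        assert prune_spurs(s).length_px == s.length_px

    def test_prune_removes_short_branch(self):
        img = np.zeros((30, 40), bool)
        img[15, 5:35] = True
        img[12:15, 20] = True  # 3-px stub off the main line
        s = skeletonize_regions(img)[0]
        assert prune_spurs(s, 5).length_px < s.length_px


class TestSelectSkeleton:
    def _skeleton(self, pts):
        coords = np.array(pts)
        from stomapore.morphometry import Skeleton

        return Skeleton(coords=coords, length_px=len(coords))

    def test_empty(self):
        cfg = PoreConfig(skeleton_length_bounds=(2, 100))
        assert select_skeleton([], (10, 10), cfg) is None

    def test_single_in_bounds(self):
        cfg = PoreConfig(skeleton_length_bounds=(2, 100))
        s = self._skeleton([(9, 9), (10, 10), (11, 11)])
        assert select_skeleton([s], (10, 10), cfg) is s

    def test_nearest_selected(self):
        cfg = PoreConfig(skeleton_length_bounds=(2, 100))
        near = self._skeleton([(12, 12), (13, 13), (14, 14)])
        far = self._skeleton([(50, 50), (51, 51), (52, 52)])
        assert select_skeleton([far, near], (10, 10), cfg) is near

    def test_length_bounds_enforced(self):
        cfg = PoreConfig(skeleton_length_bounds=(5, 10))
        short = self._skeleton([(10, 10), (10, 11)])
        assert select_skeleton([short], (10, 10), cfg) is None


class TestFitEllipse:
    TRUE = EllipseParams((40.0, 50.0), 30.0, 15.0, 30.0)

    def test_exact_recovery(self):
        pts = ellipse_points(self.TRUE, 20)
        f = fit_ellipse(pts)
        assert f.center[0] == pytest.approx(40.0, rel=1e-6)
        assert f.center[1] == pytest.approx(50.0, rel=1e-6)
        assert f.semi_major_px == pytest.approx(30.0, rel=1e-6)
        assert f.semi_minor_px == pytest.approx(15.0, rel=1e-6)
        assert f.orientation_deg == pytest.approx(30.0, abs=1e-4)

    def test_under_determined(self):
        pts = ellipse_points(self.TRUE, 4)
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)

    def test_collinear(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)

    def test_65pct_arc_within_5pct(self):
        pts = ellipse_points(self.TRUE, 60, t0=0.0, t1=0.65 * 2 * np.pi)
        f = fit_ellipse(pts)
        assert f.semi_major_px == pytest.approx(30.0, rel=0.05)
        assert f.semi_minor_px == pytest.approx(15.0, rel=0.05)

    def test_arc_coverage_gate(self):
        pts = ellipse_points(self.TRUE, 60, t0=0.0, t1=0.4 * 2 * np.pi)
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts, min_arc_fraction=0.6)


class TestMaskAndMeasure:
    def test_single_blob_measured(self):
        binary = np.zeros((80, 80), bool)
        binary[disk((40, 40), 15)] = True
        e = EllipseParams((40.0, 40.0), 18.0, 18.0, 0.0)
        img = np.where(binary, 0.1, 0.8)
        cfg = PoreConfig(area_max_px=4000, area_min_px=30)
        m = mask_and_measure(e, img, binary, 1.0, cfg)
        assert m.status == "measured"
        assert m.method == "skeleton"
        assert m.area_px2 == pytest.approx(np.pi * 225, rel=0.03)

    def test_empty_interior_discarded(self):
        binary = np.zeros((80, 80), bool)
        e = EllipseParams((40.0, 40.0), 15.0, 10.0, 0.0)
        img = np.full((80, 80), 0.8)
        cfg = PoreConfig(area_max_px=4000, area_min_px=30)
        m = mask_and_measure(e, img, binary, 1.0, cfg)
        assert m.status == "discarded"
        assert m.area_px2 is None

    def test_local_rebinarization_recovers_faded_interior(self):
        """Pixels brighter than the global threshold but darker than the
        surroundings are recovered inside the mask."""
        img = np.full((100, 100), 0.8)
        e = EllipseParams((50.0, 50.0), 20.0, 12.0, 0.0)
        interior = ellipse_mask(e, img.shape)
        img[interior] = 0.6  # faded: above a global threshold set by the ring
        ring = ellipse_mask(e, img.shape) & ~ellipse_mask(
            EllipseParams((50.0, 50.0), 17.0, 9.0, 0.0), img.shape
        )
        img[ring] = 0.1
        binary = img < 0.3  # global threshold catches only the ring
        cfg = PoreConfig(area_max_px=4000, area_min_px=30)
        m = mask_and_measure(e, img, binary, 1.0, cfg)
        assert m.status == "measured"
        expected = np.pi * 20 * 12
        assert m.area_px2 == pytest.approx(expected, rel=0.1)


class TestMeasurePore:
    def test_complete_stoma_segmentation_path(self):
        spec = SceneSpec(seed=301, complete_fraction=1.0)
        for roi, cfg, gt, scale in _ground_truth_rois(spec):
            m = measure_pore(roi, cfg, scale)
            assert m.status == "measured"
            assert m.method == "segmentation"

    def test_incomplete_stoma_skeleton_path(self):
        spec = SceneSpec(seed=302, complete_fraction=0.0, completeness_range=(0.7, 0.7))
        results = [measure_pore(roi, cfg, s) for roi, cfg, _, s in _ground_truth_rois(spec)]
        measured = [m for m in results if m.status == "measured"]
        assert len(measured) >= len(results) - 1
        assert all(m.method == "skeleton" for m in measured)

    def test_blank_roi_discarded(self):
        m = measure_pore(np.full((80, 80), 0.7), PoreConfig())
        assert m.status == "discarded"
        assert m.reason

    def test_measured_invariants(self):
        spec = SceneSpec(seed=303)
        for roi, cfg, _, scale in _ground_truth_rois(spec):
            m = measure_pore(roi, cfg, scale)
            if m.status != "measured":
                continue
            assert np.pi * m.major_axis_px * m.minor_axis_px == pytest.approx(
                m.area_px2, rel=1e-9
            )
            assert m.minor_axis_px / m.major_axis_px == pytest.approx(
                np.sqrt(1 - m.eccentricity**2), rel=1e-9
            )
            assert 0 <= m.eccentricity < 1

    def test_discarded_measurement_has_no_numbers(self):
        from stomapore.morphometry import PoreMeasurement

        with pytest.raises(ValueError):
            PoreMeasurement(status="discarded", area_px2=3.0)


class TestRecoveryProperties:
    def test_segmentation_path_recovery(self):
        """>= 50 seeded complete stomata: mean area error <= 5%, mean |dE| <= 0.05."""
        area_err = []
        ecc_err = []
        for seed in range(310, 317):
            spec = SceneSpec(seed=seed, complete_fraction=1.0)
            for roi, cfg, gt, scale in _ground_truth_rois(spec):
                m = measure_pore(roi, cfg, scale)
                assert m.status == "measured"
                area_err.append(abs(m.area_px2 - gt.pore.area) / gt.pore.area)
                ecc_err.append(abs(m.eccentricity - gt.pore.eccentricity))
        assert len(area_err) >= 50
        assert np.mean(area_err) <= 0.05
        assert np.mean(ecc_err) <= 0.05

    def test_skeleton_path_recovery(self):
        """Completeness 0.65-0.85: mean area error <= 15% on measured pores."""
        area_err = []
        n = 0
        for seed in range(320, 327):
            spec = SceneSpec(
                seed=seed, complete_fraction=0.0, completeness_range=(0.65, 0.85)
            )
            for roi, cfg, gt, scale in _ground_truth_rois(spec):
                n += 1
                m = measure_pore(roi, cfg, scale)
                if m.status == "measured":
                    area_err.append(abs(m.area_px2 - gt.pore.area) / gt.pore.area)
        assert len(area_err) >= 50
        assert len(area_err) / n >= 0.8
        assert np.mean(area_err) <= 0.15

    def test_completeness_gate_below_half(self):
        """The skeleton path rejects sub-50%-complete boundaries >= 80% of the time."""
        attempts = 0
        rejected = 0
        for seed in range(330, 335):
            spec = SceneSpec(
                seed=seed, complete_fraction=0.0, completeness_range=(0.3, 0.5)
            )
            for roi, cfg, _, scale in _ground_truth_rois(spec):
                binary = binarize_roi(roi, cfg)
                skeletons = [
                    prune_spurs(s, cfg.spur_length_px)
                    for s in skeletonize_regions(binary)
                ]
                skeletons = [s for s in skeletons if s.length_px > 0]
                remnant = select_skeleton(
                    skeletons, ((roi.shape[0] - 1) / 2, (roi.shape[1] - 1) / 2), cfg
                )
                attempts += 1
                if remnant is None:
                    rejected += 1
                    continue
                try:
                    fit_ellipse(
                        remnant.coords,
                        min_arc_fraction=cfg.min_completeness,
                        max_radial_deviation=cfg.max_fit_residual,
                    )
                except EllipseFitError:
                    rejected += 1
        assert attempts >= 30
        assert rejected / attempts >= 0.8

    def test_path_exclusivity(self):
        """method='skeleton' only when segmentation found no pore region."""
        spec = SceneSpec(seed=340)
        for roi, cfg, _, scale in _ground_truth_rois(spec):
            m = measure_pore(roi, cfg, scale)
            if m.method == "skeleton":
                resolved = cfg.resolved_for(roi.shape)
                region = select_pore_region(
                    find_regions(binarize_roi(roi, resolved), resolved.connectivity),
                    ((roi.shape[0] - 1) / 2, (roi.shape[1] - 1) / 2),
                    resolved,
                )
                assert region is None
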