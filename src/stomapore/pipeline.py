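"""End-to-end orchestration: train, detect, measure, evaluate.

The main entry points are :func:`run_end_to_end`, which takes a trained
cascade and a micrograph through detection and pore measurement, and
:func:`run_synthetic_study`, which reproduces the whole workflow on seeded
synthetic scenes with known ground truth and reports detection and
measurement quality in one record.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cascade import CascadeConfig, CascadeModel, Detection, detect, train_cascade
from .io import DETECTION_COLUMNS, MEASUREMENT_COLUMNS, Micrograph
from .metrics import ConfusionCounts, DetectionMetrics, detection_metrics, match_detection_indices
from .morphometry import PoreConfig, PoreMeasurement, measure_pore
from .synth import SceneSpec, make_training_set, render_scene

__all__ = [
    "DetectConfig",
    "StudyResult",
    "STUDY_SCALES",
    "roi_bounds",
    "pore_config_for_box",
    "measure_detections",
    "run_end_to_end",
    "detections_frame",
    "measurements_frame",
    "run_synthetic_study",
]

#: Scale ladder matched to the synthetic size range: positives are cropped at
#: 3.2x the pore semi-major axis and resampled to the 96-px window, so pores
#: of 12-35 px map to window scale factors of roughly 0.86-2.45.
STUDY_SCALES = (0.86, 1.12, 1.45, 1.89, 2.45)

#: ROI crop margin relative to the detection box (the measurement engine
#: wants a little context around the pore).
ROI_MARGIN = 1.3


@dataclass(frozen=True)
class DetectConfig:
    """Sliding-window detection parameters."""

    stride_px: int = 8
    scale_factors: tuple[float, ...] = STUDY_SCALES
    nms_iou: float = 0.3
    merge_concentric: bool = True


def roi_bounds(
    detection: Detection, image_shape: tuple[int, int], margin: float = ROI_MARGIN
) -> tuple[int, int, int, int]:
    """Clipped ROI box: the detection box grown by ``margin`` about its center."""
    r0, c0, r1, c1 = detection.box
    cr, cc = detection.center
    half_r = margin * (r1 - r0) / 2.0
    half_c = margin * (c1 - c0) / 2.0
    return (
        max(0, int(round(cr - half_r))),
        max(0, int(round(cc - half_c))),
        min(image_shape[0], int(round(cr + half_r))),
        min(image_shape[1], int(round(cc + half_c))),
    )


def pore_config_for_box(detection: Detection, base: PoreConfig = PoreConfig()) -> PoreConfig:
    """Size the pore-selection gates from the detection box side.

    A correct detection frames the stoma, so the box side ``w`` bounds the
    plausible pore: area within ``[0.08 w², 0.45 w²]`` and boundary-skeleton
    length within ``[0.6 w, 2.6 w]`` (an ellipse perimeter is between ~2 and
    ~4 times its semi-major axis, and the pore fills a good fraction of a
    matched window).
    """
    r0, c0, r1, c1 = detection.box
    w = (r1 - r0 + c1 - c0) / 2.0
    from dataclasses import replace

    return replace(
        base,
        area_min_px=int(0.08 * w * w),
        area_max_px=int(0.45 * w * w),
        skeleton_length_bounds=(0.6 * w, 2.6 * w),
    )


def measure_detections(
    micrograph: Micrograph,
    detections: list[Detection],
    base_config: PoreConfig = PoreConfig(),
) -> list[PoreMeasurement]:
    """Measure the pore inside each detection's ROI, one record per box."""
    out = []
    for det in detections:
        r0, c0, r1, c1 = roi_bounds(det, micrograph.shape)
        roi = micrograph.pixels[r0:r1, c0:c1]
        cfg = pore_config_for_box(det, base_config)
        out.append(measure_pore(roi, cfg, pixel_scale=micrograph.pixel_scale))
    return out


def detections_frame(micrograph: Micrograph, detections: list[Detection]) -> pd.DataFrame:
    rows = [
        {
            "image_id": micrograph.image_id,
            "row0": d.box[0],
            "col0": d.box[1],
            "row1": d.box[2],
            "col1": d.box[3],
            "score": d.score,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def measurements_frame(
    micrograph: Micrograph, measurements: list[PoreMeasurement]
) -> pd.DataFrame:
    rows = [
        {
            "image_id": micrograph.image_id,
            "roi_id": i,
            "status": m.status,
            "method": m.method or "",
            "area_px2": m.area_px2,
            "area_um2": m.area_um2,
            "major_axis_px": m.major_axis_px,
            "minor_axis_px": m.minor_axis_px,
            "eccentricity": m.eccentricity,
        }
        for i, m in enumerate(measurements)
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def run_end_to_end(
    model: CascadeModel,
    micrograph: Micrograph,
    detect_config: DetectConfig = DetectConfig(),
    pore_config: PoreConfig = PoreConfig(),
) -> tuple[list[Detection], list[PoreMeasurement]]:
    """Detect stomata, then measure each detected pore.

    The two returned lists are index-aligned: measurement ``i`` belongs to
    detection ``i``, and every detection yields exactly one record (measured
    or discarded) — counts are conserved.
    """
    detections = detect(
        model,
        micrograph,
        stride_px=detect_config.stride_px,
        scale_factors=detect_config.scale_factors,
        nms_iou=detect_config.nms_iou,
        merge_concentric=detect_config.merge_concentric,
    )
    measurements = measure_detections(micrograph, detections, pore_config)
    return detections, measurements


@dataclass(frozen=True)
class StudyResult:
    """Outcome of one seeded synthetic study."""

    n_scenes: int
    n_true_stomata: int
    detection: DetectionMetrics
    n_rois: int
    n_measured: int
    measured_fraction_pct: float
    #: mean agreement (percent) over matched true-positive ROIs, by path
    area_agreement_segmentation_pct: Optional[float]
    area_agreement_skeleton_pct: Optional[float]
    eccentricity_agreement_pct: Optional[float]
    n_matched_measured_segmentation: int
    n_matched_measured_skeleton: int
    train_seconds: float
    detect_seconds: float
    measure_seconds: float
    model: CascadeModel = field(repr=False)


def run_synthetic_study(
    seed: int,
    n_pos: int = 200,
    n_neg: int = 100,
    n_scenes: int = 20,
    cascade_config: Optional[CascadeConfig] = None,
    detect_config: DetectConfig = DetectConfig(),
    scene_spec: SceneSpec = SceneSpec(),
) -> StudyResult:
    """Train on fresh synthetic data, evaluate on held-out scenes.

    Training scenes derive from ``seed``; evaluation scenes derive from
    ``seed + 1`` so the two sets never share a scene.  Detection quality is
    scored against ground-truth centers; measurement agreement is computed
    only over matched (true-positive) ROIs, where the planted pore provides
    the reference area ``π a b`` and eccentricity.
    """
    from dataclasses import replace

    root = np.random.SeedSequence(seed)
    train_seed, eval_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(2))

    t0 = time.perf_counter()
    positives, negatives = make_training_set(
        replace(scene_spec, seed=train_seed), n_pos=n_pos, n_neg=n_neg
    )
    config = cascade_config or CascadeConfig(seed=seed % (2**31 - 1))
    model = train_cascade(positives, negatives, config)
    train_seconds = time.perf_counter() - t0

    tp = fp = fn = 0
    n_true = 0
    area_seg: list[float] = []
    area_skel: list[float] = []
    ecc_all: list[float] = []
    n_rois = 0
    n_measured = 0
    detect_seconds = 0.0
    measure_seconds = 0.0

    eval_root = np.random.SeedSequence(eval_seed)
    for child in eval_root.spawn(n_scenes):
        scene_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        micrograph, truths = render_scene(replace(scene_spec, seed=scene_seed))
        n_true += len(truths)

        t0 = time.perf_counter()
        detections = detect(
            model,
            micrograph,
            stride_px=detect_config.stride_px,
            scale_factors=detect_config.scale_factors,
            nms_iou=detect_config.nms_iou,
            merge_concentric=detect_config.merge_concentric,
        )
        detect_seconds += time.perf_counter() - t0

        centers = np.array([t.center for t in truths]).reshape(-1, 2)
        matches, unmatched_d, unmatched_t = match_detection_indices(detections, centers)
        tp += len(matches)
        fp += len(unmatched_d)
        fn += len(unmatched_t)

        t0 = time.perf_counter()
        measurements = measure_detections(micrograph, detections)
        measure_seconds += time.perf_counter() - t0
        n_rois += len(measurements)
        n_measured += sum(1 for m in measurements if m.status == "measured")

        for di, ti in matches:
            m = measurements[di]
            if m.status != "measured":
                continue
            pore = truths[ti].pore
            ref_area = pore.area
            agree_area = 100.0 - 100.0 * abs(m.area_px2 - ref_area) / ref_area
            agree_ecc = 100.0 - 100.0 * abs(m.eccentricity - pore.eccentricity) / pore.eccentricity
            (area_seg if m.method == "segmentation" else area_skel).append(agree_area)
            ecc_all.append(agree_ecc)

    det_metrics = detection_metrics(ConfusionCounts(tp, fp, fn))
    return StudyResult(
        n_scenes=n_scenes,
        n_true_stomata=n_true,
        detection=det_metrics,
        n_rois=n_rois,
        n_measured=n_measured,
        measured_fraction_pct=100.0 * n_measured / n_rois if n_rois else 0.0,
        area_agreement_segmentation_pct=float(np.mean(area_seg)) if area_seg else None,
        area_agreement_skeleton_pct=float(np.mean(area_skel)) if area_skel else None,
        eccentricity_agreement_pct=float(np.mean(ecc_all)) if ecc_all else None,
        n_matched_measured_segmentation=len(area_seg),
        n_matched_measured_skeleton=len(area_skel),
        train_seconds=train_seconds,
        detect_seconds=detect_seconds,
        measure_seconds=measure_seconds,
        model=model,
    )
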