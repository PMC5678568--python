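"""Trainable attentional cascade of boosted HOG stumps.

Each stage is a discrete-AdaBoost ensemble of depth-1 decision stumps on
single HOG components.  After boosting, the stage threshold is lowered until
the stage retains at least ``stage_tpr_min`` of its training positives, and
the false-positive rate actually achieved on the stage's negatives is
recorded.  Stages are trained sequentially: stage k sees only the positives
surviving stages 1..k-1 and negatives that earlier stages still accept
(false positives bootstrapped from the negative patch pool), so early stages
reject the easy background and later stages refine.

Detection slides the window over an image pyramid at a cell-aligned stride,
evaluates the cascade with early exit (vectorized per stage), maps accepted
windows back to original coordinates and merges them by greedy
non-maximum suppression.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import rescale, resize

from .hog import CellHogGrid, HOGParams, compute_hog
from .io import Micrograph

logger = logging.getLogger(__name__)

MODEL_FORMAT = "stomapore-cascade"
MODEL_VERSION = 1


@dataclass(frozen=True)
class WeakLearner:
    """Decision stump on one HOG component.

    Accepts (votes positive) when ``polarity=+1`` and ``value <= threshold``,
    or ``polarity=-1`` and ``value > threshold``.
    """

    feature_index: int
    threshold: float
    polarity: int
    weight: float


@dataclass
class BoostedStage:
    weak_learners: list[WeakLearner]
    stage_threshold: float
    training_tpr: float = 1.0
    training_fpr: float = 1.0

    def __post_init__(self) -> None:
        if not self.weak_learners:
            raise ValueError("a stage needs at least one weak learner")
        if any(w.weight < 0 for w in self.weak_learners):
            raise ValueError("weak-learner weights must be non-negative")

    def response(self, get_feature) -> np.ndarray:
        """Weighted vote sum; ``get_feature(i)`` returns feature i per window."""
        total = None
        for wl in self.weak_learners:
            values = np.asarray(get_feature(wl.feature_index), dtype=np.float64)
            votes = (values <= wl.threshold) if wl.polarity > 0 else (values > wl.threshold)
            term = wl.weight * votes
            total = term if total is None else total + term
        return total


@dataclass
class CascadeModel:
    hog: HOGParams
    stages: list[BoostedStage]

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def to_json(self) -> str:
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "hog": {
                "window_px": list(self.hog.window_px),
                "cell_px": self.hog.cell_px,
                "block_cells": self.hog.block_cells,
                "n_orientation_bins": self.hog.n_orientation_bins,
                "normalization_epsilon": self.hog.normalization_epsilon,
            },
            "stages": [
                {
                    "stage_threshold": s.stage_threshold,
                    "training_tpr": s.training_tpr,
                    "training_fpr": s.training_fpr,
                    "weak_learners": [
                        [w.feature_index, w.threshold, w.polarity, w.weight]
                        for w in s.weak_learners
                    ],
                }
                for s in self.stages
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CascadeModel":
        payload = json.loads(text)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError("not a stomapore cascade model file")
        if payload.get("version") != MODEL_VERSION:
            raise ValueError(f"unsupported model version {payload.get('version')}")
        hog = HOGParams(
            window_px=tuple(payload["hog"]["window_px"]),
            cell_px=payload["hog"]["cell_px"],
            block_cells=payload["hog"]["block_cells"],
            n_orientation_bins=payload["hog"]["n_orientation_bins"],
            normalization_epsilon=payload["hog"]["normalization_epsilon"],
        )
        stages = [
            BoostedStage(
                weak_learners=[
                    WeakLearner(int(f), float(t), int(p), float(w))
                    for f, t, p, w in s["weak_learners"]
                ],
                stage_threshold=float(s["stage_threshold"]),
                training_tpr=float(s.get("training_tpr", 1.0)),
                training_fpr=float(s.get("training_fpr", 1.0)),
            )
            for s in payload["stages"]
        ]
        return cls(hog=hog, stages=stages)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CascadeModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class Detection:
    """Axis-aligned box (0-based, half-open) with a ranking score."""

    box: tuple[int, int, int, int]
    score: float

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1):
            raise ValueError("detection box must have positive extent")

    @property
    def center(self) -> tuple[float, float]:
        r0, c0, r1, c1 = self.box
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


@dataclass(frozen=True)
class CascadeConfig:
    n_stages: int = 8
    stage_tpr_min: float = 0.995
    stage_fpr_max: float = 0.5
    max_weak_learners: int = 64
    #: Lower bound on boosting rounds per stage, growing with stage depth the
    #: way attentional cascades usually do; deeper stages carve a smoother
    #: margin and generalize to distractor configurations (vein angles,
    #: wall junctions) not present verbatim in the bootstrap sample.
    min_weak_learners_schedule: tuple[int, ...] = (4, 8, 12, 16, 20, 24, 28, 32)
    max_negatives_per_stage: int = 800
    min_negatives_per_stage: int = 10
    hog: HOGParams = field(default_factory=HOGParams)
    seed: int = 0


def to_window(patch: np.ndarray, window_px: tuple[int, int]) -> np.ndarray:
    """Resample a patch to the detector window size."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape == tuple(window_px):
        return patch
    return resize(patch, window_px, anti_aliasing=True, preserve_range=True)


def train_stage(
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    stage_tpr_min: float = 0.995,
    stage_fpr_max: float = 0.5,
    max_weak_learners: int = 64,
    min_weak_learners: int = 1,
) -> BoostedStage:
    """Boost decision stumps into one cascade stage.

    Discrete AdaBoost over all HOG components; after each round the stage
    threshold is set so the stage keeps at least ``stage_tpr_min`` of the
    positives, and boosting stops as soon as the induced false-positive rate
    on ``neg_features`` drops to ``stage_fpr_max`` (or the learner budget is
    spent, in which case the achieved rate is recorded).
    """
    pos_features = np.atleast_2d(np.asarray(pos_features, dtype=np.float64))
    neg_features = np.atleast_2d(np.asarray(neg_features, dtype=np.float64))
    if pos_features.size == 0 or neg_features.size == 0:
        raise ValueError("both positive and negative feature sets must be non-empty")
    n_pos, n_feat = pos_features.shape
    n_neg = neg_features.shape[0]
    if neg_features.shape[1] != n_feat:
        raise ValueError("positive/negative feature dimensionality mismatch")

    X = np.vstack([pos_features, neg_features])
    y = np.concatenate([np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)])
    m = n_pos + n_neg
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    # Thresholds at midpoints of distinct neighbours; last row accepts all.
    invalid = np.zeros((m, n_feat), dtype=bool)
    invalid[:-1] = xs[:-1] >= xs[1:]
    thresholds = np.empty_like(xs)
    thresholds[:-1] = 0.5 * (xs[:-1] + xs[1:])
    thresholds[-1] = xs[-1] + 1.0

    w = np.where(y, 0.5 / n_pos, 0.5 / n_neg)
    learners: list[WeakLearner] = []
    scores = np.zeros(m)
    stage_threshold = 0.0
    tpr = fpr = 1.0

    for _round in range(max_weak_learners):
        ws = np.take_along_axis(np.broadcast_to(w[:, None], (m, n_feat)), order, axis=0)
        cpos = np.cumsum(ws * ys, axis=0)
        cneg = np.cumsum(ws * (~ys), axis=0)
        tot_pos = cpos[-1:]
        tot_neg = cneg[-1:]
        err_below = cneg + (tot_pos - cpos)  # accept values <= threshold
        err_above = cpos + (tot_neg - cneg)  # accept values > threshold
        err_below[invalid] = np.inf
        err_above[invalid] = np.inf
        best_b = int(np.argmin(err_below))
        best_a = int(np.argmin(err_above))
        if err_below.ravel()[best_b] <= err_above.ravel()[best_a]:
            k, f = np.unravel_index(best_b, err_below.shape)
            polarity, eps = 1, float(err_below[k, f])
        else:
            k, f = np.unravel_index(best_a, err_above.shape)
            polarity, eps = -1, float(err_above[k, f])
        eps = min(max(eps, 1e-12), 1.0 - 1e-12)
        # eps can round a hair above 0.5 on undiscriminable data; clamp the
        # vote weight at zero rather than letting it go negative.
        alpha = max(0.0, float(np.log((1.0 - eps) / eps)))
        learner = WeakLearner(int(f), float(thresholds[k, f]), polarity, alpha)
        learners.append(learner)

        values = X[:, f]
        votes = (values <= learner.threshold) if polarity > 0 else (values > learner.threshold)
        scores += alpha * votes
        mistakes = votes != y
        w = w * np.exp(alpha * mistakes)
        w = w / w.sum()

        pos_sorted = np.sort(scores[:n_pos])
        idx = int(np.floor((1.0 - stage_tpr_min) * n_pos))
        stage_threshold = float(pos_sorted[idx] - 1e-9)
        tpr = float(np.mean(scores[:n_pos] >= stage_threshold))
        fpr = float(np.mean(scores[n_pos:] >= stage_threshold))
        if fpr <= stage_fpr_max and len(learners) >= min_weak_learners:
            break

    if tpr < stage_tpr_min:
        raise RuntimeError(
            f"stage TPR {tpr:.4f} below target {stage_tpr_min} with "
            f"{len(learners)} weak learners"
        )
    return BoostedStage(learners, stage_threshold, training_tpr=tpr, training_fpr=fpr)


class _NegativePool:
    """Window references into negative patches, across a few patch scales.

    The scales span the detection pyramid so bootstrapped negatives look
    like what the sliding window will actually see.
    """

    SCALES = (0.8, 1.0, 1.3, 1.9, 2.5)
    STRIDE_CELLS = 1

    def __init__(self, patches: list[np.ndarray], hog: HOGParams, scales=None):
        self.hog = hog
        if scales is not None:
            self.SCALES = tuple(scales)
        self.grids: list[CellHogGrid] = []
        entries = []
        for patch in patches:
            for s in self.SCALES:
                scaled = patch if s == 1.0 else rescale(
                    np.asarray(patch, dtype=np.float64), s, anti_aliasing=s < 1.0
                )
                cells = (scaled.shape[0] // hog.cell_px, scaled.shape[1] // hog.cell_px)
                wr, wc = hog.cells_per_window
                if cells[0] < wr or cells[1] < wc:
                    continue
                grid = CellHogGrid(scaled, hog)
                gi = len(self.grids)
                self.grids.append(grid)
                for pos in grid.window_positions(self.STRIDE_CELLS):
                    entries.append((gi, pos[0], pos[1]))
        self.entries = np.array(entries, dtype=np.intp).reshape(-1, 3)
        self.alive = np.ones(len(self.entries), dtype=bool)

    def __len__(self) -> int:
        return int(self.alive.sum())

    def filter_by_stage(self, stage: BoostedStage) -> None:
        idx = np.flatnonzero(self.alive)
        if idx.size == 0:
            return
        by_grid: dict[int, np.ndarray] = {}
        for gi in np.unique(self.entries[idx, 0]):
            by_grid[int(gi)] = idx[self.entries[idx, 0] == gi]
        keep = np.zeros(idx.size, dtype=bool)
        for gi, rows in by_grid.items():
            grid = self.grids[gi]
            positions = self.entries[rows, 1:]
            resp = stage.response(lambda f: grid.gather_feature(positions, f))
            self.alive[rows] = resp >= stage.stage_threshold

    def sample_features(self, k: int, rng: np.random.Generator) -> np.ndarray:
        idx = np.flatnonzero(self.alive)
        if idx.size > k:
            idx = rng.choice(idx, size=k, replace=False)
        vectors = [
            self.grids[gi].window_vector(r, c) for gi, r, c in self.entries[idx]
        ]
        return np.array(vectors)


def train_cascade(
    positives: list[np.ndarray],
    negatives: list[np.ndarray],
    config: CascadeConfig = CascadeConfig(),
) -> CascadeModel:
    """Train the full attentional cascade.

    ``positives`` are patches each showing one centered stoma (any size;
    resampled to the window); ``negatives`` are stoma-free patches from
    which stage-wise false positives are bootstrapped.  Training stops early
    with a logged warning if the negative pool is exhausted, returning the
    stages trained so far.
    """
    if not positives:
        raise ValueError("no positive training patches")
    if not negatives:
        raise ValueError("no negative training patches")
    hog = config.hog
    rng = np.random.default_rng(config.seed)

    pos_features = np.array(
        [compute_hog(to_window(p, hog.window_px), hog) for p in positives]
    )
    pool = _NegativePool(negatives, hog)
    logger.info("negative pool: %d windows from %d patches", len(pool), len(negatives))

    stages: list[BoostedStage] = []
    pos_alive = np.ones(len(positives), dtype=bool)
    for k in range(config.n_stages):
        n_alive = len(pool)
        if n_alive < config.min_negatives_per_stage:
            warnings.warn(
                f"negative pool exhausted after {k} stages "
                f"({n_alive} windows left); returning a shorter cascade",
                stacklevel=2,
            )
            break
        neg_features = pool.sample_features(config.max_negatives_per_stage, rng)
        schedule = config.min_weak_learners_schedule
        min_learners = schedule[min(k, len(schedule) - 1)] if schedule else 1
        stage = train_stage(
            pos_features[pos_alive],
            neg_features,
            stage_tpr_min=config.stage_tpr_min,
            stage_fpr_max=config.stage_fpr_max,
            max_weak_learners=config.max_weak_learners,
            min_weak_learners=min_learners,
        )
        stages.append(stage)
        # Update survivors for the attentional scheme.
        resp = stage.response(lambda f: pos_features[:, f])
        pos_alive &= resp >= stage.stage_threshold
        pool.filter_by_stage(stage)
        logger.info(
            "stage %d: %d learners, tpr=%.4f fpr=%.4f, %d negatives remain",
            k + 1,
            len(stage.weak_learners),
            stage.training_tpr,
            stage.training_fpr,
            len(pool),
        )
    return CascadeModel(hog=hog, stages=stages)


def classify_window(
    model: CascadeModel, patch: np.ndarray, early_exit: bool = True
) -> tuple[bool, float]:
    """Run one window through the cascade.

    Returns ``(accepted, score)``; the score is the sum of stage margins
    (weighted vote sum minus stage threshold) over the stages evaluated.
    With ``early_exit`` the first failing stage stops evaluation, which is
    decision-equivalent to evaluating every stage.
    """
    vector = compute_hog(to_window(patch, model.hog.window_px), model.hog)
    accepted = True
    score = 0.0
    for stage in model.stages:
        resp = float(stage.response(lambda f: np.array([vector[f]]))[0])
        margin = resp - stage.stage_threshold
        if margin < 0:
            accepted = False
            if early_exit:
                break
        else:
            score += margin
    return accepted, score


def non_max_suppression(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy NMS by descending score; score ties break by (row0, col0)."""
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in [0, 1]")
    ordered = sorted(detections, key=lambda d: (-d.score, d.box[0], d.box[1]))
    kept: list[Detection] = []
    for det in ordered:
        if all(box_iou(det.box, other.box) < iou_threshold for other in kept):
            kept.append(det)
    return kept


def box_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    inter_r = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    inter_c = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = inter_r * inter_c
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


DEFAULT_SCALES = (0.8, 1.0, 1.25)


def suppress_contained_centers(detections: list[Detection]) -> list[Detection]:
    """Drop boxes whose center lies inside a higher-scoring kept box.

    Concentric multi-scale duplicates of one object can survive IoU-based
    NMS when their sizes differ enough; one object should yield one box, so
    the weaker concentric box is removed.
    """
    ordered = sorted(detections, key=lambda d: (-d.score, d.box[0], d.box[1]))
    kept: list[Detection] = []
    for det in ordered:
        r, c = det.center
        if all(
            not (o.box[0] <= r < o.box[2] and o.box[1] <= c < o.box[3])
            for o in kept
        ):
            kept.append(det)
    return kept


def detect(
    model: CascadeModel,
    image: Micrograph | np.ndarray,
    stride_px: int = 8,
    scale_factors: tuple[float, ...] = DEFAULT_SCALES,
    nms_iou: float = 0.3,
    merge_concentric: bool = True,
) -> list[Detection]:
    """Sliding-window detection over an image pyramid.

    The stride is rounded to a whole number of HOG cells (the cell grid is
    shared across windows).  Accepted windows from every scale are mapped
    back to original-image pixel coordinates and merged with NMS, followed
    by concentric-duplicate suppression unless ``merge_concentric=False``.
    """
    pixels = image.pixels if isinstance(image, Micrograph) else np.asarray(image, dtype=np.float64)
    hog = model.hog
    stride_cells = max(1, int(round(stride_px / hog.cell_px)))
    win_r, win_c = hog.window_px

    raw: list[Detection] = []
    any_scale_fits = False
    for s in scale_factors:
        scaled = pixels if s == 1.0 else rescale(pixels, s, anti_aliasing=s < 1.0)
        if scaled.shape[0] < win_r or scaled.shape[1] < win_c:
            continue
        any_scale_fits = True
        grid = CellHogGrid(scaled, hog)
        positions = grid.window_positions(stride_cells)
        # windows with zero gradient energy carry no oriented structure and
        # cannot contain a stoma, whatever the trained stages would vote
        alive = grid.window_energies(positions) > 0.0
        scores = np.zeros(len(positions))
        for stage in model.stages:
            if not alive.any():
                break
            pos_alive = positions[alive]
            resp = stage.response(lambda f: grid.gather_feature(pos_alive, f))
            margins = resp - stage.stage_threshold
            passed = margins >= 0
            idx = np.flatnonzero(alive)
            scores[idx[passed]] += margins[passed]
            alive[idx[~passed]] = False
        for i in np.flatnonzero(alive):
            r_px = positions[i, 0] * hog.cell_px
            c_px = positions[i, 1] * hog.cell_px
            r0 = int(round(r_px / s))
            c0 = int(round(c_px / s))
            r1 = int(round((r_px + win_r) / s))
            c1 = int(round((c_px + win_c) / s))
            r1 = min(r1, pixels.shape[0])
            c1 = min(c1, pixels.shape[1])
            if r0 < r1 and c0 < c1:
                raw.append(Detection((r0, c0, r1, c1), float(scores[i])))
    if not any_scale_fits:
        warnings.warn("image smaller than the detector window at every scale", stacklevel=2)
        return []
    merged = non_max_suppression(raw, nms_iou)
    if merge_concentric:
        merged = suppress_contained_centers(merged)
    return merged
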