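"""End-to-end orchestration: training, inference, cross-validation.

The central objects follow the fitted-model idiom: a
:class:`JointSegmentationModel` is built from a labelled cohort and a
:class:`PipelineConfig`; ``fit()`` returns a
:class:`JointSegmentationResults` carrying everything inference needs (the
registration template, the liver and tumor ELM classifiers, the fusion
weights) plus training diagnostics and a ``summary()`` table.  Segmentation
(`results.segment`), tumor delineation (`results.segment_tumor`) and
evaluation hang off the results object.

Pipeline order per slice: position (ROP) → preprocess → FCM mask → ELM
mask → accuracy-weighted fusion → snake refinement; slices are processed
independently and stacked.  Tumor segmentation runs a second ELM over the
raw-intensity features of liver-interior pixels, so its output is a subset
of the liver mask by construction.  The tumor classifier is trained on
ground-truth liver masks and applied inside the predicted liver at
inference (the standard cascade convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from . import coarse as coarse_mod
from . import metrics as metrics_mod
from .coarse import (FusionWeights, elm_liver_mask, fcm_liver_mask, fuse,
                     fusion_weights)
from .elm import ELMModel, binarize, elm_predict, elm_train
from .features import extract_features, feature_spec
from .io import BBox2D, Mask, Volume, tight_bbox
from .preprocess import LiverWindow, preprocess_slice, window_and_stretch
from .rop import TemplatePack, position_liver, select_template
from .snake import SnakeParams, refine


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything tunable in one schema-checked place."""

    window_low: float = 130.0
    window_high: float = 150.0
    out_max: float = 255.0
    margin: int = 5                   # bounding-box padding, px
    n_hidden: int = 630
    elm_seed: int = 0
    fcm_seed: int = 0
    fcm_clusters: int = 4
    fusion_top_k: int = 100
    max_train_pixels: int = 40000     # per-model cap on ELM training rows
    refine_enabled: bool = True
    snake: SnakeParams = field(default_factory=SnakeParams)
    registration_downsample: int = 2
    tumor_threshold: float = 0.5

    def __post_init__(self):
        if self.window_low >= self.window_high:
            raise PipelineError("window_low must be < window_high")
        if isinstance(self.snake, dict):
            self.snake = SnakeParams(**self.snake)

    @property
    def window(self) -> LiverWindow:
        return LiverWindow(self.window_low, self.window_high)

    def to_dict(self):
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# cross-validation plan

@dataclass
class CVPlan:
    """Subject-level fold assignment: folds partition the subjects."""

    k: int
    folds: tuple                      # tuple of tuples of subject indices

    def training_subjects(self, fold: int):
        return tuple(i for j, f in enumerate(self.folds) if j != fold
                     for i in f)


def make_cv_plan(n_subjects: int, k: int = 10, seed: int = 0) -> CVPlan:
    """Shuffle subjects and deal them round-robin into k folds."""
    if n_subjects < k:
        raise PipelineError(f"cannot make {k} folds from {n_subjects} subjects")
    order = np.random.default_rng(seed).permutation(n_subjects)
    folds = tuple(tuple(int(i) for i in order[j::k]) for j in range(k))
    return CVPlan(k=k, folds=folds)


# ---------------------------------------------------------------------------
# training

def _liver_training_box(label_slice, margin, shape):
    return tight_bbox(label_slice).expand(margin, shape=shape)


def _subsample(X, y, cap, seed):
    if X.shape[0] <= cap:
        return X, y
    idx = np.random.default_rng(seed).choice(X.shape[0], size=cap, replace=False)
    idx.sort()
    return X[idx], y[idx]


def _stage_accuracy(pred_mask, truth, box):
    p = pred_mask[box.row_min:box.row_max, box.col_min:box.col_max]
    t = truth[box.row_min:box.row_max, box.col_min:box.col_max]
    return float(np.mean(p == t))


@dataclass
class SegmentationOutput:
    fine: Mask
    coarse: Mask
    boxes: dict
    intermediates: dict = None


@dataclass
class JointSegmentationResults:
    """Fitted pipeline state plus training diagnostics."""

    template: TemplatePack
    liver_model: ELMModel
    tumor_model: ELMModel
    weights: FusionWeights
    config: PipelineConfig
    train_acc_fcm: np.ndarray
    train_acc_elm: np.ndarray
    n_train_subjects: int
    n_train_pixels: int

    def summary(self) -> str:
        lines = [
            "Joint liver/tumor segmentation — fit summary",
            "=" * 52,
            f"training subjects          {self.n_train_subjects}",
            f"template subject           {self.template.subject_id} "
            f"(hull volume {self.template.hull_volume_cm3:.0f} cm3)",
            f"liver ELM                  {self.liver_model.n_hidden} hidden "
            f"sine units, {self.n_train_pixels} training pixels",
            f"fusion weights (FCM, ELM)  ({self.weights.w_F:.4f}, "
            f"{self.weights.w_E:.4f})",
            f"mean FCM stage accuracy    {self.train_acc_fcm.mean():.4f}",
            f"mean ELM stage accuracy    {self.train_acc_elm.mean():.4f}",
            f"tumor ELM                  "
            f"{'fitted' if self.tumor_model is not None else 'absent'}",
        ]
        return "\n".join(lines)

    # ---- inference ------------------------------------------------------

    def segment(self, volume: Volume, keep_intermediates: bool = False
                ) -> SegmentationOutput:
        return segment_liver(volume, self, self.config,
                             keep_intermediates=keep_intermediates)

    def segment_tumor(self, volume: Volume, liver: Mask) -> Mask:
        return segment_tumor(volume, liver, self.tumor_model,
                             threshold=self.config.tumor_threshold)


class JointSegmentationModel:
    """Trainable coarse-to-fine liver/tumor segmenter.

    Parameters
    ----------
    cohort : list of (Volume, liver Mask[, tumor Mask]) training subjects.
    config : PipelineConfig, optional.
    """

    def __init__(self, cohort, config: PipelineConfig = None):
        if len(cohort) < 3:
            raise PipelineError("training needs at least 3 labelled subjects")
        self.cohort = [tuple(c) for c in cohort]
        self.config = config or PipelineConfig()

    def fit(self) -> JointSegmentationResults:
        cfg = self.config
        template = select_template([(c[0], c[1]) for c in self.cohort])

        X_rows, y_rows = [], []
        slice_records = []   # (prep image, truth slice, box) for stage accuracies
        tumor_X, tumor_y = [], []
        for vol, liver, *rest in self.cohort:
            tumor = rest[0] if rest else None
            for k in range(vol.n_slices):
                truth = liver.voxels[k]
                if not truth.any():
                    continue
                box = _liver_training_box(truth, cfg.margin, truth.shape)
                prep = preprocess_slice(vol.slice(k), window=cfg.window,
                                        out_max=cfg.out_max)
                patch = prep[box.row_min:box.row_max, box.col_min:box.col_max]
                fm = extract_features(patch, BBox2D(0, 0, *patch.shape))
                X_rows.append(fm.values)
                y_rows.append(truth[box.row_min:box.row_max,
                                    box.col_min:box.col_max].ravel())
                slice_records.append((prep, truth, box))
                if tumor is not None:
                    raw = np.asarray(vol.slice(k), dtype=np.float64)
                    tfm = extract_features(raw, truth)
                    tumor_X.append(tfm.values)
                    tumor_y.append(tumor.voxels[k][truth.astype(bool)])

        X = np.concatenate(X_rows)
        y = np.concatenate(y_rows).astype(np.float64)
        X, y = _subsample(X, y, cfg.max_train_pixels, cfg.elm_seed)
        spec_hash = feature_spec().hash()
        liver_model = elm_train(X, y, n_hidden=cfg.n_hidden, seed=cfg.elm_seed,
                                spec_hash=spec_hash)

        acc_F, acc_E = [], []
        for prep, truth, box in slice_records:
            m_fcm = fcm_liver_mask(prep, box, c=cfg.fcm_clusters,
                                   seed=cfg.fcm_seed)
            m_elm = elm_liver_mask(prep, box, liver_model)
            acc_F.append(_stage_accuracy(m_fcm.voxels, truth, box))
            acc_E.append(_stage_accuracy(m_elm.voxels, truth, box))
        weights = fusion_weights(acc_F, acc_E, top_k=cfg.fusion_top_k)

        tumor_model = None
        if tumor_X:
            tX = np.concatenate(tumor_X)
            ty = np.concatenate(tumor_y).astype(np.float64)
            tX, ty = _subsample(tX, ty, cfg.max_train_pixels, cfg.elm_seed + 1)
            tumor_model = elm_train(tX, ty, n_hidden=cfg.n_hidden,
                                    seed=cfg.elm_seed + 1, spec_hash=spec_hash)

        return JointSegmentationResults(
            template=template, liver_model=liver_model,
            tumor_model=tumor_model, weights=weights, config=cfg,
            train_acc_fcm=np.asarray(acc_F), train_acc_elm=np.asarray(acc_E),
            n_train_subjects=len(self.cohort), n_train_pixels=X.shape[0])


def train_liver(cohort, config: PipelineConfig = None) -> JointSegmentationResults:
    """Functional wrapper: fit the joint model on a labelled cohort."""
    return JointSegmentationModel(cohort, config).fit()


# ---------------------------------------------------------------------------
# inference

def segment_liver(volume: Volume, bundle: JointSegmentationResults,
                  config: PipelineConfig = None,
                  keep_intermediates: bool = False) -> SegmentationOutput:
    """Coarse-to-fine liver segmentation of a full volume.

    Per slice: ROP box → preprocess → FCM and ELM stage scores → weighted
    fusion → snake refinement.  Slices without a box stay empty; a failed
    refinement falls back to that slice's coarse mask.
    """
    cfg = config or bundle.config
    boxes = position_liver(volume, bundle.template, margin=cfg.margin,
                           window=cfg.window,
                           downsample=cfg.registration_downsample)
    shape = volume.shape
    coarse3d = np.zeros(shape, dtype=np.uint8)
    fine3d = np.zeros(shape, dtype=np.uint8)
    inter = {"fcm": np.zeros(shape, np.uint8), "elm": np.zeros(shape, np.uint8)} \
        if keep_intermediates else None
    for k in range(shape[0]):
        box = boxes.get(k)
        if box is None:
            continue
        prep = preprocess_slice(volume.slice(k), window=cfg.window,
                                out_max=cfg.out_max)
        m_fcm = fcm_liver_mask(prep, box, c=cfg.fcm_clusters, seed=cfg.fcm_seed)
        m_elm = elm_liver_mask(prep, box, bundle.liver_model)
        # fuse the stage *decisions*: a soft score dipping below w_E^-1/2 in a
        # region the other stage rejects would otherwise erode the coarse mask
        coarse_slice = fuse(m_fcm.voxels.astype(float),
                            m_elm.voxels.astype(float), bundle.weights)
        coarse3d[k] = coarse_slice.voxels
        if inter is not None:
            inter["fcm"][k] = m_fcm.voxels
            inter["elm"][k] = m_elm.voxels
        if cfg.refine_enabled and coarse_slice.voxels.any():
            fine_slice, _ = refine(prep, coarse_slice, cfg.snake)
            fine3d[k] = fine_slice.voxels
        else:
            fine3d[k] = coarse_slice.voxels
    out = SegmentationOutput(
        fine=Mask(fine3d, label_name="fine", spacing=volume.spacing),
        coarse=Mask(coarse3d, label_name="coarse", spacing=volume.spacing),
        boxes=boxes, intermediates=inter)
    return out


def segment_tumor(volume: Volume, liver: Mask, tumor_model: ELMModel,
                  threshold: float = 0.5) -> Mask:
    """ELM tumor segmentation inside the liver.

    Features come from the raw intensity image (tumor gray values fall below
    the liver window, so windowed features would carry no tumor contrast).
    The output is a subset of the liver mask by construction; an empty liver
    (or absent tumor model) yields an empty tumor mask.
    """
    out = np.zeros(volume.shape, dtype=np.uint8)
    if tumor_model is None or not liver.voxels.any():
        return Mask(out, label_name="tumor", spacing=volume.spacing)
    for k in range(volume.n_slices):
        sel = liver.voxels[k].astype(bool)
        if not sel.any():
            continue
        raw = np.asarray(volume.slice(k), dtype=np.float64)
        fm = extract_features(raw, sel)
        scores = elm_predict(tumor_model, fm.values)[:, 0]
        score_map = np.zeros(raw.shape)
        score_map[fm.pixel_index[:, 0], fm.pixel_index[:, 1]] = scores
        smoothed = ndimage.median_filter(score_map, size=5, mode="nearest")
        out[k] = ((smoothed >= threshold) & sel).astype(np.uint8)
    return Mask(out, label_name="tumor", spacing=volume.spacing)


# ---------------------------------------------------------------------------
# cross-validation

def run_cv(cohort, k: int = 10, config: PipelineConfig = None, seed: int = 0,
           evaluate_tumor: bool = False):
    """Subject-level k-fold cross-validation of the full pipeline.

    Per fold: fit on the other k−1 folds, segment each held-out subject and
    score all six criteria against its ground truth.  Returns
    (CVPlan, list of per-subject MetricsReport, mean report dict).
    """
    if len(cohort) < k:
        raise PipelineError(f"cohort of {len(cohort)} cannot be split {k}-fold")
    cfg = config or PipelineConfig()
    plan = make_cv_plan(len(cohort), k=k, seed=seed)
    reports = []
    tumor_reports = []
    for j, fold in enumerate(plan.folds):
        train_idx = plan.training_subjects(j)
        bundle = JointSegmentationModel([cohort[i] for i in train_idx], cfg).fit()
        for i in fold:
            vol, liver = cohort[i][0], cohort[i][1]
            seg = segment_liver(vol, bundle, cfg)
            reports.append(metrics_mod.evaluate_all(liver.voxels,
                                                    seg.fine.voxels,
                                                    vol.spacing))
            if evaluate_tumor and len(cohort[i]) > 2 \
                    and cohort[i][2].voxels.any():
                pred_t = segment_tumor(vol, seg.fine, bundle.tumor_model,
                                       cfg.tumor_threshold)
                if pred_t.voxels.any():
                    tumor_reports.append(metrics_mod.evaluate_all(
                        cohort[i][2].voxels, pred_t.voxels, vol.spacing))
    mean = {name: float(np.mean([getattr(r, name) for r in reports]))
            for name in ("voe", "rvd", "asd", "rmsd", "msd", "dice")}
    if evaluate_tumor:
        return plan, reports, mean, tumor_reports
    return plan, reports, mean
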