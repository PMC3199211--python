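"""Pixel-wise evaluation: confusion counts, ROC sweeps, cross-validation.

Sensitivity (true-positive rate over lesion pixels) and specificity
(true-negative rate over skin pixels) are pooled over pixels across images
(micro-average) by default.  The ROC sweep thresholds the normalized
likelihood maps of the per-pixel model; the CRF contributes a single
operating point rather than a curve.  The k-fold cross-validation harness
refits everything after feature computation — LDA projection, class
conditionals, prior and (optionally) CRF weights — inside each fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .crf import build_grid, crf_features_from_pp, map_inference
from .features import (
    FeatureStack,
    RasterImage,
    ScaleSet,
    filter_bank,
    normalize_lstar,
    rgb_to_lab,
)
from .pp import (
    LabelField,
    LabelSet,
    LikelihoodMap,
    fit_pp_model,
)
from .training import CrfInstance, train_weights

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "confusion",
    "sens_spec",
    "roc_sweep",
    "sensitivity_at_specificity",
    "nearest_point_comparison",
    "fold_assignment",
    "compute_stack",
    "cross_validate",
    "CrossValResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise true/false positive/negative counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    pred: LabelField, truth: LabelField, positive_label: int
) -> ConfusionCounts:
    """Pixel-wise confusion counts of a prediction against ground truth."""
    if (pred.height, pred.width) != (truth.height, truth.width):
        raise ValueError("prediction and truth shapes differ")
    p = pred.labels == positive_label
    t = truth.labels == positive_label
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity) = (tp/(tp+fn), tn/(tn+fp)).

    Either value is NaN when its denominator class is empty.
    """
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    return sens, spec


@dataclass(frozen=True)
class RocCurve:
    """Operating points of a likelihood-threshold sweep.

    Thresholds are descending, so sensitivity is non-decreasing along the
    arrays; points are (1 - specificity, sensitivity).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([1.0 - self.specificity, self.sensitivity])


def roc_sweep(
    lmaps: list[LikelihoodMap],
    truths: list[LabelField],
    positive_label: int = 1,
    n_thresholds: int = 256,
) -> RocCurve:
    """Pooled ROC over many thresholds T on the positive-label likelihood.

    Counts are pooled over all pixels of all images at each threshold;
    the grid is ``n_thresholds`` evenly spaced values in [0, 1] including
    both endpoints, swept from 1 down to 0.
    """
    scores = np.concatenate([m.L_mat[:, positive_label] for m in lmaps])
    truth = np.concatenate([t.labels == positive_label for t in truths])
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    thresholds = np.linspace(1.0, 0.0, n_thresholds)
    sens = np.empty(n_thresholds)
    spec = np.empty(n_thresholds)
    for i, T in enumerate(thresholds):
        pred = scores >= T
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        sens[i] = tp / n_pos if n_pos else float("nan")
        spec[i] = (n_neg - fp) / n_neg if n_neg else float("nan")
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def sensitivity_at_specificity(curve: RocCurve, specificity: float) -> float:
    """Linearly interpolated sensitivity at a given specificity level."""
    order = np.argsort(curve.specificity, kind="stable")
    sp = curve.specificity[order]
    se = curve.sensitivity[order]
    return float(np.interp(specificity, sp, se))


def nearest_point_comparison(
    curve: RocCurve, point: tuple[float, float]
) -> tuple[float, float]:
    """Curve point nearest (Euclidean, ROC plane) to a reference point.

    ``point`` is a (sensitivity, specificity) operating point of another
    method; the distance is measured in (1 - specificity, sensitivity)
    coordinates and the matching curve point is returned as
    (sensitivity, specificity).
    """
    ref = np.array([1.0 - point[1], point[0]])
    d2 = np.sum((curve.points - ref) ** 2, axis=1)
    i = int(np.argmin(d2))
    return float(curve.sensitivity[i]), float(curve.specificity[i])


def fold_assignment(n_images: int, k: int, seed: int) -> np.ndarray:
    """Seeded shuffle into k folds whose sizes differ by at most one."""
    if k > n_images:
        raise ValueError("k must not exceed the number of images")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    folds = np.empty(n_images, dtype=np.int64)
    folds[order] = np.arange(n_images) % k
    return folds


def compute_stack(image: RasterImage, cfg: PipelineConfig) -> tuple[FeatureStack, RasterImage]:
    """Features for one sRGB image: returns (stack, Lab image used)."""
    lab = rgb_to_lab(image)
    if cfg.normalize_lstar:
        lab = normalize_lstar(lab)
    stack = filter_bank(
        lab,
        ScaleSet(cfg.scales),
        log_scale_normalized=cfg.log_scale_normalized,
        padding_mode=cfg.padding_mode,
    )
    return stack, lab


@dataclass
class CrossValResult:
    """Held-out predictions and pooled metrics of a k-fold run."""

    folds: np.ndarray
    lmaps: list
    pp_predictions: list
    crf_predictions: list  # empty if the CRF stage was not run
    pp_counts: ConfusionCounts
    crf_counts: ConfusionCounts | None
    crf_traces: list
    seed: int

    @property
    def pp_sens_spec(self) -> tuple[float, float]:
        return sens_spec(self.pp_counts)

    @property
    def crf_sens_spec(self) -> tuple[float, float]:
        if self.crf_counts is None:
            raise ValueError("CRF stage was not run")
        return sens_spec(self.crf_counts)


def cross_validate(
    images: list[RasterImage],
    truths: list[LabelField],
    k: int,
    config: PipelineConfig | None = None,
    seed: int = 0,
    *,
    with_crf: bool = False,
) -> CrossValResult:
    """k-fold cross-validation of the full pipeline.

    Features are computed once per image; everything downstream — the LDA
    projection, class-conditional Gaussians, prior, and (with
    ``with_crf``) the CRF weight vector — is refit on the k-1 training
    folds of each split and applied to the held-out images only.  Pixel
    counts are pooled over all held-out predictions.
    """
    config = config or PipelineConfig()
    if len(images) != len(truths):
        raise ValueError("images and truths must align")
    labels = LabelSet((0, 1))
    pos = config.positive_index
    feats = [compute_stack(img, config) for img in images]
    stacks = [f[0] for f in feats]
    labs = [f[1] for f in feats]
    folds = fold_assignment(len(images), k, seed)

    lmaps: list = [None] * len(images)
    pp_pred: list = [None] * len(images)
    crf_pred: list = [None] * len(images)
    traces = []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        try:
            model = fit_pp_model(
                [stacks[i] for i in train_idx],
                [truths[i] for i in train_idx],
                labels,
            )
        except ValueError as e:
            raise ValueError(f"fold {f}: {e}") from e
        weights = None
        if with_crf:
            tcfg = config.training_config()
            instances = []
            for i in train_idx:
                g = build_grid(truths[i].height, truths[i].width)
                cf = crf_features_from_pp(
                    model.likelihood_map(stacks[i]), labs[i], g
                )
                instances.append(CrfInstance(cf, truths[i], g))
            trace = train_weights(instances, tcfg)
            traces.append(trace)
            weights = trace.best_w
        for i in test_idx:
            lm = model.likelihood_map(stacks[i])
            lmaps[i] = lm
            pp_pred[i] = model.map_label(stacks[i])
            if with_crf:
                g = build_grid(truths[i].height, truths[i].width)
                cf = crf_features_from_pp(lm, labs[i], g)
                crf_pred[i] = map_inference(cf, weights, g)

    pp_counts = ConfusionCounts()
    crf_counts = ConfusionCounts() if with_crf else None
    for i in range(len(images)):
        pp_counts = pp_counts + confusion(pp_pred[i], truths[i], pos)
        if with_crf:
            crf_counts = crf_counts + confusion(crf_pred[i], truths[i], pos)
    return CrossValResult(
        folds=folds,
        lmaps=lmaps,
        pp_predictions=pp_pred,
        crf_predictions=crf_pred if with_crf else [],
        pp_counts=pp_counts,
        crf_counts=crf_counts,
        crf_traces=traces,
        seed=seed,
    )
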