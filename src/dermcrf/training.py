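"""Maximum-likelihood estimation of CRF weights.

The conditional log-likelihood of ground-truth labelings,

    l(w) = sum_m [ -E(y^m, x^m; w) - ln Z(x^m, w) ] - ||w||^2 / (2 sigma^2),

is maximized by projected gradient ascent.  The gradient's model
expectation term is computed exactly by enumeration on tiny instances and
replaced by the feature totals of the single MAP labeling under the
saddle-point approximation (SPA) at scale.  Because SPA gradients can
oscillate, the best-scoring iterate is tracked and returned instead of the
final one, and edge-feature weights are clipped to a small positive floor
after every step to keep the energy submodular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crf import (
    CrfFeatures,
    GridGraph,
    WeightVector,
    MAX_ENUM_PIXELS,
    _all_energies,
    feature_totals,
)
from .pp import LabelField

__all__ = [
    "CrfInstance",
    "TrainingConfig",
    "TrainingTrace",
    "regularized_log_likelihood",
    "exact_gradient",
    "spa_gradient",
    "train_weights",
]

#: Edge weights are projected onto [EDGE_WEIGHT_FLOOR, inf) after each step.
EDGE_WEIGHT_FLOOR = 1e-8


@dataclass(frozen=True)
class CrfInstance:
    """One training example: features, ground-truth labeling, grid."""

    feats: CrfFeatures
    truth: LabelField
    graph: GridGraph

    @property
    def is_tiny(self) -> bool:
        return self.feats.n_pixels <= MAX_ENUM_PIXELS


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the gradient-based weight estimator.

    sigma2 is the variance of the L2 penalty (math.inf disables
    regularization), gamma the step size (scaled per feature by the mean
    ground-truth feature magnitude), epsilon the convergence tolerance on
    the scaled gradient norm, n_itr the iteration cap.
    """

    w0: WeightVector = field(default_factory=lambda: WeightVector.standard(1.0, 0.1))
    sigma2: float = 10.0
    gamma: float = 1e-3
    epsilon: float = 1e-4
    n_itr: int = 200
    gradient: str = "spa"  # "spa" or "exact"

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0):
            raise ValueError("sigma2 must be positive (inf allowed)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_itr < 1:
            raise ValueError("n_itr must be >= 1")
        if self.gradient not in ("spa", "exact"):
            raise ValueError("gradient must be 'spa' or 'exact'")


@dataclass
class TrainingTrace:
    """Per-iteration record of the weight trajectory.

    ``weights[k]``, ``gradients[k]`` and ``scores[k]`` describe iteration
    k; ``best_w`` is the weight vector of the best-scoring iteration (the
    oscillation safeguard), not necessarily the last.
    """

    weights: list
    gradients: list
    scores: list
    map_labelings: list
    best_index: int
    converged: bool
    aborted: bool = False

    @property
    def best_w(self) -> WeightVector:
        return self.weights[self.best_index]

    @property
    def n_iterations(self) -> int:
        return len(self.weights)

    def to_dataframe(self) -> pd.DataFrame:
        n_w = self.weights[0].w.size
        rows = {
            f"w{k}": [wv.w[k] for wv in self.weights] for k in range(n_w)
        }
        rows.update(
            {f"grad{k}": [g[k] for g in self.gradients] for k in range(n_w)}
        )
        rows["score"] = list(self.scores)
        df = pd.DataFrame(rows)
        df.index.name = "iteration"
        return df


def _penalty(w: np.ndarray, sigma2: float) -> float:
    if math.isinf(sigma2):
        return 0.0
    return float(w @ w) / (2.0 * sigma2)


def _penalty_grad(w: np.ndarray, sigma2: float) -> np.ndarray:
    if math.isinf(sigma2):
        return np.zeros_like(w)
    return w / sigma2


def _check_weights(instances: list[CrfInstance], w: WeightVector) -> None:
    for inst in instances:
        if w.w.size != inst.feats.n_features:
            raise ValueError("weight vector does not match instance features")


def regularized_log_likelihood(
    w: WeightVector,
    instances: list[CrfInstance],
    sigma2: float = 10.0,
    *,
    method: str = "auto",
) -> float:
    """Regularized conditional log-likelihood of the ground-truth labelings.

    Exact evaluation (enumerating the partition function) requires every
    instance to be tiny; otherwise the SPA surrogate
    ``sum_m [E(y*) - E(y^m)] - penalty`` is returned, which replaces
    ``-ln Z`` by ``E(y*)`` (the dominant term of the sum).  ``method`` may
    force ``"exact"`` or ``"spa"``.
    """
    if not (sigma2 > 0):
        raise ValueError("sigma2 must be positive")
    _check_weights(instances, w)
    if method == "auto":
        method = "exact" if all(i.is_tiny for i in instances) else "spa"
    total = 0.0
    if method == "exact":
        from scipy.special import logsumexp

        for inst in instances:
            _, energies = _all_energies(inst.feats, w, inst.graph)
            e_truth = float(w.w @ feature_totals(inst.truth, inst.feats, inst.graph))
            total += -e_truth - float(logsumexp(-energies))
    elif method == "spa":
        from .crf import map_inference

        for inst in instances:
            y_star = map_inference(inst.feats, w, inst.graph)
            e_star = float(w.w @ feature_totals(y_star, inst.feats, inst.graph))
            e_truth = float(w.w @ feature_totals(inst.truth, inst.feats, inst.graph))
            total += e_star - e_truth
    else:
        raise ValueError("method must be 'auto', 'exact' or 'spa'")
    return total - _penalty(w.w, sigma2)


def exact_gradient(
    w: WeightVector,
    instances: list[CrfInstance],
    sigma2: float = 10.0,
) -> np.ndarray:
    """Exact ascent gradient of the regularized log-likelihood.

    d l / d w_k = sum_m ( E_P[Phi_k] - Phi_k(y^m) ) - w_k / sigma^2,
    with the model expectation E_P[Phi_k] computed by exhaustive
    enumeration; tiny instances only.
    """
    _check_weights(instances, w)
    grad = np.zeros_like(w.w)
    idx_all = None
    for inst in instances:
        if not inst.is_tiny:
            raise ValueError("exact_gradient requires tiny instances (N_P <= 20)")
        Y, energies = _all_energies(inst.feats, w, inst.graph)
        p = np.exp(-(energies - energies.min()))
        p /= p.sum()
        n_p = inst.feats.n_pixels
        if idx_all is None or idx_all.size != n_p:
            idx_all = np.arange(n_p)
        eu, ev = inst.graph.edges[:, 0], inst.graph.edges[:, 1]
        differ = Y[:, eu] != Y[:, ev]
        k = 0
        phi_truth = feature_totals(inst.truth, inst.feats, inst.graph)
        for nf in inst.feats.node_features:
            phi_all = nf[idx_all[None, :], Y].sum(axis=1)
            grad[k] += float(p @ phi_all) - phi_truth[k]
            k += 1
        for ef in inst.feats.edge_features:
            phi_all = differ.astype(np.float64) @ ef
            grad[k] += float(p @ phi_all) - phi_truth[k]
            k += 1
    return grad - _penalty_grad(w.w, sigma2)


def spa_gradient(
    w: WeightVector,
    instances: list[CrfInstance],
    sigma2: float = 10.0,
) -> np.ndarray:
    """Saddle-point-approximated ascent gradient.

    The model expectation is replaced by the feature totals of the single
    MAP labeling y* of each instance:
    d l / d w_k ~= sum_m ( Phi_k(y*) - Phi_k(y^m) ) - w_k / sigma^2.
    When every ground truth is already MAP, only the shrinkage term
    remains.
    """
    from .crf import map_inference

    _check_weights(instances, w)
    grad = np.zeros_like(w.w)
    for inst in instances:
        y_star = map_inference(inst.feats, w, inst.graph)
        grad += feature_totals(y_star, inst.feats, inst.graph)
        grad -= feature_totals(inst.truth, inst.feats, inst.graph)
    return grad - _penalty_grad(w.w, sigma2)


def _step_scales(instances: list[CrfInstance]) -> np.ndarray:
    """Per-feature step scaling: mean |Phi_k(y^m)| over instances, floor 1."""
    totals = np.mean(
        [
            np.abs(feature_totals(i.truth, i.feats, i.graph))
            for i in instances
        ],
        axis=0,
    )
    return np.maximum(totals, 1.0)


def train_weights(
    instances: list[CrfInstance],
    config: TrainingConfig | None = None,
) -> TrainingTrace:
    """Projected gradient ascent on the regularized log-likelihood.

    Each iteration records the current weights, gradient, MAP labelings
    (SPA mode) and score; the update is ``w <- w + gamma * g / scale``
    with a per-feature scale, after which edge weights are clipped to a
    positive floor.  Terminates when the scaled gradient norm drops below
    epsilon or after n_itr iterations; non-finite weights abort with the
    trace collected so far flagged ``aborted``.
    """
    config = config or TrainingConfig()
    if not instances:
        raise ValueError("need at least one training instance")
    w = config.w0
    _check_weights(instances, w)
    all_tiny = all(i.is_tiny for i in instances)
    if config.gradient == "exact" and not all_tiny:
        raise ValueError("exact-gradient training requires tiny instances")
    grad_fn = exact_gradient if config.gradient == "exact" else spa_gradient
    score_method = "exact" if all_tiny else "spa"
    scales = _step_scales(instances)

    phi_truth = np.sum(
        [feature_totals(i.truth, i.feats, i.graph) for i in instances], axis=0
    )

    weights, gradients, scores, labelings = [], [], [], []
    converged = False
    aborted = False
    for _ in range(config.n_itr):
        if not np.all(np.isfinite(w.w)):
            aborted = True
            break
        if config.gradient == "spa":
            from .crf import map_inference

            y_stars = [map_inference(i.feats, w, i.graph) for i in instances]
            phi_star = np.sum(
                [
                    feature_totals(y, i.feats, i.graph)
                    for y, i in zip(y_stars, instances)
                ],
                axis=0,
            )
            g = phi_star - phi_truth - _penalty_grad(w.w, config.sigma2)
            if score_method == "exact":
                score = regularized_log_likelihood(
                    w, instances, config.sigma2, method="exact"
                )
            else:
                score = float(w.w @ (phi_star - phi_truth)) - _penalty(
                    w.w, config.sigma2
                )
            labelings.append(y_stars)
        else:
            g = grad_fn(w, instances, config.sigma2)
            score = regularized_log_likelihood(
                w, instances, config.sigma2, method=score_method
            )
            labelings.append(None)
        weights.append(w)
        gradients.append(g.copy())
        scores.append(score)
        scaled = g / scales
        if np.linalg.norm(scaled) < config.epsilon:
            converged = True
            break
        new_w = w.w + config.gamma * scaled
        new_w[list(w.edge_indices)] = np.maximum(
            new_w[list(w.edge_indices)], EDGE_WEIGHT_FLOOR
        )
        w = WeightVector(new_w, w.edge_indices)
    if not weights:
        raise RuntimeError("training diverged before the first iteration")
    best = int(np.argmax(scores))
    return TrainingTrace(
        weights=weights,
        gradients=gradients,
        scores=scores,
        map_labelings=labelings,
        best_index=best,
        converged=converged,
        aborted=aborted,
    )
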