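"""Per-pixel MAP labeling model.

Pixels are labeled independently: supervised dimensionality reduction by
linear discriminant analysis (LDA) projects the N_C-dimensional filter-bank
observations onto N_L - 1 discriminant directions; each label's projected
observations are modeled as a multivariate Gaussian; the label prior is the
empirical pixel-count distribution.  Per-pixel MAP labeling maximizes
likelihood x prior, and row-normalized likelihood maps feed the CRF model
and threshold sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as _sla
from scipy.special import logsumexp

from .features import FeatureStack

__all__ = [
    "LabelSet",
    "LabelField",
    "LdaProjection",
    "ClassConditionalSet",
    "PriorDistribution",
    "LikelihoodMap",
    "PPModel",
    "fit_lda",
    "fit_class_conditionals",
    "fit_prior",
    "fit_pp_model",
    "likelihood_map",
    "map_label",
    "threshold_labeling",
]

_SHRINKAGE_COND = 1e10


@dataclass(frozen=True)
class LabelSet:
    """Ordered set of N_L >= 2 distinct integer label identifiers."""

    labels: tuple = (0, 1)

    def __post_init__(self) -> None:
        labs = tuple(int(v) for v in self.labels)
        if len(labs) < 2:
            raise ValueError("need at least 2 labels")
        if len(set(labs)) != len(labs):
            raise ValueError("labels must be distinct")
        if any(v < 0 for v in labs):
            raise ValueError("labels are natural numbers")
        object.__setattr__(self, "labels", labs)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def index_of(self, label: int) -> int:
        return self.labels.index(int(label))

    def to_indices(self, labels: np.ndarray) -> np.ndarray:
        """Map label identifiers to their positions in the set."""
        lut = {l: i for i, l in enumerate(self.labels)}
        try:
            return np.array([lut[int(v)] for v in np.asarray(labels).ravel()])
        except KeyError as e:  # pragma: no cover - defensive
            raise ValueError(f"label {e} not in label set") from None


@dataclass(frozen=True)
class LabelField:
    """Per-pixel label assignment over a height x width grid (row-major)."""

    labels: np.ndarray
    height: int
    width: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64).ravel()
        if lab.size != self.height * self.width:
            raise ValueError("label count must equal height*width")
        object.__setattr__(self, "labels", lab)

    @property
    def n_pixels(self) -> int:
        return self.labels.size

    def as_image(self) -> np.ndarray:
        return self.labels.reshape(self.height, self.width)


@dataclass(frozen=True)
class LdaProjection:
    """LDA eigenvectors Q (N_C x (N_L-1)) and the overall feature mean."""

    Q: np.ndarray
    mu_global: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project observations into the discriminant subspace (xQ)."""
        return np.asarray(values, dtype=np.float64) @ self.Q


@dataclass(frozen=True)
class ClassConditionalSet:
    """Per-label Gaussian parameters in the projected space."""

    means: np.ndarray  # N_L x d
    covariances: np.ndarray  # N_L x d x d

    @property
    def n_labels(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class PriorDistribution:
    """Discrete label prior: nonnegative, sums to one."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64).ravel()
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("prior must be nonnegative and sum to 1")
        object.__setattr__(self, "p", p)

    @classmethod
    def uniform(cls, n_labels: int) -> "PriorDistribution":
        return cls(np.full(n_labels, 1.0 / n_labels))


@dataclass(frozen=True)
class LikelihoodMap:
    """Row-normalized per-pixel, per-label likelihoods (rows sum to 1)."""

    L_mat: np.ndarray  # N_P x N_L
    height: int
    width: int

    def __post_init__(self) -> None:
        L = np.asarray(self.L_mat, dtype=np.float64)
        if L.ndim != 2 or L.shape[0] != self.height * self.width:
            raise ValueError("L_mat must be N_P x N_L with N_P = height*width")
        if np.any(L < -1e-12) or np.any(L > 1 + 1e-12):
            raise ValueError("likelihood entries must lie in [0, 1]")
        if not np.allclose(L.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("likelihood rows must sum to 1")
        object.__setattr__(self, "L_mat", L)

    def label_image(self, j: int) -> np.ndarray:
        return self.L_mat[:, j].reshape(self.height, self.width)


def _pool_pixels(
    stacks: list[FeatureStack], truths: list[LabelField]
) -> tuple[np.ndarray, np.ndarray]:
    if len(stacks) != len(truths) or not stacks:
        raise ValueError("need equally many (nonzero) stacks and truths")
    xs, ys = [], []
    for s, t in zip(stacks, truths):
        if s.n_pixels != t.n_pixels:
            raise ValueError("feature stack and label field are misaligned")
        xs.append(s.values)
        ys.append(t.labels)
    return np.vstack(xs), np.concatenate(ys)


def fit_lda(
    stacks: list[FeatureStack],
    truths: list[LabelField],
    labels: LabelSet,
) -> LdaProjection:
    """Fisher discriminant directions from pooled training pixels.

    Solves the generalized symmetric eigenproblem S_b q = lambda S_w q,
    where S_w is the (unweighted) sum of per-class ML covariances and S_b
    the sum of outer products of class-mean deviations from the overall
    mean, and keeps the N_L - 1 leading eigenvectors.  When S_w is
    ill-conditioned a small shrinkage ridge is added (with a warning)
    rather than inverting S_w explicitly.
    """
    X, y = _pool_pixels(stacks, truths)
    n_c = X.shape[1]
    mu = X.mean(axis=0)
    s_w = np.zeros((n_c, n_c))
    s_b = np.zeros((n_c, n_c))
    for l in labels.labels:
        Xl = X[y == l]
        if Xl.shape[0] == 0:
            raise ValueError(f"label {l} absent from training data")
        if Xl.shape[0] < n_c + 1:
            raise ValueError(
                f"label {l} has {Xl.shape[0]} samples; need at least {n_c + 1}"
            )
        mul = Xl.mean(axis=0)
        d = Xl - mul
        s_w += d.T @ d / Xl.shape[0]
        s_b += np.outer(mul - mu, mul - mu)
    if np.linalg.cond(s_w) > _SHRINKAGE_COND:
        lam = 1e-6 * np.trace(s_w) / n_c
        warnings.warn(
            f"within-class scatter is ill-conditioned; adding shrinkage {lam:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        s_w = s_w + lam * np.eye(n_c)
    evals, evecs = _sla.eigh(s_b, s_w)
    order = np.argsort(evals)[::-1][: labels.n_labels - 1]
    Q = evecs[:, order]
    # deterministic sign: largest-magnitude component of each column positive
    for k in range(Q.shape[1]):
        i = np.argmax(np.abs(Q[:, k]))
        if Q[i, k] < 0:
            Q[:, k] = -Q[:, k]
    return LdaProjection(Q=Q, mu_global=mu)


def fit_class_conditionals(
    projected: list[np.ndarray],
    truths: list[LabelField],
    labels: LabelSet,
) -> ClassConditionalSet:
    """Per-label sample mean and ML covariance of projected observations.

    Pixels are pooled across images.  A near-singular covariance is
    ridge-regularized (with a warning) so downstream density evaluation
    stays defined; fewer than 2 samples for a label is an error.
    """
    X = np.vstack([np.asarray(p, dtype=np.float64) for p in projected])
    y = np.concatenate([t.labels for t in truths])
    if X.shape[0] != y.size:
        raise ValueError("projected data and truths are misaligned")
    d = X.shape[1]
    if d != labels.n_labels - 1:
        raise ValueError("projected data must have N_L - 1 columns")
    means = np.zeros((labels.n_labels, d))
    covs = np.zeros((labels.n_labels, d, d))
    for j, l in enumerate(labels.labels):
        Xl = X[y == l]
        if Xl.shape[0] < 2:
            raise ValueError(f"label {l} has fewer than 2 samples")
        means[j] = Xl.mean(axis=0)
        dev = Xl - means[j]
        cov = dev.T @ dev / Xl.shape[0]  # ML estimator
        floor = max(1e-12, 1e-9 * max(np.trace(cov) / d, 0.0))
        if np.linalg.eigvalsh(cov).min() < floor:
            warnings.warn(
                f"covariance for label {l} is near-singular; adding ridge {floor:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
            cov = cov + floor * np.eye(d)
        covs[j] = cov
    return ClassConditionalSet(means=means, covariances=covs)


def fit_prior(truths: list[LabelField], labels: LabelSet) -> PriorDistribution:
    """Empirical label prior: pooled pixel counts over all training images."""
    if not truths:
        raise ValueError("need at least one ground-truth field")
    y = np.concatenate([t.labels for t in truths])
    counts = np.array([(y == l).sum() for l in labels.labels], dtype=np.float64)
    return PriorDistribution(counts / counts.sum())


def _log_densities(
    projected: np.ndarray, cc: ClassConditionalSet
) -> np.ndarray:
    """N_P x N_L matrix of Gaussian log densities, computed stably."""
    X = np.asarray(projected, dtype=np.float64)
    n, d = X.shape
    out = np.empty((n, cc.n_labels))
    for j in range(cc.n_labels):
        cov = cc.covariances[j]
        chol = _sla.cholesky(cov, lower=True)
        dev = X - cc.means[j]
        z = _sla.solve_triangular(chol, dev.T, lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, j] = -0.5 * (
            d * np.log(2 * np.pi) + logdet + np.sum(z * z, axis=0)
        )
    return out


def likelihood_map(
    stack: FeatureStack,
    proj: LdaProjection,
    cc: ClassConditionalSet,
) -> LikelihoodMap:
    """Per-pixel likelihoods normalized across the label set.

    Densities are evaluated in log space and normalized with log-sum-exp,
    so rows sum to one even where all raw densities underflow.
    """
    logd = _log_densities(proj.transform(stack.values), cc)
    L = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
    return LikelihoodMap(L, stack.height, stack.width)


def map_label(
    stack: FeatureStack,
    proj: LdaProjection,
    cc: ClassConditionalSet,
    prior: PriorDistribution,
) -> LabelField:
    """Independent per-pixel MAP labeling: argmax of likelihood x prior.

    Ties break toward the lowest label index.  Labels in the returned
    field are positions 0..N_L-1 in the label set's order.
    """
    logd = _log_densities(proj.transform(stack.values), cc)
    with np.errstate(divide="ignore"):
        logpost = logd + np.log(prior.p)[None, :]
    # np.argmax returns the first (lowest-index) maximizer on ties
    y = np.argmax(logpost, axis=1)
    return LabelField(y, stack.height, stack.width)


def threshold_labeling(
    lmap: LikelihoodMap, target_index: int, T: float
) -> LabelField:
    """Binary labeling by thresholding the target label's likelihood.

    A pixel receives the target label iff its normalized likelihood is
    >= T.  Only defined for a binary label set.
    """
    if lmap.L_mat.shape[1] != 2:
        raise ValueError("threshold labeling requires a binary label set")
    if not (0.0 <= T <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    hit = lmap.L_mat[:, target_index] >= T
    other = 1 - target_index
    y = np.where(hit, target_index, other)
    return LabelField(y, lmap.height, lmap.width)


@dataclass(frozen=True)
class PPModel:
    """Bundled fitted per-pixel model (projection + Gaussians + prior)."""

    labels: LabelSet
    projection: LdaProjection
    conditionals: ClassConditionalSet
    prior: PriorDistribution

    def likelihood_map(self, stack: FeatureStack) -> LikelihoodMap:
        return likelihood_map(stack, self.projection, self.conditionals)

    def map_label(self, stack: FeatureStack, *, uniform_prior: bool = False) -> LabelField:
        prior = (
            PriorDistribution.uniform(self.labels.n_labels)
            if uniform_prior
            else self.prior
        )
        return map_label(stack, self.projection, self.conditionals, prior)


def fit_pp_model(
    stacks: list[FeatureStack],
    truths: list[LabelField],
    labels: LabelSet,
) -> PPModel:
    """Fit LDA projection, class-conditional Gaussians and prior at once.

    Ground-truth fields must contain label-set *identifiers*; internally
    class statistics are computed per identifier and stored in label-set
    order.
    """
    proj = fit_lda(stacks, truths, labels)
    projected = [proj.transform(s.values) for s in stacks]
    cc = fit_class_conditionals(projected, truths, labels)
    prior = fit_prior(truths, labels)
    return PPModel(labels=labels, projection=proj, conditionals=cc, prior=prior)
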