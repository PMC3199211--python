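"""Grid-structured conditional random field over pixel labels.

The model defines P(y | x; w) = exp(-E(y, x; w)) / Z(x, w) with an energy
that is a weighted sum of feature totals: node features accumulate a
per-pixel cost of the assigned label, edge features accumulate a
nonnegative cost on each 4-neighbor pair whose labels differ.  With
positive edge weights this pairwise structure is submodular, so binary MAP
inference is solved *exactly* by an s-t minimum cut.  Exhaustive
enumeration routines provide exact partition functions, probabilities and
brute-force MAP on tiny grids, serving as oracles for the scalable path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._maxflow import min_cut_binary
from .pp import LabelField, LikelihoodMap
from .features import RasterImage

__all__ = [
    "GridGraph",
    "CrfFeatures",
    "WeightVector",
    "build_grid",
    "crf_features_from_pp",
    "feature_totals",
    "energy",
    "map_inference",
    "brute_force_inference",
    "partition_function",
    "log_partition_function",
    "label_probability",
    "enumerate_labelings",
]

#: Enumeration guard: exhaustive routines refuse above this pixel count.
MAX_ENUM_PIXELS = 20


@dataclass(frozen=True)
class GridGraph:
    """4-connected pixel grid: nodes are row-major indices, edges (E, 2)."""

    height: int
    width: int
    edges: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.height * self.width

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def build_grid(height: int, width: int) -> GridGraph:
    """Construct the 4-connected grid over a height x width image.

    Edge count is height*(width-1) + (height-1)*width; each unordered
    neighbor pair appears once, smaller index first.
    """
    if height < 1 or width < 1:
        raise ValueError("grid dimensions must be positive")
    idx = np.arange(height * width).reshape(height, width)
    horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    vert = np.stack([idx[:-1].ravel(), idx[1:].ravel()], axis=1)
    edges = np.vstack([horiz, vert]).astype(np.int64)
    return GridGraph(height=height, width=width, edges=edges)


@dataclass(frozen=True)
class CrfFeatures:
    """Feature functions of one CRF instance, in cost form.

    ``node_features[k]`` is an N_P x N_L matrix: entry (i, j) is the cost
    feature accumulated when pixel i takes label index j.
    ``edge_features[k]`` is a length-E nonnegative vector: the cost
    incurred on edge e iff its endpoint labels differ.
    """

    node_features: tuple  # of N_P x N_L arrays
    edge_features: tuple  # of length-E arrays

    def __post_init__(self) -> None:
        nf = tuple(np.asarray(a, dtype=np.float64) for a in self.node_features)
        ef = tuple(np.asarray(a, dtype=np.float64) for a in self.edge_features)
        if not nf:
            raise ValueError("need at least one node feature")
        for a in nf:
            if a.ndim != 2 or not np.all(np.isfinite(a)):
                raise ValueError("node features must be finite N_P x N_L matrices")
        for a in ef:
            if a.ndim != 1 or not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValueError("edge features must be finite and nonnegative")
        object.__setattr__(self, "node_features", nf)
        object.__setattr__(self, "edge_features", ef)

    @property
    def n_pixels(self) -> int:
        return self.node_features[0].shape[0]

    @property
    def n_labels(self) -> int:
        return self.node_features[0].shape[1]

    @property
    def n_features(self) -> int:
        return len(self.node_features) + len(self.edge_features)


@dataclass(frozen=True)
class WeightVector:
    """Energy weights; entries at ``edge_indices`` must be nonnegative.

    Nonnegative edge weights keep the pairwise energy submodular, which
    is what exact min-cut inference requires; a negative edge weight is a
    constraint violation.  Training additionally clips edge weights to a
    strictly positive floor, but the boundary value 0 is permitted here:
    w = [1, 0] is the model's own PP-equivalence fixed point.
    """

    w: np.ndarray
    edge_indices: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64).ravel()
        ei = tuple(int(i) for i in self.edge_indices)
        if any(i < 0 or i >= w.size for i in ei):
            raise ValueError("edge index out of range")
        if any(w[i] < 0 for i in ei):
            raise ValueError("edge-feature weights must be nonnegative")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "edge_indices", ei)

    @classmethod
    def standard(cls, w_node: float = 1.0, w_edge: float = 0.1) -> "WeightVector":
        """The two-feature vector [node weight, edge weight]."""
        return cls(np.array([w_node, w_edge]), edge_indices=(1,))


def _split_weights(feats: CrfFeatures, w: WeightVector) -> tuple[np.ndarray, np.ndarray]:
    """Split w into node-feature and edge-feature weights, order-checked."""
    if w.w.size != feats.n_features:
        raise ValueError(
            f"weight vector has {w.w.size} entries for {feats.n_features} features"
        )
    n_node = len(feats.node_features)
    expected_edge = tuple(range(n_node, feats.n_features))
    if w.edge_indices != expected_edge:
        raise ValueError(
            "weights must list node features first, then edge features "
            f"(edge_indices {w.edge_indices} != {expected_edge})"
        )
    return w.w[:n_node], w.w[n_node:]


def crf_features_from_pp(
    lmap: LikelihoodMap, lab_img: RasterImage, graph: GridGraph
) -> CrfFeatures:
    """Build the standard two-feature instance from PP likelihoods.

    Node feature: 1 - likelihood of the assigned label, so that with
    w = [1, 0] minimizing the energy reproduces the per-pixel MAP of the
    likelihood map.  Edge feature: absolute L* difference between the
    edge's endpoint pixels (offset-invariant, so normalized and raw L*
    give identical edge costs).
    """
    if lmap.height != graph.height or lmap.width != graph.width:
        raise ValueError("likelihood map and grid are misaligned")
    if lab_img.color_space != "CIELab":
        raise ValueError("edge features require a CIELab image")
    if (lab_img.height, lab_img.width) != (graph.height, graph.width):
        raise ValueError("image and grid are misaligned")
    node = 1.0 - lmap.L_mat
    lstar = lab_img.pixels[:, :, 0].ravel()
    eu, ev = graph.edges[:, 0], graph.edges[:, 1]
    edge = np.abs(lstar[eu] - lstar[ev])
    return CrfFeatures(node_features=(node,), edge_features=(edge,))


def feature_totals(
    y: LabelField, feats: CrfFeatures, graph: GridGraph
) -> np.ndarray:
    """Vector of feature totals Phi_k(y, x), node features first."""
    lab = y.labels
    if lab.size != feats.n_pixels:
        raise ValueError("labeling and features are misaligned")
    eu, ev = graph.edges[:, 0], graph.edges[:, 1]
    differ = lab[eu] != lab[ev]
    idx = np.arange(lab.size)
    phis = [nf[idx, lab].sum() for nf in feats.node_features]
    phis += [ef[differ].sum() for ef in feats.edge_features]
    return np.array(phis)


def energy(
    y: LabelField, feats: CrfFeatures, w: WeightVector, graph: GridGraph
) -> float:
    """E(y, x; w) = sum_k w_k Phi_k(y, x); lower is more probable."""
    _split_weights(feats, w)
    return float(w.w @ feature_totals(y, feats, graph))


def _effective_potentials(
    feats: CrfFeatures, w: WeightVector
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted node potential matrix and per-edge cost vector."""
    wn, we = _split_weights(feats, w)
    node = sum(a * nf for a, nf in zip(wn, feats.node_features))
    if feats.edge_features:
        edge = sum(b * ef for b, ef in zip(we, feats.edge_features))
    else:
        edge = np.zeros(0)
    return np.asarray(node), np.asarray(edge)


def map_inference(
    feats: CrfFeatures, w: WeightVector, graph: GridGraph
) -> LabelField:
    """Exact binary MAP labeling via s-t minimum cut.

    The binary pairwise energy with nonnegative boundary costs is
    submodular, so the global minimizer corresponds to a minimum s-t cut:
    source-side pixels take label 0, sink-side pixels label 1.  The cut is
    computed on float64 capacities directly (Dinic's algorithm), so the
    optimum is exact up to floating-point arithmetic.

    Raises
    ------
    NotImplementedError
        For N_L > 2 (multi-label inference is out of scope).
    """
    if feats.n_labels != 2:
        raise NotImplementedError("map_inference supports binary label sets only")
    node, edge = _effective_potentials(feats, w)
    n = feats.n_pixels
    if graph.n_nodes != n:
        raise ValueError("graph and features are misaligned")

    if edge.size == 0 or not np.any(edge > 0):
        # no pairwise coupling: per-pixel argmin, ties toward label 0
        y = np.argmin(node, axis=1)
        return LabelField(y, graph.height, graph.width)

    # t-link capacities: paying node[i,1] cuts the s-arc, node[i,0] the t-arc
    base = node.min(axis=1)
    cap_s = node[:, 1] - base
    cap_t = node[:, 0] - base
    is_one = min_cut_binary(
        n,
        cap_s,
        cap_t,
        graph.edges[:, 0],
        graph.edges[:, 1],
        edge,
    )
    return LabelField(is_one.astype(np.int64), graph.height, graph.width)


def enumerate_labelings(n_pixels: int, n_labels: int = 2) -> np.ndarray:
    """All label fields over n_pixels, lexicographically ordered.

    Row r is the r-th labeling with pixel 0 the most significant digit,
    so row order equals lexicographic order.  Refuses above 2^20 states.
    """
    if n_pixels > MAX_ENUM_PIXELS or n_labels**n_pixels > 2**MAX_ENUM_PIXELS:
        raise ValueError("instance too large for exhaustive enumeration")
    m = n_labels**n_pixels
    r = np.arange(m)
    digits = np.empty((m, n_pixels), dtype=np.int64)
    for i in range(n_pixels - 1, -1, -1):
        digits[:, i] = r % n_labels
        r = r // n_labels
    return digits


def _all_energies(
    feats: CrfFeatures, w: WeightVector, graph: GridGraph
) -> tuple[np.ndarray, np.ndarray]:
    """(labelings, energies) over the full label-field space."""
    node, edge = _effective_potentials(feats, w)
    Y = enumerate_labelings(feats.n_pixels, feats.n_labels)
    idx = np.arange(feats.n_pixels)
    e_node = node[idx[None, :], Y].sum(axis=1)
    eu, ev = graph.edges[:, 0], graph.edges[:, 1]
    if edge.size:
        e_edge = (Y[:, eu] != Y[:, ev]).astype(np.float64) @ edge
    else:
        e_edge = 0.0
    return Y, e_node + e_edge


def brute_force_inference(
    feats: CrfFeatures, w: WeightVector, graph: GridGraph
) -> LabelField:
    """Exact argmin of the energy by enumeration (tiny instances only).

    Ties break toward the lexicographically smallest labeling.
    """
    Y, E = _all_energies(feats, w, graph)
    return LabelField(Y[np.argmin(E)], graph.height, graph.width)


def log_partition_function(
    feats: CrfFeatures, w: WeightVector, graph: GridGraph
) -> float:
    """ln Z(x, w) by exhaustive enumeration in log space."""
    _, E = _all_energies(feats, w, graph)
    return float(logsumexp(-E))


def partition_function(
    feats: CrfFeatures, w: WeightVector, graph: GridGraph
) -> float:
    """Z(x, w) = sum_y exp(-E(y, x; w)); tiny instances only."""
    return float(np.exp(log_partition_function(feats, w, graph)))


def label_probability(
    y: LabelField, feats: CrfFeatures, w: WeightVector, graph: GridGraph
) -> float:
    """P(y | x; w) = exp(-E(y)) / Z, by enumeration."""
    return float(
        np.exp(-energy(y, feats, w, graph) - log_partition_function(feats, w, graph))
    )
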