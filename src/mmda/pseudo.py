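"""Two-round weighted-centroid pseudo-labeling.

Round 0 builds class centroids from mu-weighted source features, softly
weighted by each source classifier's confidence; labels come from the
nearest centroid under cosine distance against the *target*-encoder
features. Round 1 rebuilds centroids from the hard assignments and
re-assigns. Exactly two rounds by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateClassError,
    InvalidLabelError,
    ShapeError,
    UndefinedDistanceError,
)

#: soft-mass threshold below which a class counts as degenerate
MASS_EPS = 1e-12


@dataclass
class CentroidSet:
    m: np.ndarray  # (K, d)
    round: int = 0

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=np.float64)
        if self.m.ndim != 2:
            raise ShapeError(f"centroids must be (K, d), got {self.m.shape}")

    @property
    def k(self) -> int:
        return self.m.shape[0]


@dataclass
class PseudoLabelState:
    labels: np.ndarray  # (N_t,) ints in [0, K)
    centroids: CentroidSet
    min_distance: np.ndarray | None = None  # cosine distance to winning centroid
    margin: np.ndarray | None = None  # runner-up minus winner

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.centroids.k
        ):
            raise InvalidLabelError("pseudo label outside [0, K)")


def _check_stack(source_arrs: list[np.ndarray], name: str) -> np.ndarray:
    arrs = [np.asarray(a, dtype=np.float64) for a in source_arrs]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ShapeError(f"inconsistent {name} shapes: {a.shape} vs {shape}")
    return np.stack(arrs)  # (n, N, ·)


def init_centroids(
    source_probs: list[np.ndarray],
    source_feats: list[np.ndarray],
    mu: np.ndarray,
    fallback: np.ndarray | None = None,
) -> CentroidSet:
    """Round-0 centroids: soft, confidence- and mu-weighted source features.

    m_k = [sum_i sum_t mu_i p_ik(x_t) f_i(x_t)] / [sum_i sum_t mu_i p_ik(x_t)].
    A class with zero soft mass raises unless ``fallback`` centroids are
    provided (as the adaptation loop does between epochs).
    """
    probs = _check_stack(source_probs, "probability")  # (n, N, K)
    feats = _check_stack(source_feats, "feature")  # (n, N, d)
    mu = np.asarray(mu, dtype=np.float64)
    if probs.shape[0] != len(mu) or feats.shape[0] != len(mu):
        raise ShapeError(f"{len(mu)} weights for {probs.shape[0]} sources")
    if probs.shape[1] != feats.shape[1]:
        raise ShapeError("probs and feats disagree on sample count")
    k = probs.shape[2]
    d = feats.shape[2]
    num = np.einsum("i,ink,ind->kd", mu, probs, feats)
    den = np.einsum("i,ink->k", mu, probs)
    m = np.empty((k, d))
    for cls in range(k):
        if den[cls] > MASS_EPS:
            m[cls] = num[cls] / den[cls]
        elif fallback is not None:
            m[cls] = fallback[cls]
        else:
            raise DegenerateClassError(cls)
    return CentroidSet(m, round=0)


def assign_labels(target_feats: np.ndarray, centroids: CentroidSet) -> np.ndarray:
    """Nearest centroid under cosine distance; ties go to the lowest class."""
    x = np.asarray(target_feats, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != centroids.m.shape[1]:
        raise ShapeError(f"features {x.shape} incompatible with centroids {centroids.m.shape}")
    dist = cosine_distances(x, centroids.m)
    return dist.argmin(axis=1)


def cosine_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise 1 - cos(a_i, b_j); zero-norm rows are an error."""
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise UndefinedDistanceError("cosine distance undefined for zero-norm vector")
    return 1.0 - (a @ b.T) / np.outer(na, nb)


def refine(
    labels: np.ndarray,
    source_feats: list[np.ndarray],
    mu: np.ndarray,
    target_feats: np.ndarray,
    prev: CentroidSet | None = None,
    k: int | None = None,
) -> PseudoLabelState:
    """Round-1 refinement: indicator-weighted centroids, then re-assign.

    m_k = [sum_i sum_t 1(y_t=k) mu_i f_i(x_t)] / [sum_t 1(y_t=k)]; empty
    classes keep the previous round's centroid.
    """
    feats = _check_stack(source_feats, "feature")  # (n, N, d)
    mu = np.asarray(mu, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != feats.shape[1]:
        raise ShapeError("label count does not match feature rows")
    if k is None:
        k = prev.k if prev is not None else int(labels.max()) + 1
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise InvalidLabelError(f"labels outside [0, {k})")
    weighted = np.einsum("i,ind->nd", mu, feats)  # mu-avg source features per sample
    d = feats.shape[2]
    m = np.empty((k, d))
    for cls in range(k):
        members = labels == cls
        count = int(members.sum())
        if count > 0:
            m[cls] = weighted[members].sum(axis=0) / count
        elif prev is not None:
            m[cls] = prev.m[cls]
        else:
            raise DegenerateClassError(cls, f"class {cls} has no assigned members")
    centroids = CentroidSet(m, round=1)
    dist = cosine_distances(np.asarray(target_feats, dtype=np.float64), centroids.m)
    new_labels = dist.argmin(axis=1)
    sorted_d = np.sort(dist, axis=1)
    margin = sorted_d[:, 1] - sorted_d[:, 0] if k > 1 else np.zeros(len(new_labels))
    return PseudoLabelState(new_labels, centroids, min_distance=sorted_d[:, 0], margin=margin)


def pseudo_label(
    source_probs: list[np.ndarray],
    source_feats: list[np.ndarray],
    target_feats: np.ndarray,
    mu: np.ndarray,
    rounds: int = 2,
    fallback: np.ndarray | None = None,
) -> PseudoLabelState:
    """Full pipeline: init -> assign -> (rounds - 1) x refine."""
    centroids = init_centroids(source_probs, source_feats, mu, fallback=fallback)
    labels = assign_labels(target_feats, centroids)
    state = PseudoLabelState(labels, centroids)
    for _ in range(max(rounds - 1, 0)):
        state = refine(labels, source_feats, mu, target_feats, prev=state.centroids, k=centroids.k)
        labels = state.labels
    return state
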