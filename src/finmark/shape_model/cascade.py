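"""Trainer and regressor for the boosted cascade over intensity-difference features.

Shapes are handled in box-normalized coordinates (the bounding box maps to
the unit square). Every stage samples a pool of candidate pixel locations
expressed relative to the mean shape, reads image intensities at those
locations (indexed through the current shape estimate via a similarity
transform), and fits a gradient-boosted ensemble of depth-limited
regression trees whose split features are differences between two pooled
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from finmark.shape_model.params import Hyperparameters

__all__ = ["CascadeStage", "RegressionTree", "FittedCascade", "train_cascade", "predict_shape"]


@dataclass
class RegressionTree:
    """Complete binary tree of fixed depth, stored breadth-first.

    ``feat_i``/``feat_j``/``thresh`` describe the split at each internal
    node (go left when ``F[feat_i] - F[feat_j] > thresh``); ``leaves``
    holds the shrinkage-scaled shape increment at each leaf.
    """

    feat_i: np.ndarray  # (n_splits,) int32
    feat_j: np.ndarray  # (n_splits,) int32
    thresh: np.ndarray  # (n_splits,) float32
    leaves: np.ndarray  # (n_splits + 1, 2 * n_landmarks) float64


@dataclass
class CascadeStage:
    anchor_idx: np.ndarray  # (pool,) int32: nearest mean-shape landmark per pool point
    deltas: np.ndarray  # (pool, 2) float64: offset from that landmark (normalized units)
    trees: List[RegressionTree] = field(default_factory=list)


@dataclass
class FittedCascade:
    mean_shape: np.ndarray  # (n_landmarks, 2) in box-normalized coordinates
    stages: List[CascadeStage]

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]


def similarity_transform(src: np.ndarray, dst: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares similarity (scale-rotation ``M`` and translation ``t``)
    mapping point set ``src`` onto ``dst``: ``dst ~ src @ M.T + t``."""
    src_mean = src.mean(axis=0)
    dst_mean = dst.mean(axis=0)
    s = src - src_mean
    d = dst - dst_mean
    var_src = float((s**2).sum()) / len(src)
    if var_src < 1e-12:
        return np.eye(2), dst_mean - src_mean
    cov = d.T @ s / len(src)
    u, sv, vt = np.linalg.svd(cov)
    sign = float(np.sign(np.linalg.det(u @ vt))) or 1.0
    diag = np.array([1.0, sign])
    rot = u @ np.diag(diag) @ vt
    scale = float((sv * diag).sum()) / var_src
    m = scale * rot
    t = dst_mean - src_mean @ m.T
    return m, t


def _extract_features(
    gray: np.ndarray,
    shape_norm: np.ndarray,
    mean_shape: np.ndarray,
    anchor_idx: np.ndarray,
    deltas: np.ndarray,
    box: Sequence[float],
) -> np.ndarray:
    """Intensities at the pool locations indexed through the current estimate."""
    m, _ = similarity_transform(mean_shape, shape_norm)
    locs = shape_norm[anchor_idx] + deltas @ m.T
    left, top, bw, bh = box
    h, w = gray.shape
    xi = np.clip(np.rint(locs[:, 0] * bw + left).astype(np.int64), 0, w - 1)
    yi = np.clip(np.rint(locs[:, 1] * bh + top).astype(np.int64), 0, h - 1)
    return gray[yi, xi].astype(np.float32)


def _sample_split_pairs(
    pool_locs: np.ndarray, n_pairs: int, lam: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw pixel-pair candidates with acceptance probability exp(-dist/lam)."""
    p = pool_locs.shape[0]
    lam = max(lam, 1e-6)
    out_i = np.empty(n_pairs, dtype=np.int64)
    out_j = np.empty(n_pairs, dtype=np.int64)
    filled = 0
    for _ in range(64):
        need = n_pairs - filled
        if need <= 0:
            break
        ci = rng.integers(0, p, size=4 * need)
        cj = rng.integers(0, p, size=4 * need)
        dist = np.linalg.norm(pool_locs[ci] - pool_locs[cj], axis=1)
        accept = (ci != cj) & (rng.random(4 * need) < np.exp(-dist / lam))
        idx = np.flatnonzero(accept)[:need]
        out_i[filled : filled + len(idx)] = ci[idx]
        out_j[filled : filled + len(idx)] = cj[idx]
        filled += len(idx)
    if filled < n_pairs:  # pathological lambda: fall back to uniform pairs
        out_i[filled:] = rng.integers(0, p, size=n_pairs - filled)
        out_j[filled:] = rng.integers(0, p, size=n_pairs - filled)
    return out_i, out_j


def _fit_tree(
    feats: np.ndarray,
    residuals: np.ndarray,
    pool_locs: np.ndarray,
    hp: Hyperparameters,
    rng: np.random.Generator,
) -> Tuple[RegressionTree, np.ndarray]:
    """Fit one tree on the current residuals; returns the tree and the leaf
    index assigned to each training sample."""
    n, _ = feats.shape
    k = residuals.shape[1]
    depth = hp.tree_depth
    n_splits = 2**depth - 1
    n_leaves = 2**depth

    feat_i = np.zeros(n_splits, dtype=np.int32)
    feat_j = np.zeros(n_splits, dtype=np.int32)
    thresh = np.zeros(n_splits, dtype=np.float32)
    leaves = np.zeros((n_leaves, k))

    # Breadth-first: node_members[node] = sample indices reaching that node.
    node_members: dict[int, np.ndarray] = {0: np.arange(n)}
    for node in range(n_splits):
        members = node_members.pop(node, np.empty(0, dtype=np.int64))
        ci, cj = _sample_split_pairs(pool_locs, hp.test_splits, hp.regularization, rng)
        if len(members) < 2:
            feat_i[node], feat_j[node], thresh[node] = ci[0], cj[0], 0.0
            node_members[2 * node + 1] = members
            node_members[2 * node + 2] = np.empty(0, dtype=np.int64)
            continue
        fm = feats[members]
        diffs = fm[:, ci] - fm[:, cj]  # (m, n_candidates)
        # Thresholds taken from observed diffs of random members: scale-free.
        pick = rng.integers(0, len(members), size=hp.test_splits)
        cand_thresh = diffs[pick, np.arange(hp.test_splits)]
        left_mask = diffs > cand_thresh[None, :]
        y = residuals[members]
        left_sum = left_mask.T.astype(np.float64) @ y  # (cand, k)
        total = y.sum(axis=0)
        n_left = left_mask.sum(axis=0).astype(np.float64)
        n_right = len(members) - n_left
        right_sum = total[None, :] - left_sum
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(n_left > 0, (left_sum**2).sum(axis=1) / n_left, 0.0) + np.where(
                n_right > 0, (right_sum**2).sum(axis=1) / n_right, 0.0
            )
        gain[(n_left == 0) | (n_right == 0)] = -np.inf
        best = int(np.argmax(gain))
        if not np.isfinite(gain[best]):
            best = 0
        feat_i[node] = ci[best]
        feat_j[node] = cj[best]
        thresh[node] = cand_thresh[best]
        go_left = diffs[:, best] > cand_thresh[best]
        node_members[2 * node + 1] = members[go_left]
        node_members[2 * node + 2] = members[~go_left]

    leaf_of_sample = np.empty(n, dtype=np.int64)
    for leaf in range(n_leaves):
        members = node_members[n_splits + leaf]
        leaf_of_sample[members] = leaf
        if len(members):
            leaves[leaf] = hp.learning_rate * residuals[members].mean(axis=0)
    tree = RegressionTree(feat_i, feat_j, thresh, leaves)
    return tree, leaf_of_sample


def train_cascade(
    images: Sequence[np.ndarray],
    shapes_px: np.ndarray,
    boxes: np.ndarray,
    hp: Hyperparameters,
    seed: int,
) -> FittedCascade:
    """Train the full cascade.

    Parameters
    ----------
    images
        Grayscale 2-D arrays, one per annotated image.
    shapes_px
        ``(n_images, n_landmarks, 2)`` ground-truth pixel coordinates.
    boxes
        ``(n_images, 4)`` rows ``(left, top, width, height)``.
    hp, seed
        Training hyperparameters and the RNG seed; the result is a
        deterministic function of ``(images, shapes_px, boxes, hp, seed)``.
    """
    n_images, n_lm, _ = shapes_px.shape
    if n_images == 0:
        raise ValueError("training set is empty")
    if n_lm == 0:
        raise ValueError("training set has zero landmarks")
    rng = np.random.default_rng(seed)

    origins = boxes[:, :2].astype(float)
    sizes = boxes[:, 2:].astype(float)
    shapes = (shapes_px - origins[:, None, :]) / sizes[:, None, :]
    mean_shape = shapes.mean(axis=0)

    over = hp.oversampling
    n_samples = n_images * over
    sample_img = np.repeat(np.arange(n_images), over)
    current = np.empty((n_samples, n_lm, 2))
    for s in range(n_samples):
        img = sample_img[s]
        if s % over == 0 or n_images == 1:
            current[s] = mean_shape
        else:
            # Perturbed initialization: another image's ground-truth shape.
            other = int(rng.integers(0, n_images - 1))
            current[s] = shapes[other + (other >= img)]
    target = shapes[sample_img]

    pool = hp.feature_pool_size
    pad = hp.feature_pool_padding
    stages: List[CascadeStage] = []
    for _ in range(hp.cascade_depth):
        pool_locs = rng.uniform(-pad, 1.0 + pad, size=(pool, 2))
        d2 = ((pool_locs[:, None, :] - mean_shape[None, :, :]) ** 2).sum(axis=2)
        anchor_idx = d2.argmin(axis=1).astype(np.int32)
        deltas = pool_locs - mean_shape[anchor_idx]
        stage = CascadeStage(anchor_idx=anchor_idx, deltas=deltas)

        feats = np.empty((n_samples, pool), dtype=np.float32)
        for s in range(n_samples):
            feats[s] = _extract_features(
                images[sample_img[s]], current[s], mean_shape, anchor_idx, deltas,
                boxes[sample_img[s]],
            )
        residuals = (target - current).reshape(n_samples, n_lm * 2)
        for _ in range(hp.trees_per_cascade):
            tree, leaf_of_sample = _fit_tree(feats, residuals, pool_locs, hp, rng)
            residuals = residuals - tree.leaves[leaf_of_sample]
            stage.trees.append(tree)
        current = target - residuals.reshape(n_samples, n_lm, 2)
        stages.append(stage)
    return FittedCascade(mean_shape=mean_shape, stages=stages)


def _tree_leaf(tree: RegressionTree, feats: np.ndarray) -> int:
    node = 0
    n_splits = len(tree.feat_i)
    while node < n_splits:
        go_left = feats[tree.feat_i[node]] - feats[tree.feat_j[node]] > tree.thresh[node]
        node = 2 * node + 1 if go_left else 2 * node + 2
    return node - n_splits


def predict_shape(
    cascade: FittedCascade, gray: np.ndarray, box: Sequence[float] | None = None
) -> np.ndarray:
    """Run the cascade on one grayscale image; returns pixel coordinates
    ``(n_landmarks, 2)`` clamped to the frame."""
    h, w = gray.shape
    if box is None:
        box = (0.0, 0.0, float(w), float(h))
    shape = cascade.mean_shape.copy()
    n_lm = cascade.n_landmarks
    for stage in cascade.stages:
        feats = _extract_features(gray, shape, cascade.mean_shape, stage.anchor_idx,
                                  stage.deltas, box)
        incr = np.zeros(n_lm * 2)
        for tree in stage.trees:
            incr += tree.leaves[_tree_leaf(tree, feats)]
        shape = shape + incr.reshape(n_lm, 2)
    left, top, bw, bh = box
    px = shape * np.array([bw, bh]) + np.array([left, top])
    px[:, 0] = np.clip(px[:, 0], 0, w - 1)
    px[:, 1] = np.clip(px[:, 1], 0, h - 1)
    return px
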