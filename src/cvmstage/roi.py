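"""Sliding-window vertebral-region detector over aggregated image channels.

A deliberately compact take on the aggregate-channel-features (ACF) family:
eight grayscale channels (intensity, gradient magnitude, six orientation
bins) are block-summed 4x4 and smoothed; a boosted ensemble of depth-2
decision trees (discrete AdaBoost over scikit-learn trees, with hard-negative
mining) scores fixed-size windows over a scale pyramid (step 2^(1/4)); greedy
non-maximum suppression keeps the best window.

The detector is pipeline plumbing for locating the C2-C4 stack, not a
faithful reproduction of any particular ACF implementation: it uses a single
window aspect learned from the mean training box and grayscale channels
only.  When no window clears the score threshold, :func:`detect_roi` returns
``None`` so the caller can fall back to manual crops from the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize
from sklearn.tree import DecisionTreeClassifier

from .roi_types import RoiBox

__all__ = [
    "RoiBox", "RoiDetectorConfig", "RoiDetector",
    "compute_channels", "train_roi_detector", "detect_roi",
]

SHRINK = 4          # block aggregation factor
N_ORIENT = 6        # gradient-orientation bins


@dataclass(frozen=True)
class RoiDetectorConfig:
    n_trees: int = 128
    max_depth: int = 2
    neg_per_image: int = 10
    mining_rounds: int = 2
    mined_per_image: int = 4
    jitter_positives: int = 2
    score_threshold: float = 0.0
    nms_iou: float = 0.5
    pyramid_octaves: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)  # scale = 2^(k/4)
    seed: int = 0


@dataclass
class _Tree:
    """Flattened depth-<=2 decision tree (arrays from sklearn's tree_)."""

    feature: np.ndarray        # -2 at leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_sign: np.ndarray      # +1 object / -1 background at leaves


@dataclass
class RoiDetector:
    window_blocks: tuple[int, int]      # (rows, cols) in channel blocks
    trees: list[_Tree]
    alphas: np.ndarray
    config: RoiDetectorConfig
    train_recall: float = float("nan")

    @property
    def window_px(self) -> tuple[int, int]:
        return (self.window_blocks[0] * SHRINK, self.window_blocks[1] * SHRINK)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "window_blocks": list(self.window_blocks),
            "alphas": self.alphas.tolist(),
            "train_recall": self.train_recall,
            "config": asdict(self.config),
            "trees": [
                {k: getattr(t, k).tolist()
                 for k in ("feature", "threshold", "left", "right", "leaf_sign")}
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RoiDetector":
        d = json.loads(Path(path).read_text())
        cfg_d = d["config"]
        cfg_d["pyramid_octaves"] = tuple(cfg_d["pyramid_octaves"])
        trees = [
            _Tree(feature=np.array(t["feature"], dtype=np.int64),
                  threshold=np.array(t["threshold"]),
                  left=np.array(t["left"], dtype=np.int64),
                  right=np.array(t["right"], dtype=np.int64),
                  leaf_sign=np.array(t["leaf_sign"]))
            for t in d["trees"]
        ]
        return cls(window_blocks=tuple(d["window_blocks"]), trees=trees,
                   alphas=np.array(d["alphas"]),
                   config=RoiDetectorConfig(**cfg_d),
                   train_recall=d["train_recall"])


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------


def compute_channels(image: np.ndarray) -> np.ndarray:
    """Aggregated channel stack, shape (8, ceil(H/4), ceil(W/4)).

    Channels: intensity, gradient magnitude, and the magnitude split over six
    hard-assigned orientation bins in [0, pi); each channel is 4x4 block-summed
    and smoothed with a [1, 2, 1]/4 triangle filter.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("grayscale image expected")
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), np.pi)
    bins = np.minimum((ori / (np.pi / N_ORIENT)).astype(int), N_ORIENT - 1)
    chans = [img, mag]
    for b in range(N_ORIENT):
        chans.append(np.where(bins == b, mag, 0.0))
    stack = np.stack(chans)

    h, w = img.shape
    hp, wp = -(-h // SHRINK) * SHRINK, -(-w // SHRINK) * SHRINK
    stack = np.pad(stack, ((0, 0), (0, hp - h), (0, wp - w)))
    agg = stack.reshape(stack.shape[0], hp // SHRINK, SHRINK,
                        wp // SHRINK, SHRINK).sum(axis=(2, 4))
    kern = np.array([1.0, 2.0, 1.0]) / 4.0
    agg = ndimage.convolve1d(agg, kern, axis=1, mode="nearest")
    agg = ndimage.convolve1d(agg, kern, axis=2, mode="nearest")
    return agg


def _window_count(ch_shape: tuple[int, int], wb: tuple[int, int]) -> tuple[int, int]:
    return (ch_shape[0] - wb[0] + 1, ch_shape[1] - wb[1] + 1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _pyramid_features_for_box(
    image: np.ndarray,
    box: RoiBox,
    wb: tuple[int, int],
    rng: np.random.Generator,
    n_jitter: int,
    n_neg: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Positive and negative window features from the scale where the true
    box best matches the detector window."""
    hb, wbk = wb
    s = float(np.sqrt((hb * SHRINK / box.height) * (wbk * SHRINK / box.width)))
    ch = compute_channels(_resize_by(image, s))
    nr, nc = _window_count(ch.shape[1:], wb)
    if nr <= 0 or nc <= 0:
        return [], []
    r0 = int(np.clip(round(box.y * s / SHRINK), 0, nr - 1))
    c0 = int(np.clip(round(box.x * s / SHRINK), 0, nc - 1))

    def window(r: int, c: int) -> np.ndarray:
        return ch[:, r:r + hb, c:c + wbk].ravel()

    pos = [window(r0, c0)]
    for _ in range(n_jitter):
        rj = int(np.clip(r0 + rng.integers(-1, 2), 0, nr - 1))
        cj = int(np.clip(c0 + rng.integers(-1, 2), 0, nc - 1))
        pos.append(window(rj, cj))

    neg = []
    attempts = 0
    while len(neg) < n_neg and attempts < 50 * n_neg:
        attempts += 1
        r = int(rng.integers(0, nr))
        c = int(rng.integers(0, nc))
        # same-size windows: IoU from centre offsets
        dy, dx = abs(r - r0), abs(c - c0)
        inter = max(0, hb - dy) * max(0, wbk - dx)
        iou = inter / (2 * hb * wbk - inter)
        if iou < 0.3:
            neg.append(window(r, c))
    return pos, neg


def _resize_by(image: np.ndarray, s: float) -> np.ndarray:
    h, w = image.shape
    return sk_resize(image, (max(1, round(h * s)), max(1, round(w * s))),
                     order=1, mode="reflect", anti_aliasing=s < 1.0,
                     preserve_range=True)


def _fit_boost(
    X: np.ndarray, y: np.ndarray, cfg: RoiDetectorConfig
) -> tuple[list[_Tree], np.ndarray]:
    """Discrete AdaBoost over depth-limited scikit-learn trees.

    Each tree sees a random feature subset ('sqrt'), which keeps the ensemble
    diverse even when single trees separate the boosting sample perfectly;
    the weighted error is clipped so no tree can dominate the vote and the
    window score stays graded rather than saturating.
    """
    n = X.shape[0]
    npos = int((y > 0).sum())
    w = np.where(y > 0, 0.5 / max(npos, 1), 0.5 / max(n - npos, 1))
    w /= w.sum()
    yy = np.where(y > 0, 1.0, -1.0)
    trees: list[_Tree] = []
    alphas: list[float] = []
    for t in range(cfg.n_trees):
        clf = DecisionTreeClassifier(max_depth=cfg.max_depth,
                                     max_features="sqrt",
                                     random_state=cfg.seed + t)
        clf.fit(X, y, sample_weight=w)
        pred = clf.predict(X)
        hh = np.where(pred > 0, 1.0, -1.0)
        err = float(np.clip(w[hh != yy].sum(), 0.02, 0.98))
        alpha = 0.5 * np.log((1 - err) / err)
        if alpha <= 0:
            continue
        tr = clf.tree_
        value = tr.value[:, 0, :]          # (n_nodes, 2) class weights
        leaf_sign = np.where(value.argmax(axis=1) == 1, 1.0, -1.0)
        trees.append(_Tree(feature=tr.feature.copy(),
                           threshold=tr.threshold.copy(),
                           left=tr.children_left.copy(),
                           right=tr.children_right.copy(),
                           leaf_sign=leaf_sign))
        alphas.append(alpha)
        w = w * np.exp(-alpha * yy * hh)
        w /= w.sum()
    return trees, np.array(alphas)


def train_roi_detector(
    labeled: Sequence[tuple[np.ndarray, RoiBox]],
    config: RoiDetectorConfig | None = None,
) -> RoiDetector:
    """Train the boosted sliding-window detector on (image, true box) pairs.

    Runs ``mining_rounds`` rounds of hard-negative mining: after each fit the
    detector is applied to the training images and confidently-scored windows
    far from the truth (IoU < 0.3) join the negative pool for a refit.
    """
    cfg = config or RoiDetectorConfig()
    if len(labeled) < 2:
        raise ValueError("need at least 2 labelled positives")
    for img, box in labeled:
        if not box.inside(img.shape):
            raise ValueError("true box extends outside its image")

    mh = float(np.mean([b.height for _, b in labeled]))
    mw = float(np.mean([b.width for _, b in labeled]))
    wb = (max(2, round(mh / SHRINK)), max(2, round(mw / SHRINK)))

    rng = np.random.default_rng(cfg.seed)
    pos_feats: list[np.ndarray] = []
    neg_feats: list[np.ndarray] = []
    for img, box in labeled:
        p, n = _pyramid_features_for_box(img, box, wb, rng,
                                         cfg.jitter_positives, cfg.neg_per_image)
        pos_feats += p
        neg_feats += n
    if not pos_feats or not neg_feats:
        raise ValueError("could not harvest training windows (boxes degenerate?)")

    def fit(neg: list[np.ndarray]) -> RoiDetector:
        X = np.vstack(pos_feats + neg).astype(np.float32)
        y = np.concatenate([np.ones(len(pos_feats), dtype=int),
                            np.zeros(len(neg), dtype=int)])
        trees, alphas = _fit_boost(X, y, cfg)
        return RoiDetector(window_blocks=wb, trees=trees, alphas=alphas,
                           config=cfg)

    det = fit(neg_feats)
    for _ in range(cfg.mining_rounds):
        mined: list[np.ndarray] = []
        for img, box in labeled:
            cands = _scan(img, det, top_k=cfg.mined_per_image,
                          min_score=None)
            for cand, feats in cands:
                if cand.iou(box) < 0.3:
                    mined.append(feats)
        if not mined:
            break
        neg_feats += mined
        det = fit(neg_feats)

    hits = 0
    for img, box in labeled:
        found = detect_roi(img, det)
        if found is not None and found.iou(box) >= 0.5:
            hits += 1
    det.train_recall = hits / len(labeled)
    return det


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _score_windows(ch: np.ndarray, det: RoiDetector) -> np.ndarray:
    """Boosted score for every window position; shape (nr, nc)."""
    hb, wbk = det.window_blocks
    nr, nc = _window_count(ch.shape[1:], det.window_blocks)
    if nr <= 0 or nc <= 0:
        return np.empty((0, 0))
    used = sorted({int(f) for t in det.trees for f in t.feature if f >= 0})
    fmap = {f: i for i, f in enumerate(used)}
    planes = np.empty((len(used), nr, nc))
    area = hb * wbk
    for i, f in enumerate(used):
        c_idx, rem = divmod(f, area)
        dr, dc = divmod(rem, wbk)
        planes[i] = ch[c_idx, dr:dr + nr, dc:dc + nc]
    flat = planes.reshape(len(used), -1)

    score = np.zeros(nr * nc)

    def walk(tree: _Tree, alpha: float, node: int, mask: np.ndarray) -> None:
        f = tree.feature[node]
        if f < 0:
            score[mask] += alpha * tree.leaf_sign[node]
            return
        go_left = np.zeros_like(mask)
        sel = flat[fmap[int(f)]] <= tree.threshold[node]
        go_left[mask] = sel[mask]
        walk(tree, alpha, tree.left[node], go_left)
        walk(tree, alpha, tree.right[node], mask & ~go_left)

    full = np.ones(nr * nc, dtype=bool)
    for tree, alpha in zip(det.trees, det.alphas):
        walk(tree, alpha, 0, full)
    return score.reshape(nr, nc)


def _scan(
    image: np.ndarray,
    det: RoiDetector,
    top_k: int = 1,
    min_score: Optional[float] = 0.0,
) -> list[tuple[RoiBox, np.ndarray]]:
    """All-scales scan; returns up to ``top_k`` NMS survivors with features."""
    img = np.asarray(image, dtype=np.float64)
    hpx, wpx = det.window_px
    cands: list[tuple[float, float, float, float, float, float]] = []
    feats_at: list[tuple[np.ndarray, int, int]] = []
    for k in det.config.pyramid_octaves:
        s = 2.0 ** (k / 4.0)
        if round(img.shape[0] * s) < hpx or round(img.shape[1] * s) < wpx:
            continue
        ch = compute_channels(_resize_by(img, s))
        scores = _score_windows(ch, det)
        if scores.size == 0:
            continue
        thr = -np.inf if min_score is None else min_score
        rr, cc = np.nonzero(scores > thr) if min_score is not None else \
            np.unravel_index(np.argsort(scores, axis=None)[-top_k * 3:],
                             scores.shape)
        for r, c in zip(np.atleast_1d(rr), np.atleast_1d(cc)):
            cands.append((float(scores[r, c]), c * SHRINK / s, r * SHRINK / s,
                          wpx / s, hpx / s, s))
            feats_at.append((ch, int(r), int(c)))

    if not cands:
        return []
    order = np.argsort([-c[0] for c in cands])
    kept: list[tuple[RoiBox, np.ndarray]] = []
    kept_boxes: list[RoiBox] = []
    hb, wbk = det.window_blocks
    H, W = img.shape
    for i in order:
        sc, x, y, bw, bh, s = cands[i]
        bx = int(np.clip(round(x), 0, W - 1))
        by = int(np.clip(round(y), 0, H - 1))
        bw = int(np.clip(round(bw), 1, W - bx))
        bh = int(np.clip(round(bh), 1, H - by))
        box = RoiBox(x=bx, y=by, width=bw, height=bh, score=sc)
        if any(box.iou(kb) > det.config.nms_iou for kb in kept_boxes):
            continue
        ch, r, c = feats_at[i]
        kept.append((box, ch[:, r:r + hb, c:c + wbk].ravel()))
        kept_boxes.append(box)
        if len(kept) >= top_k:
            break
    return kept


def detect_roi(image: np.ndarray, detector: RoiDetector) -> Optional[RoiBox]:
    """Best-scoring window over the pyramid, or ``None`` if nothing clears
    the detector's score threshold (caller falls back to a manual crop)."""
    hpx, wpx = detector.window_px
    if image.shape[0] < hpx / 2 or image.shape[1] < wpx / 2:
        raise ValueError("image smaller than detector window")
    hits = _scan(image, detector, top_k=1,
                 min_score=detector.config.score_threshold)
    return hits[0][0] if hits else None
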