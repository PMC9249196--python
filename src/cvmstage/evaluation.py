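"""The study evaluation protocol: stage merging, stratified k-fold plans with
split-before-augmentation, confusion-matrix metrics, one-vs-rest ROC/AUC,
report averaging across folds, and the subset-based significance procedure.

Six morphological stages (CS1-CS6) are optionally merged to the five-stage
scheme (CVMS I-V): CS1 and CS2 - whose distinction rests on a weak C2
concavity cue - collapse into CVMS I, and the remaining stages shift down by
one.

Folds partition the *original* images only; augmented copies are created
afterwards and only inside training folds, so no augmented descendant of a
validation image can leak into training.  Fold reports are averaged
elementwise on the confusion matrix (fractional counts are expected) and the
summary metrics are recomputed from the averaged matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_curve as sk_roc_curve

from .preprocess import LabeledImage

__all__ = [
    "merge_six_to_five", "FoldPlan", "make_folds", "EvalReport", "evaluate",
    "average_reports", "subset_significance", "SignificanceResult",
    "assert_not_augmented", "density_preserving_subsets",
    "f1_from_precision_recall",
]


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 2PR / (P + R)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)

_MERGE = {1: 1, 2: 1, 3: 2, 4: 3, 5: 4, 6: 5}


def merge_six_to_five(label: Union[int, np.ndarray]) -> Union[int, np.ndarray]:
    """Map six-stage labels to the merged five-stage scheme.

    1,2 -> 1 (CVMS I); 3 -> 2; 4 -> 3; 5 -> 4; 6 -> 5.
    """
    arr = np.asarray(label)
    if arr.min() < 1 or arr.max() > 6:
        raise ValueError("labels must be stages in 1..6")
    merged = np.where(arr <= 2, 1, arr - 1)
    return int(merged) if np.isscalar(label) or arr.ndim == 0 else merged


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Stratified partition of source ids into k validation folds."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignments.values():
            sizes[f] += 1
        return sizes

    def val_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f != fold]


def make_folds(
    source_ids: Sequence[str],
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Stratified k-fold plan with largest-remainder allocation.

    Each class is shuffled and dealt ``n_c // k`` images to every fold; the
    remainders are handed out round-robin with a pointer that persists across
    classes, so overall fold sizes differ by at most one (761 images yield
    validation folds of 153, 152, 152, 152, 152).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    ids = list(source_ids)
    labs = np.asarray(labels)
    if len(ids) != len(labs):
        raise ValueError("ids/labels length mismatch")
    if len(set(ids)) != len(ids):
        raise ValueError("source ids must be unique")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    pointer = 0
    for cls in np.unique(labs):
        members = [ids[i] for i in np.flatnonzero(labs == cls)]
        if len(members) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
        members = [members[i] for i in rng.permutation(len(members))]
        base, rem = divmod(len(members), k)
        it = iter(members)
        quota = [base] * k
        for j in range(rem):
            quota[(pointer + j) % k] += 1
        pointer = (pointer + rem) % k
        for fold, q in enumerate(quota):
            for _ in range(q):
                assignments[next(it)] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def assert_not_augmented(images: Sequence[LabeledImage]) -> None:
    """Contamination guard: augmented copies must never be scored."""
    bad = [im.source_id for im in images if im.is_augmented]
    if bad:
        raise ValueError(f"augmented images in an evaluation set: {bad[:3]}...")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalReport:
    confusion: np.ndarray               # rows = truth (may be fractional)
    accuracy: float
    precision: np.ndarray               # per class
    recall: np.ndarray
    f1: np.ndarray
    roc: Optional[list[tuple[np.ndarray, np.ndarray]]]   # per class (fpr, tpr)
    auc: Optional[np.ndarray]

    @property
    def num_classes(self) -> int:
        return self.confusion.shape[0]


def _metrics_from_confusion(cm: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    total = cm.sum()
    acc = float(np.trace(cm) / total) if total > 0 else 0.0
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return acc, precision, recall, f1


def evaluate(
    model,
    images: Union[np.ndarray, Sequence[LabeledImage]],
    labels: Optional[Sequence[int]] = None,
    num_classes: Optional[int] = None,
) -> EvalReport:
    """Score a classifier on a test set.

    ``model`` is anything exposing ``predict_proba(images) -> (N, C)`` or a
    bare callable with that signature.  ``images`` may be a pixel array or a
    list of :class:`LabeledImage` (augmented images are rejected, and labels
    are taken from the objects).  ROC curves are one-vs-rest on the class
    probability; AUC is the trapezoidal area.
    """
    if labels is None:
        assert_not_augmented(images)           # type: ignore[arg-type]
        labels = [im.label for im in images]   # type: ignore[union-attr]
        images = np.stack([im.pixels for im in images])  # type: ignore[union-attr]
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ValueError("empty test set")

    proba_fn = model.predict_proba if hasattr(model, "predict_proba") else model
    probs = np.asarray(proba_fn(images), dtype=float)
    n_cls = num_classes or probs.shape[1]
    if probs.shape[1] != n_cls:
        raise ValueError("probability width does not match num_classes")
    if y.min() < 1 or y.max() > n_cls:
        raise ValueError("labels out of range for the class count")

    preds = probs.argmax(axis=1) + 1
    cm = sk_confusion(y, preds, labels=np.arange(1, n_cls + 1)).astype(float)
    acc, precision, recall, f1 = _metrics_from_confusion(cm)

    roc, aucs = [], []
    for c in range(1, n_cls + 1):
        truth = (y == c).astype(int)
        if truth.min() == truth.max():      # class absent or exhaustive
            roc.append((np.array([0.0, 1.0]), np.array([0.0, 1.0])))
            aucs.append(np.nan)
            continue
        fpr, tpr, _ = sk_roc_curve(truth, probs[:, c - 1],
                                   drop_intermediate=False)
        roc.append((fpr, tpr))
        aucs.append(float(sk_auc(fpr, tpr)))
    return EvalReport(confusion=cm, accuracy=acc, precision=precision,
                      recall=recall, f1=f1, roc=roc, auc=np.array(aucs))


def average_reports(reports: Sequence[EvalReport]) -> EvalReport:
    """Elementwise-mean confusion matrix across folds; metrics recomputed
    from the averaged (fractional) matrix; AUCs averaged per class."""
    if not reports:
        raise ValueError("no reports to average")
    shape = reports[0].confusion.shape
    if any(r.confusion.shape != shape for r in reports):
        raise ValueError("reports have mismatched class sets")
    cm = np.mean([r.confusion for r in reports], axis=0)
    acc, precision, recall, f1 = _metrics_from_confusion(cm)
    if all(r.auc is not None for r in reports):
        auc = np.nanmean([r.auc for r in reports], axis=0)
    else:
        auc = None
    return EvalReport(confusion=cm, accuracy=acc, precision=precision,
                      recall=recall, f1=f1, roc=None, auc=auc)


# ---------------------------------------------------------------------------
# significance procedure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignificanceResult:
    mean_without: float
    std_without: float
    mean_with: float
    std_with: float
    p_value: float
    method: str


def subset_significance(
    acc_without_df: Sequence[float],
    acc_with_df: Sequence[float],
    method: str = "welch",
) -> SignificanceResult:
    """One-sided test of "directional filters improve subset accuracy".

    ``method="welch"`` (default): Welch two-sample t-test of H1
    mean(with) > mean(without).  ``method="normal-overlap"``: fit a normal to
    the without-DF accuracies and report P(N(mu0, sigma0) >= mu1), the tail
    mass of the null fit beyond the with-DF mean.  Standard deviations are
    the n-1 sample form.
    """
    a = np.asarray(acc_without_df, dtype=float)
    b = np.asarray(acc_with_df, dtype=float)
    if len(a) != len(b):
        raise ValueError("subset accuracy lists must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 subsets")
    m0, s0 = float(a.mean()), float(a.std(ddof=1))
    m1, s1 = float(b.mean()), float(b.std(ddof=1))

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
        p = float(p)
        if np.isnan(p):                      # zero variance, zero difference
            p = 0.5 if m1 == m0 else (0.0 if m1 > m0 else 1.0)
    elif method == "normal-overlap":
        if s0 == 0.0:
            p = 0.5 if m1 == m0 else (0.0 if m1 > m0 else 1.0)
        else:
            p = float(stats.norm.sf((m1 - m0) / s0))
    else:
        raise ValueError("method must be 'welch' or 'normal-overlap'")
    return SignificanceResult(mean_without=m0, std_without=s0,
                              mean_with=m1, std_with=s1,
                              p_value=p, method=method)


def density_preserving_subsets(
    labels: Sequence[int],
    n_subsets: int = 7,
    subset_size: int = 30,
    seed: int = 0,
) -> list[np.ndarray]:
    """Index subsets whose class mix follows the overall label density.

    Used to turn one test set into several accuracy measurements for the
    significance procedure.  Per-class quotas use largest-remainder rounding;
    images are drawn without replacement within each subset.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    frac = counts / counts.sum()
    quota = np.floor(frac * subset_size).astype(int)
    rem = subset_size - quota.sum()
    order = np.argsort(-(frac * subset_size - quota))
    quota[order[:rem]] += 1

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subsets):
        idx = []
        for cls, q in zip(classes, quota):
            members = np.flatnonzero(y == cls)
            if q > len(members):
                raise ValueError("subset quota exceeds class size")
            idx.extend(rng.choice(members, size=q, replace=False))
        out.append(np.array(sorted(idx)))
    return out
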