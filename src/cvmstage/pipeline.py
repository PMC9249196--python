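"""End-to-end orchestration: stratified cross-validation of the CNNDF with
split-before-augmentation semantics, and the with/without-directional-filter
comparison harness."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .evaluation import (EvalReport, FoldPlan, assert_not_augmented,
                         average_reports, evaluate, make_folds,
                         merge_six_to_five)
from .model import CNNDF, ModelConfig, TrainConfig, train_cnndf
from .preprocess import LabeledImage, augment_dataset

__all__ = ["CrossValResult", "cross_validate"]


@dataclass
class CrossValResult:
    fold_reports: list[EvalReport]
    averaged: EvalReport
    histories: list[dict]
    plan: FoldPlan


def cross_validate(
    images: Sequence[LabeledImage],
    k: int = 5,
    num_classes: int = 5,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    augment_training: bool = False,
    seed: int = 0,
    verbose: bool = False,
) -> CrossValResult:
    """k-fold cross-validation of the CNNDF on labelled crops.

    Folds are made on the original (non-augmented) images; when
    ``augment_training`` is set, the ten-variant augmentation is applied to
    the training portion of each fold only.  With ``num_classes=5`` the
    six-stage labels are merged before training and scoring.
    """
    assert_not_augmented(images)
    ids = [im.source_id for im in images]
    labels6 = np.array([im.label for im in images])
    labels = merge_six_to_five(labels6) if num_classes == 5 else labels6
    plan = make_folds(ids, labels, k=k, seed=seed)

    mcfg = model_cfg or ModelConfig(num_classes=num_classes, seed=seed)
    tcfg = train_cfg or TrainConfig(seed=seed)
    by_id = {im.source_id: (im, lab) for im, lab in zip(images, labels)}

    fold_reports, histories = [], []
    for fold in range(k):
        train_items = [by_id[s] for s in plan.train_ids(fold)]
        val_items = [by_id[s] for s in plan.val_ids(fold)]
        train_imgs = [im for im, _ in train_items]
        train_labs = [lab for _, lab in train_items]
        if augment_training:
            # each original is followed by its 10 variants, label repeated
            train_imgs = augment_dataset(train_imgs)
            train_labs = [lab for _, lab in train_items for _ in range(11)]
        x = np.stack([im.pixels for im in train_imgs]).astype(np.float32)
        y = np.array(train_labs)
        vx = np.stack([im.pixels for im, _ in val_items]).astype(np.float32)
        vy = np.array([lab for _, lab in val_items])

        model = CNNDF(mcfg)
        hist = train_cnndf(model, x, y, tcfg, val_images=vx, val_labels=vy,
                           verbose=verbose)
        report = evaluate(model, vx, vy, num_classes=num_classes)
        fold_reports.append(report)
        histories.append(hist)
    return CrossValResult(fold_reports=fold_reports,
                          averaged=average_reports(fold_reports),
                          histories=histories, plan=plan)
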