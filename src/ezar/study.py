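"""Desk-scale end-to-end segmentation study on synthetic eyes.

Bundles the full pipeline — simulate eyes, derive rule-based ground truth,
train the band-segmentation network, run the automatic-retraining round,
and evaluate on held-out eyes — into one seeded, reproducible function.
Problem sizes are chosen for a single CPU: 11 eyes of 32 B-scans at
128 x 128 px (6 x 6 mm en-face field), 200 training B-scans, 64 px model
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ScanGeometry
from .harness import (
    ExampleSet,
    TrainConfig,
    automatic_retrain,
    build_model,
    desk_preset,
    fscore,
    preprocess,
    train,
)
from .metrics import evaluate_run
from .synthetic import PhenotypeParams, generate_labeled_volume

__all__ = ["study_geometry", "build_study_sets", "run_segmentation_study"]

N_TRAIN_BSCANS = 200
N_EYES = 11  # 8 train, 1 validation, 2 held-out test


def study_geometry() -> ScanGeometry:
    """6 x 6 mm cube at reduced raster density (32 B-scans of 128 x 128)."""
    return ScanGeometry(
        n_bscans=32,
        n_ascans=128,
        n_depth=128,
        lateral_scale=6000 / 128,
        bscan_spacing=6000 / 32,
        fovea_bscan=16,
        fovea_ascan=64,
    )


def _eye_examples(geometry, params, eye_seed, eye_id, input_size):
    volume, _, truth = generate_labeled_volume(geometry, params, eye_seed)
    images, masks, ids = [], [], []
    for b in range(geometry.n_bscans):
        img_r, mask_r, _ = preprocess(
            volume.bscans[b], truth.band_masks[b].pixels, input_size
        )
        images.append(img_r)
        masks.append(mask_r)
        ids.append(f"{eye_id}:{b}")
    return np.stack(images), np.stack(masks), ids


def build_study_sets(
    seed: int,
    input_size: int = 64,
    params: PhenotypeParams | None = None,
) -> tuple[ExampleSet, ExampleSet, dict[str, list], dict[str, list]]:
    """Simulate the study eyes and preprocess them into example sets.

    Returns (train_set, val_set, test_probs_placeholder, test_masks) where
    the test dicts are keyed by eye id for evaluate_run; the first 8 eyes
    train (capped at 200 B-scans), eye 9 validates, eyes 10-11 are held out.
    """
    geometry = study_geometry()
    params = params or PhenotypeParams()
    rng = np.random.default_rng(seed)
    eye_seeds = [int(rng.integers(2**31)) for _ in range(N_EYES)]

    train_imgs, train_masks, train_ids = [], [], []
    for i in range(8):
        imgs, masks, ids = _eye_examples(
            geometry, params, eye_seeds[i], f"eye{i:02d}", input_size
        )
        train_imgs.append(imgs)
        train_masks.append(masks)
        train_ids += ids
    train_set = ExampleSet(
        np.concatenate(train_imgs)[:N_TRAIN_BSCANS],
        np.concatenate(train_masks)[:N_TRAIN_BSCANS],
        train_ids[:N_TRAIN_BSCANS],
    )

    imgs, masks, ids = _eye_examples(
        geometry, params, eye_seeds[8], "eye08", input_size
    )
    val_set = ExampleSet(imgs, masks, ids)

    test_images: dict[str, list] = {}
    test_masks: dict[str, list] = {}
    for i in (9, 10):
        eye_id = f"eye{i:02d}"
        imgs, masks, _ = _eye_examples(
            geometry, params, eye_seeds[i], eye_id, input_size
        )
        test_images[eye_id] = list(imgs)
        test_masks[eye_id] = list(masks)
    return train_set, val_set, test_images, test_masks


def _predict_all(model, images_by_eye):
    out = {}
    for eye_id, images in images_by_eye.items():
        stack = np.stack(images)
        probs = []
        for i in range(0, len(stack), 16):
            probs += list(model.predict_proba(stack[i : i + 16]))
        out[eye_id] = probs
    return out


def _mean_dice(model, images, masks, threshold=0.5):
    dices = []
    for i in range(0, len(images), 16):
        probs = model.predict_proba(np.stack(images[i : i + 16]))
        for off in range(len(probs)):
            dices.append(fscore(probs[off] >= threshold, masks[i + off]))
    return float(np.mean(dices))


@dataclass
class StudyResult:
    config: TrainConfig
    initial_state: object
    retrain_state: object
    heldout_mean_dice: float
    untrained_mean_dice: float
    pixel_auc: float
    icc: float
    report: dict
    duplicated_count: int
    train_size_before: int
    train_size_after: int
    duplicated_dice_before: float | None
    duplicated_dice_after: float | None


def run_segmentation_study(
    seed: int,
    max_epochs: int = 8,
    n_sample: int = 100,
) -> StudyResult:
    """Train, retrain, and evaluate the desk-scale segmentation model."""
    config = desk_preset(seed=seed, max_epochs=max_epochs)
    train_set, val_set, test_images, test_masks = build_study_sets(
        seed, config.input_size
    )
    model = build_model(config)

    flat_test_imgs = [im for ims in test_images.values() for im in ims]
    flat_test_masks = [m for ms in test_masks.values() for m in ms]
    untrained_dice = _mean_dice(model, flat_test_imgs, flat_test_masks)

    initial_state = train(model, train_set, val_set, config)
    heldout_dice = _mean_dice(model, flat_test_imgs, flat_test_masks)

    report = evaluate_run(_predict_all(model, test_images), test_masks)

    retrain_state, augmented = automatic_retrain(
        model, train_set, val_set, config, n_sample=n_sample
    )
    meta = retrain_state.retrain
    dup_ids = meta["duplicated_ids"]
    id_to_idx = {eid: i for i, eid in enumerate(train_set.ids)}
    dup_idx = [id_to_idx[eid] for eid in dup_ids]
    before = after = None
    if dup_idx:
        scores = dict(zip(meta["sampled_ids"], meta["fscores"]))
        before = float(np.mean([scores[eid] for eid in dup_ids]))
        after = _mean_dice(
            model,
            [train_set.images[i] for i in dup_idx],
            [train_set.masks[i] for i in dup_idx],
        )
    return StudyResult(
        config=config,
        initial_state=initial_state,
        retrain_state=retrain_state,
        heldout_mean_dice=heldout_dice,
        untrained_mean_dice=untrained_dice,
        pixel_auc=float(report["pixel"].auc),
        icc=float(report["icc"].icc),
        report=report,
        duplicated_count=len(dup_ids),
        train_size_before=len(train_set),
        train_size_after=len(augmented),
        duplicated_dice_before=before,
        duplicated_dice_after=after,
    )
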