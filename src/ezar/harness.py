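"""Segmentation-model training harness.

Implements the training protocol around the band-segmentation network:
patient-level 80/10/10 splitting (all visits of a patient stay together),
resizing to a square model input with exact inverse scale bookkeeping,
epoch-based training with early stopping on validation loss, high-precision
area measurement of binarised outputs, and the automatic-retraining round
that duplicates the worst-performing training examples (those below the
30th percentile of F-scores in a random sample of 100) and trains a second
round with the same configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .core import ValidationError
from .nn import ConvEncoderDecoder

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "ScaleRecord",
    "TrainState",
    "ExampleSet",
    "desk_preset",
    "full_scale_preset",
    "split_patients",
    "preprocess",
    "build_model",
    "train",
    "predict_bscan",
    "measure_area_pct",
    "fscore",
    "duplication_selection",
    "automatic_retrain",
    "EarlyStopping",
    "UNetSegmenter",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the full-scale protocol (256 px inputs, kernel width 5,
    batch 40, 200 samples per epoch, patience 7, BCE loss with an
    RMSprop-style optimizer at learning rate 1e-4).  ``desk_preset()``
    scales the same architecture down for single-CPU runs.
    """

    input_size: int = 256
    kernel_width: int = 5
    base_filters: int = 8
    depth: int = 3
    batch_size: int = 40
    samples_per_epoch: int = 200
    early_stop_patience: int = 7
    learning_rate: float = 1e-4
    max_epochs: int = 50
    loss: str = "binary_cross_entropy"
    optimizer: str = "rms_style"
    retrain_from_current: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        s, d = self.input_size, self.depth
        if s < 1 or (s & (s - 1)) or s % (2**d):
            raise ValidationError(
                "input_size must be a power of two divisible by 2**depth"
            )
        if self.kernel_width % 2 != 1:
            raise ValidationError("kernel_width must be odd")
        if self.early_stop_patience < 1:
            raise ValidationError("early_stop_patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.loss != "binary_cross_entropy":
            raise ValidationError("only binary_cross_entropy loss is supported")
        if self.optimizer != "rms_style":
            raise ValidationError("only the rms_style optimizer is supported")


def desk_preset(seed: int = 0, **overrides) -> TrainConfig:
    """Scaled-down configuration for single-CPU training runs.

    Same architecture family as the full-scale protocol (kernel 5, double
    convolutions, depth 3) at 64 px input with 8 base filters (<0.5 M
    parameters) and a larger learning rate with small batches so the loss
    moves within a handful of epochs.
    """
    cfg = dict(
        input_size=64,
        base_filters=8,
        depth=3,
        batch_size=4,
        samples_per_epoch=200,
        learning_rate=1e-3,
        max_epochs=8,
        seed=seed,
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)


def full_scale_preset(seed: int = 0) -> TrainConfig:
    """Full-scale configuration: 256 px inputs, ~20 M parameters."""
    return TrainConfig(
        input_size=256, base_filters=32, depth=4, learning_rate=1e-4, seed=seed
    )


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def set_of(self, patient_id: str) -> str:
        for name in ("train", "val", "test"):
            if patient_id in getattr(self, f"{name}_ids"):
                return name
        raise KeyError(patient_id)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    quotas = [n * f for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    remainders = sorted(
        range(len(fractions)),
        key=lambda i: (-(quotas[i] - base[i]), i),
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def split_patients(
    patient_ids,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Randomly partition patients into train/val/test sets.

    The split is at the patient level — every visit of a patient lands in
    the same set by construction, since assignment is by patient id.  Set
    sizes follow largest-remainder rounding of the fractions; the partition
    is deterministic in the seed.
    """
    ids = [str(p) for p in patient_ids]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient ids")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_train, n_val, n_test = _largest_remainder(len(ids), tuple(fractions))
    return SplitPlan(
        train_ids=tuple(order[:n_train]),
        val_ids=tuple(order[n_train : n_train + n_val]),
        test_ids=tuple(order[n_train + n_val :]),
        fractions=tuple(fractions),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Preprocessing and area bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleRecord:
    """Exact original/resized shape bookkeeping for inverse mapping."""

    original: tuple[int, int]
    resized: tuple[int, int]

    @property
    def row_factor(self) -> float:
        return self.original[0] / self.resized[0]

    @property
    def col_factor(self) -> float:
        return self.original[1] / self.resized[1]


def preprocess(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    input_size: int = 256,
) -> tuple[np.ndarray, np.ndarray | None, ScaleRecord]:
    """Resize a B-scan (bilinear) and optional mask (nearest) to model input."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("preprocess expects a 2-D grayscale image")
    record = ScaleRecord(image.shape, (input_size, input_size))
    img_r = resize(
        image,
        (input_size, input_size),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    mask_r = None
    if mask is not None:
        mask_r = (
            resize(
                np.asarray(mask, dtype=float),
                (input_size, input_size),
                order=0,
                preserve_range=True,
                anti_aliasing=False,
            )
            >= 0.5
        )
    return img_r, mask_r, record


def measure_area_pct(
    prob_map: np.ndarray,
    threshold: float,
    scale: ScaleRecord,
) -> float:
    """Positive-area percentage at original resolution, full precision.

    The probability map is binarised at ``threshold``, mapped back to the
    original resolution through the scale record (nearest neighbour), and
    the positive-pixel percentage is returned unrounded so at least four
    decimal places survive to presentation.
    """
    if not (0 < threshold < 1):
        raise ValidationError("threshold must lie in (0, 1)")
    binary = np.asarray(prob_map) >= threshold
    back = resize(
        binary.astype(float),
        scale.original,
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    ) >= 0.5
    return 100.0 * float(np.count_nonzero(back)) / back.size


def fscore(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice / F-score of two binary masks.

    Two empty masks agree perfectly (1.0); empty vs non-empty is 0.0.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError("mask shapes differ")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / denom


# ---------------------------------------------------------------------------
# Example sets and training
# ---------------------------------------------------------------------------


@dataclass
class ExampleSet:
    """Preprocessed training examples: images, masks and stable ids."""

    images: np.ndarray  # (N, S, S) float in [0,1]
    masks: np.ndarray  # (N, S, S) bool
    ids: list[str]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.masks = np.asarray(self.masks, dtype=bool)
        if len(self.images) != len(self.masks) or len(self.images) != len(
            self.ids
        ):
            raise ValidationError("images, masks and ids must align")

    def __len__(self) -> int:
        return len(self.ids)

    def append_copies(self, indices) -> "ExampleSet":
        """Return a new set with one extra copy of each given example."""
        idx = list(indices)
        return ExampleSet(
            np.concatenate([self.images, self.images[idx]]),
            np.concatenate([self.masks, self.masks[idx]]),
            self.ids + [self.ids[i] for i in idx],
        )


@dataclass
class TrainState:
    """Loss trajectory and retraining metadata of one run."""

    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int  # 1-based
    stopped_epoch: int  # 1-based
    n_params: int
    retrain: dict | None = None


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            return False
        return self.epoch - self.best_epoch >= self.patience


def build_model(config: TrainConfig) -> ConvEncoderDecoder:
    """Instantiate the encoder-decoder for a configuration (seeded init)."""
    return ConvEncoderDecoder(
        in_channels=1,
        base_filters=config.base_filters,
        depth=config.depth,
        kernel=config.kernel_width,
        seed=config.seed,
    )


def train(
    model: ConvEncoderDecoder,
    train_set: ExampleSet,
    val_set: ExampleSet,
    config: TrainConfig,
) -> TrainState:
    """Train with per-epoch resampling and early stopping.

    Each epoch draws ``samples_per_epoch`` examples (with replacement) from
    the training set and steps through them in batches of ``batch_size``,
    minimising pixel-wise binary cross-entropy with the RMSprop-style rule.
    Training stops when validation loss has not improved for
    ``early_stop_patience`` consecutive epochs or at ``max_epochs``; the
    best epoch's weights are restored before returning.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValidationError("train and validation sets must be nonempty")
    # Start the output layer at the base-rate logit: with sparse positive
    # masks a zero-initialised sigmoid head wastes early epochs driving
    # probabilities down and can stall below the decision threshold.
    if not model.head.b.any():
        pos = float(train_set.masks.mean())
        pos = min(max(pos, 1e-4), 1 - 1e-4)
        model.head.b[:] = np.log(pos / (1 - pos))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    stopper = EarlyStopping(config.early_stop_patience)
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_weights = model.get_weights()
    for _epoch in range(1, config.max_epochs + 1):
        idx = rng.integers(0, len(train_set), size=config.samples_per_epoch)
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(idx), config.batch_size):
            batch = idx[start : start + config.batch_size]
            try:
                loss = model.train_batch(
                    train_set.images[batch],
                    train_set.masks[batch],
                    config.learning_rate,
                )
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"divergence at epoch {_epoch}: {exc}"
                ) from exc
            epoch_loss += loss * len(batch)
            n_seen += len(batch)
        train_losses.append(epoch_loss / n_seen)
        val_loss = model.eval_loss(val_set.images, val_set.masks)
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss)
        val_losses.append(val_loss)
        if improved:
            best_weights = model.get_weights()
        if stop:
            break
    model.set_weights(best_weights)
    return TrainState(
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=stopper.best_epoch,
        stopped_epoch=stopper.epoch,
        n_params=model.n_params,
    )


def predict_bscan(
    model: ConvEncoderDecoder,
    image: np.ndarray,
    input_size: int | None = None,
) -> tuple[np.ndarray, ScaleRecord]:
    """Per-pixel probability map for one B-scan plus its scale record."""
    if input_size is None:
        input_size = image.shape[0] if image.shape[0] == image.shape[1] else 256
    img_r, _, record = preprocess(image, input_size=input_size)
    prob = model.predict_proba(img_r[None])[0]
    return prob, record


def duplication_selection(
    scores: np.ndarray, percentile: float = 30.0
) -> tuple[float, np.ndarray]:
    """Percentile cut and strictly-below mask of the duplication rule.

    The cut is the linear-interpolation percentile of the profiled
    F-scores; only examples scoring strictly below it are duplicated, so
    with all scores equal nothing is duplicated.
    """
    scores = np.asarray(scores, dtype=float)
    cut = float(np.percentile(scores, percentile))
    return cut, scores < cut


def automatic_retrain(
    model: ConvEncoderDecoder,
    train_set: ExampleSet,
    val_set: ExampleSet,
    config: TrainConfig,
    n_sample: int = 100,
    percentile: float = 30.0,
    threshold: float = 0.5,
) -> tuple[TrainState, ExampleSet]:
    """Second training round focused on poorly segmented examples.

    A sample of ``n_sample`` training examples is drawn without replacement
    and profiled for F-scores of the binarised prediction against its mask.
    Examples scoring strictly below the ``percentile``-th percentile
    (linear interpolation) are duplicated — one extra copy appended — and
    training is rerun with the identical configuration, continuing from the
    current weights (or from a fresh initialisation when
    ``config.retrain_from_current`` is False).

    Returns the new TrainState (with the retraining metadata attached) and
    the augmented training set.
    """
    if len(train_set) < n_sample:
        warnings.warn(
            f"training set has {len(train_set)} < n_sample={n_sample} "
            "examples; profiling all of them",
            stacklevel=2,
        )
        n_sample = len(train_set)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sampled = rng.choice(len(train_set), size=n_sample, replace=False)
    scores = np.empty(n_sample)
    for pos in range(0, n_sample, 16):
        chunk = sampled[pos : pos + 16]
        probs = model.predict_proba(train_set.images[chunk])
        for off, i in enumerate(chunk):
            scores[pos + off] = fscore(
                probs[off] >= threshold, train_set.masks[i]
            )
    cut, dup_mask = duplication_selection(scores, percentile)
    duplicated = sampled[dup_mask]
    augmented = train_set.append_copies(duplicated)
    if not config.retrain_from_current:
        model.set_weights(build_model(config).get_weights())
    state = train(model, augmented, val_set, config)
    state.retrain = {
        "sampled_ids": [train_set.ids[i] for i in sampled],
        "fscores": scores.tolist(),
        "percentile": percentile,
        "cut": cut,
        "duplicated_ids": [train_set.ids[i] for i in duplicated],
    }
    return state, augmented


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------


class UNetSegmenter:
    """Scikit-learn-style estimator facade over the training harness.

    Parameters mirror TrainConfig.  ``fit(X, y)`` takes an image stack
    ``(n, s, s)`` in [0, 1] and boolean masks of the same shape, holds out
    ``val_fraction`` of the examples for early stopping, and exposes the
    fitted network as ``model_``.
    """

    def __init__(
        self,
        input_size: int = 64,
        kernel_width: int = 5,
        base_filters: int = 8,
        depth: int = 3,
        batch_size: int = 4,
        samples_per_epoch: int = 200,
        early_stop_patience: int = 7,
        learning_rate: float = 1e-3,
        max_epochs: int = 8,
        val_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.kernel_width = kernel_width
        self.base_filters = base_filters
        self.depth = depth
        self.batch_size = batch_size
        self.samples_per_epoch = samples_per_epoch
        self.early_stop_patience = early_stop_patience
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "input_size",
                "kernel_width",
                "base_filters",
                "depth",
                "batch_size",
                "samples_per_epoch",
                "early_stop_patience",
                "learning_rate",
                "max_epochs",
                "val_fraction",
                "random_state",
            )
        }

    def set_params(self, **params) -> "UNetSegmenter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> TrainConfig:
        return TrainConfig(
            input_size=self.input_size,
            kernel_width=self.kernel_width,
            base_filters=self.base_filters,
            depth=self.depth,
            batch_size=self.batch_size,
            samples_per_epoch=self.samples_per_epoch,
            early_stop_patience=self.early_stop_patience,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            seed=self.random_state,
        )

    def fit(self, X, y) -> "UNetSegmenter":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=bool)
        if X.shape != y.shape or X.ndim != 3:
            raise ValidationError("X and y must be aligned (n, s, s) stacks")
        config = self._config()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        order = rng.permutation(len(X))
        n_val = max(1, int(round(self.val_fraction * len(X))))
        val_idx, train_idx = order[:n_val], order[n_val:]
        ids = [str(i) for i in range(len(X))]
        train_set = ExampleSet(
            X[train_idx], y[train_idx], [ids[i] for i in train_idx]
        )
        val_set = ExampleSet(X[val_idx], y[val_idx], [ids[i] for i in val_idx])
        self.model_ = build_model(config)
        self.train_state_ = train(self.model_, train_set, val_set, config)
        self.n_params_ = self.model_.n_params
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = np.empty(X.shape, dtype=float)
        for i in range(0, len(X), 16):
            out[i : i + 16] = self.model_.predict_proba(X[i : i + 16])
        return out

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(X) >= threshold
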