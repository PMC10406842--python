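"""Masked-reconstruction training and the two-stage transfer protocol.

At every training step a batch of genomic bins is drawn from a fixed
random subset of locations; for each bin a fresh mask hides part of the
observed tracks, the masked entries are zeroed in the input slice, and the
model is fitted by Adam on the mean squared reconstruction error of the
masked entries.

Two masking schemes are supported: ``random_track`` (a fixed number of
uniformly chosen observed tracks per bin) and ``tissue_wise`` (all
observed tracks of one randomly chosen cell type per bin).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import Tensor
from .model import ModelConfig, ModelParams, forward_batch

__all__ = [
    "MaskSpec",
    "TrainConfig",
    "sample_training_bins",
    "sample_mask",
    "masked_mse_loss",
    "train",
    "transfer_fit",
]


@dataclasses.dataclass(frozen=True)
class MaskSpec:
    """Set of (cell, assay) pairs masked at one bin."""

    entries: tuple[tuple[int, int], ...]
    scheme: str  # "random_track" | "tissue_wise"

    def __post_init__(self):
        if self.scheme not in ("random_track", "tissue_wise"):
            raise ValueError(f"unknown masking scheme {self.scheme!r}")
        if self.scheme == "tissue_wise" and self.entries:
            cells = {i for i, _ in self.entries}
            if len(cells) != 1:
                raise ValueError("tissue_wise mask entries must share one cell index")

    def __len__(self) -> int:
        return len(self.entries)


@dataclasses.dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the published regimes: Adam at 3e-4 for 50 epochs with
    120 masked tracks per bin; transfer pretraining for 30 epochs followed
    by 15 fine-tuning epochs at 3e-5.
    """

    n_masked: int = 120
    epochs: int = 50
    learning_rate: float = 3e-4
    pretrain_epochs: int = 30
    finetune_epochs: int = 15
    finetune_lr: float = 3e-5
    batch_bins: int = 256
    n_train_bins: int = 10_000
    seed: int = 0
    scheme: str = "random_track"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.n_masked < 1:
            raise ValueError("n_masked must be >= 1")
        if self.batch_bins < 1 or self.n_train_bins < 1:
            raise ValueError("batch_bins and n_train_bins must be >= 1")


def sample_training_bins(binning, n_train_bins: int, seed: int) -> np.ndarray:
    """Uniform sample of bin indices without replacement, fixed per run."""
    n_bins = binning.n_bins if hasattr(binning, "n_bins") else int(binning)
    if n_train_bins > n_bins:
        raise ValueError(f"n_train_bins ({n_train_bins}) exceeds n_bins ({n_bins})")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_bins, size=n_train_bins, replace=False))


def sample_mask(observed: np.ndarray, scheme: str, n_masked: int | None = None,
                rng: np.random.Generator | None = None,
                eligible_cells: np.ndarray | None = None) -> MaskSpec:
    """Draw one mask over the observed (cell, assay) tracks.

    ``random_track``: ``n_masked`` distinct observed pairs, uniformly.
    ``tissue_wise``: one cell type uniform among cells with >= 1 observed
    track (optionally restricted to ``eligible_cells``); all its observed
    tracks are masked.
    """
    rng = rng if rng is not None else np.random.default_rng()
    observed = np.asarray(observed, dtype=bool)
    if scheme == "random_track":
        pairs = np.argwhere(observed)
        if n_masked is None:
            raise ValueError("random_track masking requires n_masked")
        if n_masked > len(pairs):
            raise ValueError(
                f"cannot mask {n_masked} tracks: only {len(pairs)} observed"
            )
        pick = rng.choice(len(pairs), size=n_masked, replace=False)
        entries = tuple(map(tuple, pairs[pick]))
        return MaskSpec(entries, "random_track")
    if scheme == "tissue_wise":
        cells = np.flatnonzero(observed.any(axis=1))
        if eligible_cells is not None:
            cells = np.intersect1d(cells, np.asarray(eligible_cells))
        if len(cells) == 0:
            raise ValueError("no cell type with observed tracks to mask")
        cell = int(rng.choice(cells))
        entries = tuple((cell, int(j)) for j in np.flatnonzero(observed[cell]))
        return MaskSpec(entries, "tissue_wise")
    raise ValueError(f"unknown masking scheme {scheme!r}")


def masked_mse_loss(predictions, truth_slice: np.ndarray, mask: MaskSpec) -> float:
    """(1/|M|) sum of squared errors over the masked entries."""
    if len(mask) == 0:
        raise ValueError("mask is empty")
    truth_slice = np.asarray(truth_slice, dtype=float)
    predictions = dict(predictions) if not isinstance(predictions, dict) else predictions
    err = 0.0
    for (i, j) in mask.entries:
        if (i, j) not in predictions:
            raise KeyError(f"no prediction for masked entry ({i}, {j})")
        err += (predictions[(i, j)] - truth_slice[i, j]) ** 2
    return err / len(mask)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, arrays: dict[str, np.ndarray], lr: float, beta1: float,
                 beta2: float, eps: float, trainable=None):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.trainable = set(trainable) if trainable is not None else set(arrays)
        self.m = {k: np.zeros_like(v) for k, v in arrays.items() if k in self.trainable}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items() if k in self.trainable}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bias1 = 1.0 - self.b1 ** self.t
        bias2 = 1.0 - self.b2 ** self.t
        for k in self.trainable:
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            arrays[k] -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _draw_batch_masks(observed: np.ndarray, scheme: str, n_masked: int,
                      n_bins: int, rng: np.random.Generator,
                      eligible_cells: np.ndarray | None) -> list[MaskSpec]:
    return [
        sample_mask(observed, scheme, n_masked=n_masked, rng=rng,
                    eligible_cells=eligible_cells)
        for _ in range(n_bins)
    ]


def _batch_step(tensor_values: np.ndarray, observed: np.ndarray, bin_idx: np.ndarray,
                params: ModelParams, config: ModelConfig, tc: TrainConfig,
                rng: np.random.Generator, update: _Adam | None,
                eligible_cells: np.ndarray | None = None) -> float:
    """One optimization step on a batch of bins; returns the batch loss."""
    n_bins = len(bin_idx)
    masks = _draw_batch_masks(observed, tc.scheme, tc.n_masked, n_bins, rng, eligible_cells)

    visible = np.broadcast_to(observed, (n_bins,) + observed.shape).copy()
    t_bins, t_cells, t_assays, weights = [], [], [], []
    for b, mask in enumerate(masks):
        for (i, j) in mask.entries:
            visible[b, i, j] = False
            t_bins.append(b)
            t_cells.append(i)
            t_assays.append(j)
            weights.append(1.0 / len(mask))
    t_bins = np.asarray(t_bins)
    t_cells = np.asarray(t_cells)
    t_assays = np.asarray(t_assays)
    # per-bin mean over its mask, then mean over bins (Monte Carlo estimate)
    weights = np.asarray(weights) / n_bins

    block = tensor_values[:, :, bin_idx].transpose(2, 0, 1).astype(float)
    truth = block[t_bins, t_cells, t_assays]
    inputs = block * visible

    dropout_masks = None
    if config.dropout_rate > 0:
        keep = 1.0 - config.dropout_rate
        dropout_masks = [
            (rng.random((len(t_bins), config.decoder_hidden)) < keep) / keep
            for _ in range(config.decoder_layers)
        ]

    tensors = params.as_tensors(requires_grad=True)
    pred = forward_batch(inputs, visible, t_bins, t_cells, t_assays, tensors,
                         config, dropout_masks)
    sq = (pred - Tensor(truth)) ** 2
    loss = (sq * Tensor(weights)).sum()
    loss_val = float(loss.data)
    if not np.isfinite(loss_val):
        raise FloatingPointError("training diverged: non-finite loss")
    if update is not None:
        loss.backward()
        grads = {k: t.grad for k, t in tensors.items() if t.grad is not None}
        update.step(params.arrays, grads)
    return loss_val


def train(tensor, model_config: ModelConfig, train_config: TrainConfig,
          params: ModelParams | None = None, observed_mask: np.ndarray | None = None,
          trainable: set[str] | None = None, eligible_cells: np.ndarray | None = None,
          learning_rate: float | None = None, epochs: int | None = None,
          log=None) -> tuple[ModelParams, list[float]]:
    """Masked-reconstruction training of the model on one signal tensor.

    Returns the fitted parameters and the per-epoch mean training loss.
    ``observed_mask`` restricts which tracks participate (default: the
    tensor's training split when a track table is present, else all
    observed tracks).  Deterministic for a fixed seed and thread count.
    """
    if observed_mask is None:
        if tensor.track_table is not None:
            observed_mask = tensor.split_mask("train")
        else:
            observed_mask = tensor.observed
    observed_mask = np.asarray(observed_mask, dtype=bool)
    n_observed = int(observed_mask.sum())
    if train_config.scheme == "random_track" and train_config.n_masked >= n_observed:
        raise ValueError(
            f"n_masked ({train_config.n_masked}) must be smaller than the number "
            f"of observed tracks ({n_observed})"
        )

    if params is None:
        params = ModelParams.initialize(tensor.n_cells, tensor.n_assays, model_config,
                                        seed=train_config.seed)
    else:
        params = params.copy()

    epochs = train_config.epochs if epochs is None else epochs
    lr = train_config.learning_rate if learning_rate is None else learning_rate
    history: list[float] = []
    if epochs == 0:
        return params, history

    rng = np.random.default_rng(train_config.seed)
    bins = sample_training_bins(tensor.binning, min(train_config.n_train_bins, tensor.n_bins),
                                train_config.seed)
    adam = _Adam(params.arrays, lr, train_config.adam_beta1, train_config.adam_beta2,
                 train_config.adam_eps, trainable=trainable)

    # zero out anything outside the participating track set
    values = tensor.values * observed_mask[:, :, None]

    for epoch in range(epochs):
        order = rng.permutation(bins)
        losses, weights = [], []
        for start in range(0, len(order), train_config.batch_bins):
            batch = order[start:start + train_config.batch_bins]
            loss = _batch_step(values, observed_mask, batch, params, model_config,
                               train_config, rng, adam, eligible_cells)
            losses.append(loss)
            weights.append(len(batch))
        epoch_loss = float(np.average(losses, weights=weights))
        history.append(epoch_loss)
        if log is not None:
            log(epoch, epoch_loss)
    return params, history


def transfer_fit(pretrained: ModelParams, target_tensor, target_cell: int,
                 train_config: TrainConfig, model_config: ModelConfig | None = None,
                 freeze_encoders: bool = False, log=None) -> tuple[ModelParams, list[float]]:
    """Fine-tune a pretrained model on a target individual.

    All tracks of ``target_cell`` (the held-out tissue) are excluded both
    from the input context and from the masking targets; masking is
    tissue-wise over the remaining cells.  Set ``freeze_encoders`` to
    update only the global cell/assay embeddings.
    """
    model_config = model_config or pretrained.config
    if not 0 <= target_cell < target_tensor.n_cells:
        raise ValueError(f"target tissue index {target_cell} not found in tensor")
    if (pretrained.n_cells, pretrained.n_assays) != (target_tensor.n_cells,
                                                     target_tensor.n_assays):
        raise ValueError("target tensor does not share the pretrained index spaces")

    observed = target_tensor.observed.copy()
    observed[target_cell, :] = False  # held-out tissue never participates
    eligible = np.setdiff1d(np.flatnonzero(observed.any(axis=1)), [target_cell])

    trainable = None
    if freeze_encoders:
        trainable = {"u_cell", "u_assay"}

    tc = dataclasses.replace(train_config, scheme="tissue_wise")
    return train(
        target_tensor, model_config, tc, params=pretrained,
        observed_mask=observed, trainable=trainable, eligible_cells=eligible,
        learning_rate=tc.finetune_lr, epochs=tc.finetune_epochs, log=log,
    )
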