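"""Model-free and factorization reference predictors.

All averaging happens on the arcsinh scale, the same scale on which the
metrics are computed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import Tensor, gather_pairs
from .data_io import SignalTensor
from .training import _Adam

__all__ = [
    "avg_predictor",
    "training_individual_track",
    "individual_avg_predictor",
    "FactorizationParams",
    "fit_factorization_baseline",
]


def _context_mask(tensor: SignalTensor, split: str | None = "train") -> np.ndarray:
    if split is not None and tensor.track_table is not None:
        return tensor.split_mask(split)
    return tensor.observed


def avg_predictor(tensor: SignalTensor, target: tuple[int, int],
                  split: str | None = "train") -> np.ndarray:
    """Per-bin mean of the target assay over all other cell types."""
    ci, aj = target
    usable = _context_mask(tensor, split)
    cells = np.flatnonzero(usable[:, aj])
    cells = cells[cells != ci]
    if len(cells) == 0:
        raise ValueError(
            f"no other cell type has assay {tensor.assay_ids[aj]!r} available for averaging"
        )
    return tensor.values[cells, aj, :].mean(axis=0)


def training_individual_track(training_tensor: SignalTensor,
                              target: tuple[int, int]) -> np.ndarray:
    """Verbatim copy of the corresponding track in the training individual."""
    ci, aj = target
    if not training_tensor.observed[ci, aj]:
        raise ValueError(
            f"track ({training_tensor.cell_ids[ci]}, {training_tensor.assay_ids[aj]}) "
            "is not observed in the training individual"
        )
    return training_tensor.values[ci, aj, :].copy()


def individual_avg_predictor(target_tensor: SignalTensor,
                             target: tuple[int, int]) -> np.ndarray:
    """Within-individual AVG: mean over the other tissues of one individual."""
    ci, aj = target
    cells = np.flatnonzero(target_tensor.observed[:, aj])
    cells = cells[cells != ci]
    if len(cells) == 0:
        raise ValueError(
            f"no other tissue has assay {target_tensor.assay_ids[aj]!r} observed "
            "in the target individual"
        )
    return target_tensor.values[cells, aj, :].mean(axis=0)


# ---------------------------------------------------------------------------
# single-resolution tensor factorization baseline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FactorizationParams:
    """Trilinear factors: prediction = sum_d c_id * a_jd * b_kd + bias."""

    cell_factors: np.ndarray  # [n_c, r]
    assay_factors: np.ndarray  # [n_a, r]
    bin_factors: np.ndarray  # [n_bins, r]
    bias: float

    def predict(self, cells, assays, bins) -> np.ndarray:
        c = self.cell_factors[np.asarray(cells)]
        a = self.assay_factors[np.asarray(assays)]
        b = self.bin_factors[np.asarray(bins)]
        return np.einsum("td,td,td->t", c, a, b) + self.bias

    def predict_track(self, cell: int, assay: int) -> np.ndarray:
        ca = self.cell_factors[cell] * self.assay_factors[assay]
        return self.bin_factors @ ca + self.bias


def _observed_triples(tensor: SignalTensor, mask: np.ndarray):
    cells, assays = np.nonzero(mask)
    n_bins = tensor.n_bins
    ci = np.repeat(cells, n_bins)
    aj = np.repeat(assays, n_bins)
    bk = np.tile(np.arange(n_bins), len(cells))
    y = tensor.values[cells, assays, :].reshape(-1)
    return ci, aj, bk, y


def fit_factorization_baseline(tensor: SignalTensor, rank: int = 8, epochs: int = 50,
                               learning_rate: float = 0.05, batch: int = 65536,
                               seed: int = 0, split: str | None = "train",
                               params: FactorizationParams | None = None,
                               fit_bins_only: bool = False) -> tuple[FactorizationParams, list[float]]:
    """Fit the trilinear baseline by Adam on observed entries.

    With ``fit_bins_only`` the cell/assay factors of ``params`` are frozen
    and only the genomic-bin factors (and bias) are refitted — the staged
    procedure used when transferring a fitted model to a new chromosome.
    """
    rng = np.random.default_rng(seed)
    mask = _context_mask(tensor, split)
    ci, aj, bk, y = _observed_triples(tensor, mask)
    if params is None:
        params = FactorizationParams(
            cell_factors=rng.normal(0, 0.3, (tensor.n_cells, rank)),
            assay_factors=rng.normal(0, 0.3, (tensor.n_assays, rank)),
            bin_factors=rng.normal(0, 0.3, (tensor.n_bins, rank)),
            bias=float(y.mean()),
        )
    else:
        params = FactorizationParams(params.cell_factors.copy(), params.assay_factors.copy(),
                                     rng.normal(0, 0.3, (tensor.n_bins, params.cell_factors.shape[1])),
                                     params.bias)

    arrays = {
        "cell": params.cell_factors,
        "assay": params.assay_factors,
        "bin": params.bin_factors,
        "bias": np.array([params.bias]),
    }
    trainable = {"bin", "bias"} if fit_bins_only else set(arrays)
    adam = _Adam(arrays, learning_rate, 0.9, 0.999, 1e-8, trainable=trainable)

    history = []
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            c = Tensor(arrays["cell"], requires_grad="cell" in trainable)
            a = Tensor(arrays["assay"], requires_grad="assay" in trainable)
            b = Tensor(arrays["bin"], requires_grad="bin" in trainable)
            bias = Tensor(arrays["bias"], requires_grad=True)

            zeros = np.zeros(len(idx), dtype=int)
            cr = gather_pairs(c.reshape(1, *c.shape), zeros, ci[idx])
            ar = gather_pairs(a.reshape(1, *a.shape), zeros, aj[idx])
            br = gather_pairs(b.reshape(1, *b.shape), zeros, bk[idx])
            pred = (cr * ar * br).sum(axis=1) + bias
            err = pred - Tensor(y[idx])
            loss = (err ** 2).mean()
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError("factorization baseline diverged")
            loss.backward()
            grads = {}
            if c.grad is not None:
                grads["cell"] = c.grad
            if a.grad is not None:
                grads["assay"] = a.grad
            if b.grad is not None:
                grads["bin"] = b.grad
            grads["bias"] = bias.grad
            adam.step(arrays, grads)
            losses.append(loss_val)
        history.append(float(np.mean(losses)))

    return FactorizationParams(arrays["cell"], arrays["assay"], arrays["bin"],
                               float(arrays["bias"][0])), history
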