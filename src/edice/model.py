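"""Factorized self-attentive imputation model.

A local signal slice (one genomic bin of the cell x assay matrix, with
missing and masked tracks zeroed) is encoded twice: rows are embedded into
per-cell tokens and columns into per-assay tokens.  Each token set passes
through a Transformer-style self-attention block (without layer
normalization by default), and a target (cell, assay) pair is decoded by
an MLP applied to the concatenation of its contextual cell and assay
embeddings.

The arithmetic runs on a small numpy autodiff engine (``edice._autodiff``)
so that the same forward code serves both inference and training.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._autodiff import Tensor, concat, gather_pairs, relu, softmax

__all__ = [
    "ModelConfig",
    "ModelParams",
    "SignalSlice",
    "EmbeddingSet",
    "embed_cells",
    "embed_assays",
    "self_attention_block",
    "decode",
    "impute_slice",
    "impute_track",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the published configuration: 256-dim embeddings,
    4 attention heads, a 128-wide attention feed-forward with 256-dim
    output, and a 2x2048 ReLU decoder with dropout 0.3.  Layer
    normalization is off by default.
    """

    embed_dim: int = 256
    n_heads: int = 4
    attn_hidden: int = 128
    attn_out: int = 256
    decoder_hidden: int = 2048
    decoder_layers: int = 2
    dropout_rate: float = 0.3
    layer_norm: bool = False

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim ({self.embed_dim}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.attn_out != self.embed_dim:
            raise ValueError(
                "attn_out must equal embed_dim so the residual connection is well-defined"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.decoder_layers < 1:
            raise ValueError("decoder_layers must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sab_param_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    d, h = config.embed_dim, config.attn_hidden
    shapes = {}
    for name in ("q", "k", "v", "o"):
        shapes[f"W{name}"] = (d, d)
        shapes[f"b{name}"] = (d,)
    shapes["ffn_W1"] = (d, h)
    shapes["ffn_b1"] = (h,)
    shapes["ffn_W2"] = (h, config.attn_out)
    shapes["ffn_b2"] = (config.attn_out,)
    if config.layer_norm:
        shapes["ln1_gamma"] = (d,)
        shapes["ln1_beta"] = (d,)
        shapes["ln2_gamma"] = (d,)
        shapes["ln2_beta"] = (d,)
    return shapes


def _param_shapes(n_cells: int, n_assays: int, config: ModelConfig) -> dict[str, tuple[int, ...]]:
    d = config.embed_dim
    shapes: dict[str, tuple[int, ...]] = {
        "u_cell": (n_cells, d),
        "u_assay": (n_assays, d),
        "cell_map_W": (n_assays, d),
        "cell_map_b": (d,),
        "assay_map_W": (n_cells, d),
        "assay_map_b": (d,),
    }
    for side in ("cell_sab", "assay_sab"):
        for name, shape in _sab_param_shapes(config).items():
            shapes[f"{side}.{name}"] = shape
    in_dim = 2 * d
    for layer in range(config.decoder_layers):
        shapes[f"decoder_W{layer}"] = (in_dim, config.decoder_hidden)
        shapes[f"decoder_b{layer}"] = (config.decoder_hidden,)
        in_dim = config.decoder_hidden
    shapes["decoder_Wout"] = (in_dim, 1)
    shapes["decoder_bout"] = (1,)
    return shapes


class ModelParams:
    """All learnable state, stored as a flat name -> ndarray mapping."""

    def __init__(self, arrays: dict[str, np.ndarray], n_cells: int, n_assays: int,
                 config: ModelConfig):
        expected = _param_shapes(n_cells, n_assays, config)
        for name, shape in expected.items():
            if name not in arrays:
                raise ValueError(f"missing parameter {name!r}")
            if arrays[name].shape != shape:
                raise ValueError(
                    f"parameter {name!r} has shape {arrays[name].shape}, expected {shape}"
                )
        self.arrays = {k: np.asarray(v, dtype=np.float64) for k, v in arrays.items()}
        self.n_cells = n_cells
        self.n_assays = n_assays
        self.config = config

    @classmethod
    def initialize(cls, n_cells: int, n_assays: int, config: ModelConfig,
                   seed: int = 0) -> "ModelParams":
        """Uniform fan-in initialization (embeddings ~ N(0, 0.1))."""
        rng = np.random.default_rng(seed)
        arrays: dict[str, np.ndarray] = {}
        for name, shape in _param_shapes(n_cells, n_assays, config).items():
            if name in ("u_cell", "u_assay"):
                arrays[name] = rng.normal(0.0, 0.1, size=shape)
            elif name.endswith("gamma"):
                arrays[name] = np.ones(shape)
            elif len(shape) == 1:  # biases and LN shifts
                arrays[name] = np.zeros(shape)
            else:
                bound = 1.0 / np.sqrt(shape[0])
                arrays[name] = rng.uniform(-bound, bound, size=shape)
        return cls(arrays, n_cells, n_assays, config)

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.arrays.items()},
                           self.n_cells, self.n_assays, self.config)

    def as_tensors(self, requires_grad: bool = False) -> dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=requires_grad) for k, v in self.arrays.items()}

    def allclose(self, other: "ModelParams") -> bool:
        return all(np.array_equal(self.arrays[k], other.arrays[k]) for k in self.arrays)


@dataclasses.dataclass
class SignalSlice:
    """Local cell x assay signal at one genomic bin.

    ``values`` carries the arcsinh signal with invisible entries zeroed;
    ``track_observed`` marks existing tracks and ``input_visible`` the
    subset currently usable as input (observed and not masked).
    """

    values: np.ndarray
    track_observed: np.ndarray
    input_visible: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.track_observed = np.asarray(self.track_observed, dtype=bool)
        self.input_visible = np.asarray(self.input_visible, dtype=bool)
        if not (self.values.shape == self.track_observed.shape == self.input_visible.shape):
            raise ValueError("slice arrays must share one (n_c, n_a) shape")
        if (self.input_visible & ~self.track_observed).any():
            raise ValueError("input_visible must imply track_observed")
        if (self.values[~self.input_visible] != 0).any():
            raise ValueError("values must be 0 wherever input_visible is false")


@dataclasses.dataclass
class EmbeddingSet:
    cell_embeddings: np.ndarray
    assay_embeddings: np.ndarray


# ---------------------------------------------------------------------------
# forward graph (batched, autodiff)
# ---------------------------------------------------------------------------

def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered ** 2).mean(axis=-1, keepdims=True)
    return centered * ((var + eps) ** -0.5) * gamma + beta


def _sab_forward(h: Tensor, params: dict[str, Tensor], prefix: str,
                 config: ModelConfig) -> Tensor:
    """Self-attention block: MHA + residual, FFN + residual; LN optional."""
    b, n, d = h.shape
    n_heads = config.n_heads
    d_head = d // n_heads

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(b, n, n_heads, d_head).transpose(0, 2, 1, 3)

    q = split_heads(h @ params[f"{prefix}.Wq"] + params[f"{prefix}.bq"])
    k = split_heads(h @ params[f"{prefix}.Wk"] + params[f"{prefix}.bk"])
    v = split_heads(h @ params[f"{prefix}.Wv"] + params[f"{prefix}.bv"])

    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d_head))
    attn = softmax(scores, axis=-1)
    ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
    h = h + (ctx @ params[f"{prefix}.Wo"] + params[f"{prefix}.bo"])
    if config.layer_norm:
        h = _layer_norm(h, params[f"{prefix}.ln1_gamma"], params[f"{prefix}.ln1_beta"])
    ffn = relu(h @ params[f"{prefix}.ffn_W1"] + params[f"{prefix}.ffn_b1"])
    h = h + (ffn @ params[f"{prefix}.ffn_W2"] + params[f"{prefix}.ffn_b2"])
    if config.layer_norm:
        h = _layer_norm(h, params[f"{prefix}.ln2_gamma"], params[f"{prefix}.ln2_beta"])
    return h


def _signal_embedding(x: Tensor, W: Tensor, b: Tensor,
                      u: Tensor, axis_counts: np.ndarray) -> Tensor:
    """ReLU(affine(x)) scaled by 1/n_obs (zero when n_obs == 0), plus u."""
    act = relu(x @ W + b)
    with np.errstate(divide="ignore"):
        scale = np.where(axis_counts > 0, 1.0 / np.maximum(axis_counts, 1), 0.0)
    return act * scale[..., None] + u


def _encode(values: np.ndarray, visible: np.ndarray, params: dict[str, Tensor],
            config: ModelConfig) -> tuple[Tensor, Tensor]:
    """Contextual cell and assay embeddings for a batch of slices.

    ``values``: [batch, n_c, n_a] with invisible entries zeroed;
    ``visible``: same-shape boolean mask.
    Returns (cell_embeddings [batch, n_c, d], assay_embeddings [batch, n_a, d]).
    """
    x = Tensor(values * visible)  # invisible entries provably carry no signal
    n_obs_cell = visible.sum(axis=2)  # [batch, n_c]
    n_obs_assay = visible.sum(axis=1)  # [batch, n_a]

    h_cell = _signal_embedding(x, params["cell_map_W"], params["cell_map_b"],
                               params["u_cell"], n_obs_cell)
    cell_emb = _sab_forward(h_cell, params, "cell_sab", config)

    xt = x.transpose(0, 2, 1)
    h_assay = _signal_embedding(xt, params["assay_map_W"], params["assay_map_b"],
                                params["u_assay"], n_obs_assay)
    assay_emb = _sab_forward(h_assay, params, "assay_sab", config)
    return cell_emb, assay_emb


def _decode(cell_rows: Tensor, assay_rows: Tensor, params: dict[str, Tensor],
            config: ModelConfig, dropout_masks: list[np.ndarray] | None = None) -> Tensor:
    """MLP on [c ; a] -> scalar per target row."""
    h = concat([cell_rows, assay_rows], axis=-1)
    for layer in range(config.decoder_layers):
        h = relu(h @ params[f"decoder_W{layer}"] + params[f"decoder_b{layer}"])
        if dropout_masks is not None:
            h = h * dropout_masks[layer]
    out = h @ params["decoder_Wout"] + params["decoder_bout"]
    return out.reshape(out.shape[0])


def forward_batch(values: np.ndarray, visible: np.ndarray,
                  target_bins: np.ndarray, target_cells: np.ndarray,
                  target_assays: np.ndarray, params: dict[str, Tensor],
                  config: ModelConfig,
                  dropout_masks: list[np.ndarray] | None = None) -> Tensor:
    """Predict signal for target (bin, cell, assay) triples of a slice batch."""
    cell_emb, assay_emb = _encode(values, visible, params, config)
    c_rows = gather_pairs(cell_emb, target_bins, target_cells)
    a_rows = gather_pairs(assay_emb, target_bins, target_assays)
    return _decode(c_rows, a_rows, params, config, dropout_masks)


# ---------------------------------------------------------------------------
# public single-slice API (eval mode, numpy in / numpy out)
# ---------------------------------------------------------------------------

def _check_slice_shapes(sl: SignalSlice, params: ModelParams) -> None:
    if sl.values.shape != (params.n_cells, params.n_assays):
        raise ValueError(
            f"slice shape {sl.values.shape} does not match model "
            f"({params.n_cells}, {params.n_assays})"
        )


def embed_cells(sl: SignalSlice, params: ModelParams,
                config: ModelConfig | None = None) -> np.ndarray:
    """Pre-attention cell embeddings: scaled signal embedding plus u_cell."""
    config = config or params.config
    _check_slice_shapes(sl, params)
    t = params.as_tensors()
    x = Tensor((sl.values * sl.input_visible)[None])
    n_obs = sl.input_visible.sum(axis=1)[None]
    h = _signal_embedding(x, t["cell_map_W"], t["cell_map_b"],
                          t["u_cell"], n_obs)
    return h.data[0]


def embed_assays(sl: SignalSlice, params: ModelParams,
                 config: ModelConfig | None = None) -> np.ndarray:
    """Pre-attention assay embeddings (column-wise analogue of embed_cells)."""
    config = config or params.config
    _check_slice_shapes(sl, params)
    t = params.as_tensors()
    x = Tensor((sl.values * sl.input_visible).T[None])
    n_obs = sl.input_visible.sum(axis=0)[None]
    h = _signal_embedding(x, t["assay_map_W"], t["assay_map_b"],
                          t["u_assay"], n_obs)
    return h.data[0]


def self_attention_block(embeddings: np.ndarray, sab_params: dict[str, np.ndarray],
                         config: ModelConfig) -> np.ndarray:
    """Apply one self-attention block to an [n, embed_dim] token set."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[1] != config.embed_dim:
        raise ValueError(f"expected [n, {config.embed_dim}] embeddings, got {embeddings.shape}")
    expected = _sab_param_shapes(config)
    for name, shape in expected.items():
        if name not in sab_params or np.asarray(sab_params[name]).shape != shape:
            raise ValueError(f"self-attention parameter {name!r} missing or of wrong shape")
    tensors = {f"sab.{k}": Tensor(np.asarray(v, dtype=float)) for k, v in sab_params.items()}
    out = _sab_forward(Tensor(embeddings[None]), tensors, "sab", config)
    return out.data[0]


def sab_params_of(params: ModelParams, side: str) -> dict[str, np.ndarray]:
    """Extract the cell- or assay-side attention parameters by name."""
    prefix = f"{side}_sab."
    return {k[len(prefix):]: v for k, v in params.arrays.items() if k.startswith(prefix)}


def contextual_embeddings(sl: SignalSlice, params: ModelParams,
                          config: ModelConfig | None = None) -> EmbeddingSet:
    """Full encoder pass: signal embedding + self-attention, both axes."""
    config = config or params.config
    _check_slice_shapes(sl, params)
    cell_emb, assay_emb = _encode(sl.values[None], sl.input_visible[None],
                                  params.as_tensors(), config)
    return EmbeddingSet(cell_emb.data[0], assay_emb.data[0])


def decode(cell_embedding: np.ndarray, assay_embedding: np.ndarray,
           params: ModelParams, config: ModelConfig | None = None) -> float:
    """Decode one (cell, assay) embedding pair to a scalar arcsinh signal."""
    config = config or params.config
    cell_embedding = np.asarray(cell_embedding, dtype=float)
    assay_embedding = np.asarray(assay_embedding, dtype=float)
    if cell_embedding.shape != (config.embed_dim,) or assay_embedding.shape != (config.embed_dim,):
        raise ValueError(f"embeddings must have length {config.embed_dim}")
    t = params.as_tensors()
    out = _decode(Tensor(cell_embedding[None]), Tensor(assay_embedding[None]), t, config)
    return float(out.data[0])


def impute_slice(sl: SignalSlice, targets, params: ModelParams,
                 config: ModelConfig | None = None) -> np.ndarray:
    """Predict arcsinh signal for a list of (cell, assay) targets at one bin."""
    config = config or params.config
    _check_slice_shapes(sl, params)
    targets = list(targets)
    if not targets:
        return np.zeros(0)
    cells = np.asarray([t[0] for t in targets], dtype=int)
    assays = np.asarray([t[1] for t in targets], dtype=int)
    if (cells < 0).any() or (cells >= params.n_cells).any():
        raise IndexError("target cell index out of range")
    if (assays < 0).any() or (assays >= params.n_assays).any():
        raise IndexError("target assay index out of range")
    out = forward_batch(sl.values[None], sl.input_visible[None],
                        np.zeros(len(targets), dtype=int), cells, assays,
                        params.as_tensors(), config)
    return out.data.copy()


def impute_track(tensor, target: tuple[int, int], params: ModelParams,
                 config: ModelConfig | None = None, batch_bins: int = 512,
                 input_mask: np.ndarray | None = None) -> np.ndarray:
    """Impute a full-length track for one (cell, assay) pair.

    ``input_mask`` restricts the visible context (default: the tensor's
    training-split tracks when a track table is present, else all observed
    tracks).
    """
    config = config or params.config
    ci, aj = target
    if input_mask is None:
        if tensor.track_table is not None:
            input_mask = tensor.split_mask("train")
        else:
            input_mask = tensor.observed
    input_mask = np.asarray(input_mask, dtype=bool)
    t = params.as_tensors()
    out = np.empty(tensor.n_bins)
    for start in range(0, tensor.n_bins, batch_bins):
        stop = min(start + batch_bins, tensor.n_bins)
        block = tensor.values[:, :, start:stop].transpose(2, 0, 1).astype(float)
        visible = np.broadcast_to(input_mask, (stop - start,) + input_mask.shape)
        block = block * visible
        idx = np.arange(stop - start)
        pred = forward_batch(block, visible, idx,
                             np.full(stop - start, ci), np.full(stop - start, aj),
                             t, config)
        out[start:stop] = pred.data
    return out


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: ModelParams, cell_ids=None, assay_ids=None) -> None:
    meta = {
        "config": params.config.to_dict(),
        "n_cells": params.n_cells,
        "n_assays": params.n_assays,
        "cell_ids": list(cell_ids) if cell_ids is not None else None,
        "assay_ids": list(assay_ids) if assay_ids is not None else None,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **params.arrays)


def load_checkpoint(path) -> tuple[ModelParams, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    params = ModelParams(arrays, meta["n_cells"], meta["n_assays"], config)
    return params, meta
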