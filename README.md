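# edice

Factorized self-attentive imputation of epigenomic signal tracks, plus the
surrounding analysis toolkit: model-free baselines, a simplified
Poisson/Benjamini-Hochberg peak caller with stratified evaluation metrics,
negative-binomial pseudo-replicate simulation with Wasserstein peak-shape
comparison, and a synthetic tensor generator that makes everything testable
end to end without external data.

## What it does

Epigenomic experiments (histone ChIP-seq, DNase-seq) yield one signal track
per (cell type, assay) pair, but most pairs are never measured. The data
form a partially observed `cells x assays x genomic bins` tensor of
arcsinh-transformed, 25 bp-binned -log10 p-value signal. At each genomic
bin, the model encodes the local cell x assay signal matrix twice — rows
into per-cell tokens, columns into per-assay tokens — adds learned global
embeddings, contextualizes each token set with a Transformer-style
self-attention block (no layer normalization), and decodes any
(cell, assay) pair from the concatenation of its two contextual embeddings
with an MLP. Training hides a random subset of observed tracks per bin
(masked reconstruction); a tissue-wise variant masks all tracks of one cell
type, and a two-stage transfer protocol fine-tunes a model pretrained on
one individual onto a second individual with a held-out tissue.

The neural network runs on a small numpy reverse-mode autodiff engine
(`edice._autodiff`), so the package has no deep-learning framework
dependency and trains desk-scale models on a single CPU.

## CLI

Every subcommand writes a JSON run manifest next to its output.

```sh
edice synth --spec spec.yaml --seed 7 --out tensor.h5
edice ingest --tracks tracks.tsv --chrom chr21 --chrom-length 46709983 --out tensor.h5
edice train --tensor tensor.h5 --config train.yaml --seed 7 --out model.ckpt.npz
edice transfer --pretrained model.ckpt.npz --target target.h5 \
    --held-out-tissue C03 --out tuned.ckpt.npz
edice impute --tensor tensor.h5 --model model.ckpt.npz --cell C00 --assay A02 \
    --out imputed.bedGraph
edice baseline --tensor tensor.h5 --method avg --cell C00 --assay A02 --out avg.bedGraph
edice evaluate --imputed imputed.bedGraph --observed observed.bedGraph \
    --chrom chr21 --chrom-length 46709983 --report report.json
edice simulate-replicates --imputed imputed.bedGraph --model nb.json \
    --chrom chr21 --chrom-length 46709983 --n 3 --seed 7 --out counts.tsv
```

Config files are YAML whose keys mirror `ModelConfig` and `TrainConfig`
field names; one file may carry both. Signal I/O is bedGraph (bigWig read
support is available via the optional `pyBigWig` extra), peaksets are
BED6/narrowPeak, tensors are HDF5.

## Package layout

| module | contents |
| --- | --- |
| `edice.data_io` | binning, arcsinh transform, bedGraph/bigWig reading, HDF5 tensor store, track tables |
| `edice.model` | model configuration/parameters, encoders, self-attention block, decoder, track imputation, checkpoints |
| `edice.training` | mask sampling, masked-MSE loss, Adam training loop, transfer fine-tuning |
| `edice.baselines` | AVG / individual-AVG / training-individual-track predictors, trilinear factorization baseline |
| `edice.evaluation` | Poisson/BH peak caller, stratified MSE/Pearson, AUPRC, peakset precision/recall, individual-specific scoring |
| `edice.replicate_sim` | NB dispersion estimation, pseudo-replicate simulation, Wasserstein-1 peak-shape distance, affinity-matrix export |
| `edice.synthetic` | ground-truthed synthetic tensors, two-individual scenarios, track splits |
| `edice.cli` | `edice` command group |

## Notes and simplifications

- The peak caller is a deterministic simplification of MACS2 (global or
  1/5/10 kb local background rate, integer-rounded inverse-arcsinh signal
  as the count observation, no gap tolerance); absolute peak counts will
  not match MACS2 itself.
- NB dispersion is estimated by method of moments with a small-sample bias
  correction on the numerator (`mean^2 - var/n`); pass
  `bias_correction=False` for the plain plug-in ratio.
- The factorization baseline is a single-resolution trilinear model meant
  for synthetic benchmarking, not a reimplementation of multi-scale
  genome-wide factorization models.
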