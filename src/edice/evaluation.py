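"""Metric layer: Poisson/BH peak calling, stratified MSE/Pearson, AUPRC,
peakset precision/recall and individual-specific enrichment scoring.

The peak caller is a deterministic simplification of MACS2: a one-sided
Poisson test per 25 bp bin against a background rate, Benjamini-Hochberg
adjustment across the track, threshold 0.01, and merging of contiguous
significant bins.  Absolute peak counts are therefore not expected to
match MACS2 itself.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .data_io import GenomicBinning, inverse_arcsinh

__all__ = [
    "PeakSet",
    "MetricReport",
    "poisson_peak_call",
    "stratified_mse_pearson",
    "auprc",
    "peakset_precision_recall",
    "individual_specific_regions",
    "individual_specific_auprc",
    "evaluate_track",
]


@dataclasses.dataclass
class PeakSet:
    """Sorted, non-overlapping genomic intervals (bp, 0-based half-open)."""

    chrom: str
    intervals: list[tuple[int, int]]
    scores: list[float] = None

    def __post_init__(self):
        self.intervals = [(int(s), int(e)) for s, e in self.intervals]
        if self.scores is None:
            self.scores = [0.0] * len(self.intervals)
        if len(self.scores) != len(self.intervals):
            raise ValueError("scores must align with intervals")
        prev_end = -1
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty or inverted interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = e

    def __len__(self) -> int:
        return len(self.intervals)

    def bin_mask(self, binning: GenomicBinning) -> np.ndarray:
        """Boolean per-bin indicator of overlap with any peak."""
        mask = np.zeros(binning.n_bins, dtype=bool)
        for s, e in self.intervals:
            first = s // binning.bin_size
            last = math.ceil(e / binning.bin_size)
            mask[first:min(last, binning.n_bins)] = True
        return mask

    def to_bed(self, path, name_prefix: str = "peak") -> None:
        """BED6; the score column is min(1000, round(100 * peak score))."""
        with open(path, "w") as fh:
            for idx, ((s, e), score) in enumerate(zip(self.intervals, self.scores)):
                bed_score = min(1000, int(round(100 * score)))
                fh.write(f"{self.chrom}\t{s}\t{e}\t{name_prefix}{idx}\t{bed_score}\t.\n")

    @classmethod
    def from_bed(cls, path, chrom: str | None = None) -> "PeakSet":
        """Read BED3/BED6/narrowPeak; keeps intervals of one chromosome."""
        intervals, scores, seen = [], [], None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if chrom is None:
                    seen = seen or fields[0]
                    if fields[0] != seen:
                        raise ValueError("multi-chromosome BED needs an explicit chrom")
                elif fields[0] != chrom:
                    continue
                intervals.append((int(fields[1]), int(fields[2])))
                scores.append(float(fields[4]) / 100 if len(fields) >= 5 and fields[4] != "." else 0.0)
        order = np.argsort([s for s, _ in intervals]) if intervals else []
        return cls(chrom or seen or "", [intervals[i] for i in order], [scores[i] for i in order])


@dataclasses.dataclass
class MetricReport:
    mse_global: float
    mse_fg: float | None
    mse_bg: float | None
    pearson_global: float | None
    pearson_fg: float | None
    pearson_bg: float | None
    auprc: float | None
    peak_precision: float | None
    peak_recall: float | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def _local_lambda(counts: np.ndarray, bin_size: int, global_rate: float) -> np.ndarray:
    """MACS2-style background: max of global and 1 kb/5 kb/10 kb local means."""
    lam = np.full(len(counts), global_rate)
    for window_bp in (1000, 5000, 10000):
        w = max(1, window_bp // bin_size)
        local = ndimage.uniform_filter1d(counts, size=w, mode="nearest")
        lam = np.maximum(lam, local)
    return lam


def poisson_peak_call(track: np.ndarray, binning: GenomicBinning, alpha: float = 0.01,
                      lambda_mode: str = "global", signal_scale: str = "arcsinh") -> PeakSet:
    """Call enriched bins with a one-sided Poisson test and BH correction.

    The track is inverted from the arcsinh scale (unless
    ``signal_scale='raw'``) and rounded to integers to serve as count-like
    observations.  ``lambda_mode`` is ``'global'`` (per-track mean rate,
    default) or ``'local'`` (max of global and 1/5/10 kb window means).
    """
    track = np.asarray(track, dtype=float)
    if (track < 0).any():
        raise ValueError("track must be nonnegative")
    if signal_scale == "arcsinh":
        raw = inverse_arcsinh(track)
    elif signal_scale == "raw":
        raw = track
    else:
        raise ValueError(f"unknown signal_scale {signal_scale!r}")
    counts = np.round(raw).astype(np.int64)
    if counts.max(initial=0) == 0:
        return PeakSet(binning.chrom, [])

    global_rate = float(raw.mean())
    if lambda_mode == "global":
        lam = np.full(len(counts), global_rate)
    elif lambda_mode == "local":
        lam = _local_lambda(raw, binning.bin_size, global_rate)
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    # upper-tail P(X >= k) under Poisson(lam)
    pvals = stats.poisson.sf(counts - 1, lam)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    significant = adj <= alpha
    if not significant.any():
        return PeakSet(binning.chrom, [])

    neglog_adj = -np.log10(np.maximum(adj, 1e-300))
    intervals, scores = [], []
    labels, n_runs = ndimage.label(significant)
    for run in range(1, n_runs + 1):
        idx = np.flatnonzero(labels == run)
        start = binning.bin_start(idx[0])
        end = binning.bin_end(idx[-1])
        intervals.append((start, end))
        scores.append(float(neglog_adj[idx].max()))
    return PeakSet(binning.chrom, intervals, scores)


# ---------------------------------------------------------------------------
# stratified regression metrics
# ---------------------------------------------------------------------------

def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))

def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def stratified_mse_pearson(imputed: np.ndarray, observed: np.ndarray,
                           foreground: np.ndarray) -> dict[str, dict[str, float | None]]:
    """MSE and Pearson over all bins, foreground bins and background bins."""
    imputed = np.asarray(imputed, dtype=float)
    observed = np.asarray(observed, dtype=float)
    foreground = np.asarray(foreground, dtype=bool)
    if not (imputed.shape == observed.shape == foreground.shape):
        raise ValueError("imputed, observed and foreground must have equal length")
    out: dict[str, dict[str, float | None]] = {}
    for name, mask in (("global", np.ones_like(foreground)),
                       ("fg", foreground), ("bg", ~foreground)):
        if mask.sum() == 0:
            out[name] = {"mse": None, "pearson": None}
            continue
        a, b = imputed[mask], observed[mask]
        out[name] = {"mse": _mse(a, b), "pearson": _pearson(a, b)}
    return out


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall step function (average precision).

    Equal scores are grouped into a single threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("labels must contain at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    n_pred = np.arange(1, len(scores) + 1)
    # threshold boundaries: last index of each tied-score group
    boundary = np.flatnonzero(np.diff(sorted_scores) != 0)
    cut = np.append(boundary, len(scores) - 1)
    precision = tp[cut] / n_pred[cut]
    recall = tp[cut] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def peakset_precision_recall(predicted: PeakSet, reference: PeakSet,
                             binning: GenomicBinning) -> tuple[float | None, float]:
    """Bin-level precision/recall of a predicted peakset against a reference."""
    pred = predicted.bin_mask(binning)
    ref = reference.bin_mask(binning)
    inter = int((pred & ref).sum())
    precision = inter / int(pred.sum()) if pred.sum() else None
    recall = inter / int(ref.sum()) if ref.sum() else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# individual-specific enrichment
# ---------------------------------------------------------------------------

def _overlaps(iv: tuple[int, int], peaks: PeakSet) -> bool:
    s, e = iv
    return any(ps < e and s < pe for ps, pe in peaks.intervals)


def individual_specific_regions(target_peaks: PeakSet, training_peaks: PeakSet,
                                binning: GenomicBinning,
                                min_len: int = 150) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation mask and positive labels for individual-specific scoring.

    Bins of target peaks that overlap any training-individual peak are
    excluded (conserved enrichment), as are target-only peaks shorter than
    ``min_len`` bp.  Remaining target-only peaks are positives; all other
    non-excluded bins are negatives.
    """
    evaluate = np.ones(binning.n_bins, dtype=bool)
    positive = np.zeros(binning.n_bins, dtype=bool)
    for iv in target_peaks.intervals:
        shared = _overlaps(iv, training_peaks)
        sub = PeakSet(binning.chrom, [iv])
        bins = sub.bin_mask(binning)
        if shared:
            evaluate &= ~bins
        elif iv[1] - iv[0] < min_len:
            evaluate &= ~bins
        else:
            positive |= bins
    # peaks of the training individual absent from the target are ordinary
    # negatives: the task is detecting target-only enrichment
    return evaluate, positive & evaluate


def individual_specific_auprc(imputed: np.ndarray, evaluate: np.ndarray,
                              positive: np.ndarray) -> dict[str, float | None]:
    """AUPRC over non-excluded bins plus the positive-fraction baseline."""
    imputed = np.asarray(imputed, dtype=float)
    evaluate = np.asarray(evaluate, dtype=bool)
    positive = np.asarray(positive, dtype=bool)
    scores = imputed[evaluate]
    labels = positive[evaluate]
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        return {"auprc": None, "positive_fraction": None, "n_positive": n_pos}
    return {
        "auprc": auprc(scores, labels),
        "positive_fraction": n_pos / len(labels),
        "n_positive": n_pos,
    }


# ---------------------------------------------------------------------------
# one-call report
# ---------------------------------------------------------------------------

def evaluate_track(imputed: np.ndarray, observed: np.ndarray, binning: GenomicBinning,
                   alpha: float = 0.01) -> MetricReport:
    """Full metric report for one imputed track against its observation."""
    obs_peaks = poisson_peak_call(observed, binning, alpha=alpha)
    imp_peaks = poisson_peak_call(imputed, binning, alpha=alpha)
    fg = obs_peaks.bin_mask(binning)
    strat = stratified_mse_pearson(imputed, observed, fg)
    try:
        area = auprc(imputed, fg)
    except ValueError:
        area = None
    precision, recall = peakset_precision_recall(imp_peaks, obs_peaks, binning)
    return MetricReport(
        mse_global=strat["global"]["mse"],
        mse_fg=strat["fg"]["mse"],
        mse_bg=strat["bg"]["mse"],
        pearson_global=strat["global"]["pearson"],
        pearson_fg=strat["fg"]["pearson"],
        pearson_bg=strat["bg"]["pearson"],
        auprc=area,
        peak_precision=precision,
        peak_recall=recall,
    )
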