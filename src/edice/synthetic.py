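"""Synthetic partially observed epigenome tensors with known ground truth.

The generator mimics the structure the imputation model exploits: a
low-rank background (softplus of cell/assay latent inner products)
modulated by a smooth per-bin process, plus Gaussian-bump peak
enrichments planted at shared loci whose amplitudes factorize into
per-cell loadings and per-assay strengths.  A core block of assays is
observed in every cell; the remaining assays have sparse coverage.

Two-individual scenarios share all latent structure but toggle a fraction
of peak loci on or off in the second individual, recording the resulting
individual-specific regions as ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .data_io import GenomicBinning, SignalTensor, TrackTable, arcsinh_transform
from .evaluation import PeakSet

__all__ = ["SyntheticSpec", "GroundTruth", "generate_tensor", "generate_individual_pair",
           "split_tracks"]

_SOFTPLUS_CAP = 30.0


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic tensor generator.

    The default is desk-scale: 12 cells x 8 assays x 20,000 bins
    (~500 kb at 25 bp), 5 core assays, 50% coverage elsewhere.
    """

    n_cells: int = 12
    n_assays: int = 8
    n_bins: int = 20_000
    latent_dim: int = 8
    core_assays: int = 5
    coverage: float = 0.5
    peak_rate: float = 2.0  # expected peaks per 10 kb
    peak_width_bp: float = 400.0
    peak_amplitude: float = 8.0
    cell_loading_sd: float = 1.5  # dispersion of per-cell peak amplitudes
    cell_loading_common: float = 0.0  # weight of a per-peak offset shared by all cells
    noise_sd: float = 0.25
    smooth_sd: float = 0.4  # log-scale sd of the smooth background process
    smooth_len_bins: int = 40
    individual_effect: float = 0.3
    bin_size: int = 25
    chrom: str = "chrSim"
    constant_latents: bool = False
    cell_specific_peaks: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_assays, self.n_bins, self.latent_dim) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if not 0 <= self.individual_effect <= 1:
            raise ValueError("individual_effect must lie in [0, 1]")
        if self.core_assays > self.n_assays:
            raise ValueError("core_assays cannot exceed n_assays")
        if self.peak_rate < 0 or self.peak_width_bp <= 0 or self.noise_sd < 0:
            raise ValueError("degenerate peak/noise configuration")

    @property
    def binning(self) -> GenomicBinning:
        return GenomicBinning(self.chrom, self.n_bins * self.bin_size, self.bin_size)


@dataclasses.dataclass
class Peak:
    center_bin: int
    sigma_bins: float
    cell_loadings: np.ndarray  # [n_c]
    assay_strengths: np.ndarray  # [n_a]

    def half_width_bins(self) -> int:
        return max(1, int(np.ceil(2.0 * self.sigma_bins)))


@dataclasses.dataclass
class GroundTruth:
    clean: np.ndarray  # arcsinh-scale noise-free values [n_c, n_a, n_bins]
    cell_latents: np.ndarray
    assay_latents: np.ndarray
    background: np.ndarray  # [n_c, n_a] base rates
    smooth_process: np.ndarray  # [n_bins]
    peaks: list[Peak]

    def planted_peakset(self, cell: int, assay: int, spec: SyntheticSpec,
                        min_amplitude: float = 1.0) -> PeakSet:
        """Intervals around planted peaks whose amplitude exceeds a floor."""
        intervals = []
        for p in self.peaks:
            amp = spec.peak_amplitude * p.cell_loadings[cell] * p.assay_strengths[assay]
            if amp >= min_amplitude:
                hw = p.half_width_bins()
                s = max(0, p.center_bin - hw) * spec.bin_size
                e = min(spec.n_bins, p.center_bin + hw + 1) * spec.bin_size
                intervals.append((s, e))
        return PeakSet(spec.chrom, _merge_intervals(intervals))


def _merge_intervals(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _latents(spec: SyntheticSpec, rng: np.random.Generator):
    if spec.constant_latents:
        c = np.ones((spec.n_cells, spec.latent_dim))
        a = np.ones((spec.n_assays, spec.latent_dim)) / spec.latent_dim
        return c, a
    # scaled so cell.assay inner products are approximately standard normal
    c = rng.normal(size=(spec.n_cells, spec.latent_dim))
    a = rng.normal(size=(spec.n_assays, spec.latent_dim)) / np.sqrt(spec.latent_dim)
    return c, a


def _smooth_process(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.smooth_sd == 0:
        return np.ones(spec.n_bins)
    white = rng.normal(size=spec.n_bins)
    w = ndimage.gaussian_filter1d(white, sigma=spec.smooth_len_bins, mode="wrap")
    sd = w.std()
    if sd > 0:
        w = w * (spec.smooth_sd / sd)
    return np.exp(w - spec.smooth_sd ** 2 / 2)  # mean ~ 1


def _draw_peaks(spec: SyntheticSpec, rng: np.random.Generator,
                n_peaks: int | None = None, min_width_bp: float | None = None) -> list[Peak]:
    if n_peaks is None:
        expected = spec.peak_rate * spec.n_bins * spec.bin_size / 10_000.0
        n_peaks = rng.poisson(expected)
    peaks = []
    for _ in range(n_peaks):
        center = int(rng.integers(0, spec.n_bins))
        width_bp = rng.exponential(spec.peak_width_bp)
        width_bp = max(width_bp, min_width_bp if min_width_bp is not None else 100.0)
        sigma_bins = width_bp / spec.bin_size / 4.0  # ~95% of mass within width
        common = spec.cell_loading_common * rng.normal()
        if spec.cell_specific_peaks:
            loadings = (rng.random(spec.n_cells) < 0.5) * _softplus(
                common + rng.normal(size=spec.n_cells) * spec.cell_loading_sd)
        else:
            # per-(peak, cell) loading shared across assays: the local context
            # in observed assays is informative about held-out ones
            loadings = _softplus(common + rng.normal(size=spec.n_cells) * spec.cell_loading_sd)
        strengths = _softplus(rng.normal(loc=0.5, size=spec.n_assays))
        peaks.append(Peak(center, sigma_bins, loadings, strengths))
    return peaks


def _peak_signal(spec: SyntheticSpec, peaks: list[Peak]) -> np.ndarray:
    """Sum of factorized Gaussian bumps, [n_c, n_a, n_bins]."""
    signal = np.zeros((spec.n_cells, spec.n_assays, spec.n_bins))
    for p in peaks:
        hw = max(1, int(np.ceil(4 * p.sigma_bins)))
        lo = max(0, p.center_bin - hw)
        hi = min(spec.n_bins, p.center_bin + hw + 1)
        k = np.arange(lo, hi)
        bump = np.exp(-0.5 * ((k - p.center_bin) / p.sigma_bins) ** 2)
        amp = spec.peak_amplitude * np.outer(p.cell_loadings, p.assay_strengths)
        signal[:, :, lo:hi] += amp[:, :, None] * bump[None, None, :]
    return signal


def _observation_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    observed = np.zeros((spec.n_cells, spec.n_assays), dtype=bool)
    observed[:, :spec.core_assays] = True
    non_core = np.arange(spec.core_assays, spec.n_assays)
    observed[:, non_core] = rng.random((spec.n_cells, len(non_core))) < spec.coverage
    for j in non_core:  # every assay needs at least one observed track
        if not observed[:, j].any():
            observed[int(rng.integers(spec.n_cells)), j] = True
    return observed


def _assemble(spec: SyntheticSpec, rng: np.random.Generator, cell_latents, assay_latents,
              smooth, peaks, observed) -> tuple[SignalTensor, GroundTruth]:
    background = _softplus(cell_latents @ assay_latents.T)
    raw_clean = background[:, :, None] * smooth[None, None, :] + _peak_signal(spec, peaks)
    clean = arcsinh_transform(raw_clean)
    raw = raw_clean
    if spec.noise_sd > 0:
        raw = np.maximum(raw_clean + rng.normal(0, spec.noise_sd, size=raw_clean.shape), 0.0)
    values = arcsinh_transform(raw).astype(np.float32)
    values[~observed, :] = 0.0
    tensor = SignalTensor(values, observed, spec.binning,
                          [f"C{i:02d}" for i in range(spec.n_cells)],
                          [f"A{j:02d}" for j in range(spec.n_assays)])
    truth = GroundTruth(clean, cell_latents, assay_latents, background, smooth, peaks)
    return tensor, truth


def generate_tensor(spec: SyntheticSpec) -> tuple[SignalTensor, GroundTruth]:
    """Draw one partially observed synthetic tensor plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    cell_latents, assay_latents = _latents(spec, rng)
    smooth = _smooth_process(spec, rng)
    peaks = _draw_peaks(spec, rng)
    observed = _observation_mask(spec, rng)
    return _assemble(spec, rng, cell_latents, assay_latents, smooth, peaks, observed)


def generate_individual_pair(spec: SyntheticSpec):
    """Two tensors sharing tissue structure but differing at a fraction of loci.

    Individual B shares all latents with individual A; a fraction
    ``individual_effect`` of peak loci are individual-specific, split
    evenly between A-only and B-only, each at least 150 bp wide so it
    survives the evaluation length filter.  Independent measurement noise
    is drawn per individual.

    Returns ``(tensor_a, tensor_b, truth_a, truth_b, specific)`` where
    ``specific`` maps ``"A"``/``"B"`` to lists of that individual's
    private peaks.
    """
    if spec.individual_effect == 0:
        rng = np.random.default_rng(spec.seed)
        cell_latents, assay_latents = _latents(spec, rng)
        smooth = _smooth_process(spec, rng)
        peaks = _draw_peaks(spec, rng)
        observed = _observation_mask(spec, rng)
        state = rng.bit_generator.state
        tensor_a, truth_a = _assemble(spec, rng, cell_latents, assay_latents, smooth,
                                      peaks, observed)
        rng_b = np.random.default_rng()
        rng_b.bit_generator.state = state
        tensor_b, truth_b = _assemble(spec, rng_b, cell_latents, assay_latents, smooth,
                                      peaks, observed)
        return tensor_a, tensor_b, truth_a, truth_b, {"A": [], "B": []}

    rng = np.random.default_rng(spec.seed)
    cell_latents, assay_latents = _latents(spec, rng)
    smooth = _smooth_process(spec, rng)
    # individual-specific loci must be scoreable after the 150 bp filter
    peaks = _draw_peaks(spec, rng, min_width_bp=200.0)
    observed = _observation_mask(spec, rng)

    n = len(peaks)
    n_specific = int(round(spec.individual_effect * n))
    order = rng.permutation(n)
    only_a = set(order[: n_specific // 2].tolist())
    only_b = set(order[n_specific // 2 : n_specific].tolist())

    peaks_a = [p for i, p in enumerate(peaks) if i not in only_b]
    peaks_b = [p for i, p in enumerate(peaks) if i not in only_a]

    tensor_a, truth_a = _assemble(spec, rng, cell_latents, assay_latents, smooth,
                                  peaks_a, observed)
    tensor_b, truth_b = _assemble(spec, rng, cell_latents, assay_latents, smooth,
                                  peaks_b, observed)
    specific = {
        "A": [peaks[i] for i in sorted(only_a)],
        "B": [peaks[i] for i in sorted(only_b)],
    }
    return tensor_a, tensor_b, truth_a, truth_b, specific


def split_tracks(observed: np.ndarray, fractions: tuple[float, float, float],
                 seed: int) -> np.ndarray:
    """Random track-level train/val/test split with context guarantees.

    Every cell type and every assay retains at least one training track.
    Returns an object array with split names at observed positions and
    ``None`` elsewhere.
    """
    observed = np.asarray(observed, dtype=bool)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    pairs = np.argwhere(observed)
    n = len(pairs)
    if n == 0:
        raise ValueError("no observed tracks to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    labels = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val),
                      dtype=object)
    assignment = np.full(observed.shape, None, dtype=object)
    for idx, (i, j) in zip(order, pairs):
        assignment[i, j] = labels[idx]

    if fractions[0] == 0:
        if observed.any():
            raise ValueError("train fraction 0 cannot satisfy context constraints")
        return assignment

    # repair: each cell and assay needs >= 1 training track among observed
    for axis, size in ((0, observed.shape[0]), (1, observed.shape[1])):
        for k in range(size):
            sel = pairs[:, axis] == k
            if not sel.any():
                continue
            slots = [tuple(p) for p in pairs[sel]]
            if not any(assignment[p] == "train" for p in slots):
                promote = slots[int(rng.integers(len(slots)))]
                assignment[promote] = "train"
    return assignment


def tensor_with_split(tensor: SignalTensor, assignment: np.ndarray,
                      individual_id=None) -> SignalTensor:
    """Attach a track table derived from a split assignment."""
    records = []
    for (i, j) in np.argwhere(tensor.observed):
        split = assignment[i, j]
        if split is None:
            continue
        records.append((
            f"{tensor.cell_ids[i]}_{tensor.assay_ids[j]}",
            tensor.cell_ids[i], tensor.assay_ids[j], individual_id, split, "",
        ))
    tensor = SignalTensor(tensor.values, tensor.observed, tensor.binning,
                          tensor.cell_ids, tensor.assay_ids,
                          TrackTable.from_records(records))
    return tensor
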