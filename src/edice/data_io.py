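"""Reading, binning and storage of genomic signal tracks.

Signal tracks arrive as per-base (or bedGraph interval) -log10 p-values,
are averaged over fixed-width non-overlapping bins (default 25 bp) and
arcsinh-transformed.  The partially observed cell x assay x bin tensor is
persisted to HDF5 together with its observation mask and track metadata.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "GenomicBinning",
    "TrackTable",
    "SignalTensor",
    "bin_signal",
    "arcsinh_transform",
    "inverse_arcsinh",
    "read_track",
    "read_bedgraph",
    "write_bedgraph",
    "save_tensor",
    "load_tensor",
]

TRACK_COLUMNS = ["track_id", "cell_type_id", "assay_id", "individual_id", "split", "source_path"]
VALID_SPLITS = frozenset({"train", "val", "test"})


@dataclasses.dataclass(frozen=True)
class GenomicBinning:
    """Partition of one chromosome into fixed-width bins.

    Bin ``k`` covers ``[k * bin_size, (k + 1) * bin_size)``; the last bin
    may be shorter than ``bin_size``.
    """

    chrom: str
    chrom_length: int
    bin_size: int = 25

    def __post_init__(self):
        if self.chrom_length <= 0:
            raise ValueError(f"chrom_length must be positive, got {self.chrom_length}")
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.chrom_length / self.bin_size)

    def bin_start(self, k: int) -> int:
        return k * self.bin_size

    def bin_end(self, k: int) -> int:
        return min((k + 1) * self.bin_size, self.chrom_length)


class TrackTable:
    """Metadata table mapping track ids to (cell type, assay, individual, split)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TRACK_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        bad = set(frame["split"]) - VALID_SPLITS
        if bad:
            raise ValueError(f"invalid split values: {sorted(bad)}")
        key = frame[["cell_type_id", "assay_id", "individual_id"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate (cell, assay, individual) triple: {dup}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(cls, records) -> "TrackTable":
        return cls(pd.DataFrame.from_records(records, columns=TRACK_COLUMNS))

    @classmethod
    def from_tsv(cls, path) -> "TrackTable":
        frame = pd.read_csv(path, sep="\t", dtype={"individual_id": "object"})
        if "individual_id" not in frame.columns:
            frame["individual_id"] = None
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def lookup(self, cell_type_id, assay_id, individual_id=None) -> pd.Series:
        f = self.frame
        hit = f[(f.cell_type_id == cell_type_id) & (f.assay_id == assay_id)]
        if individual_id is not None:
            hit = hit[hit.individual_id == individual_id]
        if len(hit) == 0:
            raise KeyError(f"no track for ({cell_type_id}, {assay_id}, {individual_id})")
        return hit.iloc[0]

    def split_tracks(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame.split == split]


@dataclasses.dataclass
class SignalTensor:
    """Partially observed cell x assay x bin array of arcsinh signal.

    ``observed[i, j]`` is True when the (cell i, assay j) track exists;
    values of unobserved tracks are stored as 0.
    """

    values: np.ndarray  # [n_c, n_a, n_bins] float32
    observed: np.ndarray  # [n_c, n_a] bool
    binning: GenomicBinning
    cell_ids: list[str]
    assay_ids: list[str]
    track_table: TrackTable | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D [n_c, n_a, n_bins]")
        if self.observed.shape != self.values.shape[:2]:
            raise ValueError(
                f"observation mask shape {self.observed.shape} does not match "
                f"value array {self.values.shape[:2]}"
            )
        if self.values.shape[2] != self.binning.n_bins:
            raise ValueError(
                f"value array has {self.values.shape[2]} bins, binning implies "
                f"{self.binning.n_bins}"
            )
        if len(self.cell_ids) != self.values.shape[0] or len(self.assay_ids) != self.values.shape[1]:
            raise ValueError("cell/assay id lists do not match tensor shape")
        if not np.isfinite(self.values).all():
            raise ValueError("tensor values must be finite")
        if (self.values < 0).any():
            raise ValueError("tensor values must be nonnegative (arcsinh of nonnegative signal)")
        # hard contract: missing tracks are stored as zeros
        self.values[~self.observed, :] = 0.0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def split_mask(self, split: str) -> np.ndarray:
        """Track-level boolean mask of observed tracks belonging to ``split``."""
        if self.track_table is None:
            raise ValueError("tensor has no track table; cannot resolve splits")
        mask = np.zeros_like(self.observed)
        cell_index = {c: i for i, c in enumerate(self.cell_ids)}
        assay_index = {a: j for j, a in enumerate(self.assay_ids)}
        for row in self.track_table.split_tracks(split).itertuples():
            i = cell_index.get(row.cell_type_id)
            j = assay_index.get(row.assay_id)
            if i is not None and j is not None:
                mask[i, j] = True
        return mask & self.observed

    def region(self, start_bin: int, end_bin: int) -> "SignalTensor":
        if not (0 <= start_bin < end_bin <= self.n_bins):
            raise ValueError(f"invalid bin region [{start_bin}, {end_bin})")
        sub_binning = GenomicBinning(
            self.binning.chrom,
            min((end_bin - start_bin) * self.binning.bin_size, self.binning.chrom_length),
            self.binning.bin_size,
        )
        return SignalTensor(
            self.values[:, :, start_bin:end_bin].copy(),
            self.observed.copy(),
            sub_binning,
            list(self.cell_ids),
            list(self.assay_ids),
            self.track_table,
        )


# ---------------------------------------------------------------------------
# transforms and binning
# ---------------------------------------------------------------------------

def arcsinh_transform(x):
    """y = ln(x + sqrt(x^2 + 1))."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite value in input to arcsinh_transform")
    return np.arcsinh(x)


def inverse_arcsinh(y):
    """x = sinh(y), the inverse of :func:`arcsinh_transform`."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite value in input to inverse_arcsinh")
    return np.sinh(y)


def bin_signal(per_base: np.ndarray, binning: GenomicBinning) -> np.ndarray:
    """Average a per-base signal vector over the bins of ``binning``.

    The final bin may be partial; it is averaged over its actual width.
    """
    per_base = np.asarray(per_base, dtype=float)
    if per_base.ndim != 1:
        raise ValueError("per_base signal must be 1-D")
    if len(per_base) != binning.chrom_length:
        raise ValueError(
            f"per-base vector length {len(per_base)} != chrom_length {binning.chrom_length}"
        )
    finite = np.isfinite(per_base)
    if not finite.all():
        pos = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite signal value at position {pos}")
    if (per_base < 0).any():
        pos = int(np.flatnonzero(per_base < 0)[0])
        raise ValueError(f"negative signal value at position {pos}")

    n_bins = binning.n_bins
    size = binning.bin_size
    full = len(per_base) // size
    out = np.empty(n_bins, dtype=float)
    if full:
        out[:full] = per_base[: full * size].reshape(full, size).mean(axis=1)
    if n_bins > full:  # trailing partial bin
        out[full] = per_base[full * size :].mean()
    return out


# ---------------------------------------------------------------------------
# track file I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path, binning: GenomicBinning) -> np.ndarray:
    """Expand a bedGraph file to per-base signal for one chromosome.

    Bases not covered by any record are 0.  Overlapping records are
    rejected.
    """
    per_base = np.zeros(binning.chrom_length, dtype=float)
    covered = np.zeros(binning.chrom_length, dtype=bool)
    seen_chroms: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            seen_chroms.add(chrom)
            if chrom != binning.chrom:
                continue
            if end > binning.chrom_length:
                raise ValueError(
                    f"{path}:{ln}: interval end {end} exceeds chromosome length "
                    f"{binning.chrom_length}"
                )
            if covered[start:end].any():
                raise ValueError(f"{path}:{ln}: overlapping interval [{start}, {end})")
            covered[start:end] = True
            per_base[start:end] = value
    if seen_chroms and binning.chrom not in seen_chroms:
        raise ValueError(
            f"{path}: chromosome {binning.chrom!r} not present (found {sorted(seen_chroms)})"
        )
    return per_base


def write_bedgraph(path, binning: GenomicBinning, binned_values: np.ndarray) -> None:
    """Write per-bin values as a bedGraph, skipping zero bins."""
    binned_values = np.asarray(binned_values, dtype=float)
    with open(path, "w") as fh:
        for k, v in enumerate(binned_values):
            if v != 0.0:
                fh.write(f"{binning.chrom}\t{binning.bin_start(k)}\t{binning.bin_end(k)}\t{v:.6g}\n")


def _read_bigwig(path, binning: GenomicBinning) -> np.ndarray:
    try:
        import pyBigWig  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading bigWig files requires the optional pyBigWig dependency; "
            "install edice[bigwig] or supply bedGraph input"
        ) from exc
    bw = pyBigWig.open(str(path))  # pragma: no cover - optional dependency
    try:
        if binning.chrom not in bw.chroms():
            raise ValueError(f"{path}: chromosome {binning.chrom!r} not present")
        vals = np.asarray(bw.values(binning.chrom, 0, binning.chrom_length), dtype=float)
    finally:
        bw.close()
    return np.nan_to_num(vals, nan=0.0)


def read_track(source_path, binning: GenomicBinning) -> np.ndarray:
    """Read a signal file, bin to ``binning`` and arcsinh-transform."""
    path = Path(source_path)
    if path.suffix.lower() in {".bw", ".bigwig"}:
        per_base = _read_bigwig(path, binning)
    else:
        per_base = read_bedgraph(path, binning)
    return arcsinh_transform(bin_signal(per_base, binning))


# ---------------------------------------------------------------------------
# tensor store (HDF5)
# ---------------------------------------------------------------------------

def save_tensor(tensor: SignalTensor, store_path) -> None:
    with h5py.File(store_path, "w") as f:
        f.create_dataset("values", data=tensor.values, dtype="float32")
        f.create_dataset("observed", data=tensor.observed)
        f.attrs["chrom"] = tensor.binning.chrom
        f.attrs["chrom_length"] = tensor.binning.chrom_length
        f.attrs["bin_size"] = tensor.binning.bin_size
        f.attrs["cell_ids"] = [str(c) for c in tensor.cell_ids]
        f.attrs["assay_ids"] = [str(a) for a in tensor.assay_ids]
        if tensor.track_table is not None:
            grp = f.create_group("track_table")
            for col in TRACK_COLUMNS:
                vals = tensor.track_table.frame[col].astype(str).fillna("").tolist()
                grp.create_dataset(col, data=vals)


def load_tensor(store_path, region: tuple[int, int] | None = None) -> SignalTensor:
    with h5py.File(store_path, "r") as f:
        for field in ("values", "observed"):
            if field not in f:
                raise ValueError(f"tensor store {store_path} is missing the {field!r} dataset")
        values = f["values"][...]
        observed = f["observed"][...]
        binning = GenomicBinning(
            str(f.attrs["chrom"]), int(f.attrs["chrom_length"]), int(f.attrs["bin_size"])
        )
        cell_ids = [str(c) for c in f.attrs["cell_ids"]]
        assay_ids = [str(a) for a in f.attrs["assay_ids"]]
        table = None
        if "track_table" in f:
            cols = {
                col: [v.decode() if isinstance(v, bytes) else str(v) for v in f["track_table"][col][...]]
                for col in TRACK_COLUMNS
            }
            frame = pd.DataFrame(cols)
            frame["individual_id"] = frame["individual_id"].replace({"": None, "None": None})
            table = TrackTable(frame)
    tensor = SignalTensor(values, observed, binning, cell_ids, assay_ids, table)
    if region is not None:
        tensor = tensor.region(*region)
    return tensor


def ingest_tracks(track_table: TrackTable, binning: GenomicBinning) -> SignalTensor:
    """Build a SignalTensor by reading every source file in a track table."""
    cell_ids = list(dict.fromkeys(track_table.frame.cell_type_id))
    assay_ids = list(dict.fromkeys(track_table.frame.assay_id))
    values = np.zeros((len(cell_ids), len(assay_ids), binning.n_bins), dtype=np.float32)
    observed = np.zeros((len(cell_ids), len(assay_ids)), dtype=bool)
    for row in track_table.frame.itertuples():
        i = cell_ids.index(row.cell_type_id)
        j = assay_ids.index(row.assay_id)
        values[i, j] = read_track(row.source_path, binning)
        observed[i, j] = True
    return SignalTensor(values, observed, binning, cell_ids, assay_ids, track_table)
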