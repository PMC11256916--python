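"""Readers and writers for the on-disk dialects the pipeline touches.

Supported contact-map formats
-----------------------------
``.cool``
    Single-resolution cooler HDF5 layout (chroms / bins / pixels / indexes
    tables), read and written directly through h5py. Only intra-chromosomal
    pixels of the requested chromosome are loaded.
``.txt`` / ``.tsv``
    Sparse upper-triangle text: tab-separated ``bin_i  bin_j  count`` records
    with a ``# bin_i bin_j count`` header, ``i <= j``, nonzero entries only.
``.npy`` or other extensions
    Dense matrix, either a numpy binary array or whitespace-separated text
    (auto-detected from the extension).

Tracks are read from bedGraph (0-based half-open intervals); TAD boundary
sets are written as BED3, one bin-sized interval per boundary.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Sequence

import h5py
import numpy as np

from .types import BoundarySet, ContactMap, NormState, TRACK_CHANNELS, TrackSet

_SPARSE_EXTS = {".txt", ".tsv"}
_HEADER = "# bin_i bin_j count"


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".cool":
        return "cooler"
    if ext in _SPARSE_EXTS:
        return "sparse_text"
    return "dense"


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------


def load_contact_map(
    path: str,
    chrom: str,
    resolution: int,
    n_bins: int | None = None,
) -> ContactMap:
    """Load a contact map, symmetrizing sparse upper-triangle input.

    The on-disk format is inferred from the file extension. The returned map
    has ``norm_state=raw``; sparse input is mirrored across the diagonal.
    """
    fmt = _infer_format(path)
    if fmt == "cooler":
        matrix = _read_cool(path, chrom, resolution)
    elif fmt == "sparse_text":
        matrix = _read_sparse_text(path, n_bins)
    else:
        matrix = _read_dense(path)
    if np.min(matrix, initial=0.0) < 0:
        raise ValueError("invalid contact value: negative count")
    return ContactMap(chrom=chrom, resolution=resolution, matrix=matrix, norm_state=NormState.RAW)


def _read_sparse_text(path: str, n_bins: int | None) -> np.ndarray:
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed sparse record: {line!r}")
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if i < 0 or j < 0:
                raise ValueError("negative bin index")
            rows.append(i)
            cols.append(j)
            vals.append(v)
    size = n_bins if n_bins is not None else (max(rows + cols) + 1 if rows else 0)
    matrix = np.zeros((size, size), dtype=np.float64)
    seen: set[tuple[int, int]] = set()
    for i, j, v in zip(rows, cols, vals):
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate off-diagonal record for bin pair {key}")
        seen.add(key)
        matrix[i, j] = v
        matrix[j, i] = v
    return matrix


def _read_dense(path: str) -> np.ndarray:
    if path.endswith(".npy"):
        matrix = np.load(path)
    else:
        matrix = np.loadtxt(path, ndmin=2)
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("shape error: dense contact map must be square")
    return 0.5 * (matrix + matrix.T)


def _read_cool(path: str, chrom: str, resolution: int) -> np.ndarray:
    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["chroms/name"][:]]
        if chrom not in names:
            raise KeyError(f"chromosome not found: {chrom!r}")
        cid = names.index(chrom)
        file_res = int(f.attrs.get("bin-size", resolution))
        if file_res != resolution:
            raise ValueError(f"resolution mismatch: file has {file_res}, requested {resolution}")
        bin_chrom = f["bins/chrom"][:]
        mask = bin_chrom == cid
        bin_ids = np.nonzero(mask)[0]
        lo, hi = int(bin_ids[0]), int(bin_ids[-1]) + 1
        n = hi - lo
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:].astype(np.float64)
        sel = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        matrix = np.zeros((n, n), dtype=np.float64)
        ii = b1[sel] - lo
        jj = b2[sel] - lo
        matrix[ii, jj] = cnt[sel]
        matrix[jj, ii] = cnt[sel]
    return matrix


def write_contact_map(cmap: ContactMap, path: str, format: str | None = None) -> None:
    """Write ``cmap`` to ``path`` in the requested (or extension-inferred) format.

    Round trips through :func:`load_contact_map` within 1e-6 relative
    tolerance for text formats and exactly for binary ones.
    """
    cmap.validate()
    fmt = format or _infer_format(path)
    if fmt == "cooler":
        _write_cool(cmap, path)
    elif fmt == "sparse_text":
        _write_sparse_text(cmap, path)
    elif fmt == "dense":
        if path.endswith(".npy"):
            np.save(path, cmap.matrix)
        else:
            np.savetxt(path, cmap.matrix, fmt="%.10g", delimiter="\t")
    else:
        raise ValueError(f"unknown contact-map format {fmt!r}")


def _write_sparse_text(cmap: ContactMap, path: str) -> None:
    m = cmap.matrix
    iu, ju = np.nonzero(np.triu(m))
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for i, j in zip(iu, ju):
            fh.write(f"{i}\t{j}\t{m[i, j]:.10g}\n")


def _write_cool(cmap: ContactMap, path: str) -> None:
    n = cmap.n_bins
    res = cmap.resolution
    m = cmap.matrix
    iu, ju = np.nonzero(np.triu(m))
    order = np.lexsort((ju, iu))
    iu, ju = iu[order], ju[order]
    counts = m[iu, ju]
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-size"] = res
        f.attrs["bin-type"] = "fixed"
        f.attrs["nbins"] = n
        f.attrs["nchroms"] = 1
        f.attrs["nnz"] = len(counts)
        f.attrs["symmetric-upper"] = True
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array([cmap.chrom.encode()]))
        g.create_dataset("length", data=np.array([n * res], dtype=np.int64))
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        starts = np.arange(n, dtype=np.int64) * res
        g.create_dataset("start", data=starts)
        g.create_dataset("end", data=starts + res)
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=iu.astype(np.int64))
        g.create_dataset("bin2_id", data=ju.astype(np.int64))
        g.create_dataset("count", data=counts)
        g = f.create_group("indexes")
        bin1_offset = np.searchsorted(iu, np.arange(n + 1))
        g.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))
        g.create_dataset("chrom_offset", data=np.array([0, n], dtype=np.int64))


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------


def _bin_bedgraph(path: str, chrom: str, resolution: int, n_bins: int) -> np.ndarray:
    """Bin one bedGraph file to per-bin means, weighting by overlap length.

    A bin's value is the interval-value integral over the bin divided by the
    bin width, so uncovered stretches contribute 0 and total signal mass is
    conserved for fully covered chromosomes.
    """
    chrom_end = n_bins * resolution
    acc = np.zeros(n_bins, dtype=np.float64)
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            c, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if c != chrom:
                continue
            if end <= start:
                raise ValueError(f"empty or inverted bedGraph interval {start}-{end}")
            if end > chrom_end:
                warnings.warn(
                    f"bedGraph interval [{start}, {end}) extends beyond chromosome end "
                    f"{chrom_end}; clipping",
                    stacklevel=3,
                )
                end = chrom_end
                if end <= start:
                    continue
            intervals.append((start, end))
            first = start // resolution
            last = (end - 1) // resolution
            for b in range(first, last + 1):
                lo = max(start, b * resolution)
                hi = min(end, (b + 1) * resolution)
                acc[b] += value * (hi - lo)
    intervals.sort()
    for (s0, e0), (s1, _e1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping bedGraph intervals near {s1} in {path}")
    return acc / resolution


def load_tracks(
    paths: Sequence[str],
    chrom: str,
    resolution: int,
    n_bins: int,
) -> TrackSet:
    """Load the 5 guide channels from bedGraph files in fixed channel order.

    ``paths`` must list one file per channel in the order
    ``(scRNA+, scRNA-, CTCF+, CTCF-, CpG)``.
    """
    if len(paths) != len(TRACK_CHANNELS):
        raise ValueError(f"expected {len(TRACK_CHANNELS)} track files, got {len(paths)}")
    channels = np.stack([_bin_bedgraph(p, chrom, resolution, n_bins) for p in paths])
    return TrackSet(chrom=chrom, resolution=resolution, channels=channels)


def write_tracks(tracks: TrackSet, paths: Sequence[str]) -> None:
    """Write each channel as a bedGraph file (one interval per nonzero bin)."""
    if len(paths) != len(TRACK_CHANNELS):
        raise ValueError(f"expected {len(TRACK_CHANNELS)} output paths")
    res = tracks.resolution
    for channel, path in zip(tracks.channels, paths):
        with open(path, "w") as fh:
            for b, v in enumerate(channel):
                if v != 0:
                    fh.write(f"{tracks.chrom}\t{b * res}\t{(b + 1) * res}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# boundary sets
# ---------------------------------------------------------------------------


def write_boundaries(bset: BoundarySet, path: str, resolution: int) -> None:
    """Write a boundary set as BED3, one bin-sized interval per boundary."""
    with open(path, "w") as fh:
        for b in bset.boundaries:
            fh.write(f"{bset.chrom}\t{b * resolution}\t{(b + 1) * resolution}\n")


def read_boundaries(path: str, resolution: int) -> BoundarySet:
    chrom = None
    bins: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            c, start, _end = line.split()[:3]
            chrom = c
            bins.append(int(start) // resolution)
    return BoundarySet(chrom=chrom or "", boundaries=np.array(sorted(set(bins)), dtype=np.int64))
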