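"""Normalization, denoising, pseudo-bulking and tiling of Hi-C maps and tracks.

The per-modality stack, applied in this fixed order:

* pseudo-bulk scRNA-seq and scHi-C: pseudo-bulk aggregation -> library-size
  normalization -> (scHi-C only) eigenvalue soft-threshold denoising ->
  min-max scaling to [0, 1];
* bulk Hi-C: library-size normalization -> min-max (never denoised — bulk
  coverage is deep enough that the high-frequency eigencomponents carry
  signal, not noise);
* CTCF / CpG motif-score tracks: min-max only.

Library-size normalization rescales a count table to the likelihood of
observing a read at each locus, multiplies by a library-size constant
``alpha`` and log-transforms, so pseudo-bulks built from different numbers of
cells end up with comparable read-distribution profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ContactMap, NormState, TrackSet


@dataclass
class LibNormParams:
    """Library-size normalization constants.

    ``alpha`` is the target library size (default 25 000); ``pseudocount`` is
    added inside the natural log so empty bins stay finite. The default of 1
    follows the counts-per-alpha-then-log1p convention of scRNA-seq
    normalization: empty bins map to exactly 0 rather than a large negative
    constant, so the log-normalized matrix is not dominated by its zero
    pattern and the downstream eigenvalue soft-threshold acts on genuine
    noise components.
    """

    alpha: float = 25_000.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.pseudocount <= 0:
            raise ValueError("alpha and pseudocount must be positive")


@dataclass
class DenoiseParams:
    """Eigenvalue soft-threshold (default t = 0.5)."""

    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class TileSpec:
    """Diagonal tiling geometry: 128-bin windows (6.4 Mbp at 50 kb).

    Training tiles use stride 32; prediction tiles use stride 16 and are
    averaged back over their overlaps.
    """

    window_bins: int = 128
    stride_bins: int = 16
    start_bin: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.stride_bins <= self.window_bins):
            raise ValueError("require 0 < stride_bins <= window_bins")

    def starts(self, n_bins: int) -> list[int]:
        """Window start bins; windows that would overrun the end are dropped."""
        return [
            s
            for s in range(self.start_bin, n_bins + 1, self.stride_bins)
            if s + self.window_bins <= n_bins
        ]


# ---------------------------------------------------------------------------
# pseudo-bulking
# ---------------------------------------------------------------------------


def pseudobulk_expression(
    cell_by_gene: pd.DataFrame,
    gene_annotations: pd.DataFrame,
    chrom: str,
    resolution: int,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Reverse-map a cell-by-gene UMI table onto strand-separated bin tracks.

    Per gene, UMI counts are summed over all cells of the pseudo-bulk and the
    total is contributed to every bin the gene body overlaps, on the gene's
    strand; each bin then averages the per-gene contributions it received.

    Parameters
    ----------
    cell_by_gene
        Cells x genes UMI count table (columns are gene ids).
    gene_annotations
        One row per gene, indexed by gene id, with columns
        ``chrom, start, end, strand``.

    Returns
    -------
    (plus, minus)
        Per-bin expression vectors of length ``n_bins`` for each strand.
    """
    if cell_by_gene.shape[0] == 0:
        raise ValueError("empty pseudo-bulk: no cells")
    totals = cell_by_gene.sum(axis=0)
    sums = {"+": np.zeros(n_bins), "-": np.zeros(n_bins)}
    counts = {"+": np.zeros(n_bins), "-": np.zeros(n_bins)}
    for gene in cell_by_gene.columns:
        if gene not in gene_annotations.index:
            warnings.warn(f"gene {gene!r} missing from annotations; skipped", stacklevel=2)
            continue
        ann = gene_annotations.loc[gene]
        if ann["chrom"] != chrom:
            continue
        strand = ann["strand"]
        if strand not in sums:
            warnings.warn(f"gene {gene!r} has unknown strand {strand!r}; skipped", stacklevel=2)
            continue
        first = int(ann["start"]) // resolution
        last = (int(ann["end"]) - 1) // resolution
        total = float(totals[gene])
        for b in range(max(first, 0), min(last, n_bins - 1) + 1):
            sums[strand][b] += total
            counts[strand][b] += 1
    out = []
    for strand in ("+", "-"):
        with np.errstate(invalid="ignore"):
            track = np.where(counts[strand] > 0, sums[strand] / np.maximum(counts[strand], 1), 0.0)
        out.append(track)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# normalization stack
# ---------------------------------------------------------------------------


def library_size_normalize(
    T: np.ndarray, params: LibNormParams | None = None
) -> np.ndarray:
    """log((T / sum(T)) * alpha + pseudocount), elementwise natural log.

    Inputs that are positive scalar multiples of each other map to identical
    outputs (up to the pseudocount), which is the point: pseudo-bulks with
    different cell counts get comparable profiles.
    """
    params = params or LibNormParams()
    T = np.asarray(T, dtype=np.float64)
    total = T.sum()
    if total <= 0:
        raise ValueError("empty library: input sums to zero")
    out = np.log((T / total) * params.alpha + params.pseudocount)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("library normalization produced non-finite values")
    return out


def library_size_normalize_map(
    cmap: ContactMap, params: LibNormParams | None = None
) -> ContactMap:
    out = library_size_normalize(cmap.matrix, params)
    return ContactMap(cmap.chrom, cmap.resolution, 0.5 * (out + out.T), NormState.LIBNORM)


def soft_threshold(eigenvalues: np.ndarray, t: float) -> np.ndarray:
    """sign(lam) * max(|lam| - t, 0) elementwise."""
    lam = np.asarray(eigenvalues, dtype=np.float64)
    return np.sign(lam) * np.maximum(np.abs(lam) - t, 0.0)


def eigen_denoise(cmap: ContactMap, params: DenoiseParams | None = None) -> ContactMap:
    """Suppress the small-magnitude eigencomponents of a symmetric map.

    The matrix is eigendecomposed, eigenvalues are soft-thresholded
    (``sign(lam) * max(|lam| - t, 0)``) and the matrix reconstructed as
    ``P diag(lam') P^T``. Small eigenvalues carry the high-frequency
    experimental noise of sparse scHi-C, so shrinking them denoises the map;
    the Frobenius norm never increases. Applied per chromosome on the full
    intra-chromosomal matrix, before tiling.
    """
    params = params or DenoiseParams()
    m = cmap.matrix
    if np.max(np.abs(m - m.T), initial=0.0) > 1e-8:
        raise ValueError("eigen_denoise requires a symmetric matrix")
    eigvals, eigvecs = np.linalg.eigh(0.5 * (m + m.T))
    shrunk = soft_threshold(eigvals, params.threshold)
    rec = (eigvecs * shrunk) @ eigvecs.T
    rec = 0.5 * (rec + rec.T)
    return ContactMap(cmap.chrom, cmap.resolution, rec, NormState.DENOISED)


def minmax_normalize(array: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant array maps to all zeros."""
    a = np.asarray(array, dtype=np.float64)
    if a.size == 0:
        raise ValueError("cannot min-max normalize an empty array")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def minmax_normalize_map(cmap: ContactMap) -> ContactMap:
    return ContactMap(cmap.chrom, cmap.resolution, minmax_normalize(cmap.matrix), NormState.MINMAX)


def preprocess_schic(
    cmap: ContactMap,
    libnorm: LibNormParams | None = None,
    denoise: DenoiseParams | None = None,
) -> ContactMap:
    """Full target-map stack: library normalization -> denoise -> min-max."""
    out = library_size_normalize_map(cmap, libnorm)
    out = eigen_denoise(out, denoise)
    return minmax_normalize_map(out)


def preprocess_bulk(cmap: ContactMap, libnorm: LibNormParams | None = None) -> ContactMap:
    """Bulk stack: library normalization -> min-max (no denoising)."""
    return minmax_normalize_map(library_size_normalize_map(cmap, libnorm))


def preprocess_tracks(tracks: TrackSet, libnorm: LibNormParams | None = None) -> TrackSet:
    """Per-channel stack: scRNA channels get library normalization + min-max;
    CTCF/CpG motif scores get min-max only."""
    channels = []
    for idx, channel in enumerate(tracks.channels):
        if idx < 2 and channel.sum() > 0:  # scRNA+ / scRNA-
            channel = library_size_normalize(channel, libnorm)
        channels.append(minmax_normalize(channel))
    return TrackSet(tracks.chrom, tracks.resolution, np.stack(channels), NormState.MINMAX)


# ---------------------------------------------------------------------------
# tiling and chromosome split
# ---------------------------------------------------------------------------


def tile_region(
    cmap: ContactMap,
    tracks: TrackSet,
    spec: TileSpec,
    target: ContactMap | None = None,
):
    """Yield ``(start_bin, window x window submatrix, window x 5 features[, target])``.

    Windows are diagonal-aligned squares; windows that would overrun the
    chromosome end are dropped (with a warning if none fit at all).
    """
    if cmap.n_bins != tracks.n_bins:
        raise ValueError("contact map and tracks are not aligned")
    if target is not None and target.n_bins != cmap.n_bins:
        raise ValueError("target map is not aligned with inputs")
    n = cmap.n_bins
    w = spec.window_bins
    starts = spec.starts(n)
    if not starts:
        warnings.warn(f"chromosome of {n} bins is shorter than one {w}-bin window", stacklevel=2)
    feats = tracks.feature_matrix()
    for s in starts:
        tile = cmap.matrix[s : s + w, s : s + w]
        block = feats[s : s + w]
        if target is None:
            yield s, tile, block
        else:
            yield s, tile, block, target.matrix[s : s + w, s : s + w]


_EXCLUDED_SUFFIXES = ("X", "Y", "MT", "M")
_DEFAULT_TEST = ("chr7", "chr11", "7", "11")


def split_chromosomes(
    all_chroms: list[str],
    test_chroms: set[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Partition chromosomes into train / test sets.

    By default the gene-dense mouse chromosomes 7 and 11 form the test set;
    sex and mitochondrial chromosomes (X, Y, MT) land in neither split.
    ``test_chroms`` overrides the test set for non-standard labels.
    """
    if test_chroms is None:
        test_set = {c for c in all_chroms if c in _DEFAULT_TEST}
    else:
        test_set = {c for c in all_chroms if c in test_chroms}
    train, test = [], []
    for c in all_chroms:
        stripped = c[3:] if c.lower().startswith("chr") else c
        if stripped.upper() in _EXCLUDED_SUFFIXES:
            continue
        if c in test_set:
            test.append(c)
        else:
            train.append(c)
    return train, test
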