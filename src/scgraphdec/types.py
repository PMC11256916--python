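"""Core in-memory containers for binned Hi-C contact maps and 1-D genomic tracks.

All genomic coordinates are 0-based half-open; bin ``i`` covers
``[i * resolution, (i + 1) * resolution)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

DEFAULT_RESOLUTION = 50_000

#: Fixed channel order for guide tracks.
TRACK_CHANNELS = ("scRNA+", "scRNA-", "CTCF+", "CTCF-", "CpG")


class NormState(str, Enum):
    """Normalization state of a map or track set."""

    RAW = "raw"
    LIBNORM = "libnorm"
    DENOISED = "denoised"
    MINMAX = "minmax"


@dataclass
class ContactMap:
    """A symmetric, non-negative binned intra-chromosomal contact matrix.

    Parameters
    ----------
    chrom
        Chromosome label.
    resolution
        Bin width in base pairs.
    matrix
        Dense ``(n_bins, n_bins)`` symmetric matrix.
    norm_state
        Where the matrix sits in the normalization stack.
    """

    chrom: str
    resolution: int
    matrix: np.ndarray
    norm_state: NormState = NormState.RAW

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.validate()

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("shape error: contact matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("invalid contact value: non-finite entry")
        if np.max(np.abs(m - m.T), initial=0.0) > atol:
            raise ValueError("contact matrix is not symmetric")
        if self.norm_state is NormState.RAW and np.min(m, initial=0.0) < 0:
            raise ValueError("invalid contact value: negative count")
        if self.norm_state is NormState.MINMAX and (m.size and (m.min() < -1e-9 or m.max() > 1 + 1e-9)):
            raise ValueError("minmax-normalized map must lie in [0, 1]")

    def copy(self) -> "ContactMap":
        return ContactMap(self.chrom, self.resolution, self.matrix.copy(), self.norm_state)


@dataclass
class TrackSet:
    """Aligned per-bin 1-D guide signals for one chromosome.

    ``channels`` is an ``(5, n_bins)`` array in the fixed order
    (scRNA+, scRNA-, CTCF+, CTCF-, CpG); see :data:`TRACK_CHANNELS`.
    """

    chrom: str
    resolution: int
    channels: np.ndarray
    norm_state: NormState = NormState.RAW

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[0] != len(TRACK_CHANNELS):
            raise ValueError(f"track set must have exactly {len(TRACK_CHANNELS)} channels")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("non-finite track value")

    @property
    def n_bins(self) -> int:
        return self.channels.shape[1]

    def feature_matrix(self) -> np.ndarray:
        """Per-bin feature block of shape ``(n_bins, 5)``."""
        return self.channels.T.copy()

    def copy(self) -> "TrackSet":
        return TrackSet(self.chrom, self.resolution, self.channels.copy(), self.norm_state)


@dataclass
class BoundarySet:
    """Sorted TAD boundary bin indices for one chromosome."""

    chrom: str
    boundaries: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_bins: int | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=np.int64)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if b.size and (b[0] < 0 or (self.n_bins is not None and b[-1] >= self.n_bins)):
            raise ValueError("boundary index out of range")
        self.boundaries = b

    def __len__(self) -> int:
        return int(self.boundaries.size)
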