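"""Per-tile graph construction and Laplacian eigenvector positional encodings.

Each 128-bin tile of the bulk Hi-C map is treated as a weighted graph whose
nodes are genomic bins and whose edge weights are the bulk contact values
(self-loops, i.e. the matrix diagonal, are excluded — they carry no
structural information). Spectral positional encodings are the eigenvectors
of the symmetric normalized Laplacian ``L = I - D^{-1/2} H D^{-1/2}``
belonging to the smallest eigenvalues: the low-frequency harmonics of the
contact graph, which vary smoothly within compartments and TADs and so give
each node coordinates that encode its place in the hierarchical topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PositionalEncoding:
    """``vectors[:, c]`` is the eigenvector of the c-th smallest (or largest,
    if ``largest=True`` was requested) Laplacian eigenvalue, sign-fixed."""

    k: int
    vectors: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class RegionGraph:
    """One tile as a weighted graph plus per-node features.

    ``edge_weights`` is the tile's bulk Hi-C submatrix with the diagonal
    zeroed; ``node_features`` stacks the 5 track channels with the k
    positional-encoding components, one row per bin.
    """

    n_nodes: int
    edge_weights: np.ndarray
    node_features: np.ndarray

    def edge_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Directed edge list (src, dst, weight) over strictly off-diagonal
        nonzero entries; both directions of each undirected edge appear."""
        src, dst = np.nonzero(self.edge_weights)
        keep = src != dst
        src, dst = src[keep], dst[keep]
        return src, dst, self.edge_weights[src, dst]


def strip_diagonal(H: np.ndarray) -> np.ndarray:
    out = np.array(H, dtype=np.float64, copy=True)
    np.fill_diagonal(out, 0.0)
    return out


def normalized_laplacian(H: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian ``I - D^{-1/2} H D^{-1/2}``.

    ``D`` is the diagonal weighted-degree matrix (self-loops excluded).
    Zero-degree nodes get ``D^{-1/2} = 0``, so their Laplacian row reduces to
    the identity row.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("contact matrix must be square")
    if np.max(np.abs(H - H.T), initial=0.0) > 1e-8:
        raise ValueError("contact matrix must be symmetric")
    if H.size and H.min() < 0:
        raise ValueError("contact matrix must be non-negative")
    A = strip_diagonal(H)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = -dinv[:, None] * A * dinv[None, :]
    np.fill_diagonal(L, 1.0)
    return 0.5 * (L + L.T)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (ties -> lowest index)."""
    out = vectors.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        idx = int(np.argmax(np.abs(col)))  # argmax takes the lowest index on ties
        if col[idx] < 0:
            out[:, c] = -col
    return out


def positional_encodings(H: np.ndarray, k: int = 16, largest: bool = False) -> PositionalEncoding:
    """k Laplacian eigenvectors as per-node spectral coordinates.

    By default the eigenvectors of the k smallest eigenvalues are returned
    (low-frequency structure: compartments and TADs); ``largest=True``
    selects the other end of the spectrum. Columns are ordered by ascending
    eigenvalue and sign-fixed for reproducibility. Eigenvalues of the
    normalized Laplacian lie in [0, 2].
    """
    n = H.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nodes {n}")
    L = normalized_laplacian(H)
    eigvals, eigvecs = np.linalg.eigh(L)
    if largest:
        sel = np.arange(n - k, n)
    else:
        sel = np.arange(k)
    vecs = _fix_signs(eigvecs[:, sel])
    return PositionalEncoding(k=k, vectors=vecs, eigenvalues=eigvals[sel])


def build_region_graph(
    bulk_tile: np.ndarray,
    feature_block: np.ndarray,
    k: int = 16,
    largest: bool = False,
) -> RegionGraph:
    """Assemble a tile graph: features ``[tracks | positional encodings]``.

    An all-zero tile yields an edgeless graph whose encodings fall back to
    the zero-degree convention (Laplacian = identity); downstream layers must
    tolerate edgeless graphs.
    """
    bulk_tile = np.asarray(bulk_tile, dtype=np.float64)
    feature_block = np.asarray(feature_block, dtype=np.float64)
    if not (np.all(np.isfinite(bulk_tile)) and np.all(np.isfinite(feature_block))):
        raise ValueError("NaN or infinite value in graph inputs")
    if bulk_tile.shape[0] != feature_block.shape[0]:
        raise ValueError("tile and feature block are not aligned")
    pe = positional_encodings(bulk_tile, k=k, largest=largest)
    features = np.concatenate([feature_block, pe.vectors], axis=1)
    return RegionGraph(
        n_nodes=bulk_tile.shape[0],
        edge_weights=strip_diagonal(bulk_tile),
        node_features=features,
    )
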