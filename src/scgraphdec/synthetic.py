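"""Synthetic co-assay data generator.

Emulates the statistical structure the deconvolution method assumes, with no
external downloads:

* per-cell-type ground-truth contact probability maps with power-law distance
  decay and TAD block enrichment — a shared backbone of TADs present in every
  cell type plus cell-type-specific TADs;
* a bulk Hi-C map sampled as a read-depth-limited mixture of the cell types
  (bulk = population average, the premise the deconvolution exploits);
* sparse read-sampled scHi-C targets per cell type;
* guide tracks: scRNA-seq expression elevated inside each cell type's active
  (cell-type-specific) TADs, CTCF motif peaks at the shared backbone's TAD
  boundaries, and a CpG track correlated with CTCF.

Reads are drawn multinomially from the full-matrix probability mass and the
count matrix symmetrized as ``(U + U^T) / 2``, so the expected count at
``(i, j)`` is exactly ``depth * p(i, j)`` and the total mass is exactly the
read depth (unordered read pairs are split across the two mirror cells, so
off-diagonal entries can be half-integers).

Per-artifact random streams derive from the master seed as
``np.random.default_rng([seed, counter])`` with a fixed counter per artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import data_io
from .types import ContactMap, NormState, TrackSet

# stream counters for the per-artifact RNG scheme
_STREAM_LAYOUT = 0
_STREAM_BULK = 1
_STREAM_SC_BASE = 10  # + cell type index
_STREAM_TRACKS_BASE = 100  # + cell type index


@dataclass(frozen=True)
class TAD:
    """A contact-enriched block ``[start_bin, end_bin)`` with a multiplicative
    intensity over the background decay."""

    start: int
    end: int
    intensity: float

    def overlaps(self, other: "TAD") -> bool:
        return self.start < other.end and other.start < self.end

    def nests_with(self, other: "TAD") -> bool:
        return (self.start >= other.start and self.end <= other.end) or (
            other.start >= self.start and other.end <= self.end
        )


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic chromosome.

    Defaults are the desk-scale conditions: 256 bins, two cell types mixed
    0.6 / 0.4, three shared TADs plus two cell-type-specific TADs each,
    distance-decay exponent 1, bulk depth 5e5 reads, single-cell depth 5e4.
    When ``shared_tads`` / ``specific_tads`` are None a layout is drawn from
    the seed.
    """

    chrom: str = "s1"
    n_bins: int = 256
    n_cell_types: int = 2
    mixture_weights: tuple[float, ...] = (0.6, 0.4)
    shared_tads: tuple[TAD, ...] | None = None
    specific_tads: tuple[tuple[TAD, ...], ...] | None = None
    n_shared_tads: int = 3
    n_specific_tads: int = 2
    decay_exponent: float = 1.0
    read_depth_bulk: float = 5e5
    read_depth_sc: float = 5e4
    expr_coupling: float = 0.9
    expr_scale: float = 10.0
    noise_sd: float = 0.05
    resolution: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=np.float64)
        if len(w) != self.n_cell_types:
            raise ValueError("mixture_weights length must equal n_cell_types")
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("mixture_weights must lie on the simplex")
        if self.read_depth_bulk < 0 or self.read_depth_sc < 0:
            raise ValueError("read depths must be non-negative")
        if not (0.0 <= self.expr_coupling <= 1.0):
            raise ValueError("expr_coupling must be in [0, 1]")

    def rng(self, counter: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, counter])


def _check_layout(tads: list[TAD], n_bins: int) -> None:
    for t in tads:
        if not (0 <= t.start < t.end <= n_bins):
            raise ValueError(f"TAD {t} outside [0, {n_bins})")
        if t.intensity <= 0:
            raise ValueError("TAD intensity must be positive")
    for i, a in enumerate(tads):
        for b in tads[i + 1 :]:
            if a.overlaps(b) and not a.nests_with(b):
                raise ValueError(f"contradictory partially overlapping TADs {a} and {b}")


def resolve_layout(spec: SyntheticSpec) -> tuple[tuple[TAD, ...], tuple[tuple[TAD, ...], ...]]:
    """Shared and per-cell-type specific TADs, drawn from the seed if unset.

    Generated layouts partition the chromosome into contiguous TAD segments
    (as real TADs tile the genome back to back), with jittered junction
    positions and intensities in [1.8, 3.0]. Segment roles — shared backbone
    vs cell-type-specific — are shuffled so the two interleave; a
    cell-type-specific segment is plain decay background in the other cell
    types, which is exactly the differential structure the deconvolution is
    asked to recover.
    """
    if spec.shared_tads is not None and spec.specific_tads is not None:
        shared = tuple(spec.shared_tads)
        specific = tuple(tuple(s) for s in spec.specific_tads)
        if len(specific) != spec.n_cell_types:
            raise ValueError("need one specific-TAD list per cell type")
        for c in range(spec.n_cell_types):
            _check_layout(list(shared) + list(specific[c]), spec.n_bins)
        return shared, specific
    rng = spec.rng(_STREAM_LAYOUT)
    n_slots = spec.n_shared_tads + spec.n_specific_tads * spec.n_cell_types
    slot = spec.n_bins // n_slots
    if slot < 8:
        raise ValueError("n_bins too small for the requested TAD counts")
    # contiguous segmentation with jittered junctions
    cuts = [0]
    for s_idx in range(1, n_slots):
        jitter = int(rng.integers(-(slot // 4), slot // 4 + 1))
        cuts.append(s_idx * slot + jitter)
    cuts.append(spec.n_bins)
    roles: list[int] = [-1] * spec.n_shared_tads  # -1 = shared
    for c in range(spec.n_cell_types):
        roles += [c] * spec.n_specific_tads
    roles = [roles[i] for i in rng.permutation(len(roles))]
    shared_list: list[TAD] = []
    specific_lists: list[list[TAD]] = [[] for _ in range(spec.n_cell_types)]
    for (lo, hi), role in zip(zip(cuts[:-1], cuts[1:]), roles):
        tad = TAD(lo, hi, float(rng.uniform(1.8, 3.0)))
        if role < 0:
            shared_list.append(tad)
        else:
            specific_lists[role].append(tad)
    return tuple(shared_list), tuple(tuple(s) for s in specific_lists)


# ---------------------------------------------------------------------------
# ground truth and read sampling
# ---------------------------------------------------------------------------


def make_ground_truth(spec: SyntheticSpec) -> list[ContactMap]:
    """Per-cell-type contact probability maps (symmetric, sum to 1).

    ``p(i, j)`` is proportional to ``(1 + |i - j|) ** -decay_exponent``
    multiplied by the intensity of every TAD block (shared backbone plus the
    cell type's specific TADs) containing both bins.
    """
    shared, specific = resolve_layout(spec)
    n = spec.n_bins
    idx = np.arange(n)
    base = (1.0 + np.abs(idx[:, None] - idx[None, :])) ** (-spec.decay_exponent)
    maps = []
    for c in range(spec.n_cell_types):
        m = base.copy()
        for tad in list(shared) + list(specific[c]):
            m[tad.start : tad.end, tad.start : tad.end] *= tad.intensity
        m /= m.sum()
        maps.append(ContactMap(spec.chrom, spec.resolution, m, NormState.RAW))
    return maps


def _sample_counts(prob: np.ndarray, depth: float, rng: np.random.Generator) -> np.ndarray:
    """Multinomial read sampling with mirror-cell symmetrization."""
    n_reads = int(round(depth))
    if n_reads == 0:
        return np.zeros_like(prob)
    flat = prob.ravel() / prob.sum()
    counts = rng.multinomial(n_reads, flat).reshape(prob.shape).astype(np.float64)
    return 0.5 * (counts + counts.T)


def sample_bulk(
    ground_truths: list[ContactMap],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> ContactMap:
    """Bulk Hi-C as a multinomial sample of the mixture probability."""
    w = np.asarray(spec.mixture_weights, dtype=np.float64)
    mix = sum(wc * gt.matrix for wc, gt in zip(w, ground_truths))
    counts = _sample_counts(mix, spec.read_depth_bulk, rng or spec.rng(_STREAM_BULK))
    return ContactMap(spec.chrom, spec.resolution, counts, NormState.RAW)


def sample_sc_target(
    ground_truth: ContactMap,
    spec: SyntheticSpec,
    cell_type: int = 0,
    rng: np.random.Generator | None = None,
) -> ContactMap:
    """Sparse pseudo-bulk scHi-C target: a shallow multinomial sample of one
    cell type's ground truth. Downstream normalization/denoising is the
    preprocessing stack's job, not the sampler's."""
    rng = rng or spec.rng(_STREAM_SC_BASE + cell_type)
    counts = _sample_counts(ground_truth.matrix, spec.read_depth_sc, rng)
    return ContactMap(spec.chrom, spec.resolution, counts, NormState.RAW)


# ---------------------------------------------------------------------------
# guide tracks
# ---------------------------------------------------------------------------


def shared_boundary_bins(spec: SyntheticSpec) -> np.ndarray:
    """TAD boundary bins of the shared backbone (cell-type-agnostic)."""
    shared, _ = resolve_layout(spec)
    bins = sorted({b for t in shared for b in (t.start, t.end) if 0 <= b < spec.n_bins})
    return np.array(bins, dtype=np.int64)


def active_tad_indicator(spec: SyntheticSpec, cell_type: int) -> np.ndarray:
    """1 inside the cell type's active (cell-type-specific) TADs, else 0."""
    _, specific = resolve_layout(spec)
    ind = np.zeros(spec.n_bins)
    for tad in specific[cell_type]:
        ind[tad.start : tad.end] = 1.0
    return ind


def make_tracks(
    spec: SyntheticSpec,
    cell_type: int,
    rng: np.random.Generator | None = None,
) -> TrackSet:
    """Guide tracks for one cell type.

    scRNA channels mix the active-TAD indicator (weight ``expr_coupling``)
    with uniform background (weight ``1 - expr_coupling``), Poisson-sampled
    when ``noise_sd > 0``; CTCF channels peak at the shared backbone's TAD
    boundary bins; CpG follows the CTCF peak structure. With ``noise_sd = 0``
    every channel is its clean deterministic profile.
    """
    rng = rng or spec.rng(_STREAM_TRACKS_BASE + cell_type)
    n = spec.n_bins
    active = active_tad_indicator(spec, cell_type)
    clean = active * spec.expr_scale
    if spec.expr_coupling < 1.0:
        background = rng.uniform(0, spec.expr_scale, size=n)
    else:
        background = np.zeros(n)
    lam = spec.expr_coupling * clean + (1.0 - spec.expr_coupling) * background
    if spec.noise_sd > 0:
        expr = rng.poisson(lam).astype(np.float64)
    else:
        expr = lam
    plus = 0.5 * expr
    minus = expr - plus

    peaks = np.zeros(n)
    peaks[shared_boundary_bins(spec)] = 1.0

    def noisy(base: np.ndarray, sd: float) -> np.ndarray:
        if sd <= 0:
            return base.copy()
        return np.clip(base + rng.normal(0, sd, size=n), 0.0, None)

    ctcf_plus = noisy(peaks, spec.noise_sd)
    ctcf_minus = noisy(peaks, spec.noise_sd)
    cpg = noisy(peaks, 0.5 * spec.noise_sd)
    channels = np.stack([plus, minus, ctcf_plus, ctcf_minus, cpg])
    return TrackSet(spec.chrom, spec.resolution, channels, NormState.RAW)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def make_dataset(spec: SyntheticSpec, out_dir: str) -> dict:
    """Write bulk map, per-cell-type targets and track sets, plus a manifest.

    Fully reproducible from ``(spec, seed)``: the manifest records the spec
    (with the resolved TAD layout) and a content hash of the spec.
    """
    os.makedirs(out_dir, exist_ok=True)
    shared, specific = resolve_layout(spec)
    truths = make_ground_truth(spec)
    bulk = sample_bulk(truths, spec)
    bulk_path = os.path.join(out_dir, f"bulk_{spec.chrom}.txt")
    data_io.write_contact_map(bulk, bulk_path, format="sparse_text")
    entries: dict = {
        "chrom": spec.chrom,
        "n_bins": spec.n_bins,
        "resolution": spec.resolution,
        "bulk": os.path.basename(bulk_path),
        "cell_types": [],
    }
    for c in range(spec.n_cell_types):
        target = sample_sc_target(truths[c], spec, cell_type=c)
        tpath = os.path.join(out_dir, f"target_ct{c}_{spec.chrom}.txt")
        data_io.write_contact_map(target, tpath, format="sparse_text")
        tracks = make_tracks(spec, c)
        track_paths = [
            os.path.join(out_dir, f"tracks_ct{c}_{spec.chrom}_{name}.bedgraph")
            for name in ("rna_plus", "rna_minus", "ctcf_plus", "ctcf_minus", "cpg")
        ]
        data_io.write_tracks(tracks, track_paths)
        entries["cell_types"].append(
            {
                "index": c,
                "target": os.path.basename(tpath),
                "tracks": [os.path.basename(p) for p in track_paths],
            }
        )
    spec_dict = asdict(spec)
    spec_dict["shared_tads"] = [asdict(t) for t in shared]
    spec_dict["specific_tads"] = [[asdict(t) for t in s] for s in specific]
    manifest = {
        "spec": spec_dict,
        "seed": spec.seed,
        "spec_hash": hashlib.sha256(
            json.dumps(spec_dict, sort_keys=True).encode()
        ).hexdigest(),
        "files": entries,
    }
    with open(os.path.join(out_dir, f"manifest_{spec.chrom}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
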