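"""Training, genome-wide prediction with overlap averaging, and the
end-to-end experiment runner.

Training minimizes the MSE between predicted and target tiles (both in
[0, 1] after preprocessing). Training tiles are cut with stride 32;
prediction tiles with stride 16, and overlapping predictions are averaged
to assemble the final intra-chromosomal map. Chromosome tails that no full
window reaches stay unpredicted (zero) and their bin count is logged.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import metrics as metrics_mod
from .graph import RegionGraph, build_region_graph
from .model import GraphDeconvolutionModel, ModelConfig, mse_loss
from .nn import Adam
from .preprocess import (
    TileSpec,
    preprocess_bulk,
    preprocess_schic,
    preprocess_tracks,
    tile_region,
)
from .synthetic import SyntheticSpec, make_ground_truth, make_tracks, sample_bulk, sample_sc_target
from .types import ContactMap, NormState, TrackSet

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings. 300 epochs matches the full-scale regime; the
    desk-scale default is 50."""

    epochs: int = 50
    batch_size: int = 1
    learning_rate: float = 3e-3
    lr_decay: str = "cosine"  # "cosine" or "none"
    seed: int = 0
    window: int = 128
    stride_train: int = 32
    stride_predict: int = 16
    checkpoint_every: int = 0
    early_stop_patience: int = 0  # 0 disables early stopping
    clip_grad_norm: float = 1.0  # 0 disables clipping

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TileSample:
    """One training example: a bulk tile graph and its target tile."""

    start_bin: int
    bulk_tile: np.ndarray
    feature_block: np.ndarray
    target_tile: np.ndarray
    graph: RegionGraph | None = None

    def ensure_graph(self, pe_k: int) -> RegionGraph:
        if self.graph is None:
            self.graph = build_region_graph(self.bulk_tile, self.feature_block, k=pe_k)
        return self.graph


def make_tile_dataset(
    bulk: ContactMap,
    tracks: TrackSet,
    target: ContactMap,
    stride: int = 32,
    window: int = 128,
) -> list[TileSample]:
    spec = TileSpec(window_bins=window, stride_bins=stride)
    return [
        TileSample(start_bin=s, bulk_tile=tile, feature_block=block, target_tile=tgt)
        for s, tile, block, tgt in tile_region(bulk, tracks, spec, target=target)
    ]


def train(
    model: GraphDeconvolutionModel,
    dataset: list[TileSample],
    cfg: TrainConfig,
) -> list[float]:
    """Optimize the model with Adam on per-tile MSE; returns per-epoch loss.

    Seed-reproducible: the shuffle order and dropout masks derive from
    ``cfg.seed`` and the model's construction seed.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    pe_k = model.config.pe_k
    for sample in dataset:
        sample.ensure_graph(pe_k)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng([cfg.seed, 0x5F])
    history: list[float] = []
    model.train(True)
    for epoch in range(cfg.epochs):
        if cfg.lr_decay == "cosine":
            optimizer.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
        order = shuffle_rng.permutation(len(dataset))
        losses = []
        for pos in range(0, len(order), cfg.batch_size):
            batch = order[pos : pos + cfg.batch_size]
            optimizer.zero_grad()
            batch_loss = 0.0
            for idx in batch:
                sample = dataset[idx]
                pred = model.forward_graph(sample.graph)
                loss = mse_loss(pred, sample.target_tile)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, tile {sample.start_bin}"
                    )
                loss.backward(np.asarray(1.0 / len(batch)))
                batch_loss += float(loss.data)
            if cfg.clip_grad_norm > 0:
                _clip_gradients(model, cfg.clip_grad_norm)
            optimizer.step()
            losses.append(batch_loss / len(batch))
        history.append(float(np.mean(losses)))
        logger.info("epoch %d/%d mse=%.6f", epoch + 1, cfg.epochs, history[-1])
        if (
            cfg.early_stop_patience
            and len(history) > cfg.early_stop_patience
            and history[-1] >= min(history[: -cfg.early_stop_patience])
        ):
            logger.info("early stop at epoch %d", epoch + 1)
            break
    model.train(False)
    return history


def _clip_gradients(model: GraphDeconvolutionModel, max_norm: float) -> None:
    """Rescale all gradients so their global L2 norm is at most ``max_norm``.

    A single oversized step can push the decoder sigmoid into saturation,
    after which gradients vanish and training freezes; clipping bounds the
    step without biasing its direction.
    """
    params = [p for p in model.parameters() if p.grad is not None]
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad = p.grad * scale


@dataclass
class PredictionAssembly:
    """Sum / count accumulators for overlap-averaged chromosome assembly."""

    n_bins: int
    sum_matrix: np.ndarray = field(init=False)
    count_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sum_matrix = np.zeros((self.n_bins, self.n_bins))
        self.count_matrix = np.zeros((self.n_bins, self.n_bins))

    def add_tile(self, start: int, tile: np.ndarray) -> None:
        w = tile.shape[0]
        self.sum_matrix[start : start + w, start : start + w] += tile
        self.count_matrix[start : start + w, start : start + w] += 1.0

    def finalize(self) -> np.ndarray:
        covered = self.count_matrix > 0
        out = np.zeros_like(self.sum_matrix)
        out[covered] = self.sum_matrix[covered] / self.count_matrix[covered]
        return 0.5 * (out + out.T)


def predict_chromosome(
    model: GraphDeconvolutionModel,
    bulk_map: ContactMap,
    tracks: TrackSet,
    stride: int = 16,
    window: int = 128,
) -> ContactMap:
    """Tile, predict, and average overlapping predictions into one map."""
    spec = TileSpec(window_bins=window, stride_bins=stride)
    starts = spec.starts(bulk_map.n_bins)
    if not starts:
        raise ValueError(
            f"region too short: {bulk_map.n_bins} bins < one {window}-bin window"
        )
    assembly = PredictionAssembly(n_bins=bulk_map.n_bins)
    for s, tile, block in tile_region(bulk_map, tracks, spec):
        assembly.add_tile(s, model.predict(tile, block))
    final = assembly.finalize()
    uncovered = int(np.count_nonzero(assembly.count_matrix.diagonal() == 0))
    if uncovered:
        logger.info(
            "%s: %d tail bins not reachable by a full window; left at zero",
            bulk_map.chrom,
            uncovered,
        )
    return ContactMap(bulk_map.chrom, bulk_map.resolution, final, NormState.MINMAX)


# ---------------------------------------------------------------------------
# end-to-end experiment on synthetic data
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeData:
    """Preprocessed inputs for one chromosome: min-max bulk, per-cell-type
    processed tracks and target maps (plus the raw bulk for baselines)."""

    chrom: str
    bulk: ContactMap
    raw_bulk: ContactMap
    tracks: list[TrackSet]
    targets: list[ContactMap]


def synthesize_chromosome(
    base_spec: SyntheticSpec, chrom: str, chrom_index: int, master_seed: int
) -> ChromosomeData:
    """Generate and preprocess one synthetic chromosome.

    Each chromosome gets its own seed stream (and hence its own TAD layout)
    derived from the master seed and the chromosome index.
    """
    spec_kwargs = {
        k: v
        for k, v in vars(base_spec).items()
        if k not in ("chrom", "seed", "shared_tads", "specific_tads")
    }
    spec = SyntheticSpec(
        chrom=chrom, seed=int((master_seed * 1000 + chrom_index) % (2**31 - 1)), **spec_kwargs
    )
    truths = make_ground_truth(spec)
    raw_bulk = sample_bulk(truths, spec)
    bulk = preprocess_bulk(raw_bulk)
    tracks = [preprocess_tracks(make_tracks(spec, c)) for c in range(spec.n_cell_types)]
    targets = [
        preprocess_schic(sample_sc_target(truths[c], spec, cell_type=c))
        for c in range(spec.n_cell_types)
    ]
    return ChromosomeData(chrom=chrom, bulk=bulk, raw_bulk=raw_bulk, tracks=tracks, targets=targets)


def run_experiment(config: dict, out_dir: str | None = None) -> dict:
    """Synthetic end-to-end run: simulate -> preprocess -> train -> predict
    -> evaluate. Returns (and optionally writes) the metric report."""
    seed = int(config.get("seed", 0))
    syn_cfg = dict(config.get("synthetic", {}))
    train_chroms = list(syn_cfg.pop("train_chroms", ["s1", "s2", "s3"]))
    test_chroms = list(syn_cfg.pop("test_chroms", ["s4"]))
    base_spec = SyntheticSpec(seed=seed, **syn_cfg)
    model_cfg = ModelConfig(seed=seed, **config.get("model", {}))
    train_cfg = TrainConfig(seed=seed, **config.get("train", {}))

    all_chroms = train_chroms + test_chroms
    data = {
        chrom: synthesize_chromosome(base_spec, chrom, i, seed)
        for i, chrom in enumerate(all_chroms)
    }

    dataset: list[TileSample] = []
    for chrom in train_chroms:
        cd = data[chrom]
        for c in range(base_spec.n_cell_types):
            dataset.extend(
                make_tile_dataset(
                    cd.bulk,
                    cd.tracks[c],
                    cd.targets[c],
                    stride=train_cfg.stride_train,
                    window=train_cfg.window,
                )
            )
    model = GraphDeconvolutionModel(model_cfg)
    history = train(model, dataset, train_cfg)

    report: dict = {
        "seed": seed,
        "train_chroms": train_chroms,
        "test_chroms": test_chroms,
        "final_train_mse": history[-1],
        "loss_history": history,
        "per_chromosome": {},
    }
    predictions: dict[tuple[str, int], ContactMap] = {}
    for chrom in test_chroms:
        cd = data[chrom]
        chrom_report = {}
        preds = []
        for c in range(base_spec.n_cell_types):
            pred = predict_chromosome(
                model,
                cd.bulk,
                cd.tracks[c],
                stride=train_cfg.stride_predict,
                window=train_cfg.window,
            )
            predictions[(chrom, c)] = pred
            preds.append(pred)
        for c in range(base_spec.n_cell_types):
            mr = metrics_mod.evaluate_pair(preds[c], cd.targets[c])
            entry = mr.as_dict()
            # cell-type specificity: this prediction against the *other*
            # cell types' targets (it should be closer to its own)
            entry["scc_vs_other_targets"] = [
                metrics_mod.scc_score(preds[c], cd.targets[o])
                for o in range(base_spec.n_cell_types)
                if o != c
            ]
            # bulk-prior baseline: the input bulk map scored against this
            # cell type's target (deconvolution should beat the prior)
            bulk_b = metrics_mod.call_tad_boundaries(cd.bulk)
            tgt_b = metrics_mod.call_tad_boundaries(cd.targets[c])
            entry["bulk_tad_f1"] = metrics_mod.tad_f1(bulk_b, tgt_b).f1
            entry["bulk_scc"] = metrics_mod.scc_score(cd.bulk, cd.targets[c])
            chrom_report[f"cell_type_{c}"] = entry
        report["per_chromosome"][chrom] = chrom_report

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        from . import data_io

        model.save(os.path.join(out_dir, "checkpoint.npz"))
        for (chrom, c), pred in predictions.items():
            data_io.write_contact_map(
                pred, os.path.join(out_dir, f"pred_{chrom}_ct{c}.txt"), format="sparse_text"
            )
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
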