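"""The graph-deconvolution architecture.

Four components, composed per tile:

1. **Positional encoding** — spectral coordinates from the bulk Hi-C tile
   (:mod:`scgraphdec.graph`), concatenated with the 5 guide-track channels
   into the node feature set X.
2. **Node feature processor** — a single window-16 Conv1D along the bin axis
   (localized feature extraction over the guide signals), a linear lift to
   the model width, then stacked transformer encoder blocks for the global
   interactions.
3. **Graph encoder** — a graph-attention layer over the bulk Hi-C graph
   (deconvolution: attention over bulk edges, guided by cell-type-specific
   node features, prunes the edges irrelevant to the requested cell type)
   followed by stacked transformer encoder blocks (mapping into the node
   latent space Z).
4. **Graph decoder** — the inner product Z Z^T as a contact-likelihood map,
   refined by residual 2-D convolution blocks, squashed by a sigmoid and
   symmetrized.

The output is a contact map tile with values in (0, 1), matching the
min-max-normalized scHi-C target.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .graph import RegionGraph, build_region_graph

CHECKPOINT_VERSION = 1
N_TRACK_CHANNELS = 5


@dataclass
class ModelConfig:
    """Architecture hyperparameters (widths, depths, heads, dropout, seed)."""

    conv_window: int = 16
    conv_filters: int = 16
    d_model: int = 48
    n_transformer_blocks_nfp: int = 2
    n_transformer_blocks_map: int = 2
    n_attention_heads: int = 4
    n_gat_layers: int = 1
    n_residual_blocks: int = 2
    residual_hidden: int = 16
    pe_k: int = 16
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_attention_heads:
            raise ValueError("d_model must be divisible by n_attention_heads")
        for name in (
            "conv_window",
            "conv_filters",
            "d_model",
            "n_attention_heads",
            "pe_k",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_attention_heads

    @property
    def feature_width(self) -> int:
        return N_TRACK_CHANNELS + self.pe_k


class NodeFeatureProcessor(nn.Module):
    """Conv1D (window 16) -> linear lift -> stacked transformer blocks.

    Input features are standardized per tile (each column z-scored) before
    the convolution: the positional-encoding columns are orthonormal
    eigenvectors with entries of order 1/sqrt(n), an order of magnitude
    smaller than the min-max-scaled track channels, and without rescaling
    the per-node differences they carry are too faint for optimization to
    pick up (tokens collapse to a common representation).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, drop_rng: np.random.Generator):
        self.conv = nn.Conv1dSame(cfg.conv_window, cfg.feature_width, cfg.conv_filters, rng)
        self.lift = nn.Linear(cfg.conv_filters, cfg.d_model, rng)
        self.blocks = [
            nn.TransformerBlock(
                cfg.d_model, cfg.n_attention_heads, rng, dropout=cfg.dropout, dropout_rng=drop_rng
            )
            for _ in range(cfg.n_transformer_blocks_nfp)
        ]

    @staticmethod
    def standardize(x: np.ndarray) -> np.ndarray:
        return (x - x.mean(axis=0)) / (x.std(axis=0) + 1e-8)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        z = self.lift(self.conv(nn.Tensor(self.standardize(x.data))))
        for block in self.blocks:
            z = block(z)
        return z


class MappingEncoder(nn.Module):
    """Stacked transformer blocks mapping Z_GAT to the node latent space Z.

    Depth 0 is the identity map.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, drop_rng: np.random.Generator):
        self.blocks = [
            nn.TransformerBlock(
                cfg.d_model, cfg.n_attention_heads, rng, dropout=cfg.dropout, dropout_rng=drop_rng
            )
            for _ in range(cfg.n_transformer_blocks_map)
        ]

    def __call__(self, z: nn.Tensor) -> nn.Tensor:
        for block in self.blocks:
            z = block(z)
        return z


class GraphDecoder(nn.Module):
    """Inner-product likelihood map, residual conv refinement, sigmoid.

    The node latent is layer-normalized before the inner product so the
    likelihood map stays inside the sigmoid's responsive range regardless of
    how the residual stream scales Z.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.norm = nn.LayerNorm(cfg.d_model)
        self.scale = nn.Parameter(np.array(1.0 / np.sqrt(cfg.d_model)))
        self.blocks = [
            nn.ResidualBlock2d(1, cfg.residual_hidden, rng) for _ in range(cfg.n_residual_blocks)
        ]
        # identity-start refinement: each residual block initially passes the
        # inner-product likelihood map through unchanged
        for block in self.blocks:
            block.conv2.weight.data[:] = 0.0

    def inner_product(self, z: nn.Tensor) -> nn.Tensor:
        return z @ z.T

    def __call__(self, z: nn.Tensor) -> nn.Tensor:
        n = z.shape[0]
        plane = (self.inner_product(self.norm(z)) * self.scale).reshape(n, n, 1)
        for block in self.blocks:
            plane = block(plane)
        pred = plane.reshape(n, n).sigmoid()
        return (pred + pred.T) * 0.5


class GraphDeconvolutionModel(nn.Module):
    """End-to-end model: bulk Hi-C tile + guide tracks -> scHi-C tile."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.dropout_rng = np.random.default_rng([config.seed, 0xD0])
        self.nfp = NodeFeatureProcessor(config, rng, self.dropout_rng)
        self.gat_layers = [
            nn.GATLayer(config.d_model, config.d_model, rng) for _ in range(config.n_gat_layers)
        ]
        self.mapper = MappingEncoder(config, rng, self.dropout_rng)
        self.decoder = GraphDecoder(config, rng)

    # -- stages ------------------------------------------------------------

    def node_feature_processor(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        x = nn.as_tensor(x)
        if not np.all(np.isfinite(x.data)):
            raise ValueError("NaN or infinite value in node features")
        return self.nfp(x)

    def gat_stage(self, graph: RegionGraph, z: nn.Tensor) -> nn.Tensor:
        src, dst, w = graph.edge_index()
        for layer in self.gat_layers:
            z = layer(z, src, dst, w)
        return z

    def mapping_encoder(self, z: nn.Tensor) -> nn.Tensor:
        if not np.all(np.isfinite(z.data)):
            raise ValueError("NaN or infinite value entering mapping encoder")
        return self.mapper(z)

    def graph_decoder(self, z: nn.Tensor) -> nn.Tensor:
        return self.decoder(z)

    # -- full forward ------------------------------------------------------

    def forward_graph(self, graph: RegionGraph) -> nn.Tensor:
        z = self.node_feature_processor(graph.node_features)
        z = self.gat_stage(graph, z)
        z = self.mapping_encoder(z)
        return self.graph_decoder(z)

    def forward(self, bulk_tile: np.ndarray, feature_block: np.ndarray) -> nn.Tensor:
        if bulk_tile.shape[0] != feature_block.shape[0]:
            raise ValueError("shape mismatch between bulk tile and feature block")
        if feature_block.shape[1] != N_TRACK_CHANNELS:
            raise ValueError(f"feature block must have {N_TRACK_CHANNELS} channels")
        graph = build_region_graph(bulk_tile, feature_block, k=self.config.pe_k)
        return self.forward_graph(graph)

    def predict(self, bulk_tile: np.ndarray, feature_block: np.ndarray) -> np.ndarray:
        """Deterministic inference forward pass (dropout inactive)."""
        was_training = self.training
        self.eval()
        out = self.forward(bulk_tile, feature_block).data
        self.train(was_training)
        return out

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(
            path,
            __meta__=np.frombuffer(
                json.dumps(
                    {"version": CHECKPOINT_VERSION, "config": asdict(self.config)}
                ).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "GraphDeconvolutionModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint format version {meta.get('version')} not supported"
                )
            config = ModelConfig(**meta["config"])
            model = cls(config)
            n = len(model.parameters())
            model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
        return model


def mse_loss(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    diff = pred - nn.Tensor(np.asarray(target, dtype=np.float64))
    return (diff**2).mean()
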