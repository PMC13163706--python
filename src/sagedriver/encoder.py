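"""Bipartite GraphSAGE encoder over the gene-sample graph.

Gene and sample nodes live on the two sides of a bipartite graph whose
edges come from the driver gene-sample association matrix (or, optionally,
the full mutation matrix). Each layer updates both node types
simultaneously:

    Hg' = ReLU(Hg W_self + Ags Hs W_neigh)
    Hs' = ReLU(Hs W_self + Asg Hg W_neigh)

where Ags / Asg are the row-normalized adjacency in the gene-to-sample and
sample-to-gene directions. Optional fixed-size neighbor sampling sparsifies
the adjacency before normalization, as in inductive GraphSAGE training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CohortDataset

__all__ = [
    "SageLayerParams",
    "EncoderParams",
    "NodeEmbeddings",
    "row_normalize",
    "sample_neighbors",
    "sage_layer",
    "init_encoder_params",
    "encode",
]


@dataclass
class SageLayerParams:
    """One GraphSAGE layer: self-feature and neighbor-feature weights."""

    W_self: np.ndarray
    W_neigh: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.W_self).all() and np.isfinite(self.W_neigh).all()):
            raise ValueError("layer weights must be finite")
        if self.W_self.shape[1] != self.W_neigh.shape[1]:
            raise ValueError("W_self and W_neigh must share their output dimension")


@dataclass
class EncoderParams:
    """Per-layer parameters for gene-side and sample-side updates."""

    gene_layers: list[SageLayerParams]
    sample_layers: list[SageLayerParams]

    @property
    def n_layers(self) -> int:
        return len(self.gene_layers)


@dataclass
class NodeEmbeddings:
    """Final gene (G x d) and sample (N x d) embeddings; nonnegative (ReLU)."""

    Hg: np.ndarray
    Hs: np.ndarray


def row_normalize(A: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; rows summing to zero stay zero.

    This is the D^-1 A normalization of the bipartite adjacency; zero rows
    correspond to isolated nodes, which then propagate self-features only.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("row_normalize requires nonnegative entries")
    sums = A.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = A / sums
    out[np.broadcast_to(sums == 0, out.shape)] = 0.0
    return out


def sample_neighbors(
    A: np.ndarray, size: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Keep at most ``size`` nonzeros per row, uniformly without replacement.

    Rows with at most ``size`` nonzeros are unchanged. The output is meant
    to be re-row-normalized before use.
    """
    A = np.asarray(A)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("sample_neighbors expects a binary adjacency")
    if size < 1:
        raise ValueError("sampling size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros_like(A)
    for i in range(A.shape[0]):
        nz = np.flatnonzero(A[i])
        if len(nz) > size:
            nz = rng.choice(nz, size=size, replace=False)
        out[i, nz] = 1
    return out


def sage_layer(
    H_self: np.ndarray,
    H_other: np.ndarray,
    A_norm: np.ndarray,
    params: SageLayerParams,
) -> np.ndarray:
    """One GraphSAGE update: ReLU(H_self W_self + A_norm H_other W_neigh)."""
    z = H_self @ params.W_self + A_norm @ (H_other @ params.W_neigh)
    return np.maximum(z, 0.0)


def glorot_uniform(
    fan_in: int, fan_out: int, rng: np.random.Generator
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder_params(
    n_genes: int,
    n_samples: int,
    hidden_dim: int = 64,
    n_layers: int = 2,
    rng: np.random.Generator | int = 0,
) -> EncoderParams:
    """Glorot-style initialization for a 1- or 2-layer bipartite encoder.

    Layer-1 input widths follow the feature definitions: gene features are
    N-dimensional (mutation profile across samples), sample features are
    G-dimensional (expression profile across genes).
    """
    if n_layers not in (1, 2):
        raise ValueError("n_layers must be 1 or 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d = hidden_dim
    gene_layers = [
        SageLayerParams(
            W_self=glorot_uniform(n_samples, d, rng),
            W_neigh=glorot_uniform(n_genes, d, rng),
        )
    ]
    sample_layers = [
        SageLayerParams(
            W_self=glorot_uniform(n_genes, d, rng),
            W_neigh=glorot_uniform(n_samples, d, rng),
        )
    ]
    for _ in range(n_layers - 1):
        gene_layers.append(
            SageLayerParams(
                W_self=glorot_uniform(d, d, rng), W_neigh=glorot_uniform(d, d, rng)
            )
        )
        sample_layers.append(
            SageLayerParams(
                W_self=glorot_uniform(d, d, rng), W_neigh=glorot_uniform(d, d, rng)
            )
        )
    return EncoderParams(gene_layers=gene_layers, sample_layers=sample_layers)


def bipartite_adjacency(
    dataset: CohortDataset,
    adjacency_source: str = "association",
    train_mask_cols: np.ndarray | None = None,
) -> np.ndarray:
    """The binary G x N adjacency the encoder aggregates over.

    ``association`` uses the driver gene-sample association matrix A;
    ``mutation`` uses the full mutation matrix Xg. When
    ``train_mask_cols`` (boolean over samples) is given, columns outside it
    are zeroed so held-out samples never contribute label-derived edges.
    """
    if adjacency_source == "association":
        B = (dataset.A != 0).astype(float)
    elif adjacency_source == "mutation":
        B = (dataset.Xg != 0).astype(float)
    else:
        raise ValueError(f"unknown adjacency_source {adjacency_source!r}")
    if train_mask_cols is not None:
        B = B * np.asarray(train_mask_cols, dtype=float)[None, :]
    return B


def encode(
    dataset: CohortDataset,
    params: EncoderParams,
    sampling_size: int | None = None,
    seed: int = 0,
    adjacency_source: str = "association",
    train_mask_cols: np.ndarray | None = None,
) -> NodeEmbeddings:
    """Run the full (1- or 2-layer) bipartite encoder on a cohort.

    Neighbor sampling, when requested, sparsifies each direction's
    adjacency to at most ``sampling_size`` neighbors per node before row
    normalization; ``sampling_size=None`` is the dense reference path.
    """
    B = bipartite_adjacency(dataset, adjacency_source, train_mask_cols)
    Ags, Asg = normalized_adjacencies(B, sampling_size, seed)
    Hg, Hs = dataset.Xg, dataset.Xs
    for lg, ls in zip(params.gene_layers, params.sample_layers):
        Hg, Hs = (
            sage_layer(Hg, Hs, Ags, lg),
            sage_layer(Hs, Hg, Asg, ls),
        )
    return NodeEmbeddings(Hg=Hg, Hs=Hs)


def normalized_adjacencies(
    B: np.ndarray, sampling_size: int | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized gene->sample and sample->gene adjacencies from B."""
    Bg = B
    Bs = B.T
    if sampling_size is not None:
        rng = np.random.default_rng(seed)
        Bg = sample_neighbors(Bg, sampling_size, rng)
        Bs = sample_neighbors(Bs, sampling_size, rng)
    return row_normalize(Bg), row_normalize(Bs)
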