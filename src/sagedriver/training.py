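"""End-to-end training of encoder + attention + decoder.

The model is small and dense (cohorts of a few hundred genes and samples),
so it is implemented directly in NumPy: the forward pass mirrors the
functional modules (:mod:`encoder`, :mod:`attention`, :mod:`decoder`) and
the backward pass is hand-derived reverse-mode differentiation through the
same graph — ReLU GraphSAGE layers, scaled dot-product softmax attention,
linear projections, row-wise cosine, and the weighted BCE. Gradients are
checked against central finite differences in the test suite. Optimization
uses Adam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .attention import BWFAParams, init_bwfa_params
from .decoder import EPS, ScoreMatrix, default_beta
from .encoder import (
    EncoderParams,
    bipartite_adjacency,
    init_encoder_params,
    normalized_adjacencies,
    glorot_uniform,
)
from .preprocess import CohortDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ModelParams",
    "TrainingDiverged",
    "init_model_params",
    "forward",
    "forward_backward",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Architecture switches and widths.

    ``n_layers`` is the number of GraphSAGE layers (1 or 2);
    ``use_attention`` toggles the bidirectional cross-attention block
    (when off, encoder embeddings feed the decoder projections directly);
    ``hidden_dim`` is the embedding width d, ``attention_dim`` the attention
    inner width dk, ``projection_dim`` the decoding width k.
    """

    hidden_dim: int = 64
    attention_dim: int = 64
    projection_dim: int = 32
    n_layers: int = 2
    use_attention: bool = True
    share_qkv: bool = False
    adjacency_source: str = "association"
    sampling_size: Optional[int] = None


@dataclass
class TrainConfig:
    """Optimization settings; ``mask`` restricts the loss to training
    gene-sample pairs (all gene rows x training-fold sample columns)."""

    beta: Optional[float] = None
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ModelParams:
    """All learnable weights of the encoder, attention block and decoder."""

    encoder: EncoderParams
    bwfa: Optional[BWFAParams]
    W0: np.ndarray
    W1: np.ndarray

    def named_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every distinct parameter tensor."""
        out: dict[str, np.ndarray] = {}
        for i, (lg, ls) in enumerate(
            zip(self.encoder.gene_layers, self.encoder.sample_layers), start=1
        ):
            out[f"enc{i}.g.W_self"] = lg.W_self
            out[f"enc{i}.g.W_neigh"] = lg.W_neigh
            out[f"enc{i}.s.W_self"] = ls.W_self
            out[f"enc{i}.s.W_neigh"] = ls.W_neigh
        if self.bwfa is not None:
            g, s = self.bwfa.gene_dir, self.bwfa.sample_dir
            out["att.g.WQ"], out["att.g.WK"], out["att.g.WV"] = g.WQ, g.WK, g.WV
            out["att.g.Wp"], out["att.g.bp"] = g.Wp, g.bp
            if self.bwfa.share_qkv:
                out["att.s.Wp"], out["att.s.bp"] = s.Wp, s.bp
            else:
                out["att.s.WQ"], out["att.s.WK"], out["att.s.WV"] = s.WQ, s.WK, s.WV
                out["att.s.Wp"], out["att.s.bp"] = s.Wp, s.bp
        out["dec.W0"] = self.W0
        out["dec.W1"] = self.W1
        return out

    def save(self, path) -> None:
        arrays = self.named_arrays()
        meta = {
            "n_layers": self.encoder.n_layers,
            "use_attention": self.bwfa is not None,
            "share_qkv": bool(self.bwfa.share_qkv) if self.bwfa else False,
        }
        np.savez(path, __meta__=np.array(list(meta.items()), dtype=object), **arrays)


def init_model_params(
    dataset: CohortDataset, config: ModelConfig, seed: int = 0
) -> ModelParams:
    rng = np.random.default_rng(seed)
    enc = init_encoder_params(
        dataset.n_genes,
        dataset.n_samples,
        hidden_dim=config.hidden_dim,
        n_layers=config.n_layers,
        rng=rng,
    )
    bwfa = (
        init_bwfa_params(
            config.hidden_dim, config.attention_dim, config.share_qkv, rng
        )
        if config.use_attention
        else None
    )
    W0 = glorot_uniform(config.hidden_dim, config.projection_dim, rng)
    W1 = glorot_uniform(config.hidden_dim, config.projection_dim, rng)
    return ModelParams(encoder=enc, bwfa=bwfa, W0=W0, W1=W1)


def _softmax_rows(L: np.ndarray) -> np.ndarray:
    L = L - L.max(axis=1, keepdims=True)
    e = np.exp(L)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: ModelParams,
    Xg: np.ndarray,
    Xs: np.ndarray,
    Ags: np.ndarray,
    Asg: np.ndarray,
) -> dict[str, np.ndarray]:
    """Full forward pass; returns every intermediate needed for backward."""
    cache: dict[str, np.ndarray] = {}
    Hg, Hs = Xg, Xs
    for i, (lg, ls) in enumerate(
        zip(params.encoder.gene_layers, params.encoder.sample_layers), start=1
    ):
        cache[f"Hg{i - 1}"], cache[f"Hs{i - 1}"] = Hg, Hs
        Zg = Hg @ lg.W_self + Ags @ (Hs @ lg.W_neigh)
        Zs = Hs @ ls.W_self + Asg @ (Hg @ ls.W_neigh)
        cache[f"Zg{i}"], cache[f"Zs{i}"] = Zg, Zs
        Hg, Hs = np.maximum(Zg, 0.0), np.maximum(Zs, 0.0)
    cache["G0"], cache["S0"] = Hg, Hs

    if params.bwfa is not None:
        g, s = params.bwfa.gene_dir, params.bwfa.sample_dir
        Qg, Ksg, Vsg = Hg @ g.WQ, Hs @ g.WK, Hs @ g.WV
        Eg = _softmax_rows((Qg @ Ksg.T) / np.sqrt(g.dk))
        Gp = Eg @ Vsg
        Zpg = Gp @ g.Wp + g.bp
        G_hat = np.maximum(Zpg, 0.0)
        Qs, Kgs, Vgs = Hs @ s.WQ, Hg @ s.WK, Hg @ s.WV
        Es = _softmax_rows((Qs @ Kgs.T) / np.sqrt(s.dk))
        Sp = Es @ Vgs
        Zps = Sp @ s.Wp + s.bp
        S_hat = np.maximum(Zps, 0.0)
        cache.update(
            Qg=Qg, Ksg=Ksg, Vsg=Vsg, Eg=Eg, Gp=Gp, Zpg=Zpg,
            Qs=Qs, Kgs=Kgs, Vgs=Vgs, Es=Es, Sp=Sp, Zps=Zps,
        )
    else:
        G_hat, S_hat = Hg, Hs
    cache["G_hat"], cache["S_hat"] = G_hat, S_hat

    Hgf = G_hat @ params.W0
    Hsf = S_hat @ params.W1
    ng = np.linalg.norm(Hgf, axis=1, keepdims=True)
    ns = np.linalg.norm(Hsf, axis=1, keepdims=True)
    ng_safe = np.where(ng == 0, 1.0, ng)
    ns_safe = np.where(ns == 0, 1.0, ns)
    U = Hgf / ng_safe
    V = Hsf / ns_safe
    C = U @ V.T
    A_hat = 0.5 * (C + 1.0)
    cache.update(
        Hgf=Hgf, Hsf=Hsf, ng=ng_safe, ns=ns_safe,
        zg=(ng == 0), zs=(ns == 0), U=U, V=V, C=C, A_hat=A_hat,
    )
    return cache


def forward_backward(
    params: ModelParams,
    Xg: np.ndarray,
    Xs: np.ndarray,
    Ags: np.ndarray,
    Asg: np.ndarray,
    A: np.ndarray,
    mask: np.ndarray,
    beta: float,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Loss, parameter gradients, and the decoded probability matrix."""
    cache = forward(params, Xg, Xs, Ags, Asg)
    A_hat = cache["A_hat"]
    mask = np.asarray(mask, dtype=bool)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("training mask is empty")
    p = np.clip(A_hat, EPS, 1.0 - EPS)
    loss = float(
        -(beta * A[mask] * np.log(p[mask]) + (1 - A[mask]) * np.log1p(-p[mask])).sum()
        / m
    )

    grads: dict[str, np.ndarray] = {}

    # loss -> A_hat -> cosine C
    dA_hat = -(beta * A / p - (1.0 - A) / (1.0 - p)) / m
    dA_hat[~mask] = 0.0
    dC = 0.5 * dA_hat

    U, V, ng, ns = cache["U"], cache["V"], cache["ng"], cache["ns"]
    dU = dC @ V
    dV = dC.T @ U
    # row-normalization backward: d(x/||x||) with zero rows frozen
    dHgf = (dU - U * (dU * U).sum(axis=1, keepdims=True)) / ng
    dHsf = (dV - V * (dV * V).sum(axis=1, keepdims=True)) / ns
    dHgf[np.broadcast_to(cache["zg"], dHgf.shape)] = 0.0
    dHsf[np.broadcast_to(cache["zs"], dHsf.shape)] = 0.0

    G_hat, S_hat = cache["G_hat"], cache["S_hat"]
    grads["dec.W0"] = G_hat.T @ dHgf
    grads["dec.W1"] = S_hat.T @ dHsf
    dG_hat = dHgf @ params.W0.T
    dS_hat = dHsf @ params.W1.T

    G0, S0 = cache["G0"], cache["S0"]
    if params.bwfa is not None:
        g, s = params.bwfa.gene_dir, params.bwfa.sample_dir
        dG0 = np.zeros_like(G0)
        dS0 = np.zeros_like(S0)

        # gene-side attention
        dZpg = dG_hat * (cache["Zpg"] > 0)
        grads["att.g.Wp"] = cache["Gp"].T @ dZpg
        grads["att.g.bp"] = dZpg.sum(axis=0)
        dGp = dZpg @ g.Wp.T
        Eg, Vsg, Qg, Ksg = cache["Eg"], cache["Vsg"], cache["Qg"], cache["Ksg"]
        dEg = dGp @ Vsg.T
        dVsg = Eg.T @ dGp
        dLg = Eg * (dEg - (dEg * Eg).sum(axis=1, keepdims=True))
        dQg = (dLg @ Ksg) / np.sqrt(g.dk)
        dKsg = (dLg.T @ Qg) / np.sqrt(g.dk)
        grads["att.g.WQ"] = G0.T @ dQg
        grads["att.g.WK"] = S0.T @ dKsg
        grads["att.g.WV"] = S0.T @ dVsg
        dG0 += dQg @ g.WQ.T
        dS0 += dKsg @ g.WK.T + dVsg @ g.WV.T

        # sample-side attention
        dZps = dS_hat * (cache["Zps"] > 0)
        grads["att.s.Wp"] = cache["Sp"].T @ dZps
        grads["att.s.bp"] = dZps.sum(axis=0)
        dSp = dZps @ s.Wp.T
        Es, Vgs, Qs, Kgs = cache["Es"], cache["Vgs"], cache["Qs"], cache["Kgs"]
        dEs = dSp @ Vgs.T
        dVgs = Es.T @ dSp
        dLs = Es * (dEs - (dEs * Es).sum(axis=1, keepdims=True))
        dQs = (dLs @ Kgs) / np.sqrt(s.dk)
        dKgs = (dLs.T @ Qs) / np.sqrt(s.dk)
        dWQs = S0.T @ dQs
        dWKs = G0.T @ dKgs
        dWVs = G0.T @ dVgs
        dS0 += dQs @ s.WQ.T
        dG0 += dKgs @ s.WK.T + dVgs @ s.WV.T
        if params.bwfa.share_qkv:
            grads["att.g.WQ"] += dWQs
            grads["att.g.WK"] += dWKs
            grads["att.g.WV"] += dWVs
        else:
            grads["att.s.WQ"] = dWQs
            grads["att.s.WK"] = dWKs
            grads["att.s.WV"] = dWVs
    else:
        dG0, dS0 = dG_hat, dS_hat

    # encoder backward, deepest layer first
    dHg, dHs = dG0, dS0
    for i in range(params.encoder.n_layers, 0, -1):
        lg = params.encoder.gene_layers[i - 1]
        ls = params.encoder.sample_layers[i - 1]
        Hg_in, Hs_in = cache[f"Hg{i - 1}"], cache[f"Hs{i - 1}"]
        dZg = dHg * (cache[f"Zg{i}"] > 0)
        dZs = dHs * (cache[f"Zs{i}"] > 0)
        grads[f"enc{i}.g.W_self"] = Hg_in.T @ dZg
        Tg = Ags.T @ dZg
        grads[f"enc{i}.g.W_neigh"] = Hs_in.T @ Tg
        grads[f"enc{i}.s.W_self"] = Hs_in.T @ dZs
        Ts = Asg.T @ dZs
        grads[f"enc{i}.s.W_neigh"] = Hg_in.T @ Ts
        if i > 1:
            dHg = dZg @ lg.W_self.T + Ts @ ls.W_neigh.T
            dHs = dZs @ ls.W_self.T + Tg @ lg.W_neigh.T
    return loss, grads, A_hat


class Adam:
    """Plain Adam over a named parameter dict, updating arrays in place."""

    def __init__(self, arrays: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, arr in self.arrays.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            arr -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(
    dataset: CohortDataset,
    train_config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> tuple[ModelParams, ScoreMatrix, list[float]]:
    """Fit the full model against the weighted BCE on the masked pairs.

    Adjacency columns outside the training mask are zeroed, so held-out
    samples never contribute association edges during message passing. With
    neighbor sampling enabled the sampled adjacency is redrawn each epoch
    (epoch index folded into the seed); the returned probability matrix is
    computed on the dense adjacency at the fitted parameters and covers all
    samples, held-out columns included.

    Returns (fitted parameters, probability ScoreMatrix, loss history).
    """
    cfg = model_config or ModelConfig()
    mask = (
        np.ones((dataset.n_genes, dataset.n_samples), dtype=bool)
        if train_config.mask is None
        else np.asarray(train_config.mask, dtype=bool)
    )
    if mask.shape != (dataset.n_genes, dataset.n_samples):
        raise ValueError("mask shape does not match the dataset")
    train_cols = mask.any(axis=0)

    B = bipartite_adjacency(dataset, cfg.adjacency_source, train_cols)
    Xg, Xs, A = dataset.Xg, dataset.Xs, dataset.A
    beta = train_config.beta if train_config.beta is not None else default_beta(A, mask)

    params = init_model_params(dataset, cfg, seed=train_config.seed)
    opt = Adam(params.named_arrays(), lr=train_config.learning_rate)
    losses: list[float] = []
    for epoch in range(train_config.epochs):
        if cfg.sampling_size is not None:
            Ags, Asg = normalized_adjacencies(
                B, cfg.sampling_size, seed=train_config.seed + epoch
            )
        elif epoch == 0:
            Ags, Asg = normalized_adjacencies(B)
        loss, grads, _ = forward_backward(params, Xg, Xs, Ags, Asg, A, mask, beta)
        if not np.isfinite(loss):
            raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
        opt.step(grads)
        losses.append(loss)

    Ags, Asg = normalized_adjacencies(B)
    A_hat = forward(params, Xg, Xs, Ags, Asg)["A_hat"]
    scores = ScoreMatrix(
        values=np.clip(A_hat, 0.0, 1.0), genes=dataset.genes, samples=dataset.samples
    )
    return params, scores, losses
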