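"""Bidirectional weighted feature aggregation (cross-attention).

Single-head scaled dot-product attention run in both directions between the
encoder's gene embeddings G and sample embeddings S:

    gene side:   E_gs = softmax(G WQ (S WK)^T / sqrt(dk)),
                 G_hat = ReLU((E_gs . S WV) Wp + bp)
    sample side: the symmetric computation with the roles of G and S swapped.

The attention rows are the learned, context-dependent gene-sample affinity
weights; each direction has its own projection set by default (a shared set
is available behind ``share_qkv``). No residual connections and no bias in
the Q/K/V projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import glorot_uniform

__all__ = [
    "AttentionParams",
    "BWFAParams",
    "attention_scores",
    "bwfa_forward",
    "init_bwfa_params",
]


@dataclass
class AttentionParams:
    """One direction of cross-attention: Q/K/V projections plus the output
    projection ``Wp`` (dk x d) and bias ``bp``."""

    WQ: np.ndarray
    WK: np.ndarray
    WV: np.ndarray
    Wp: np.ndarray
    bp: np.ndarray

    def __post_init__(self) -> None:
        dk = self.WQ.shape[1]
        if self.WK.shape[1] != dk or self.WV.shape[1] != dk:
            raise ValueError("WQ, WK, WV must share their inner dimension dk")
        for arr in (self.WQ, self.WK, self.WV, self.Wp, self.bp):
            if not np.isfinite(arr).all():
                raise ValueError("attention parameters must be finite")

    @property
    def dk(self) -> int:
        return self.WQ.shape[1]


@dataclass
class BWFAParams:
    """Both attention directions. With shared Q/K/V the two directions
    reference the same projection arrays (output projections stay separate)."""

    gene_dir: AttentionParams
    sample_dir: AttentionParams
    share_qkv: bool = False


def attention_scores(Q: np.ndarray, K: np.ndarray, dk: int | None = None) -> np.ndarray:
    """Row-stochastic attention matrix softmax(Q K^T / sqrt(dk))."""
    if dk is None:
        dk = Q.shape[1]
    if dk <= 0:
        raise ValueError("dk must be positive")
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K must share their column dimension")
    logits = (Q @ K.T) / np.sqrt(dk)
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _one_direction(
    X: np.ndarray, Y: np.ndarray, p: AttentionParams
) -> np.ndarray:
    """Attend from query side X over key/value side Y; ReLU output, X-rows."""
    Q = X @ p.WQ
    K = Y @ p.WK
    V = Y @ p.WV
    E = attention_scores(Q, K, p.dk)
    out = (E @ V) @ p.Wp + p.bp
    return np.maximum(out, 0.0)


def bwfa_forward(
    G: np.ndarray, S: np.ndarray, params: BWFAParams
) -> tuple[np.ndarray, np.ndarray]:
    """Both directions of weighted aggregation: returns (G_hat, S_hat)."""
    if G.shape[1] != params.gene_dir.WQ.shape[0]:
        raise ValueError("gene embedding width does not match attention parameters")
    if S.shape[1] != params.sample_dir.WQ.shape[0]:
        raise ValueError("sample embedding width does not match attention parameters")
    G_hat = _one_direction(G, S, params.gene_dir)
    S_hat = _one_direction(S, G, params.sample_dir)
    return G_hat, S_hat


def init_bwfa_params(
    d: int,
    dk: int = 64,
    share_qkv: bool = False,
    rng: np.random.Generator | int = 0,
) -> BWFAParams:
    """Glorot-style initialization of both attention directions."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def _qkv() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            glorot_uniform(d, dk, rng),
            glorot_uniform(d, dk, rng),
            glorot_uniform(d, dk, rng),
        )

    q1, k1, v1 = _qkv()
    if share_qkv:
        q2, k2, v2 = q1, k1, v1
    else:
        q2, k2, v2 = _qkv()
    gene_dir = AttentionParams(
        WQ=q1, WK=k1, WV=v1, Wp=glorot_uniform(dk, d, rng), bp=np.zeros(d)
    )
    sample_dir = AttentionParams(
        WQ=q2, WK=k2, WV=v2, Wp=glorot_uniform(dk, d, rng), bp=np.zeros(d)
    )
    return BWFAParams(gene_dir=gene_dir, sample_dir=sample_dir, share_qkv=share_qkv)
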