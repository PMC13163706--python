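"""Decoder: linear projections, cosine-similarity probabilities, and the
class-weighted binary cross-entropy used to fit the model.

The decoded matrix A_hat[i, j] = (cos(h_gi, h_sj) + 1) / 2 is the predicted
probability that gene i acts as a driver in sample j. Driver-positive pairs
are vastly outnumbered by negatives, so the loss up-weights positives by a
factor beta (defaulting to the negative:positive ratio inside the training
mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EPS = 1e-7

__all__ = [
    "ScoreMatrix",
    "project_embeddings",
    "cosine_probability",
    "weighted_bce",
    "weighted_bce_grad",
]


@dataclass
class ScoreMatrix:
    """Predicted gene-sample driver probabilities, entries in [0, 1]."""

    values: np.ndarray
    genes: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("score matrix shape does not match index maps")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def project_embeddings(
    G_hat: np.ndarray, S_hat: np.ndarray, W0: np.ndarray, W1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Final linear maps into the common decoding space (no activation)."""
    if G_hat.shape[1] != W0.shape[0] or S_hat.shape[1] != W1.shape[0]:
        raise ValueError("projection weight shapes do not match embeddings")
    return G_hat @ W0, S_hat @ W1


def _safe_row_norms(X: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(X, axis=1, keepdims=True)
    n[n == 0] = 1.0  # zero rows decode to cosine 0 -> probability 0.5
    return n


def cosine_probability(Hg: np.ndarray, Hs: np.ndarray) -> np.ndarray:
    """Map row-wise cosine similarities into [0, 1]: (cos + 1) / 2.

    Zero-norm rows use the convention cos = 0, giving probability 0.5.
    """
    if not (np.isfinite(Hg).all() and np.isfinite(Hs).all()):
        raise ValueError("embeddings must be finite")
    if Hg.shape[1] != Hs.shape[1]:
        raise ValueError("embedding dimensions do not match")
    U = Hg / _safe_row_norms(Hg)
    V = Hs / _safe_row_norms(Hs)
    C = np.clip(U @ V.T, -1.0, 1.0)
    return 0.5 * (C + 1.0)


def weighted_bce(
    A_hat: np.ndarray,
    A: np.ndarray,
    mask: np.ndarray,
    beta: float,
) -> float:
    """Class-weighted binary cross-entropy averaged over masked entries.

    L = -(1/|M|) sum_{(i,j) in M} [beta A log A_hat + (1 - A) log(1 - A_hat)]

    Probabilities are clipped into (EPS, 1 - EPS) to keep the logs finite.
    """
    mask = np.asarray(mask, dtype=bool)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("training mask is empty")
    if beta <= 0:
        raise ValueError("beta must be positive")
    p = np.clip(A_hat[mask], EPS, 1.0 - EPS)
    a = A[mask]
    return float(-(beta * a * np.log(p) + (1.0 - a) * np.log1p(-p)).sum() / m)


def weighted_bce_grad(
    A_hat: np.ndarray,
    A: np.ndarray,
    mask: np.ndarray,
    beta: float,
) -> np.ndarray:
    """Gradient of :func:`weighted_bce` with respect to A_hat (full matrix)."""
    mask = np.asarray(mask, dtype=bool)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("training mask is empty")
    p = np.clip(A_hat, EPS, 1.0 - EPS)
    grad = -(beta * A / p - (1.0 - A) / (1.0 - p)) / m
    grad[~mask] = 0.0
    return grad


def default_beta(A: np.ndarray, mask: np.ndarray) -> float:
    """Negative:positive ratio inside the mask — the imbalance heuristic."""
    mask = np.asarray(mask, dtype=bool)
    pos = float(A[mask].sum())
    neg = float(mask.sum() - pos)
    if pos == 0:
        return 1.0
    return max(neg / pos, 1.0)
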