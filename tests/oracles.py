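"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, no shared code with
the package — so that agreement with the package is meaningful.
"""

import math

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def sage_layer_reference(H_self, H_other, A_norm, W_self, W_neigh):
    """Eqs. written out as an explicit dense product chain."""
    return relu(np.dot(H_self, W_self) + np.dot(np.dot(A_norm, H_other), W_neigh))


def softmax_rows_reference(L):
    out = np.empty_like(L, dtype=float)
    for i in range(L.shape[0]):
        row = L[i] - L[i].max()
        e = np.exp(row)
        out[i] = e / e.sum()
    return out


def bwfa_reference(G, S, pg, ps):
    """Both cross-attention directions, written as explicit loops."""

    def one(X, Y, WQ, WK, WV, Wp, bp):
        Q, K, V = X @ WQ, Y @ WK, Y @ WV
        dk = WQ.shape[1]
        E = softmax_rows_reference((Q @ K.T) / math.sqrt(dk))
        return relu((E @ V) @ Wp + bp)

    G_hat = one(G, S, pg["WQ"], pg["WK"], pg["WV"], pg["Wp"], pg["bp"])
    S_hat = one(S, G, ps["WQ"], ps["WK"], ps["WV"], ps["Wp"], ps["bp"])
    return G_hat, S_hat


def cosine_probability_reference(Hg, Hs):
    G, N = Hg.shape[0], Hs.shape[0]
    out = np.zeros((G, N))
    for i in range(G):
        for j in range(N):
            ni, nj = np.linalg.norm(Hg[i]), np.linalg.norm(Hs[j])
            cos = 0.0 if ni == 0 or nj == 0 else float(Hg[i] @ Hs[j]) / (ni * nj)
            out[i, j] = 0.5 * (cos + 1.0)
    return out


def weighted_bce_reference(A_hat, A, mask, beta, eps=1e-7):
    total, count = 0.0, 0
    G, N = A.shape
    for i in range(G):
        for j in range(N):
            if not mask[i, j]:
                continue
            count += 1
            p = min(max(A_hat[i, j], eps), 1 - eps)
            total += beta * A[i, j] * math.log(p) + (1 - A[i, j]) * math.log(1 - p)
    return -total / count


def epv_bruteforce(rankings, alpha, universe):
    """Materialize every ordered pair x sample contest."""
    genes = sorted(universe)
    win = {g: 0.0 for g in genes}
    loss = {g: 0.0 for g in genes}
    for r in rankings:
        ranks = {g: k + 1 for k, g in enumerate(r.genes)}
        for gi in genes:
            for gj in genes:
                if gi == gj:
                    continue
                ri = ranks.get(gi)
                rj = ranks.get(gj)
                if ri is None:
                    continue
                if rj is None or ri < rj:
                    w = math.exp(-alpha * (ri - 1))
                    win[gi] += w
                    loss[gj] += w
    p = {
        g: (win[g] / (win[g] + loss[g]) if win[g] + loss[g] > 0 else 0.0)
        for g in genes
    }
    return win, loss, p
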