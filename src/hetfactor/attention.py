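"""Two-level attention aggregation over factor graphs and metapaths.

Within a single metapath, every factor graph is aggregated with multi-head
graph self-attention: per head, a shared linear map transforms the common-
space features and an attention vector scores each (node, neighbor) pair;
scores pass through LeakyReLU, are shifted by the log of the factor edge
weight (so each factor graph biases attention toward the edges it weights
highly — the self edge has weight 1), and are softmax-normalized over the
sampled neighborhood.  Head outputs are concatenated, and the per-factor
results are concatenated again, giving the metapath embedding Z^m of
dimension N * K * d_head.

Across metapaths, a semantic attention layer summarizes each metapath by
the mean of tanh(W_a Z_v + eps_a) over the endpoint type's nodes, scores
the summaries against a learned query vector, and softmax-fuses the
per-metapath embeddings into the final node embedding H_v.  The fusion
weights are metapath-level: identical for every node of the type.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .factorization import glorot

_NEG = -1e30  # additive mask value; exp underflows to exactly 0


def leaky_relu(x, slope: float = 0.2):
    return anp.where(x >= 0, x, slope * x)


def elu(x):
    return anp.where(x >= 0, x, anp.exp(anp.minimum(x, 0.0)) - 1.0)


# ---------------------------------------------------------------------------
# Intra-metapath (factor graph) attention
# ---------------------------------------------------------------------------


def init_intra_layer(
    rng: np.random.Generator,
    n_factors: int,
    n_heads: int,
    d_head: int,
    d_common: int,
) -> dict:
    """Per-(factor, head) linear maps and attention vectors for one metapath."""
    return {
        "W": glorot(rng, n_factors, n_heads, d_head, d_common),
        "a_src": glorot(rng, n_factors, n_heads, d_head),
        "a_dst": glorot(rng, n_factors, n_heads, d_head),
    }


def attention_coefficients(h, layer, W_e, mask: np.ndarray, slope: float = 0.2):
    """Normalized attention coefficients alpha for every factor and head.

    Returns ``(alpha, ht)`` where ``alpha`` is (N, K, n, n) and rows sum to
    one over each node's masked neighborhood, and ``ht`` is the transformed
    features (N, K, n, d_head).  The logit for neighbor j of node i is
    LeakyReLU(a_src . Wh'_i + a_dst . Wh'_j) + log W_e[i, j]; the self
    weight is fixed at 1 (log-shift 0).
    """
    ht = anp.einsum("fkdc,nc->fknd", layer["W"], h)
    src = anp.sum(ht * layer["a_src"][:, :, None, :], axis=-1)  # (N, K, n)
    dst = anp.sum(ht * layer["a_dst"][:, :, None, :], axis=-1)
    logits = leaky_relu(src[:, :, :, None] + dst[:, :, None, :], slope)
    n = h.shape[0]
    eye = np.eye(n)
    W_self = W_e * (1.0 - eye)[None, :, :] + eye[None, :, :]  # self weight 1
    # clip only protects masked-out zeros; on-support weights are in (0, 1)
    logits = logits + anp.log(anp.maximum(W_self, 1e-30))[:, None, :, :]
    logits = anp.where(mask[None, None, :, :], logits, _NEG)
    logits = logits - anp.max(logits, axis=-1, keepdims=True)
    expv = anp.exp(logits)
    alpha = expv / anp.sum(expv, axis=-1, keepdims=True)
    return alpha, ht


def intra_factor_aggregate(
    h, layer, W_e, mask: np.ndarray, slope: float = 0.2, apply_elu: bool = True
):
    """Per-factor, per-head attention aggregation: Z = sum_j alpha_ij Wh'_j.

    Returns an (N, K, n, d_head) array (optionally ELU-activated).
    """
    alpha, ht = attention_coefficients(h, layer, W_e, mask, slope)
    z = anp.einsum("fkij,fkjd->fkid", alpha, ht)
    return elu(z) if apply_elu else z


def metapath_embed(
    h, layer, W_e, mask: np.ndarray, slope: float = 0.2, apply_elu: bool = True
):
    """Embedding of every node under one metapath: concat factors x heads.

    Output is (n, N * K * d_head); block order is factor-major, head-minor.
    """
    z = intra_factor_aggregate(h, layer, W_e, mask, slope, apply_elu)  # (N, K, n, d)
    n_f, n_k, n, d = z.shape
    return anp.reshape(anp.transpose(z, (2, 0, 1, 3)), (n, n_f * n_k * d))


# ---------------------------------------------------------------------------
# Inter-metapath semantic attention
# ---------------------------------------------------------------------------


def init_semantic(
    rng: np.random.Generator, d_in: int, d_sem: int
) -> dict[str, np.ndarray]:
    """Per-type summary transform (W_a, eps_a) and metapath query vector Q."""
    return {
        "W": glorot(rng, d_sem, d_in),
        "eps": np.zeros(d_sem),
        "Q": glorot(rng, d_sem),
    }


def summarize_metapath(Z, sem):
    """Metapath summary P_m = mean_v tanh(W_a Z_v + eps_a)."""
    if Z.shape[0] == 0:
        raise ValueError("cannot summarize a metapath with no endpoint nodes")
    return anp.mean(anp.tanh(anp.dot(Z, sem["W"].T) + sem["eps"]), axis=0)


def fuse_metapaths(Z_list, sem):
    """Fuse per-metapath embeddings into final node embeddings H.

    Scores each metapath summary against the query Q, softmax-normalizes
    into weights omega (shared by all nodes of the type), and returns
    ``(H, omega)`` with H_v = sum_m omega_m Z_v^m.
    """
    if len(Z_list) == 0:
        raise ValueError("node type has no registered metapaths")
    P = anp.stack([summarize_metapath(Z, sem) for Z in Z_list])  # (l, d_sem)
    w = anp.dot(P, sem["Q"])
    w = w - anp.max(w)
    omega = anp.exp(w) / anp.sum(anp.exp(w))
    H = sum(omega[i] * Z_list[i] for i in range(len(Z_list)))
    return H, omega
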