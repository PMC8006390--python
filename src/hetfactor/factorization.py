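"""Common-space projection and factor-graph decomposition.

Every node type carries features in its own space; a per-type linear map
``M_a`` projects them into one shared d'-dimensional space, h'_v = M_a x_v.
Each metapath-induced homogeneous graph is then *factorized*: N independent
pairwise scorers reweight its edges, W_e[v,u] = sigmoid(S_e(h'_v, h'_u)),
yielding N "factor graphs" that share the edge support and node features
but differ in edge weights.  Left alone these copies would be redundant, so
a discrimination loss forces them apart: each factor graph is encoded to a
fixed-length vector, a single-layer classifier predicts which of the N
factors produced it, and the cross-entropy of that prediction is minimized.

All functions are written against ``autograd.numpy`` so gradients flow into
every parameter; parameters live in plain nested dicts of numpy arrays.
"""

from __future__ import annotations

import math
import warnings

import autograd.numpy as anp
import numpy as np


def glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    """Glorot-uniform initialization (fan averaged over the last two axes)."""
    fan_in = shape[-1] if len(shape) >= 1 else 1
    fan_out = shape[-2] if len(shape) >= 2 else 1
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)  # numerically stable on both tails


# ---------------------------------------------------------------------------
# Feature projection (common space)
# ---------------------------------------------------------------------------


def init_projector(
    rng: np.random.Generator, dims: dict[str, int], d_common: int
) -> dict[str, np.ndarray]:
    """One d' x d_a transformation matrix per node type."""
    return {t: glorot(rng, d_common, d_a) for t, d_a in dims.items()}


def project(x: np.ndarray, proj: dict[str, np.ndarray], node_type: str):
    """Project raw features of one type into the common space: h' = M_a x.

    ``x`` may be a single d_a vector or an (n, d_a) matrix.
    """
    if node_type not in proj:
        raise KeyError(f"no transformation registered for node type {node_type!r}")
    M = proj[node_type]
    if x.shape[-1] != M.shape[1]:
        raise ValueError(
            f"type {node_type}: feature dimension {x.shape[-1]} does not match "
            f"registered input dimension {M.shape[1]}"
        )
    return anp.dot(x, M.T)


# ---------------------------------------------------------------------------
# Factor edge weights
# ---------------------------------------------------------------------------


def init_factor_scorers(
    rng: np.random.Generator, n_factors: int, d_common: int
) -> dict[str, np.ndarray]:
    """N affine pairwise scorers S_e on the concatenation [h'_v || h'_u]."""
    return {
        "u": glorot(rng, n_factors, d_common),
        "v": glorot(rng, n_factors, d_common),
        "b": np.zeros(n_factors),
    }


def factor_edge_weights(h, scorers, mask: np.ndarray):
    """Reweight the graph's edges with each factor scorer.

    Returns an (N, n, n) array with W_e[v, u] = sigmoid of the symmetrized
    affine score, supported on ``mask`` (the homogeneous graph's edge set,
    a boolean (n, n) matrix) and zero elsewhere.  Symmetrization averages
    the two argument orders so undirected edges get a single weight.
    """
    if h.shape[1] != scorers["u"].shape[1]:
        raise ValueError(
            f"scorer dimension {scorers['u'].shape[1]} does not match "
            f"feature dimension {h.shape[1]}"
        )
    # (S(v,u) + S(u,v)) / 2 for an affine S collapses to a single node score
    t = anp.dot(h, (scorers["u"] + scorers["v"]).T) / 2.0  # (n, N)
    score = t.T[:, :, None] + t.T[:, None, :] + scorers["b"][:, None, None]
    return sigmoid(score) * mask[None, :, :]


# ---------------------------------------------------------------------------
# Factor-graph encoding and discrimination
# ---------------------------------------------------------------------------


def encode_factor_graph(W_e, h, mask: np.ndarray | None = None):
    """Permutation-invariant graph-level encoding of one factor graph.

    One round of W_e-weighted neighbor mean aggregation per node, followed
    by global mean pooling over the nodes that have at least one edge.  An
    empty edge set degenerates to the global mean of h'.
    """
    if mask is None:
        mask = np.asarray(W_e) > 0
    W = W_e * mask
    rowsum = anp.sum(W, axis=1)
    covered = np.asarray(rowsum) > 0
    if not covered.any():
        return anp.mean(h, axis=0)
    agg = anp.dot(W, h) / anp.maximum(rowsum, 1e-12)[:, None]
    return anp.sum(agg * covered[:, None], axis=0) / covered.sum()


def encode_factor_graphs(W, h, mask: np.ndarray):
    """Vectorized :func:`encode_factor_graph` over all N factors at once.

    ``W`` is (N, n, n) sharing the support ``mask``; returns (N, d').
    """
    covered = np.asarray(mask).any(axis=1)
    if not covered.any():
        return anp.tile(anp.mean(h, axis=0), (W.shape[0], 1))
    Wm = W * mask[None, :, :]
    rowsum = anp.sum(Wm, axis=2)  # (N, n)
    agg = anp.einsum("fij,jd->fid", Wm, h) / anp.maximum(rowsum, 1e-12)[:, :, None]
    return anp.sum(agg * covered[None, :, None], axis=1) / covered.sum()


def init_classifier(
    rng: np.random.Generator, d_common: int, n_factors: int
) -> dict[str, np.ndarray]:
    """Single fully-connected layer from graph encodings to N factor logits."""
    return {"W": glorot(rng, n_factors, d_common), "b": np.zeros(n_factors)}


def log_softmax(logits):
    shifted = logits - anp.max(logits, axis=-1, keepdims=True)
    return shifted - anp.log(anp.sum(anp.exp(shifted), axis=-1, keepdims=True))


def factor_discriminant_loss(encodings, clf) -> float:
    """Cross-entropy for telling the N factor graphs of one metapath apart.

    ``encodings`` is an (N, d') array whose i-th row encodes the factor
    graph with label i; the loss is (1/N) sum_i -log softmax(F(enc_i))[i].
    When several metapaths contribute, average their per-metapath losses.
    """
    n = encodings.shape[0]
    if n < 2:
        warnings.warn(
            "fewer than two factor graphs: discrimination loss is trivially "
            "minimizable and carries no constraint",
            stacklevel=2,
        )
    logits = anp.dot(encodings, clf["W"].T) + clf["b"]
    logp = log_softmax(logits)
    return -anp.mean(logp[anp.arange(n), anp.arange(n)])
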