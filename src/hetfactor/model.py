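"""End-to-end model assembly: parameters, forward pass, and losses.

The model is a pure function of a nested parameter dict (numpy arrays
only), so HIPS autograd can differentiate the training loss with respect
to every parameter.  A :class:`GraphContext` freezes everything derived
from the training graph — per-type features, metapath-induced adjacency
masks — so repeated forward passes only redo the differentiable math.

Pipeline per forward pass:

1. project per-type raw features into the common space (h');
2. per metapath: reweight edges with the N factor scorers (W_e), run
   multi-head attention aggregation per factor graph, concatenate into the
   metapath embedding Z^m; encode each factor graph for the discriminator;
3. per node type with registered metapaths (genes, diseases): fuse the Z^m
   with semantic attention into final embeddings H;
4. losses: binary cross-entropy over gene-disease pairs on
   sigmoid(<H_g, H_d>) scores, plus gamma times the factor-discrimination
   cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as np

from . import attention, factorization
from .hetnet import (
    DEFAULT_METAPATHS,
    METAPATHS_BY_TYPE,
    NODE_TYPES,
    HeteroGraph,
    MetapathGraph,
    build_metapath_graph,
    sample_neighbor_mask,
)

SCORE_EPS = 1e-7  # scores clamped to [eps, 1-eps] before logs


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` is both the common projection dimension d' and the total
    width of one factor graph's multi-head output (d_head = hidden_dim /
    num_heads); the final embedding width is num_factor_graphs * hidden_dim.
    Defaults follow the reference configuration: 128 hidden units, 8 heads,
    16 factor graphs.
    """

    hidden_dim: int = 128
    num_heads: int = 8
    num_factor_graphs: int = 16
    sem_dim: int = 128
    leaky_slope: float = 0.2
    apply_elu: bool = True
    feature_mode: str = "one-hot"  # used when the graph carries no features
    feature_dim: int = 64  # gaussian mode only
    metapaths: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {t: tuple(m) for t, m in METAPATHS_BY_TYPE.items()}
    )

    def __post_init__(self) -> None:
        if self.hidden_dim % self.num_heads:
            raise ValueError("hidden_dim must be divisible by num_heads")
        if self.num_factor_graphs < 1:
            raise ValueError("num_factor_graphs must be >= 1")

    @property
    def d_head(self) -> int:
        return self.hidden_dim // self.num_heads

    @property
    def embed_dim(self) -> int:
        return self.num_factor_graphs * self.hidden_dim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metapaths"] = {t: list(m) for t, m in self.metapaths.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "metapaths" in d:
            d["metapaths"] = {t: tuple(m) for t, m in d["metapaths"].items()}
        return cls(**d)


@dataclass
class GraphContext:
    """Frozen graph-derived state for forward passes."""

    features: dict[str, np.ndarray]
    metapath_graphs: dict[str, MetapathGraph]
    edge_masks: dict[str, np.ndarray]  # dense bool adjacency, no self-loops
    metapaths_by_type: dict[str, tuple[str, ...]]

    @property
    def endpoint_types(self) -> tuple[str, ...]:
        return tuple(t for t, ms in self.metapaths_by_type.items() if ms)


def build_context(
    g: HeteroGraph, cfg: ModelConfig, seed: int = 0
) -> GraphContext:
    """Materialize features and metapath graphs for a (training) graph."""
    rng = np.random.default_rng(seed)
    features: dict[str, np.ndarray] = {}
    for t in NODE_TYPES:
        n = g.n_nodes(t)
        if n == 0:
            continue
        f = g.get_features(t)
        if f is not None:
            features[t] = f
        elif cfg.feature_mode == "gaussian":
            features[t] = rng.standard_normal((n, cfg.feature_dim))
        else:
            features[t] = np.eye(n)
    mgs: dict[str, MetapathGraph] = {}
    masks: dict[str, np.ndarray] = {}
    metapaths_by_type = {
        t: tuple(m for m in ms if g.n_nodes(t) > 0)
        for t, ms in cfg.metapaths.items()
    }
    for t, ms in metapaths_by_type.items():
        for name in ms:
            mg = build_metapath_graph(g, DEFAULT_METAPATHS[name])
            mgs[name] = mg
            masks[name] = np.asarray(mg.adjacency.todense()) > 0
    return GraphContext(
        features=features,
        metapath_graphs=mgs,
        edge_masks=masks,
        metapaths_by_type=metapaths_by_type,
    )


def init_params(ctx: GraphContext, cfg: ModelConfig, seed: int = 0) -> dict:
    """Glorot-initialized nested parameter dict (arrays only)."""
    rng = np.random.default_rng(seed)
    dims = {t: f.shape[1] for t, f in ctx.features.items()}
    params: dict = {
        "proj": factorization.init_projector(rng, dims, cfg.hidden_dim),
        "scorers": {},
        "intra": {},
        "clf": factorization.init_classifier(
            rng, cfg.hidden_dim, cfg.num_factor_graphs
        ),
        "sem": {},
    }
    for name in ctx.metapath_graphs:
        params["scorers"][name] = factorization.init_factor_scorers(
            rng, cfg.num_factor_graphs, cfg.hidden_dim
        )
        params["intra"][name] = attention.init_intra_layer(
            rng, cfg.num_factor_graphs, cfg.num_heads, cfg.d_head, cfg.hidden_dim
        )
    for t in ctx.endpoint_types:
        params["sem"][t] = attention.init_semantic(rng, cfg.embed_dim, cfg.sem_dim)
    return params


def neighborhood_masks(
    ctx: GraphContext, limit: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-metapath attention masks: sampled neighborhoods plus self-loops.

    Rows whose degree is within ``limit`` keep their full neighborhood, so
    sampling only kicks in on high-degree nodes.
    """
    masks = {}
    for name, mg in ctx.metapath_graphs.items():
        degrees = np.diff(mg.adjacency.indptr)
        if (degrees > limit).any():
            masks[name] = sample_neighbor_mask(mg, limit, rng)
        else:
            masks[name] = ctx.edge_masks[name] | np.eye(mg.n_nodes, dtype=bool)
    return masks


def forward(
    params: dict,
    ctx: GraphContext,
    cfg: ModelConfig,
    nbr_masks: dict[str, np.ndarray],
):
    """Full forward pass.

    Returns ``(H, omega, encodings)``: final embeddings per endpoint type,
    semantic attention weights per type, and per-metapath (N, d') factor
    graph encodings for the discrimination loss.
    """
    h = {
        t: factorization.project(ctx.features[t], params["proj"], t)
        for t in ctx.features
    }
    Z: dict[str, anp.ndarray] = {}
    encodings: dict[str, anp.ndarray] = {}
    for t in ctx.endpoint_types:
        for name in ctx.metapaths_by_type[t]:
            edge_mask = ctx.edge_masks[name]
            W_e = factorization.factor_edge_weights(
                h[t], params["scorers"][name], edge_mask
            )
            Z[name] = attention.metapath_embed(
                h[t],
                params["intra"][name],
                W_e,
                nbr_masks[name],
                slope=cfg.leaky_slope,
                apply_elu=cfg.apply_elu,
            )
            encodings[name] = factorization.encode_factor_graphs(
                W_e, h[t], edge_mask
            )
    H: dict[str, anp.ndarray] = {}
    omega: dict[str, anp.ndarray] = {}
    for t in ctx.endpoint_types:
        H[t], omega[t] = attention.fuse_metapaths(
            [Z[name] for name in ctx.metapaths_by_type[t]], params["sem"][t]
        )
    return H, omega, encodings


# ---------------------------------------------------------------------------
# Scoring and losses
# ---------------------------------------------------------------------------


def score_pair(H_g, H_d):
    """Association probability of one gene/disease embedding pair.

    sigmoid of the inner product; symmetric in its arguments.
    """
    if not hasattr(H_g, "shape"):
        H_g = anp.array(H_g, dtype=float)
    if not hasattr(H_d, "shape"):
        H_d = anp.array(H_d, dtype=float)
    if H_g.shape != H_d.shape:
        raise ValueError(
            f"embedding dimensions differ: {H_g.shape} vs {H_d.shape}"
        )
    return factorization.sigmoid(anp.sum(H_g * H_d, axis=-1))


def score_pairs(H_G, H_D, pairs: np.ndarray):
    """Scores for an array of (gene-index, disease-index) pairs."""
    pairs = np.asarray(pairs).reshape(-1, 2)
    return score_pair(H_G[pairs[:, 0]], H_D[pairs[:, 1]])


def prediction_loss(pos_scores, neg_scores):
    """Binary cross-entropy link loss, summed over pairs.

    L = -sum log(score_pos) - sum log(1 - score_neg), with scores clamped
    away from {0, 1} before the logs.
    """
    pos = anp.clip(pos_scores, SCORE_EPS, 1.0 - SCORE_EPS)
    neg = anp.clip(neg_scores, SCORE_EPS, 1.0 - SCORE_EPS)
    return -anp.sum(anp.log(pos)) - anp.sum(anp.log(1.0 - neg))


def factor_loss(encodings: dict, clf) -> float:
    """Mean factor-discrimination cross-entropy over metapaths.

    Factor labels are shared across metapaths: graph e of every metapath
    carries label e, and the single classifier must recover it.
    """
    losses = [
        factorization.factor_discriminant_loss(enc, clf)
        for enc in encodings.values()
    ]
    return sum(losses) / len(losses)


def total_loss(l_pred, l_factor, gamma: float):
    """Combined objective: L_Pred + gamma * L_Factor."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return l_pred + gamma * l_factor
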