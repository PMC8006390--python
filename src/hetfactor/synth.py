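"""Synthetic four-type heterogeneous networks with planted block structure.

Generates gene/disease/GO-term/symptom networks whose four relations are
each drawn from a stochastic block model over ``B`` shared latent
communities: node pairs within a community connect with probability
``p_in``, pairs across communities with ``p_out``.  GO and symptom nodes
receive a community label before their edges are sampled, so their
partners are predominantly same-community genes/diseases and the GOG and
DSD metapaths carry the planted signal.  The G-D edges are the link
prediction positives; with ``p_in >> p_out`` held-out association is
learnable from community membership, and with ``p_in == p_out`` the
network carries no signal (a negative control).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hetnet import METAGRAPH, RELATION_FILES, HeteroGraph

#: Default per-type counts: gene/disease sizes of the planted benchmark;
#: GO and symptom counts scale the real network's type ratios (~0.66
#: GO terms per gene, ~0.44 symptoms per disease) to this size.
_DEFAULT_COUNTS = {"G": 200, "D": 100, "O": 130, "S": 45}

_ID_PREFIX = {"G": "gene", "D": "disease", "O": "go", "S": "sym"}


@dataclass
class SynthConfig:
    """Parameters of the planted-community generator.

    ``p_in``/``p_out`` may be a single float applied to every relation or a
    per-relation dict keyed like :data:`hetfactor.hetnet.METAGRAPH`.
    ``feature_mode`` is ``"one-hot"`` (identity features, d_a = n_a) or
    ``"gaussian"`` (random normal features of dimension ``feature_dim``).
    """

    n_G: int = _DEFAULT_COUNTS["G"]
    n_D: int = _DEFAULT_COUNTS["D"]
    n_O: int = _DEFAULT_COUNTS["O"]
    n_S: int = _DEFAULT_COUNTS["S"]
    n_communities: int = 2
    p_in: float | dict[str, float] = 0.3
    p_out: float | dict[str, float] = 0.02
    feature_mode: str = "one-hot"
    feature_dim: int = 64
    seed: int = 0

    def counts(self) -> dict[str, int]:
        return {"G": self.n_G, "D": self.n_D, "O": self.n_O, "S": self.n_S}

    def rel_prob(self, relation: str, which: str) -> float:
        p = self.p_in if which == "in" else self.p_out
        return float(p[relation]) if isinstance(p, dict) else float(p)

    def validate(self) -> None:
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        for t, n in self.counts().items():
            if n < self.n_communities:
                raise ValueError(
                    f"type {t}: count {n} smaller than n_communities"
                )
        for r in METAGRAPH:
            pi, po = self.rel_prob(r, "in"), self.rel_prob(r, "out")
            if not (0.0 <= po <= pi <= 1.0):
                raise ValueError(
                    f"relation {r}: need 0 <= p_out <= p_in <= 1, got "
                    f"p_in={pi}, p_out={po}"
                )
        if self.feature_mode not in ("one-hot", "gaussian"):
            raise ValueError("feature_mode must be 'one-hot' or 'gaussian'")

    def to_dict(self) -> dict:
        return asdict(self)


def _sbm_pairs(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    p_in: float,
    p_out: float,
    rng: np.random.Generator,
    same_type: bool,
) -> np.ndarray:
    """Sample block-model edges between two labelled node sets.

    For ``same_type`` only the upper triangle is sampled (undirected simple
    graph, no self-loops).
    """
    prob = np.where(labels_a[:, None] == labels_b[None, :], p_in, p_out)
    draw = rng.random(prob.shape) < prob
    if same_type:
        draw = np.triu(draw, k=1)
    src, dst = np.nonzero(draw)
    return np.stack([src, dst], axis=1).astype(np.int64)


def generate(cfg: SynthConfig) -> tuple[HeteroGraph, dict[str, np.ndarray]]:
    """Generate a heterogeneous network and its ground-truth community labels.

    Returns ``(graph, labels)`` where ``labels[t]`` assigns each node of
    type ``t`` to one of ``cfg.n_communities`` communities.  Identical
    config (including seed) yields identical edge lists.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = {
        t: rng.integers(0, cfg.n_communities, size=n)
        for t, n in cfg.counts().items()
    }
    edges: dict[str, np.ndarray] = {}
    for r, (ta, tb) in METAGRAPH.items():
        pi, po = cfg.rel_prob(r, "in"), cfg.rel_prob(r, "out")
        n_pairs = (
            cfg.counts()[ta] * (cfg.counts()[ta] - 1) // 2
            if ta == tb
            else cfg.counts()[ta] * cfg.counts()[tb]
        )
        if n_pairs * max(pi, po) < 1:
            warnings.warn(
                f"relation {r}: expected edge count below 1 — degenerate benchmark",
                stacklevel=2,
            )
        edges[r] = _sbm_pairs(labels[ta], labels[tb], pi, po, rng, ta == tb)

    node_ids = {
        t: [f"{_ID_PREFIX[t]}{i}" for i in range(n)] for t, n in cfg.counts().items()
    }
    features: dict[str, np.ndarray] = {}
    if cfg.feature_mode == "gaussian":
        for t, n in cfg.counts().items():
            features[t] = rng.standard_normal((n, cfg.feature_dim))
    g = HeteroGraph(node_ids=node_ids, edges=edges, features=features)
    g.validate()
    return g, labels


def write_edge_lists(
    g: HeteroGraph, labels: dict[str, np.ndarray], out_dir: str
) -> list[str]:
    """Write per-relation TSV edge lists plus a node-community labels TSV.

    Emits the same file layout :func:`hetfactor.hetnet.load_hetnet` reads.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for r, fname in RELATION_FILES.items():
        ta, tb = METAGRAPH[r]
        e = g.edges[r]
        df = pd.DataFrame(
            {
                "source": [g.node_ids[ta][i] for i in e[:, 0]],
                "target": [g.node_ids[tb][j] for j in e[:, 1]],
            }
        )
        path = os.path.join(out_dir, fname)
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    rows = [
        (g.node_ids[t][i], t, int(lab))
        for t, labs in labels.items()
        for i, lab in enumerate(labs)
    ]
    lab_path = os.path.join(out_dir, "community_labels.tsv")
    pd.DataFrame(rows, columns=["node", "type", "community"]).to_csv(
        lab_path, sep="\t", index=False
    )
    paths.append(lab_path)
    return paths
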