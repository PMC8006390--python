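"""Heterogeneous graph data model and metapath machinery.

A four-type biomedical network is modelled: genes (``G``), diseases (``D``),
gene-ontology terms (``O``) and disease symptoms (``S``), connected by the
four undirected relations G-G (protein-protein interaction), G-D
(disease-gene association), G-O (GO annotation) and D-S (disease-symptom
association).  A *metapath* is a typed path pattern such as G-D-G whose
instances connect same-type endpoints through intermediate types; every
registered metapath induces a weighted homogeneous graph on its endpoint
type, with edge weights counting distinct metapath instances.

This module provides the typed node/edge store (:class:`HeteroGraph`), the
TSV loaders for per-relation edge lists, metapath-induced graph
construction, reproducible neighbor sampling, and train/test splitting with
negative sampling of gene-disease non-edges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

NODE_TYPES = ("G", "D", "O", "S")

#: Permitted (type, type) pairs per relation — the metagraph schema.
METAGRAPH: dict[str, tuple[str, str]] = {
    "G-G": ("G", "G"),
    "G-D": ("G", "D"),
    "G-O": ("G", "O"),
    "D-S": ("D", "S"),
}

#: Conventional edge-list file names, one per relation.
RELATION_FILES: dict[str, str] = {
    "G-G": "gene_gene.tsv",
    "G-D": "gene_disease.tsv",
    "G-O": "gene_go.tsv",
    "D-S": "disease_symptom.tsv",
}

#: Node and relation counts of the deposited real network, for loader
#: verification when that data is locally available.
DEPOSITED_NODE_COUNTS = {"G": 21584, "D": 15030, "O": 14204, "S": 6540}
DEPOSITED_EDGE_COUNTS = {"G-D": 130820, "G-G": 213888, "D-S": 99087, "G-O": 218337}


class SchemaError(ValueError):
    """An edge list or relation violates the metagraph schema."""


class ReferentialError(ValueError):
    """An edge references a node missing from the declared node universe."""


@dataclass
class HeteroGraph:
    """Typed node/edge store with dense per-type integer indices.

    ``node_ids[t]`` maps the dense index of type ``t`` back to the original
    string identifier; ``edges[r]`` is an ``(E, 2)`` integer array of
    (source-index, target-index) pairs in the type order given by
    ``METAGRAPH[r]``.  Edges are undirected and stored once, deduplicated.
    ``features[t]`` is an optional ``(n_t, d_t)`` float matrix aligned with
    the dense index.
    """

    node_ids: dict[str, list[str]] = field(default_factory=dict)
    edges: dict[str, np.ndarray] = field(default_factory=dict)
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in NODE_TYPES:
            self.node_ids.setdefault(t, [])
        for r in METAGRAPH:
            self.edges.setdefault(r, np.empty((0, 2), dtype=np.int64))
        self._index = {
            t: {nid: i for i, nid in enumerate(ids)} for t, ids in self.node_ids.items()
        }

    # -- basic accessors ---------------------------------------------------
    def n_nodes(self, node_type: str) -> int:
        return len(self.node_ids[node_type])

    def n_edges(self, relation: str) -> int:
        return len(self.edges[relation])

    def index_of(self, node_type: str, node_id: str) -> int:
        return self._index[node_type][node_id]

    @property
    def node_type_counts(self) -> dict[str, int]:
        return {t: self.n_nodes(t) for t in NODE_TYPES}

    @property
    def edge_counts(self) -> dict[str, int]:
        return {r: self.n_edges(r) for r in METAGRAPH}

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check metagraph conformance and index integrity.

        Raises :class:`SchemaError` for unknown relations or heterogeneity
        violations and :class:`ReferentialError` for out-of-range endpoints.
        """
        present_types = {t for t in NODE_TYPES if self.n_nodes(t)}
        present_rels = {r for r in self.edges if self.n_edges(r)}
        if present_rels and len(present_types) + len(present_rels) <= 2:
            raise SchemaError(
                "graph is not heterogeneous: |A| + |R| must exceed 2, got "
                f"{len(present_types)} types and {len(present_rels)} relations"
            )
        for r, e in self.edges.items():
            if r not in METAGRAPH:
                raise SchemaError(f"unknown relation {r!r}; permitted: {sorted(METAGRAPH)}")
            ta, tb = METAGRAPH[r]
            if len(e) == 0:
                continue
            if e[:, 0].min() < 0 or e[:, 0].max() >= self.n_nodes(ta):
                raise ReferentialError(f"relation {r}: source index out of range for type {ta}")
            if e[:, 1].min() < 0 or e[:, 1].max() >= self.n_nodes(tb):
                raise ReferentialError(f"relation {r}: target index out of range for type {tb}")
        for t, ids in self.node_ids.items():
            if len(ids) != len(set(ids)):
                raise SchemaError(f"duplicate node ids within type {t}")
            if t in self.features and self.features[t] is not None:
                if self.features[t].shape[0] != len(ids):
                    raise ReferentialError(
                        f"feature matrix for type {t} has {self.features[t].shape[0]} rows "
                        f"but the type has {len(ids)} nodes"
                    )

    # -- adjacency ---------------------------------------------------------
    def biadjacency(self, relation: str) -> sp.csr_matrix:
        """Sparse 0/1 incidence of a relation, shape (n_source_type, n_target_type).

        For G-G the matrix is symmetrized (undirected interactions).
        """
        ta, tb = METAGRAPH[relation]
        e = self.edges[relation]
        m = sp.csr_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])),
            shape=(self.n_nodes(ta), self.n_nodes(tb)),
        )
        if ta == tb:
            m = m.maximum(m.T)
        m.data[:] = 1.0
        return m

    def get_features(self, node_type: str) -> np.ndarray | None:
        f = self.features.get(node_type)
        return None if f is None else np.asarray(f, dtype=float)

    def copy_without_gd_edges(self, drop: np.ndarray) -> "HeteroGraph":
        """Return a copy whose G-D edge list excludes the given (g, d) pairs."""
        drop_set = {(int(a), int(b)) for a, b in np.asarray(drop).reshape(-1, 2)}
        gd = self.edges["G-D"]
        keep = np.array(
            [(int(a), int(b)) not in drop_set for a, b in gd], dtype=bool
        )
        edges = {r: e.copy() for r, e in self.edges.items()}
        edges["G-D"] = gd[keep]
        return HeteroGraph(
            node_ids={t: list(v) for t, v in self.node_ids.items()},
            edges=edges,
            features={t: v for t, v in self.features.items()},
        )


# ---------------------------------------------------------------------------
# Metapaths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetapathSpec:
    """A typed path pattern with equal endpoint types, e.g. ``GDG``."""

    name: str
    type_sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        seq = self.type_sequence
        if len(seq) < 2:
            raise SchemaError(f"metapath {self.name}: needs at least two types")
        if seq[0] != seq[-1]:
            raise SchemaError(
                f"metapath {self.name}: endpoint types differ ({seq[0]} vs {seq[-1]})"
            )
        for a, b in zip(seq, seq[1:]):
            if not self._relation_of(a, b):
                raise SchemaError(
                    f"metapath {self.name}: no metagraph relation between {a} and {b}"
                )

    @staticmethod
    def _relation_of(a: str, b: str) -> str | None:
        for r, (ta, tb) in METAGRAPH.items():
            if (a, b) in ((ta, tb), (tb, ta)):
                return r
        return None

    @property
    def endpoint_type(self) -> str:
        return self.type_sequence[0]

    @property
    def relation_sequence(self) -> tuple[str, ...]:
        return tuple(
            self._relation_of(a, b)  # type: ignore[misc]
            for a, b in zip(self.type_sequence, self.type_sequence[1:])
        )


#: Default registry: GG, GDG, GOG for genes; DGD, DSD for diseases.
DEFAULT_METAPATHS: dict[str, MetapathSpec] = {
    "GG": MetapathSpec("GG", ("G", "G")),
    "GDG": MetapathSpec("GDG", ("G", "D", "G")),
    "GOG": MetapathSpec("GOG", ("G", "O", "G")),
    "DGD": MetapathSpec("DGD", ("D", "G", "D")),
    "DSD": MetapathSpec("DSD", ("D", "S", "D")),
}

#: Metapaths registered per endpoint type, in a fixed order.
METAPATHS_BY_TYPE: dict[str, tuple[str, ...]] = {
    "G": ("GG", "GDG", "GOG"),
    "D": ("DGD", "DSD"),
}


@dataclass
class MetapathGraph:
    """Homogeneous graph over one node type induced by one metapath.

    ``adjacency`` is a symmetric sparse matrix whose (u, v) entry counts the
    distinct metapath instances connecting u to v; the diagonal is zero.
    """

    metapath: MetapathSpec
    adjacency: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, node: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[node] : self.adjacency.indptr[node + 1]
        ]

    def degree(self, node: int) -> int:
        return int(self.adjacency.indptr[node + 1] - self.adjacency.indptr[node])


def build_metapath_graph(g: HeteroGraph, m: MetapathSpec) -> MetapathGraph:
    """Induce the homogeneous graph of metapath ``m`` over ``g``.

    The weight of edge (u, v) is the number of distinct metapath instances
    u -> ... -> v, obtained by chaining the per-step incidence matrices.
    Self-loops from trivial back-tracking (u -> x -> u reusing an edge) are
    removed: the diagonal is zeroed.
    """
    seq = m.type_sequence
    rels = m.relation_sequence
    for r in rels:
        if g.n_edges(r) == 0 and g.n_nodes(METAGRAPH[r][0]) == 0:
            raise SchemaError(f"metapath {m.name}: relation {r} absent from graph")
    acc: sp.csr_matrix | None = None
    for (a, b), r in zip(zip(seq, seq[1:]), rels):
        step = g.biadjacency(r)
        if METAGRAPH[r] != (a, b):  # traversed against the stored orientation
            step = step.T.tocsr()
        acc = step if acc is None else (acc @ step).tocsr()
    assert acc is not None
    if len(seq) > 2:
        acc = acc.tolil()
        acc.setdiag(0)
        acc = acc.tocsr()
    acc.eliminate_zeros()
    acc = acc.maximum(acc.T)  # instance counts are symmetric already; be safe
    acc.sort_indices()
    return MetapathGraph(metapath=m, adjacency=acc)


def sample_neighbors(
    mg: MetapathGraph,
    node: int,
    limit: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample up to ``limit`` neighbors of ``node`` uniformly without replacement.

    The target node itself is always appended last, so the result has at most
    ``limit + 1`` entries and never fewer than one.  Isolated nodes yield just
    ``[node]``.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    nbrs = mg.neighbors(node)
    if len(nbrs) > limit:
        if rng is None:
            rng = np.random.default_rng(seed)
        nbrs = rng.choice(nbrs, size=limit, replace=False)
        nbrs = np.sort(nbrs)
    return np.concatenate([nbrs, [node]]).astype(np.int64)


def sample_neighbor_mask(
    mg: MetapathGraph, limit: int, rng: np.random.Generator
) -> np.ndarray:
    """Dense boolean neighborhood mask with per-row sampling and self-loops.

    Row i marks the sampled neighborhood of node i (including i itself);
    vectorized counterpart of :func:`sample_neighbors` for model forward
    passes on small graphs.
    """
    n = mg.n_nodes
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        mask[i, sample_neighbors(mg, i, limit=limit, rng=rng)] = True
    return mask


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _read_edge_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected at least two ID columns")
    df = df.iloc[:, :2]
    df.columns = ["source", "target"]
    return df.dropna()


def load_hetnet(
    edge_files: str | dict[str, str],
    feature_files: dict[str, str] | None = None,
) -> HeteroGraph:
    """Load a heterogeneous network from per-relation edge-list files.

    ``edge_files`` is either a directory containing the conventional file
    names of :data:`RELATION_FILES`, or an explicit mapping from relation
    name (e.g. ``"G-D"``) to file path.  Each file holds one edge per row
    with two ID columns (header row expected; TSV or CSV).  Duplicate rows
    collapse to a single edge and all edge weights are implicitly 1.
    Missing relation files yield empty relations.

    Optional ``feature_files`` map node type to a dense table whose first
    column is the node ID; when given for a type, that table defines the
    node universe of the type and any edge endpoint absent from it raises
    :class:`ReferentialError`.
    """
    if isinstance(edge_files, str):
        edge_files = {
            r: os.path.join(edge_files, fname)
            for r, fname in RELATION_FILES.items()
            if os.path.exists(os.path.join(edge_files, fname))
        }
    for r in edge_files:
        if r not in METAGRAPH:
            raise SchemaError(f"unknown relation {r!r}; permitted: {sorted(METAGRAPH)}")

    tables = {r: _read_edge_table(path) for r, path in edge_files.items()}

    feature_tables: dict[str, pd.DataFrame] = {}
    node_ids: dict[str, list[str]] = {}
    if feature_files:
        for t, path in feature_files.items():
            ft = pd.read_csv(path, sep=None, engine="python")
            ft = ft.set_index(ft.columns[0])
            ft.index = ft.index.astype(str)
            feature_tables[t] = ft
            node_ids[t] = list(ft.index)

    # node universe per type: feature table when given, else union of endpoints
    seen: dict[str, set[str]] = {t: set() for t in NODE_TYPES}
    for r, df in tables.items():
        ta, tb = METAGRAPH[r]
        seen[ta].update(df["source"])
        seen[tb].update(df["target"])
    for t in NODE_TYPES:
        if t not in node_ids:
            node_ids[t] = sorted(seen[t])
        else:
            missing = seen[t] - set(node_ids[t])
            if missing:
                raise ReferentialError(
                    f"type {t}: {len(missing)} edge endpoint(s) absent from feature "
                    f"table, e.g. {sorted(missing)[:3]}"
                )

    index = {t: {nid: i for i, nid in enumerate(node_ids[t])} for t in NODE_TYPES}
    edges: dict[str, np.ndarray] = {}
    for r, df in tables.items():
        ta, tb = METAGRAPH[r]
        src = df["source"].map(index[ta])
        dst = df["target"].map(index[tb])
        pairs = np.stack([src.to_numpy(np.int64), dst.to_numpy(np.int64)], axis=1)
        if ta == tb:  # canonicalize undirected same-type pairs before dedup
            pairs = np.sort(pairs, axis=1)
        edges[r] = np.unique(pairs, axis=0)

    features = {
        t: ft.to_numpy(dtype=float) for t, ft in feature_tables.items()
    }
    g = HeteroGraph(node_ids=node_ids, edges=edges, features=features)
    g.validate()
    return g


def verify_dataset_statistics(
    g: HeteroGraph,
    node_counts: dict[str, int] = DEPOSITED_NODE_COUNTS,
    edge_counts: dict[str, int] = DEPOSITED_EDGE_COUNTS,
) -> dict[str, dict]:
    """Compare a loaded graph against reference node/relation counts.

    Returns ``{"node_counts": {...}, "edge_counts": {...}, "ok": bool}``
    where each per-type/per-relation entry holds ``(expected, observed,
    match)``.  Defaults to the published statistics of the deposited
    disease-gene network.
    """
    report: dict[str, dict] = {"node_counts": {}, "edge_counts": {}}
    ok = True
    for t, expected in node_counts.items():
        observed = g.n_nodes(t)
        match = observed == expected
        ok &= match
        report["node_counts"][t] = {
            "expected": expected, "observed": observed, "match": match,
        }
    for r, expected in edge_counts.items():
        observed = g.n_edges(r)
        match = observed == expected
        ok &= match
        report["edge_counts"][r] = {
            "expected": expected, "observed": observed, "match": match,
        }
    report["ok"] = ok
    return report


# ---------------------------------------------------------------------------
# Train/test splitting with negative sampling
# ---------------------------------------------------------------------------


class NegativeSamplingError(RuntimeError):
    """Requested more negative pairs than non-edges exist."""


@dataclass
class EdgeSplit:
    """Train/test partition of G-D positives plus sampled non-edge negatives.

    All arrays are ``(k, 2)`` integer (gene-index, disease-index) pairs.
    Negatives are drawn from pairs absent from the *original* positive set,
    so no negative is a positive anywhere in the split.
    """

    train_pos: np.ndarray
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray

    _PARTS = ("train_pos", "train_neg", "test_pos", "test_neg")

    def part(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def save_tsv(self, out_dir: str, g: HeteroGraph | None = None) -> list[str]:
        """Write the four partitions as TSV files (original IDs when ``g`` given)."""
        os.makedirs(out_dir, exist_ok=True)
        paths = []
        for name in self._PARTS:
            arr = self.part(name)
            if g is not None:
                df = pd.DataFrame(
                    {
                        "gene": [g.node_ids["G"][i] for i in arr[:, 0]],
                        "disease": [g.node_ids["D"][j] for j in arr[:, 1]],
                    }
                )
            else:
                df = pd.DataFrame({"gene": arr[:, 0], "disease": arr[:, 1]})
            path = os.path.join(out_dir, f"{name}.tsv")
            df.to_csv(path, sep="\t", index=False)
            paths.append(path)
        return paths

    @classmethod
    def load_tsv(cls, in_dir: str, g: HeteroGraph) -> "EdgeSplit":
        parts = {}
        for name in cls._PARTS:
            df = pd.read_csv(os.path.join(in_dir, f"{name}.tsv"), sep="\t", dtype=str)
            parts[name] = np.array(
                [
                    [g.index_of("G", a), g.index_of("D", b)]
                    for a, b in zip(df["gene"], df["disease"])
                ],
                dtype=np.int64,
            ).reshape(-1, 2)
        return cls(**parts)


def _pair_keys(pairs: np.ndarray, n_d: int) -> np.ndarray:
    return pairs[:, 0].astype(np.int64) * n_d + pairs[:, 1].astype(np.int64)


def make_split(
    g: HeteroGraph,
    test_fraction: float = 0.2,
    neg_ratio: float = 1.0,
    seed: int = 0,
) -> EdgeSplit:
    """Partition G-D positives and sample matched non-edge negatives.

    Positives are split uniformly at random into train/test; each partition
    receives ``round(neg_ratio * |positives|)`` negatives sampled uniformly
    without replacement from gene-disease pairs absent from the full
    positive set.  Reproducible under ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be positive")
    rng = np.random.default_rng(seed)
    pos = g.edges["G-D"]
    n_g, n_d = g.n_nodes("G"), g.n_nodes("D")
    n_pos = len(pos)
    if n_pos == 0:
        raise ValueError("graph has no G-D positives to split")

    perm = rng.permutation(n_pos)
    n_test = int(round(test_fraction * n_pos))
    test_pos = pos[perm[:n_test]]
    train_pos = pos[perm[n_test:]]

    pos_keys = set(_pair_keys(pos, n_d).tolist())
    n_neg_train = int(round(neg_ratio * len(train_pos)))
    n_neg_test = int(round(neg_ratio * len(test_pos)))
    n_needed = n_neg_train + n_neg_test
    n_non_edges = n_g * n_d - n_pos
    if n_needed > n_non_edges:
        raise NegativeSamplingError(
            f"need {n_needed} negatives but only {n_non_edges} non-edges exist"
        )

    chosen: list[int] = []
    chosen_set: set[int] = set()
    if n_needed > 0.25 * n_non_edges or n_g * n_d <= 200_000:
        # dense regime: enumerate the complement exactly
        all_keys = np.setdiff1d(
            np.arange(n_g * n_d, dtype=np.int64),
            np.fromiter(pos_keys, dtype=np.int64, count=len(pos_keys)),
            assume_unique=True,
        )
        chosen = rng.choice(all_keys, size=n_needed, replace=False).tolist()
    else:
        while len(chosen) < n_needed:
            cand = rng.integers(0, n_g * n_d, size=2 * (n_needed - len(chosen)))
            for k in cand:
                k = int(k)
                if k in pos_keys or k in chosen_set:
                    continue
                chosen.append(k)
                chosen_set.add(k)
                if len(chosen) == n_needed:
                    break
    neg = np.array(chosen, dtype=np.int64)
    neg_pairs = np.stack([neg // n_d, neg % n_d], axis=1)
    return EdgeSplit(
        train_pos=train_pos,
        train_neg=neg_pairs[:n_neg_train],
        test_pos=test_pos,
        test_neg=neg_pairs[n_neg_train:],
    )


def training_graph(g: HeteroGraph, split: EdgeSplit) -> HeteroGraph:
    """Copy of ``g`` with test positives removed from the G-D edge list.

    Metapath graphs built on the result cannot leak held-out links through
    G-D-traversing metapath instances.
    """
    return g.copy_without_gd_edges(split.test_pos)
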