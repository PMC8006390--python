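"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, path enumeration)
and shares no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from hetfactor.hetnet import METAGRAPH, HeteroGraph, MetapathSpec


def brute_force_metapath_counts(
    g: HeteroGraph, m: MetapathSpec
) -> dict[tuple[int, int], int]:
    """Count metapath instances by explicit path enumeration.

    Returns {(u, v): count} over ordered endpoint pairs u != v.
    """
    seq = m.type_sequence
    # adjacency lookup per step, honoring relation orientation
    steps = []
    for a, b in zip(seq, seq[1:]):
        nbrs: dict[int, list[int]] = {}
        for r, (ta, tb) in METAGRAPH.items():
            if (a, b) == (ta, tb):
                for s, t in g.edges[r]:
                    nbrs.setdefault(int(s), []).append(int(t))
                    if ta == tb:
                        nbrs.setdefault(int(t), []).append(int(s))
            elif (a, b) == (tb, ta):
                for s, t in g.edges[r]:
                    nbrs.setdefault(int(t), []).append(int(s))
        steps.append(nbrs)
    counts: dict[tuple[int, int], int] = {}

    def walk(pos: int, node: int, start: int) -> None:
        if pos == len(steps):
            if node != start:
                counts[(start, node)] = counts.get((start, node), 0) + 1
            return
        for nxt in steps[pos].get(node, []):
            walk(pos + 1, nxt, start)

    for start in range(g.n_nodes(seq[0])):
        walk(0, start, start)
    return counts


def random_hetgraph(rng: np.random.Generator, max_nodes: int = 50) -> HeteroGraph:
    """A random metagraph-conforming heterogeneous graph for oracle trials."""
    counts = {t: int(rng.integers(2, max(3, max_nodes // 4))) for t in "GDOS"}
    edges = {}
    for r, (ta, tb) in METAGRAPH.items():
        density = rng.uniform(0.05, 0.4)
        na, nb = counts[ta], counts[tb]
        pairs = []
        for i in range(na):
            for j in range(nb):
                if ta == tb and j <= i:
                    continue
                if rng.random() < density:
                    pairs.append((i, j))
        edges[r] = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    node_ids = {t: [f"{t}{i}" for i in range(n)] for t, n in counts.items()}
    return HeteroGraph(node_ids=node_ids, edges=edges)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def brute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-averaged AUC by enumerating every positive-negative pair."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_ap(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision by stepwise precision-recall summation."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    n_pos = labels.sum()
    ap, tp = 0.0, 0
    for k, lab in enumerate(labels, start=1):
        if lab == 1:
            tp += 1
            ap += (tp / k) / n_pos
    return ap


def brute_topk(scores: np.ndarray, labels: np.ndarray, k: int) -> tuple[float, float]:
    """Precision and recall at the K-th largest score, stable tie order."""
    order = np.argsort(-scores, kind="stable")[:k]
    hits = labels[order].sum()
    return hits / k, hits / labels.sum()


# ---------------------------------------------------------------------------
# Attention reference (naive, per-node loops)
# ---------------------------------------------------------------------------


def naive_metapath_embed(
    h: np.ndarray,
    layer: dict,
    W_e: np.ndarray,
    mask: np.ndarray,
    slope: float = 0.2,
    apply_elu: bool = True,
) -> np.ndarray:
    """Loop-based reference for per-metapath embeddings.

    For every factor and head: transformed features, LeakyReLU pair logits
    shifted by log edge weight (self weight 1), per-neighborhood softmax,
    weighted sum, optional ELU; concatenated factor-major, head-minor.
    """
    n_f, n_k = layer["W"].shape[0], layer["W"].shape[1]
    n, d_head = h.shape[0], layer["W"].shape[2]
    out = np.zeros((n, n_f * n_k * d_head))
    for f in range(n_f):
        for k in range(n_k):
            Wk = layer["W"][f, k]
            ht = np.array([Wk @ h[i] for i in range(n)])
            for i in range(n):
                nbrs = [j for j in range(n) if mask[i, j]]
                logits = []
                for j in nbrs:
                    x = layer["a_src"][f, k] @ ht[i] + layer["a_dst"][f, k] @ ht[j]
                    x = x if x >= 0 else slope * x
                    w = 1.0 if j == i else W_e[f, i, j]
                    logits.append(x + np.log(w))
                logits = np.array(logits)
                e = np.exp(logits - logits.max())
                alpha = e / e.sum()
                z = sum(a * ht[j] for a, j in zip(alpha, nbrs))
                if apply_elu:
                    z = np.where(z >= 0, z, np.exp(z) - 1.0)
                block = (f * n_k + k) * d_head
                out[i, block : block + d_head] = z
    return out
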