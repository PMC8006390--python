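"""Training loop, link-prediction metrics, and candidate-gene ranking.

Training is full-batch gradient descent with Adam and an L2 penalty
(reference settings: learning rate 0.005, penalty weight 0.001), the
combined objective being the link binary cross-entropy plus gamma times
the factor-discrimination loss.  Neighborhoods are resampled every epoch
under a per-epoch seed derived from the run seed; a validation slice
carved from the training pairs drives optional early stopping on AUC.

Evaluation reports AP (area under the precision-recall curve), ROC AUC,
and Precision@K / Recall@K computed by thresholding at the K-th largest
predicted score over the pooled held-out positives and negatives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.tracer import getval
from sklearn.metrics import average_precision_score, roc_auc_score

from .hetnet import EdgeSplit, HeteroGraph, training_graph
from .model import (
    GraphContext,
    ModelConfig,
    build_context,
    factor_loss,
    forward,
    init_params,
    neighborhood_masks,
    prediction_loss,
    score_pairs,
    total_loss,
)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (reference defaults)."""

    learning_rate: float = 0.005
    weight_decay: float = 0.001
    epochs: int = 200
    gamma: float = 1.0
    neighbor_limit: int = 100
    seed: int = 0
    optimizer: str = "adam"
    patience: int = 30
    val_fraction: float = 0.1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Parameter-tree utilities and Adam
# ---------------------------------------------------------------------------


def tree_map(f, *trees):
    """Apply ``f`` leaf-wise across identically shaped nested dicts."""
    first = trees[0]
    if isinstance(first, dict):
        return {k: tree_map(f, *(t[k] for t in trees)) for k in first}
    return f(*trees)


def tree_leaves(tree) -> list:
    if isinstance(tree, dict):
        return [leaf for v in tree.values() for leaf in tree_leaves(v)]
    return [tree]


class Adam:
    """Standard Adam with coupled L2 weight decay added to the gradient."""

    def __init__(self, params, lr=0.005, weight_decay=0.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2

        def upd(p, g, m, v):
            g = g + self.wd * p
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            return p - self.lr * mhat / (np.sqrt(vhat) + self.eps)

        return tree_map(upd, params, grads, self.m, self.v)


class SGD:
    """Plain gradient descent with L2 penalty (mostly for tests)."""

    def __init__(self, params, lr=0.005, weight_decay=0.0):
        self.lr, self.wd = lr, weight_decay

    def step(self, params, grads):
        return tree_map(lambda p, g: p - self.lr * (g + self.wd * p), params, grads)


_OPTIMIZERS = {"adam": Adam, "sgd": SGD}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained parameter set bound to its training graph context."""

    params: dict
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    ctx: GraphContext
    node_ids: dict[str, list[str]]
    train_pos: np.ndarray
    dropped_gd: np.ndarray  # test positives removed before metapath building
    trace: list[dict] = field(default_factory=list)

    def embeddings(self, seed: int | None = None) -> dict[str, np.ndarray]:
        """Final node embeddings H per endpoint type.

        Neighborhoods are sampled deterministically from ``seed`` (default:
        the training seed); nodes within the neighbor limit always use
        their full neighborhood.
        """
        seed = self.train_cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        masks = neighborhood_masks(self.ctx, self.train_cfg.neighbor_limit, rng)
        H, _, _ = forward(self.params, self.ctx, self.model_cfg, masks)
        return {t: np.asarray(v) for t, v in H.items()}

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: parameters + configs + id maps (.npz)."""
        flat: dict[str, np.ndarray] = {}

        def _walk(tree, prefix):
            if isinstance(tree, dict):
                for k, v in tree.items():
                    _walk(v, f"{prefix}/{k}")
            else:
                flat[f"param{prefix}"] = np.asarray(tree)

        _walk(self.params, "")
        meta = {
            "model_cfg": self.model_cfg.to_dict(),
            "train_cfg": self.train_cfg.to_dict(),
            "node_ids": self.node_ids,
            "trace": self.trace,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            __train_pos__=self.train_pos,
            __dropped_gd__=self.dropped_gd,
            **flat,
        )

    @staticmethod
    def load(path: str, g: HeteroGraph) -> "TrainedModel":
        """Restore a checkpoint; ``g`` must be the graph it was trained on."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params: dict = {}
            for key in data.files:
                if not key.startswith("param/"):
                    continue
                node = params
                *parents, leaf = key[len("param/"):].split("/")
                for p in parents:
                    node = node.setdefault(p, {})
                node[leaf] = data[key]
            train_pos = data["__train_pos__"]
            dropped = data["__dropped_gd__"]
        model_cfg = ModelConfig.from_dict(meta["model_cfg"])
        train_cfg = TrainConfig.from_dict(meta["train_cfg"])
        if meta["node_ids"] != {t: list(v) for t, v in g.node_ids.items()}:
            raise ValueError(
                "checkpoint id maps do not match the provided graph"
            )
        tg = g.copy_without_gd_edges(dropped) if len(dropped) else g
        ctx = build_context(tg, model_cfg, seed=train_cfg.seed)
        return TrainedModel(
            params=params,
            model_cfg=model_cfg,
            train_cfg=train_cfg,
            ctx=ctx,
            node_ids=meta["node_ids"],
            train_pos=train_pos,
            dropped_gd=dropped,
            trace=meta["trace"],
        )


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng([seed, epoch])


def train(
    g: HeteroGraph,
    split: EdgeSplit,
    train_cfg: TrainConfig | None = None,
    model_cfg: ModelConfig | None = None,
) -> TrainedModel:
    """Fit the model on a graph and edge split; returns model + loss trace.

    The test positives are removed from the graph before metapath
    construction, so held-out links cannot leak through metapath instances.
    The trace records, per epoch, the link loss, factor loss, total loss
    and validation AUC.  Identical config and seed give identical traces.
    """
    train_cfg = train_cfg or TrainConfig()
    model_cfg = model_cfg or ModelConfig()
    tg = training_graph(g, split)
    ctx = build_context(tg, model_cfg, seed=train_cfg.seed)
    params = init_params(ctx, model_cfg, seed=train_cfg.seed)

    rng = np.random.default_rng(train_cfg.seed)
    n_val_pos = int(round(train_cfg.val_fraction * len(split.train_pos)))
    n_val_neg = int(round(train_cfg.val_fraction * len(split.train_neg)))
    pos_perm = rng.permutation(len(split.train_pos))
    neg_perm = rng.permutation(len(split.train_neg))
    val_pos = split.train_pos[pos_perm[:n_val_pos]]
    fit_pos = split.train_pos[pos_perm[n_val_pos:]]
    val_neg = split.train_neg[neg_perm[:n_val_neg]]
    fit_neg = split.train_neg[neg_perm[n_val_neg:]]
    use_val = len(val_pos) > 0 and len(val_neg) > 0

    opt = _OPTIMIZERS[train_cfg.optimizer](
        params, lr=train_cfg.learning_rate, weight_decay=train_cfg.weight_decay
    )

    aux: dict = {}  # raw per-pass values siphoned out of the traced objective

    def objective(p, masks):
        H, _, enc = forward(p, ctx, model_cfg, masks)
        l_pred = prediction_loss(
            score_pairs(H["G"], H["D"], fit_pos),
            score_pairs(H["G"], H["D"], fit_neg),
        )
        l_fac = factor_loss(enc, p["clf"])
        aux["l_pred"] = float(getval(l_pred))
        aux["l_factor"] = float(getval(l_fac))
        aux["H"] = {t: np.asarray(getval(v)) for t, v in H.items()}
        return total_loss(l_pred, l_fac, train_cfg.gamma)

    grad_fn = value_and_grad(objective)

    trace: list[dict] = []
    best_auc, best_params, best_epoch = -np.inf, params, -1
    for epoch in range(train_cfg.epochs):
        masks = neighborhood_masks(
            ctx, train_cfg.neighbor_limit, _epoch_rng(train_cfg.seed, epoch)
        )
        loss, grads = grad_fn(params, masks)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={loss!r}; "
                "reduce the learning rate or gamma"
            )
        prev_params = params
        params = opt.step(params, grads)
        H = aux["H"]  # pre-update forward; matches prev_params
        record = {
            "epoch": epoch,
            "l_pred": aux["l_pred"],
            "l_factor": aux["l_factor"],
            "total": float(loss),
            "val_auc": float("nan"),
        }
        if use_val:
            val_scores = np.concatenate(
                [
                    np.asarray(score_pairs(H["G"], H["D"], val_pos)),
                    np.asarray(score_pairs(H["G"], H["D"], val_neg)),
                ]
            )
            val_y = np.r_[np.ones(len(val_pos)), np.zeros(len(val_neg))]
            record["val_auc"] = float(roc_auc_score(val_y, val_scores))
            if record["val_auc"] > best_auc:
                best_auc = record["val_auc"]
                best_params = tree_map(np.copy, prev_params)
                best_epoch = epoch
        trace.append(record)
        if (
            use_val
            and train_cfg.patience > 0
            and epoch - best_epoch >= train_cfg.patience
        ):
            break
    if use_val and best_epoch >= 0:
        params = best_params

    return TrainedModel(
        params=params,
        model_cfg=model_cfg,
        train_cfg=train_cfg,
        ctx=ctx,
        node_ids={t: list(v) for t, v in tg.node_ids.items()},
        train_pos=np.asarray(split.train_pos),
        dropped_gd=np.asarray(split.test_pos),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Link-prediction metrics over a held-out pool."""

    ap: float
    auc: float
    precision_at: dict[int, float]
    recall_at: dict[int, float]
    scores: pd.DataFrame  # columns: gene, disease, score, label

    def to_dict(self) -> dict:
        return {
            "AP": self.ap,
            "AUC": self.auc,
            "precision_at": {str(k): v for k, v in self.precision_at.items()},
            "recall_at": {str(k): v for k, v in self.recall_at.items()},
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def precision_recall_at_k(
    scores: np.ndarray, labels: np.ndarray, k: int
) -> tuple[float, float]:
    """Precision and recall at the K-th largest score threshold.

    Ties are broken by stable order (original pool position).
    """
    if k > len(scores):
        warnings.warn(
            f"K={k} exceeds pool size {len(scores)}; truncating", stacklevel=2
        )
        k = len(scores)
    order = np.argsort(-scores, kind="stable")
    top = labels[order[:k]]
    n_pos = labels.sum()
    precision = float(top.sum() / k) if k else 0.0
    recall = float(top.sum() / n_pos) if n_pos else 0.0
    return precision, recall


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, k_list: tuple[int, ...]
) -> tuple[float, float, dict[int, float], dict[int, float]]:
    """AP, tie-averaged AUC, and P@K / R@K for a pooled score vector."""
    ap = float(average_precision_score(labels, scores))
    auc = float(roc_auc_score(labels, scores))
    p_at, r_at = {}, {}
    for k in k_list:
        p_at[k], r_at[k] = precision_recall_at_k(scores, labels, k)
    return ap, auc, p_at, r_at


def evaluate(
    model: TrainedModel,
    split: EdgeSplit,
    k_list: tuple[int, ...] = (1000, 10000, 20000),
    seed: int | None = None,
) -> EvalReport:
    """Score the held-out pool and compute AP / AUC / P@K / R@K.

    AUC uses the tie-averaged rank convention (pairs with equal scores
    count one half).
    """
    if len(split.test_pos) == 0 or len(split.test_neg) == 0:
        raise ValueError("test positives and negatives must both be non-empty")
    H = model.embeddings(seed=seed)
    pairs = np.vstack([split.test_pos, split.test_neg])
    labels = np.r_[
        np.ones(len(split.test_pos)), np.zeros(len(split.test_neg))
    ]
    scores = np.asarray(score_pairs(H["G"], H["D"], pairs))
    ap, auc, p_at, r_at = compute_metrics(scores, labels, k_list)
    df = pd.DataFrame(
        {
            "gene": [model.node_ids["G"][i] for i in pairs[:, 0]],
            "disease": [model.node_ids["D"][j] for j in pairs[:, 1]],
            "score": scores,
            "label": labels.astype(int),
        }
    )
    return EvalReport(ap=ap, auc=auc, precision_at=p_at, recall_at=r_at, scores=df)


def roc_pr_points(report: EvalReport) -> pd.DataFrame:
    """ROC and PR curve points from a report's pooled scores."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    y = report.scores["label"].to_numpy()
    s = report.scores["score"].to_numpy()
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    roc = pd.DataFrame({"curve": "roc", "x": fpr, "y": tpr})
    pr = pd.DataFrame({"curve": "pr", "x": rec, "y": prec})
    return pd.concat([roc, pr], ignore_index=True)


# ---------------------------------------------------------------------------
# Candidate-gene ranking
# ---------------------------------------------------------------------------


def rank_candidates(
    model: TrainedModel,
    disease: str | int,
    top_k: int = 20,
    exclude_known: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank all genes by predicted association with one disease.

    Returns the ``top_k`` genes as a DataFrame (rank, gene, score), sorted
    by descending score with ties kept in gene-index order.  With
    ``exclude_known`` the genes already linked to the disease in the
    training positives are removed before ranking.
    """
    if isinstance(disease, str):
        try:
            d_idx = model.node_ids["D"].index(disease)
        except ValueError:
            near = [x for x in model.node_ids["D"] if disease in x][:5]
            raise KeyError(
                f"unknown disease id {disease!r}"
                + (f"; nearest ids: {near}" if near else "")
            ) from None
    else:
        d_idx = int(disease)
        if not 0 <= d_idx < len(model.node_ids["D"]):
            raise KeyError(f"disease index {d_idx} out of range")
    H = model.embeddings(seed=seed)
    genes = np.arange(len(model.node_ids["G"]))
    if exclude_known:
        known = set(
            model.train_pos[model.train_pos[:, 1] == d_idx, 0].tolist()
        )
        genes = np.array([i for i in genes if i not in known], dtype=np.int64)
    if len(genes) == 0:
        return pd.DataFrame(columns=["rank", "gene", "score"])
    pairs = np.stack([genes, np.full(len(genes), d_idx)], axis=1)
    scores = np.asarray(score_pairs(H["G"], H["D"], pairs))
    order = np.argsort(-scores, kind="stable")[:top_k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "gene": [model.node_ids["G"][genes[i]] for i in order],
            "score": scores[order],
        }
    )
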