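"""Portable JSON serialization for trained models.

Linear models serialize to their coefficient vector.  Forests serialize to a
tree list with per-node split feature, threshold, children, leaf values and
covers — enough to reload, predict, and attribute without scikit-learn's
binary formats.  Reloaded trees are lightweight array-backed structures that
expose the same node-array interface the rest of the package consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from fedsurvey.fed_models import ForestHyperparams, ForestModel, LinearModel

__all__ = ["save_model", "load_model", "PlainTree"]


class _PlainTreeArrays:
    """Node arrays mirroring sklearn's fitted ``tree_`` attribute."""

    def __init__(self, d: dict) -> None:
        self.children_left = np.asarray(d["children_left"], dtype=np.int64)
        self.children_right = np.asarray(d["children_right"], dtype=np.int64)
        self.feature = np.asarray(d["feature"], dtype=np.int64)
        self.threshold = np.asarray(d["threshold"], dtype=np.float64)
        self.value = np.asarray(d["value"], dtype=np.float64)
        self.n_node_samples = np.asarray(d["n_node_samples"], dtype=np.int64)
        self.weighted_n_node_samples = np.asarray(d["weighted_n_node_samples"], dtype=np.float64)


@dataclass
class PlainTree:
    """Array-backed decision tree reconstructed from JSON."""

    tree_: _PlainTreeArrays
    n_features_in_: int
    task: str

    def _leaf_of(self, X: np.ndarray) -> np.ndarray:
        t = self.tree_
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = t.children_left[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, t.feature[nd]] <= t.threshold[nd]
            node[idx] = np.where(go_left, t.children_left[nd], t.children_right[nd])
            active = t.children_left[node] >= 0
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        leaves = self._leaf_of(X)
        if self.task == "classification":
            return np.argmax(self.tree_.value[leaves, 0, :], axis=1).astype(float)
        return self.tree_.value[leaves, 0, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        leaves = self._leaf_of(X)
        proba = self.tree_.value[leaves, 0, :]
        return proba / proba.sum(axis=1, keepdims=True)


def _tree_to_dict(tree) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value.tolist(),
        "n_node_samples": t.n_node_samples.tolist(),
        "weighted_n_node_samples": t.weighted_n_node_samples.tolist(),
    }


def save_model(model: LinearModel | ForestModel, path: str | Path) -> None:
    if isinstance(model, LinearModel):
        payload = model.to_dict()
    elif isinstance(model, ForestModel):
        payload = {
            "kind": "forest",
            "task": model.task,
            "n_features": model.n_features,
            "origins": model.origins,
            "hyperparams": model.hyperparams.__dict__,
            "trees": [_tree_to_dict(t) for t in model.trees],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> LinearModel | ForestModel:
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "linear":
        return LinearModel.from_dict(payload)
    trees = [
        PlainTree(_PlainTreeArrays(d), payload["n_features"], payload["task"]) for d in payload["trees"]
    ]
    return ForestModel(
        trees,
        payload["origins"],
        payload["task"],
        payload["n_features"],
        ForestHyperparams(**payload["hyperparams"]),
    )
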