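"""Additive per-feature attribution (Shapley values) and top-k agreement.

Both model families support exact additive attribution: for a linear model
the Shapley value of feature j at sample x is βⱼ·(xⱼ − E[xⱼ]) with the
expectation taken over a background (training) sample; for tree ensembles
the exact path-dependent tree Shapley values are computed, marginalizing
absent features with the trees' own training cover.  In both cases local
accuracy holds per sample: attributions sum to the prediction minus the base
value (the background-mean prediction).

A model's feature-importance profile is the mean of absolute attributions
over a test set; `compare_top_k` checks whether two models (e.g. federated
vs. centralized) agree on their top-k features and their order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fedsurvey._treeshap import tree_shap_values
from fedsurvey.fed_models import ForestModel, LinearModel

__all__ = ["AttributionReport", "attribution_values", "feature_attribution", "compare_top_k"]


@dataclass
class AttributionReport:
    """Mean |attribution| per feature and the implied descending ranking."""

    mean_abs: pd.Series
    base_value: float
    model_label: str = ""

    @property
    def ranking(self) -> list[str]:
        return list(self.mean_abs.sort_values(ascending=False).index)

    def top_k(self, k: int) -> list[str]:
        return self.ranking[:k]

    def to_frame(self) -> pd.DataFrame:
        df = self.mean_abs.sort_values(ascending=False).rename("mean_abs_attribution").rename_axis("feature").reset_index()
        df.insert(0, "model", self.model_label)
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def _forest_phi(model: ForestModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    phi = np.zeros((X.shape[0], model.n_features))
    base = 0.0
    for t in model.trees:
        tr = t.tree_
        if model.task == "classification":
            vals = tr.value[:, 0, -1]  # positive-class proportion per node
        else:
            vals = tr.value[:, 0, 0]
        phi += tree_shap_values(
            tr.children_left,
            tr.children_right,
            tr.feature,
            tr.threshold,
            vals,
            tr.weighted_n_node_samples,
            X,
        )
        base += float(vals[0])
    n_trees = len(model.trees)
    return phi / n_trees, base / n_trees


def attribution_values(
    model: LinearModel | ForestModel,
    X: np.ndarray,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-sample attribution matrix (n × m) and the base value.

    Linear models need a ``background`` sample (typically the training
    matrix) whose column means define the expectation; tree ensembles carry
    their background in the node covers, so ``background`` is ignored.
    For classification forests the attributed output is the positive-class
    probability.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(model, LinearModel):
        if X.shape[1] != model.slopes.shape[0]:
            raise ValueError("feature dimension mismatch")
        if background is None:
            raise ValueError("linear attribution needs a background sample")
        mu = np.asarray(background, dtype=float).mean(axis=0)
        phi = model.slopes * (X - mu)
        base = float(model.intercept + model.slopes @ mu)
        return phi, base
    if isinstance(model, ForestModel):
        if X.shape[1] != model.n_features:
            raise ValueError("feature dimension mismatch")
        return _forest_phi(model, X)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def feature_attribution(
    model: LinearModel | ForestModel,
    X_test: np.ndarray,
    background: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    model_label: str = "",
) -> AttributionReport:
    """Mean absolute attribution of every feature on a test set."""
    phi, base = attribution_values(model, X_test, background=background)
    if feature_names is None:
        schema = getattr(model, "schema", None)
        feature_names = list(schema.names) if schema is not None else [f"x{j}" for j in range(phi.shape[1])]
    mean_abs = pd.Series(np.abs(phi).mean(axis=0), index=feature_names)
    return AttributionReport(mean_abs=mean_abs, base_value=base, model_label=model_label)


def compare_top_k(report_a: AttributionReport, report_b: AttributionReport, k: int = 5) -> tuple[int, bool]:
    """Top-k agreement between two attribution profiles.

    Returns the size of the intersection of the two top-k feature sets and
    whether the top-k lists agree in order.
    """
    if set(report_a.mean_abs.index) != set(report_b.mean_abs.index):
        raise ValueError("reports cover different feature sets")
    if k > len(report_a.mean_abs):
        raise ValueError(f"k={k} exceeds the feature count {len(report_a.mean_abs)}")
    top_a = report_a.top_k(k)
    top_b = report_b.top_k(k)
    overlap = len(set(top_a) & set(top_b))
    return overlap, top_a == top_b
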