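"""Learners for the local / centralized / federated scenarios.

Two model families:

* **Ordinary least squares**, federated *exactly* by sharing sufficient
  statistics: each site computes (XᵀX, Xᵀy, n) on its intercept-augmented
  design matrix, the sums over sites are formed (optionally under additive
  secret sharing, so the aggregator never sees a single site's statistics),
  and the global normal equations are solved once.  For every partition of
  a dataset the federated solution equals the pooled-data solution up to
  floating point (or fixed-point precision under SMPC).

* **Random forests**, federated by tree pooling: each site trains a standard
  random forest on its local rows, the trees are released under (ε, δ)-DP
  output perturbation (leaf values for regression, leaf class counts for
  classification), and the aggregator concatenates the trees into one
  ensemble that predicts by averaging tree outputs (soft voting for
  classification, so threshold-free scores are available).

scikit-learn provides the tree induction; the federation, privacy protection
and pooling logic live here.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from fedsurvey.fedcore import DPConfig, FedConfig, ProtocolTrace, dp_perturb, run_protocol, smpc_aggregate, smpc_share
from fedsurvey.synthetic_survey import VAS_RANGE, FeatureSchema, SurveyTable

__all__ = [
    "SufficientStats",
    "LinearModel",
    "ForestModel",
    "ForestHyperparams",
    "local_sufficient_stats",
    "fed_ols",
    "centralized_ols",
    "train_local_forest",
    "dp_protect_forest",
    "aggregate_forests",
    "fed_forest",
    "predict",
]


@dataclass
class SufficientStats:
    """(XᵀX, Xᵀy, n) on the intercept-augmented design; additive over sites."""

    xtx: np.ndarray
    xty: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.xtx = np.asarray(self.xtx, dtype=float)
        self.xty = np.asarray(self.xty, dtype=float)
        p = self.xty.shape[0]
        if self.xtx.shape != (p, p):
            raise ValueError("xtx must be square and conformable with xty")
        if not np.allclose(self.xtx, self.xtx.T, atol=1e-8):
            raise ValueError("xtx must be symmetric")

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        return SufficientStats(self.xtx + other.xtx, self.xty + other.xty, self.n + other.n)


@dataclass
class LinearModel:
    """OLS fit; ``coefficients[0]`` is the intercept."""

    coefficients: np.ndarray
    schema: FeatureSchema | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.slopes.shape[0]:
            raise ValueError("feature dimension mismatch")
        return self.intercept + X @ self.slopes

    def to_dict(self) -> dict:
        return {"kind": "linear", "coefficients": self.coefficients.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(np.asarray(d["coefficients"]))


@dataclass(frozen=True)
class ForestHyperparams:
    """Tree budget and growth limits.

    ``n_estimators`` is the **total** ensemble budget; in the federated
    setting it is divided among clients (equally by default, or
    proportionally to client sample size with ``allocation="proportional"``)
    so the pooled ensemble matches a centralized forest's tree count.
    """

    n_estimators: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 1
    max_features: str | float | None = 1.0
    allocation: str = "equal"
    rounds: int = 1

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("need at least one tree")
        if self.allocation not in ("equal", "proportional"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class ForestModel:
    """Ensemble of decision trees, each tagged with its client of origin."""

    trees: list
    origins: list[str]
    task: str
    n_features: int
    hyperparams: ForestHyperparams = field(default_factory=ForestHyperparams)

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.origins):
            raise ValueError("every tree needs an origin tag")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        for t in self.trees:
            if t.n_features_in_ != self.n_features:
                raise ValueError("trees disagree on the feature dimension")

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError("feature dimension mismatch")
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean of tree outputs (regression) or argmax of soft votes."""
        X = self._check_X(X)
        if self.task == "regression":
            out = np.zeros(X.shape[0])
            for t in self.trees:
                out += t.predict(X)
            return out / len(self.trees)
        scores = self.predict_scores(X)
        return (scores >= 0.5).astype(float)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability: mean of per-tree class proportions."""
        if self.task != "classification":
            raise ValueError("scores are only defined for classification")
        X = self._check_X(X)
        out = np.zeros(X.shape[0])
        for t in self.trees:
            proba = t.predict_proba(X)
            out += proba[:, -1] if proba.shape[1] == 2 else np.zeros(X.shape[0])
        return out / len(self.trees)


def local_sufficient_stats(table: SurveyTable) -> SufficientStats:
    """(XᵀX, Xᵀy, n) with an all-ones intercept column prepended."""
    if table.task != "regression":
        raise ValueError("sufficient statistics are defined for the regression task")
    X = np.column_stack([np.ones(table.n), table.X])
    if not (np.isfinite(X).all() and np.isfinite(table.y).all()):
        raise ValueError("non-finite entries in the design")
    return SufficientStats(X.T @ X, X.T @ table.y, table.n)


def _solve_normal_equations(xtx: np.ndarray, xty: np.ndarray, ridge: bool) -> np.ndarray:
    p = xtx.shape[0]
    if ridge:
        xtx = xtx + np.eye(p) * (1e-8 * np.trace(xtx) / p)
    eigvals = np.linalg.eigvalsh(xtx)
    if eigvals[0] <= 1e-10 * max(eigvals[-1], 1.0):
        rank = int(np.sum(eigvals > 1e-10 * max(eigvals[-1], 1.0)))
        raise np.linalg.LinAlgError(
            f"aggregated X^T X is rank deficient (rank {rank} of {p}); "
            "drop collinear features or enable the ridge jitter"
        )
    return np.linalg.solve(xtx, xty)


def fed_ols(
    sites: Sequence[SurveyTable],
    use_smpc: bool = False,
    seed: int = 0,
    ridge: bool = False,
    trace: ProtocolTrace | None = None,
) -> LinearModel:
    """One-shot federated OLS via summed sufficient statistics.

    Each client computes its local (XᵀX, Xᵀy, n); the aggregator forms the
    sums over clients — under additive secret sharing when ``use_smpc`` — and
    solves the global normal equations.  The result equals pooled-data OLS
    exactly (to fixed-point precision with SMPC).
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    schema = sites[0].schema

    def train_fn(client: SurveyTable, _model, _round) -> SufficientStats:
        return local_sufficient_stats(client)

    def aggregate_fn(payloads: list[SufficientStats], ids: list[str]) -> LinearModel:
        if use_smpc:
            k = len(payloads)
            mask_seeds = np.random.SeedSequence((seed, k)).generate_state(2 * k)
            xtx_shares = [smpc_share(s.xtx, k, seed=int(mask_seeds[2 * i])) for i, s in enumerate(payloads)]
            xty_shares = [smpc_share(s.xty, k, seed=int(mask_seeds[2 * i + 1])) for i, s in enumerate(payloads)]
            xtx = smpc_aggregate(xtx_shares)
            xty = smpc_aggregate(xty_shares)
        else:
            total = payloads[0]
            for s in payloads[1:]:
                total = total + s
            xtx, xty = total.xtx, total.xty
        return LinearModel(_solve_normal_equations(xtx, xty, ridge), schema=schema)

    plan = FedConfig(n_clients=len(sites), rounds=1, aggregation="weighted-average", seed=seed)
    return run_protocol(sites, plan, train_fn, aggregate_fn, trace=trace)


def centralized_ols(sites: Sequence[SurveyTable], ridge: bool = False) -> LinearModel:
    """Pooled-data OLS baseline (scenario B)."""
    X = np.vstack([s.X for s in sites])
    y = np.concatenate([s.y for s in sites])
    pooled = SurveyTable("pooled", X, np.clip(y, *VAS_RANGE), sites[0].schema)
    stats = local_sufficient_stats(pooled)
    return LinearModel(_solve_normal_equations(stats.xtx, stats.xty, ridge), schema=sites[0].schema)


def train_local_forest(
    table: SurveyTable,
    hyperparams: ForestHyperparams | None = None,
    seed: int = 0,
    n_trees: int | None = None,
) -> ForestModel:
    """Standard random forest (bootstrap + random feature subsets) on one site.

    ``n_trees`` overrides the hyperparameter budget for per-client
    allocations; origins of all trees are the site id.
    """
    hp = hyperparams or ForestHyperparams()
    n_estimators = n_trees if n_trees is not None else hp.n_estimators
    if table.n < 2:
        raise ValueError("need at least two rows to train a forest")
    common = dict(
        n_estimators=n_estimators,
        max_depth=hp.max_depth,
        min_samples_leaf=hp.min_samples_leaf,
        max_features=hp.max_features,
        random_state=seed % (2**31),
        n_jobs=1,
    )
    if table.task == "classification":
        if len(np.unique(table.y)) < 2:
            raise ValueError(f"site {table.site_id} has a single class; cannot train a classifier")
        rf = RandomForestClassifier(**common).fit(table.X, table.y)
    else:
        rf = RandomForestRegressor(**common).fit(table.X, table.y)
    trees = list(rf.estimators_)
    return ForestModel(trees, [table.site_id] * len(trees), table.task, table.X.shape[1], hp)


def _leaf_mask(tree) -> np.ndarray:
    return tree.tree_.children_left < 0


def dp_protect_forest(
    forest: ForestModel,
    cfg: DPConfig,
    y_range: tuple[float, float] = VAS_RANGE,
    seed: int = 0,
) -> ForestModel:
    """Release a forest under (ε, δ)-DP output perturbation.

    Regression: leaf predicted values are clipped to ``y_range`` and noised
    with the Gaussian mechanism; one record moves a leaf mean by at most
    (range width) / (leaf size), so the sensitivity is the range width over
    the smallest leaf size in the tree.  Classification: leaf class-count
    vectors are noised (sensitivity from ``cfg``), floored at zero and
    renormalized to proportions.  Tree structure is unchanged; the input
    forest is not modified.  Under the bypass mechanism (ε→∞) predictions
    are bit-identical to the input.
    """
    if cfg.bypassed:
        return forest
    protected = copy.deepcopy(forest)
    seeds = np.random.SeedSequence(seed).generate_state(len(protected.trees))
    lo, hi = float(y_range[0]), float(y_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("y_range must be a finite interval")
    width = hi - lo
    for tree, tree_seed in zip(protected.trees, seeds):
        t = tree.tree_
        leaves = _leaf_mask(tree)
        if forest.task == "regression":
            min_leaf = int(t.n_node_samples[leaves].min())
            tree_cfg = replace(cfg, sensitivity=width / min_leaf)
            vals = np.clip(t.value[leaves, 0, 0], lo, hi)
            t.value[leaves, 0, 0] = dp_perturb(vals, tree_cfg, int(tree_seed))
        else:
            counts = t.value[leaves, 0, :] * t.weighted_n_node_samples[leaves, None]
            noised = dp_perturb(counts, cfg, int(tree_seed))
            noised = np.clip(noised, 0.0, None)
            row_sums = noised.sum(axis=1, keepdims=True)
            flat = row_sums[:, 0] <= 0
            noised[flat] = 1.0  # degenerate leaf: fall back to uniform vote
            row_sums[flat] = noised.shape[1]
            t.value[leaves, 0, :] = noised / row_sums
    return protected


def aggregate_forests(forests: Sequence[ForestModel]) -> ForestModel:
    """Pool client forests into one ensemble; origins are preserved."""
    if not forests:
        raise ValueError("nothing to aggregate")
    task = forests[0].task
    m = forests[0].n_features
    for f in forests:
        if f.task != task:
            raise ValueError("cannot pool forests with different tasks")
        if f.n_features != m:
            raise ValueError("cannot pool forests with different feature dimensions")
    trees: list = []
    origins: list[str] = []
    for f in forests:
        trees.extend(f.trees)
        origins.extend(f.origins)
    return ForestModel(trees, origins, task, m, forests[0].hyperparams)


def _client_budgets(sizes: Sequence[int], total: int, allocation: str) -> list[int]:
    k = len(sizes)
    if allocation == "equal":
        budgets = [total // k] * k
        for i in range(total - sum(budgets)):
            budgets[i] += 1
    else:
        raw = np.asarray(sizes, dtype=float) / sum(sizes) * total
        budgets = np.floor(raw).astype(int)
        for i in np.argsort(raw - budgets)[::-1][: total - budgets.sum()]:
            budgets[i] += 1
        budgets = budgets.tolist()
    return [max(b, 1) for b in budgets]


def fed_forest(
    sites: Sequence[SurveyTable],
    hyperparams: ForestHyperparams | None = None,
    dp_config: DPConfig | None = None,
    seed: int = 0,
    y_range: tuple[float, float] = VAS_RANGE,
    trace: ProtocolTrace | None = None,
) -> ForestModel:
    """Federated random forest: local training, DP release, tree pooling.

    The total tree budget is split across clients (and across
    ``hyperparams.rounds`` contribution rounds, one-shot by default); each
    client's trees are DP-protected before leaving the client when
    ``dp_config`` is given, then pooled into the shared ensemble.
    """
    hp = hyperparams or ForestHyperparams()
    budgets = dict(
        zip([s.site_id for s in sites], _client_budgets([s.n for s in sites], hp.n_estimators, hp.allocation))
    )
    seeds = {s.site_id: np.random.SeedSequence((seed, i)).generate_state(2 * hp.rounds) for i, s in enumerate(sites)}

    def train_fn(client: SurveyTable, _model, round_idx: int) -> ForestModel:
        budget = budgets[client.site_id]
        per_round = budget // hp.rounds + (1 if round_idx < budget % hp.rounds else 0)
        per_round = max(per_round, 1)
        local = train_local_forest(client, hp, seed=int(seeds[client.site_id][2 * round_idx]), n_trees=per_round)
        if dp_config is not None:
            local = dp_protect_forest(local, dp_config, y_range=y_range, seed=int(seeds[client.site_id][2 * round_idx + 1]))
        return local

    collected: list[ForestModel] = []

    def aggregate_fn(payloads: list[ForestModel], ids: list[str]) -> ForestModel:
        collected.extend(payloads)
        return aggregate_forests(collected)

    plan = FedConfig(n_clients=len(sites), rounds=hp.rounds, aggregation="pooling", seed=seed)
    return run_protocol(sites, plan, train_fn, aggregate_fn, trace=trace)


def predict(model, X: np.ndarray):
    """Predictions of either model family.

    Regression models return the predicted values; classification forests
    return ``(labels, scores)`` where ``scores`` is the positive-class
    probability used for threshold-free metrics.
    """
    if isinstance(model, LinearModel):
        return model.predict(X)
    if isinstance(model, ForestModel):
        if model.task == "classification":
            scores = model.predict_scores(X)
            return (scores >= 0.5).astype(float), scores
        return model.predict(X)
    raise TypeError(f"unknown model type {type(model).__name__}")
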