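"""Local vs. centralized vs. federated comparison machinery.

The protocol mirrors a multi-site prognostic-modelling study: per-site
5-fold cross-validation with one shared fold plan, so within a fold every
scenario trains on the same training rows and is scored on the same test
rows; a global test set formed by merging the sites' test splits; for the
imbalanced classification task, supersampling of each site's training split
to class balance and four mutually exclusive balanced test subsets carved
from the merged test split; six metrics (R², RMSE; accuracy, AUROC, F1,
AUPRC); one-sided Welch t-tests for the three study hypotheses (centralized
better than mean-of-locals, federated better than mean-of-locals,
centralized better than federated); and a training-set subsampling ladder
that shrinks every site's training split while leaving the test data
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from fedsurvey.fedcore import DPConfig
from fedsurvey.fed_models import (
    ForestHyperparams,
    centralized_ols,
    fed_forest,
    fed_ols,
    train_local_forest,
)
from fedsurvey.synthetic_survey import SurveyTable

__all__ = [
    "FoldPlan",
    "MetricSet",
    "ScenarioResult",
    "ComparisonReport",
    "make_folds",
    "supersample_balance",
    "make_balanced_test_subsets",
    "score",
    "run_study",
    "welch_one_sided",
    "compare_scenarios",
    "subsampling_experiment",
    "local_centralized_gap",
]

HIGHER_IS_BETTER = {"r2": True, "rmse": False, "accuracy": True, "auroc": True, "f1": True, "auprc": True}

REGRESSION_METRICS = ("r2", "rmse")
CLASSIFICATION_METRICS = ("accuracy", "auroc", "f1", "auprc")


@dataclass
class FoldPlan:
    """Per-site train/test row indices for one cross-validation fold."""

    fold_id: int
    train: dict[str, np.ndarray]
    test: dict[str, np.ndarray]
    k: int = 5


def make_folds(sites: Sequence[SurveyTable], k: int = 5, seed: int = 0) -> list[FoldPlan]:
    """One shared k-fold plan over all sites (stratified for classification)."""
    for s in sites:
        if s.n < k:
            raise ValueError(f"site {s.site_id} has fewer rows ({s.n}) than folds ({k})")
    plans = [FoldPlan(fold_id=i + 1, train={}, test={}, k=k) for i in range(k)]
    for site_idx, s in enumerate(sites):
        rs = int(np.random.SeedSequence((seed, site_idx)).generate_state(1)[0] % (2**31))
        if s.task == "classification":
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            split_iter = splitter.split(s.X, s.y)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
            split_iter = splitter.split(s.X)
        for fold_idx, (tr, te) in enumerate(split_iter):
            plans[fold_idx].train[s.site_id] = tr
            plans[fold_idx].test[s.site_id] = te
    return plans


def supersample_balance(X: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class with replacement to exact balance.

    All original rows are kept; the added rows are duplicates drawn with
    replacement from the minority class only.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y), np.bincount(y.astype(int), minlength=2)
    if len(classes) < 2:
        raise ValueError("supersampling needs both classes present")
    minority = int(np.argmin(counts))
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


def make_balanced_test_subsets(
    X: np.ndarray, y: np.ndarray, n_subsets: int = 4, seed: int = 0
) -> list[np.ndarray]:
    """Mutually exclusive balanced test subsets (returned as row indices).

    Every subset contains all smaller-class rows plus an equally sized draw
    from the larger class; the larger-class draws are pairwise disjoint
    across subsets.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes in the test data")
    small_cls = classes[np.argmin(counts)]
    small_idx = np.flatnonzero(y == small_cls)
    large_idx = np.flatnonzero(y != small_cls)
    n_small = len(small_idx)
    feasible = len(large_idx) // n_small
    if n_subsets > feasible:
        raise ValueError(
            f"cannot build {n_subsets} disjoint balanced subsets; the larger class supports at most {feasible}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(large_idx)
    return [np.sort(np.concatenate([small_idx, perm[i * n_small : (i + 1) * n_small]])) for i in range(n_subsets)]


@dataclass
class MetricSet:
    """The study's six metrics; only those defined for the task are set."""

    r2: float | None = None
    rmse: float | None = None
    accuracy: float | None = None
    auroc: float | None = None
    f1: float | None = None
    auprc: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def score(truth: np.ndarray, predictions: np.ndarray, task: str, scores: np.ndarray | None = None) -> MetricSet:
    """Compute the task's metrics for one model on one test set.

    For classification, ``scores`` are positive-class probabilities used for
    AUROC/AUPRC.  A single-class truth leaves the threshold-free metrics
    undefined (NaN, with a warning).
    """
    truth = np.asarray(truth, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if truth.shape != predictions.shape:
        raise ValueError("truth and predictions must be aligned")
    if task == "regression":
        return MetricSet(
            r2=float(r2_score(truth, predictions)),
            rmse=float(np.sqrt(mean_squared_error(truth, predictions))),
        )
    if scores is None:
        raise ValueError("classification scoring needs class scores")
    if len(np.unique(truth)) < 2:
        warnings.warn("single-class truth: AUROC/AUPRC undefined", stacklevel=2)
        auroc = auprc = float("nan")
    else:
        auroc = float(roc_auc_score(truth, scores))
        auprc = float(average_precision_score(truth, scores))
    return MetricSet(
        accuracy=float(accuracy_score(truth, predictions)),
        auroc=auroc,
        f1=float(f1_score(truth, predictions, pos_label=1)),
        auprc=auprc,
    )


@dataclass
class ScenarioRecord:
    fold: int
    scenario: str
    test_set: str
    metrics: MetricSet


@dataclass
class ScenarioResult:
    """All per-fold, per-scenario, per-test-set metric records of one study."""

    records: list[ScenarioRecord]
    task: str
    k: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": r.fold, "scenario": r.scenario, "test_set": r.test_set, "metric": m, "value": v}
            for r in self.records
            for m, v in r.metrics.as_dict().items()
        ]
        return pd.DataFrame(rows)

    @property
    def scenarios(self) -> list[str]:
        return sorted({r.scenario for r in self.records})

    @property
    def metrics(self) -> tuple[str, ...]:
        return REGRESSION_METRICS if self.task == "regression" else CLASSIFICATION_METRICS


def _subsample_indices(idx: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    if fraction >= 1.0:
        return idx
    n_keep = int(round(fraction * len(idx)))
    if n_keep < 2:
        raise ValueError(f"training fraction {fraction} leaves fewer than 2 rows")
    return rng.choice(idx, size=n_keep, replace=False)


def _train_tables(sites, plan: FoldPlan, fraction: float, rng: np.random.Generator) -> list[SurveyTable]:
    out = []
    for s in sites:
        tr = _subsample_indices(plan.train[s.site_id], fraction, rng)
        out.append(SurveyTable(s.site_id, s.X[tr], s.y[tr], s.schema, task=s.task))
    return out


def run_study(
    sites: Sequence[SurveyTable],
    model_family: str = "ols",
    k: int = 5,
    seed: int = 0,
    use_smpc: bool = False,
    dp_config: DPConfig | None = None,
    forest_hyperparams: ForestHyperparams | None = None,
    n_test_subsets: int = 4,
    train_fraction: float = 1.0,
) -> ScenarioResult:
    """Run one full three-scenario study on a multi-site dataset.

    Per fold: every local model trains on its own site's training split, the
    centralized model on the concatenated training splits, and the federated
    model on the distributed training splits; all are evaluated on the fold's
    global test set (regression) or on its four balanced test subsets
    (classification).  Classification training splits are supersampled to
    class balance per site before any training.
    """
    if len(sites) < 2:
        raise ValueError("a comparison study needs at least two sites")
    if model_family not in ("ols", "rf"):
        raise ValueError(f"unknown model family {model_family!r}")
    task = sites[0].task
    if model_family == "ols" and task != "regression":
        raise ValueError("OLS applies to the regression task")
    hp = forest_hyperparams or ForestHyperparams()

    folds = make_folds(sites, k=k, seed=seed)
    records: list[ScenarioRecord] = []
    for plan in folds:
        fold_ss = np.random.SeedSequence((seed, plan.fold_id))
        fold_seeds = fold_ss.generate_state(4 + len(sites))
        rng = np.random.default_rng(fold_seeds[0])

        train_tables = _train_tables(sites, plan, train_fraction, rng)
        if task == "classification":
            balanced = []
            for i, t in enumerate(train_tables):
                Xb, yb = supersample_balance(t.X, t.y, seed=int(fold_seeds[4 + i] % (2**31)))
                balanced.append(SurveyTable(t.site_id, Xb, yb, t.schema, task=task))
            train_tables = balanced

        X_test = np.vstack([s.X[plan.test[s.site_id]] for s in sites])
        y_test = np.concatenate([s.y[plan.test[s.site_id]] for s in sites])
        if task == "classification":
            subset_idx = make_balanced_test_subsets(X_test, y_test, n_subsets=n_test_subsets, seed=int(fold_seeds[1] % (2**31)))
            test_sets = [(f"balanced_{i+1}", idx) for i, idx in enumerate(subset_idx)]
        else:
            test_sets = [("global", np.arange(len(y_test)))]

        models: dict[str, object] = {}
        if model_family == "ols":
            for t in train_tables:
                stats_ok = t.n >= 2
                if not stats_ok:
                    raise ValueError(f"site {t.site_id} training split too small")
                models[f"local:{t.site_id}"] = fed_ols([t], seed=int(fold_seeds[2] % (2**31)))
            models["centralized"] = centralized_ols(train_tables)
            models["federated"] = fed_ols(train_tables, use_smpc=use_smpc, seed=int(fold_seeds[2] % (2**31)))
        else:
            for i, t in enumerate(train_tables):
                models[f"local:{t.site_id}"] = train_local_forest(t, hp, seed=int(fold_seeds[4 + i] % (2**31)))
            pooled_X = np.vstack([t.X for t in train_tables])
            pooled_y = np.concatenate([t.y for t in train_tables])
            pooled = SurveyTable("pooled", pooled_X, pooled_y, sites[0].schema, task=task)
            models["centralized"] = train_local_forest(pooled, hp, seed=int(fold_seeds[3] % (2**31)))
            models["federated"] = fed_forest(
                train_tables, hp, dp_config=dp_config, seed=int(fold_seeds[2] % (2**31))
            )

        for name, model in models.items():
            if task == "classification":
                scores_all = model.predict_scores(X_test)
                labels_all = (scores_all >= 0.5).astype(float)
                for ts_name, idx in test_sets:
                    ms = score(y_test[idx], labels_all[idx], task, scores=scores_all[idx])
                    records.append(ScenarioRecord(plan.fold_id, name, ts_name, ms))
            else:
                preds = model.predict(X_test)
                for ts_name, idx in test_sets:
                    ms = score(y_test[idx], preds[idx], task)
                    records.append(ScenarioRecord(plan.fold_id, name, ts_name, ms))
    return ScenarioResult(records=records, task=task, k=k)


def welch_one_sided(sample_a: Sequence[float], sample_b: Sequence[float], alternative: str = "greater") -> float:
    """One-sided Welch t-test p-value for mean(a) > mean(b) (or '<')."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both samples are constant; the Welch statistic is undefined")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class ComparisonReport:
    """Per-metric scenario means, the three hypothesis tests, and improvement."""

    rows: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.rows, orient="index")

    def to_dict(self) -> dict:
        return self.rows


def _scenario_samples(result: ScenarioResult, metric: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (fold, test_set) values: mean-of-locals, centralized, federated."""
    df = result.to_frame()
    df = df[df.metric == metric]
    keys = df[["fold", "test_set"]].drop_duplicates().itertuples(index=False)
    locals_, cent, fed = [], [], []
    for fold, test_set in keys:
        cell = df[(df.fold == fold) & (df.test_set == test_set)]
        loc = cell[cell.scenario.str.startswith("local:")]["value"]
        locals_.append(float(loc.mean()))
        cent.append(float(cell[cell.scenario == "centralized"]["value"].iloc[0]))
        fed.append(float(cell[cell.scenario == "federated"]["value"].iloc[0]))
    return np.asarray(locals_), np.asarray(cent), np.asarray(fed)


def _p_better(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    """p-value that scenario a outperforms scenario b on this metric."""
    if np.allclose(a, b):
        return 0.5  # identical performance: no evidence either way
    if HIGHER_IS_BETTER[metric]:
        return welch_one_sided(a, b, "greater")
    return welch_one_sided(a, b, "less")


def compare_scenarios(result: ScenarioResult, alpha: float = 0.05) -> ComparisonReport:
    """The three one-sided Welch tests per metric, plus relative improvement.

    Locals are averaged within each (fold, test set) cell first; the tests
    pool all cells (k folds × test subsets).  Relative improvement of the
    federated over the mean-of-locals is sign-flipped for lower-is-better
    metrics so that positive always means "federated better".
    """
    if result.k < 2:
        raise ValueError("comparisons need at least two folds")
    rows = {}
    present = set(result.to_frame().metric)
    for metric in result.metrics:
        if metric not in present:
            continue
        loc, cent, fed = _scenario_samples(result, metric)
        mask = ~(np.isnan(loc) | np.isnan(cent) | np.isnan(fed))
        loc, cent, fed = loc[mask], cent[mask], fed[mask]
        p1 = _p_better(cent, loc, metric)
        p2 = _p_better(fed, loc, metric)
        p3 = _p_better(cent, fed, metric)
        mean_loc = float(loc.mean())
        mean_fed = float(fed.mean())
        sign = 1.0 if HIGHER_IS_BETTER[metric] else -1.0
        rel = sign * (mean_fed - mean_loc) / abs(mean_loc)
        rows[metric] = {
            "mean_local": mean_loc,
            "centralized": float(cent.mean()),
            "federated": mean_fed,
            "p_centralized_vs_local": p1,
            "stars_centralized_vs_local": _stars(p1),
            "p_federated_vs_local": p2,
            "stars_federated_vs_local": _stars(p2),
            "p_centralized_vs_federated": p3,
            "stars_centralized_vs_federated": _stars(p3),
            "relative_improvement_fed_over_local": rel,
        }
    return ComparisonReport(rows)


def subsampling_experiment(
    sites: Sequence[SurveyTable],
    fractions: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.1),
    model_family: str = "ols",
    k: int = 5,
    seed: int = 0,
    **study_kwargs,
) -> dict[float, ScenarioResult]:
    """Re-run the study with progressively smaller training splits.

    Every site's training split is subsampled to each fraction (test data
    untouched, identical fold plan throughout); fraction 1.0 reproduces the
    full study exactly.
    """
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError("fractions must lie in (0, 1]")
    return {
        float(f): run_study(sites, model_family=model_family, k=k, seed=seed, train_fraction=float(f), **study_kwargs)
        for f in fractions
    }


def local_centralized_gap(results: dict[float, ScenarioResult], metric: str = "r2") -> pd.DataFrame:
    """Mean (centralized − mean-of-locals) gap per training fraction."""
    rows = []
    for frac, res in sorted(results.items()):
        loc, cent, fed = _scenario_samples(res, metric)
        rows.append(
            {
                "fraction": frac,
                "mean_local": float(np.mean(loc)),
                "centralized": float(np.mean(cent)),
                "federated": float(np.mean(fed)),
                "gap_centralized_minus_local": float(np.mean(cent) - np.mean(loc)),
            }
        )
    return pd.DataFrame(rows)
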