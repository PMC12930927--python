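"""Replicate-study drivers for the synthetic presets.

These functions bundle the full pipelines — generate a preset, run the
three-scenario study, and summarize the quantity of interest — so the same
computation backs interactive use, the test suite and the results script.
Each driver takes a base seed and derives one generator/study seed per
replicate; everything downstream is deterministic in that seed.

Study configurations (tree budgets, depth and leaf-size limits) are fixed
here as the package's reference conditions: regression forests grow deep
(100 trees, leaves ≥ 5); the DP-released and attribution forests use leaves
of ≥ 25 samples so the Gaussian-mechanism noise (ε = 1, δ = 1e−5) does not
drown the leaf statistics; classification forests use 54 depth-12 trees with
√m feature subsampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from fedsurvey.attribution import compare_top_k, feature_attribution
from fedsurvey.evaluation import (
    compare_scenarios,
    local_centralized_gap,
    make_folds,
    run_study,
    score,
    subsampling_experiment,
)
from fedsurvey.fedcore import DPConfig
from fedsurvey.fed_models import ForestHyperparams, fed_forest, train_local_forest
from fedsurvey.synthetic_survey import SurveyTable, make_glad_like, make_share_like

__all__ = [
    "regression_forest_hp",
    "attribution_forest_hp",
    "classification_forest_hp",
    "headline_replicates",
    "pooling_fidelity",
    "subsampling_trend",
    "attribution_agreement",
    "glad_study",
    "share_study",
]


def regression_forest_hp() -> ForestHyperparams:
    return ForestHyperparams(n_estimators=100, max_depth=None, min_samples_leaf=5)


def attribution_forest_hp() -> ForestHyperparams:
    return ForestHyperparams(n_estimators=100, max_depth=8, min_samples_leaf=25)


def classification_forest_hp() -> ForestHyperparams:
    return ForestHyperparams(n_estimators=54, max_depth=12, min_samples_leaf=25, max_features="sqrt")


def _replicate_seeds(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def _fold_one_split(tables, seed: int):
    """Fold-1 train tables and merged test matrix of the shared fold plan."""
    plan = make_folds(tables, k=5, seed=seed)[0]
    train = [
        SurveyTable(s.site_id, s.X[plan.train[s.site_id]], s.y[plan.train[s.site_id]], s.schema, task=s.task)
        for s in tables
    ]
    X_test = np.vstack([s.X[plan.test[s.site_id]] for s in tables])
    y_test = np.concatenate([s.y[plan.test[s.site_id]] for s in tables])
    return train, X_test, y_test


def headline_replicates(n_replicates: int = 20, base_seed: int = 0, k: int = 5) -> pd.DataFrame:
    """Replicate OLS studies on the national preset; one row per replicate.

    Records the scenario means and the three hypothesis-test p-values for R²
    so the study's headline pattern (federated significantly better than the
    local average, centralized not significantly better than federated) can
    be tallied across replicates.
    """
    rows = []
    for seed in _replicate_seeds(base_seed, n_replicates):
        tables = make_glad_like(seed)
        result = run_study(tables, model_family="ols", k=k, seed=seed)
        rep = compare_scenarios(result).to_frame()
        row = {"seed": seed}
        for metric in ("r2", "rmse"):
            r = rep.loc[metric]
            row.update(
                {
                    f"{metric}_local": r.mean_local,
                    f"{metric}_centralized": r.centralized,
                    f"{metric}_federated": r.federated,
                    f"{metric}_p_fed_vs_local": r.p_federated_vs_local,
                    f"{metric}_p_cent_vs_fed": r.p_centralized_vs_federated,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def pooling_fidelity(n_seeds: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """Held-out R² of the pooled (no-DP) federated forest vs. centralized.

    Both ensembles use the same total tree budget; evaluation is on the
    merged fold-1 test split of the national preset.
    """
    hp = regression_forest_hp()
    rows = []
    for seed in _replicate_seeds(base_seed, n_seeds):
        tables = make_glad_like(seed)
        train, X_test, y_test = _fold_one_split(tables, seed)
        pooled = SurveyTable(
            "pooled", np.vstack([t.X for t in train]), np.concatenate([t.y for t in train]), tables[0].schema
        )
        centralized = train_local_forest(pooled, hp, seed=seed)
        federated = fed_forest(train, hp, dp_config=None, seed=seed)
        rows.append(
            {
                "seed": seed,
                "r2_centralized": score(y_test, centralized.predict(X_test), "regression").r2,
                "r2_federated": score(y_test, federated.predict(X_test), "regression").r2,
            }
        )
    df = pd.DataFrame(rows)
    df["r2_diff"] = df.r2_federated - df.r2_centralized
    return df


def subsampling_trend(
    n_seeds: int = 10,
    base_seed: int = 0,
    fractions: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0),
    k: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The data-scarcity ladder: per-seed Spearman trend of the local gap.

    Returns (per-seed trend frame, per-fraction mean-gap frame).  The gap is
    centralized minus mean-local R²; a negative Spearman correlation with the
    training fraction reproduces the widening-gap-as-data-shrinks behavior.
    """
    trend_rows, gap_frames = [], []
    for seed in _replicate_seeds(base_seed, n_seeds):
        tables = make_glad_like(seed)
        results = subsampling_experiment(tables, fractions=fractions, model_family="ols", k=k, seed=seed)
        gap = local_centralized_gap(results)
        gap.insert(0, "seed", seed)
        gap_frames.append(gap)
        rho = spearmanr(gap.fraction, gap.gap_centralized_minus_local).statistic
        trend_rows.append({"seed": seed, "spearman_rho": float(rho)})
    gaps = pd.concat(gap_frames, ignore_index=True)
    mean_gaps = gaps.groupby("fraction", as_index=False).mean(numeric_only=True).drop(columns="seed")
    return pd.DataFrame(trend_rows), mean_gaps


def attribution_agreement(
    n_seeds: int = 10,
    base_seed: int = 0,
    top_k: int = 5,
    n_test_rows: int = 150,
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Top-k feature agreement of DP-federated vs. centralized forests.

    Both forests are trained on the fold-1 training split of the national
    preset (equal total budget, federated trees DP-released at the given ε)
    and attributed on the same test rows.
    """
    hp = attribution_forest_hp()
    dp = DPConfig(epsilon=epsilon, delta=1e-5)
    rows = []
    for seed in _replicate_seeds(base_seed, n_seeds):
        tables = make_glad_like(seed)
        train, X_test, _ = _fold_one_split(tables, seed)
        X_attr = X_test[:n_test_rows]
        pooled = SurveyTable(
            "pooled", np.vstack([t.X for t in train]), np.concatenate([t.y for t in train]), tables[0].schema
        )
        centralized = train_local_forest(pooled, hp, seed=seed)
        federated = fed_forest(train, hp, dp_config=dp, seed=seed)
        names = list(tables[0].schema.names)
        rep_fed = feature_attribution(federated, X_attr, feature_names=names, model_label="federated")
        rep_cen = feature_attribution(centralized, X_attr, feature_names=names, model_label="centralized")
        overlap, order = compare_top_k(rep_fed, rep_cen, k=top_k)
        rows.append(
            {"seed": seed, "overlap": overlap, "order_match": order, "fed_top1": rep_fed.ranking[0]}
        )
    return pd.DataFrame(rows)


def glad_study(seed: int = 0, model_family: str = "ols", k: int = 5):
    """One full three-scenario study on the national regression preset."""
    tables = make_glad_like(seed)
    kwargs = {}
    if model_family == "rf":
        kwargs["forest_hyperparams"] = regression_forest_hp()
    result = run_study(tables, model_family=model_family, k=k, seed=seed, **kwargs)
    return result, compare_scenarios(result)


def share_study(seed: int = 0, k: int = 5, epsilon: float = 1.0):
    """One full three-scenario study on the international classification preset."""
    tables = make_share_like(seed)
    result = run_study(
        tables,
        model_family="rf",
        k=k,
        seed=seed,
        dp_config=DPConfig(epsilon=epsilon, delta=1e-5, sensitivity=1.0),
        forest_hyperparams=classification_forest_hp(),
    )
    return result, compare_scenarios(result)
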