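"""Between-site distribution diagnostics: ANOVA, Scheffé pairs, Cohen's D.

Site heterogeneity (non-IID data) is the main threat to federated models, so
every variable — ordinal variables treated as numeric, plus the target — is
screened with a one-way ANOVA across sites, Scheffé post-hoc tests for every
site pair (family-wise error controlled within each variable), and pairwise
Cohen's D standardized mean differences.  Pair labels follow the ``"XvsY"``
convention with 1-based site positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fedsurvey.synthetic_survey import FeatureSchema, SurveyTable

__all__ = [
    "anova_oneway",
    "scheffe_posthoc",
    "cohens_d",
    "heterogeneity_scan",
    "HeterogeneityReport",
]


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate input (zero variance within every group and equal means)
    yields ``(nan, nan)`` with a warning rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two observations")
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = np.array([g.mean() for g in groups])
    if within == 0.0 and np.allclose(means, means[0]):
        warnings.warn("degenerate ANOVA: all groups constant and equal", stacklevel=2)
        return float("nan"), float("nan")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _group_summaries(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float, int, int]:
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    n_total = int(ns.sum())
    k = len(groups)
    msw = sse / (n_total - k)
    return ns, means, msw, n_total, k


def scheffe_posthoc(groups: list[np.ndarray], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Scheffé pairwise comparisons after a one-way ANOVA.

    For pair (i, j) the statistic (x̄ᵢ−x̄ⱼ)² / (MSW·(1/nᵢ+1/nⱼ)) is referred
    to (k−1)·F(α; k−1, N−k); the adjusted p-value is the F tail probability
    of the statistic divided by (k−1).  Returns ``(flags, pvalues)`` as
    symmetric k×k matrices (diagonal: no difference, p = 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    ns, means, msw, n_total, k = _group_summaries(groups)
    if msw == 0.0:
        raise ValueError("zero within-group variance everywhere; Scheffé undefined")
    pvals = np.ones((k, k))
    flags = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            stat = (means[i] - means[j]) ** 2 / (msw * (1.0 / ns[i] + 1.0 / ns[j]))
            p = float(stats.f.sf(stat / (k - 1), k - 1, n_total - k))
            pvals[i, j] = pvals[j, i] = p
            flags[i, j] = flags[j, i] = p < alpha
    return flags, pvals


def cohens_d(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Standardized mean difference (mean_a − mean_b) / pooled SD."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0.0:
        raise ValueError("zero pooled standard deviation; Cohen's D undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class HeterogeneityReport:
    """Per-variable ANOVA, pairwise Scheffé significance, pairwise Cohen's D."""

    site_ids: list[str]
    anova: dict[str, tuple[float, float]]
    scheffe_flags: dict[str, np.ndarray]
    scheffe_p: dict[str, np.ndarray]
    d_matrix: dict[str, np.ndarray]
    skipped: list[str]
    alpha: float

    def pair_label(self, i: int, j: int) -> str:
        return f"{i + 1}vs{j + 1}"

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (variable, site pair)."""
        rows = []
        k = len(self.site_ids)
        for var in self.anova:
            f, p = self.anova[var]
            for i in range(k):
                for j in range(i + 1, k):
                    rows.append(
                        {
                            "variable": var,
                            "pair": self.pair_label(i, j),
                            "anova_F": f,
                            "anova_p": p,
                            "cohens_d": float(self.d_matrix[var][i, j]),
                            "scheffe_p": float(self.scheffe_p[var][i, j]),
                            "significant": bool(self.scheffe_flags[var][i, j]),
                        }
                    )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "sites": self.site_ids,
            "alpha": self.alpha,
            "skipped": self.skipped,
            "variables": {
                var: {
                    "anova_F": self.anova[var][0],
                    "anova_p": self.anova[var][1],
                    "scheffe_p": self.scheffe_p[var].tolist(),
                    "scheffe_significant": self.scheffe_flags[var].astype(bool).tolist(),
                    "cohens_d": self.d_matrix[var].tolist(),
                }
                for var in self.anova
            },
        }


def heterogeneity_scan(
    sites: list[SurveyTable],
    schema: FeatureSchema | None = None,
    alpha: float = 0.05,
    include_target: bool = True,
) -> HeterogeneityReport:
    """Run ANOVA + Scheffé + Cohen's D for every variable across all sites.

    Variables constant across all sites are flagged and skipped.  The target
    variable is included by default under the name ``"target"``.
    """
    if len(sites) < 2:
        raise ValueError("heterogeneity needs at least two sites")
    schema = schema or sites[0].schema
    k = len(sites)
    columns = {name: [s.X[:, j] for s in sites] for j, name in enumerate(schema.names)}
    if include_target:
        columns["target"] = [s.y for s in sites]

    anova, s_flags, s_p, d_mat, skipped = {}, {}, {}, {}, []
    for var, groups in columns.items():
        pooled = np.concatenate(groups)
        if np.allclose(pooled, pooled[0]):
            warnings.warn(f"variable {var} is constant across all sites; skipped", stacklevel=2)
            skipped.append(var)
            continue
        anova[var] = anova_oneway(groups)
        flags, pvals = scheffe_posthoc(groups, alpha=alpha)
        s_flags[var], s_p[var] = flags, pvals
        D = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d = cohens_d(groups[i], groups[j])
                D[i, j] = d
                D[j, i] = -d
        d_mat[var] = D
    return HeterogeneityReport([s.site_id for s in sites], anova, s_flags, s_p, d_mat, skipped, alpha)
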