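import numpy as np
import pytest

from fedsurvey.synthetic_survey import FeatureSchema, GeneratorConfig, SiteProfile, SurveyTable


def make_schema(m: int) -> FeatureSchema:
    """All-continuous schema with m features."""
    return FeatureSchema(
        names=tuple(f"x{j}" for j in range(m)),
        kinds=("continuous",) * m,
        levels=(0,) * m,
    )


def random_table(rng: np.random.Generator, n: int, m: int, site_id: str = "s", beta=None, noise: float = 1.0) -> SurveyTable:
    """Small regression table with a linear signal, target within VAS bounds."""
    X = rng.standard_normal((n, m))
    beta = np.asarray(beta) if beta is not None else rng.normal(size=m)
    y = np.clip(X @ beta + noise * rng.standard_normal(n), -100, 100)
    return SurveyTable(site_id, X, y, make_schema(m))


def split_table(table: SurveyTable, rng: np.random.Generator, n_sites: int) -> list[SurveyTable]:
    """Random partition of one table into n_sites non-empty sites."""
    idx = rng.permutation(table.n)
    cuts = np.sort(rng.choice(np.arange(1, table.n), size=n_sites - 1, replace=False)) if n_sites > 1 else []
    parts = np.split(idx, cuts)
    return [
        SurveyTable(f"p{i}", table.X[p], table.y[p], table.schema, task=table.task)
        for i, p in enumerate(parts)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_regression_sites():
    """Three small heterogeneous regression sites for harness tests."""
    rng = np.random.default_rng(7)
    cfg = GeneratorConfig(
        profiles=(
            SiteProfile("a", 80, (0.2, 0.0, 0.0, 0.0), 1.0),
            SiteProfile("b", 100, (0.0, -0.2, 0.0, 0.0), -1.0),
            SiteProfile("c", 60, (0.0, 0.0, 0.3, 0.0), 0.0),
        ),
        schema=make_schema(4),
        beta=(3.0, 2.0, 0.5, 0.0),
        target_r2=0.4,
        seed=7,
    )
    from fedsurvey.synthetic_survey import generate_site

    return [generate_site(p, cfg) for p in cfg.profiles]


@pytest.fixture(scope="session")
def tiny_classification_sites():
    """Three small binary-outcome sites with minority positives."""
    from fedsurvey.synthetic_survey import generate_site

    cfg = GeneratorConfig(
        profiles=(
            SiteProfile("a", 220, (), 0.0, prevalence=0.2),
            SiteProfile("b", 260, (), 0.0, prevalence=0.15),
            SiteProfile("c", 240, (), 0.0, prevalence=0.12),
        ),
        schema=make_schema(5),
        beta=(1.0, 0.8, 0.5, 0.0, 0.0),
        seed=11,
        task="classification",
    )
    return [generate_site(p, cfg) for p in cfg.profiles]
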