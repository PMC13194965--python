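import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import wntsig as w

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_config() -> w.SimConfig:
    """The default study-shaped simulation configuration."""
    return w.SimConfig(seed=11)


@pytest.fixture(scope="session")
def demo_tables(demo_config):
    tables, truth = w.generate_deg_tables(demo_config)
    return tables, truth


@pytest.fixture(scope="session")
def demo_filtered(demo_tables):
    tables, truth = demo_tables
    return [w.filter_degs(t) for t in tables], truth


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic cohort: 6 genes x 8 samples, two subtypes."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.normal(5, 1, size=(6, 8)), index=genes, columns=samples
    )
    subtype = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
    return w.ExpressionCohort(values=values, subtype=subtype)


def make_deg_table(name: str, rows: list[tuple[str, float, float]]) -> w.DEGTable:
    return w.DEGTable(
        name=name,
        records=pd.DataFrame(rows, columns=["gene", "log2fc", "padj"]),
    )
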