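import numpy as np
import pandas as pd
import pytest

from hfpmediate.pathmodel import PathModel
from hfpmediate.pathspec import build_model_spec
from hfpmediate.pipeline import prepare_model_frame
from hfpmediate.scores import AssembleOptions, assemble_analysis_table
from hfpmediate.simulate import GeneratorConfig, simulate_trial

TINY_TRUTH = {
    "a1": 0.5, "a2": 0.2, "a_mkt": 0.3, "d1": 0.2, "d2": -0.1,
    "b1": 0.4, "b2": 0.2, "b_mkt": 0.3, "direct": 0.1,
}


def make_tiny_data(n=200, seed=1, n_clusters=20, holes=False):
    """Small two-mediator system with a market pathway and known truth."""
    rng = np.random.default_rng(seed)
    t = TINY_TRUTH
    T = rng.binomial(1, 0.5, n).astype(float)
    x1 = rng.normal(size=n)
    e = rng.multivariate_normal(
        [0, 0], [[1.0, 0.3], [0.3, 0.8]], size=n
    )
    m1 = 1.0 + t["a1"] * T + 0.3 * x1 + e[:, 0]
    m2 = 0.5 + t["a2"] * T + e[:, 1]
    mkt = 0.1 + t["a_mkt"] * T + t["d1"] * m1 + t["d2"] * m2 + rng.normal(size=n)
    y = (2.0 + t["direct"] * T + t["b1"] * m1 + t["b2"] * m2
         + t["b_mkt"] * mkt + 0.2 * x1 + rng.normal(size=n))
    df = pd.DataFrame({
        "t": T, "x1": x1, "m1": m1, "m2": m2, "mkt": mkt, "y": y,
        "cl": np.repeat(np.arange(n_clusters), n // n_clusters),
    })
    if holes:
        df.loc[rng.choice(n, n // 8, replace=False), "m1"] = np.nan
        df.loc[rng.choice(n, n // 10, replace=False), "m2"] = np.nan
        df.loc[rng.choice(n, n // 10, replace=False), "mkt"] = np.nan
    return df


@pytest.fixture(scope="session")
def tiny_spec():
    return build_model_spec(
        ["m1", "m2"], "y", ["x1"], treatment="t", market="mkt",
        residual_blocks=[["m1", "m2"]],
    )


@pytest.fixture(scope="session")
def tiny_data():
    return make_tiny_data()


@pytest.fixture(scope="session")
def tiny_fit(tiny_data, tiny_spec):
    return PathModel(tiny_data, tiny_spec, cluster="cl").fit()


def small_generator(**overrides):
    base = dict(n_clusters=16, allocation=[8, 8], cluster_size_mean=10)
    base.update(overrides)
    return GeneratorConfig.default(**base)


@pytest.fixture(scope="session")
def small_trial():
    """16-settlement synthetic trial with the default missingness."""
    cfg = small_generator()
    panel, baseline = simulate_trial(cfg, 11)
    table, log = assemble_analysis_table(panel, baseline, AssembleOptions())
    return {"config": cfg, "panel": panel, "baseline": baseline,
            "table": table, "frame": prepare_model_frame(table), "log": log}
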