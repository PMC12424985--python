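import warnings

import numpy as np
import pandas as pd
import pytest

import panelscreen as ps


@pytest.fixture(scope="session")
def small_cohort():
    """A 160-mouse cohort (10 strains x 2 sex x 2 diet x 4) with all tables."""
    cfg = ps.SimConfig(n_strains=10, mice_per_cell=4, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, ps.simulate(cfg)


@pytest.fixture(scope="session")
def oneway_data():
    """Balanced one-way layout with a known strain structure."""
    rng = np.random.default_rng(0)
    g, nrep = 8, 6
    u = rng.normal(0, 1.2, g)
    y = np.repeat(u, nrep) + rng.normal(0, 0.7, g * nrep)
    return pd.DataFrame({
        "y": y,
        "grp": np.repeat([f"g{i}" for i in range(g)], nrep),
    })


def anova_components(df, value="y", group="grp"):
    """Closed-form balanced one-way REML components from mean squares."""
    nrep = df.groupby(group).size().iloc[0]
    g = df[group].nunique()
    ybar = df.groupby(group)[value].mean()
    gm = df[value].mean()
    msb = nrep * ((ybar - gm) ** 2).sum() / (g - 1)
    msw = df.groupby(group)[value].apply(
        lambda s: ((s - s.mean()) ** 2).sum()).sum() / (g * (nrep - 1))
    return max(0.0, (msb - msw) / nrep), msw, ybar, gm
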