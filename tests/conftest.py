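import dataclasses

import numpy as np
import pandas as pd
import pytest

from synopath.simulate import GeneratorConfig, generate_cohort

# small, fast study-structure config used across tests; module shift and
# noise keep the default 2:1 signal-to-noise study condition
SMALL_PANEL = dict(n_genes_per_module=20, n_background_genes=32)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=7, **SMALL_PANEL)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_expression():
    """4 genes x 6 samples with two clear groups for hand-checkable DE."""
    rng = np.random.default_rng(5)
    base = rng.normal(8, 1, size=(4, 6))
    base[0, :3] += 3.0  # gene up in group A
    return pd.DataFrame(
        base,
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(6)],
    )


@pytest.fixture()
def two_groups():
    return pd.Series(["A"] * 3 + ["B"] * 3, index=[f"s{i}" for i in range(6)])


def replace(cfg, **kwargs):
    return dataclasses.replace(cfg, **kwargs)
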