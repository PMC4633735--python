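import numpy as np
import pandas as pd
import pytest

from pcafe import (
    MultiOmicsPCA,
    OmicsMatrix,
    SampleDesign,
    SyntheticConfig,
    generate,
)

#: reduced layer sizes for unit tests; acceptance tests use the defaults
SMALL_KWARGS = dict(
    n_features={"compound": 60, "mRNA": 400, "miRNA": 100},
    n_planted_tumor={"compound": 4, "mRNA": 12, "miRNA": 5},
    n_planted_icc={"compound": 4, "mRNA": 12, "miRNA": 4},
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SyntheticConfig(seed=7, **SMALL_KWARGS))


@pytest.fixture(scope="session")
def fitted_results(small_dataset):
    model = MultiOmicsPCA(
        small_dataset.layers, small_dataset.design, log_transform=True
    )
    return model.fit(cut_height=0.4, min_layers=2)


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.lognormal(3.0, 0.5, (12, 8)),
        index=[f"f{i:02d}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    return OmicsMatrix(layer="compound", data=data)


@pytest.fixture
def toy_design():
    assignment = {}
    for i, cls in enumerate(
        ["ICC", "ICC", "ICC_NT", "ICC_NT", "HCC", "HCC", "HCC_NT", "HCC_NT"]
    ):
        assignment[f"s{i}"] = cls
    return SampleDesign(assignment)


def random_matrix(rng, n, m, layer="layer"):
    data = pd.DataFrame(
        rng.normal(0.0, 1.0, (n, m)),
        index=[f"f{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(m)],
    )
    return OmicsMatrix(layer=layer, data=data)
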