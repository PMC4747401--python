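import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from crgpipe import (
    ExpressionMatrix,
    GeneratorConfig,
    generate_cellline_experiment,
    make_sample_table,
    make_truth,
)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples, two groups of two, linear scale."""
    values = pd.DataFrame(
        {
            "a1": [100.0, 10.0, 50.0, 7.0],
            "a2": [300.0, 30.0, 50.0, 9.0],
            "b1": [100.0, 20.0, 50.0, 4.0],
            "b2": [100.0, 20.0, 50.0, 4.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    samples = make_sample_table(
        [{"sample_id": s} for s in values.columns]
    )
    return ExpressionMatrix(values=values, samples=samples, scale="linear")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast, fully featured generator configuration for unit tests."""
    return GeneratorConfig(
        seed=11,
        n_genes=800,
        n_resistance_shared=30,
        n_resistance_specific=30,
        n_stratum=10,
        n_drug_response=80,
        n_basal=40,
        clinical_datasets=((5, 6), (4, 5), (3, 3)),
        post_datasets=((5, 6),),
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    truth = make_truth(small_config)
    matrix, _ = generate_cellline_experiment(small_config, "5-FU", truth)
    return matrix, truth


@pytest.fixture(scope="session")
def default_experiment():
    """The default-scale (5000-gene) experiment used for recovery checks."""
    config = GeneratorConfig(seed=1)
    truth = make_truth(config)
    matrix, _ = generate_cellline_experiment(config, "5-FU", truth)
    return config, matrix, truth


def random_linear_matrix(
    n_genes: int, groups: dict[str, int], seed: int
) -> ExpressionMatrix:
    """Lognormal linear-scale matrix with samples named <group><i>."""
    rng = np.random.default_rng(seed)
    columns, records = [], []
    for group, count in groups.items():
        for i in range(count):
            sid = f"{group}{i}"
            columns.append(sid)
            records.append({"sample_id": sid})
    values = pd.DataFrame(
        np.exp2(rng.normal(7.0, 1.5, size=(n_genes, len(columns)))),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=columns,
    )
    return ExpressionMatrix(values, make_sample_table(records), scale="linear")
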