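import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import netgba as ng

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial simulation: planted DE, modules, coherent terms."""
    return ng.SimulationConfig(
        n_genes=200,
        n_per_group=8,
        n_de_genes=200,
        de_lfc_mean=3.0,
        n_modules=4,
        module_size=25,
        module_rho=0.8,
        noise_sd=1.0,
        n_terms=8,
        term_coherence=0.7,
        min_term_size=23,
        max_term_size=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    matrix, truth = ng.generate_expression(small_config)
    ann, truth = ng.generate_annotations(truth, small_config)
    return matrix, ann, truth


@pytest.fixture(scope="session")
def small_network(small_dataset):
    """DEG network + filtered annotations from the small dataset."""
    matrix, ann, truth = small_dataset
    res = ng.DifferentialExpression(matrix).fit()
    srcc = ng.spearman_matrix(matrix, res.deg_ids)
    net = ng.build_network(srcc)
    filtered = ng.filter_terms(ann.restrict(res.deg_ids), min_genes=20)
    return net, filtered, truth


@pytest.fixture()
def toy_matrix():
    """4 vs 4 samples, 6 genes, hand-sized values."""
    rng = np.random.default_rng(42)
    samples = [f"C{i}" for i in range(4)] + [f"P{i}" for i in range(4)]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=samples,
    )
    groups = pd.Series(["control"] * 4 + ["case"] * 4, index=samples)
    return ng.ExpressionMatrix(values=values, groups=groups, control_group="control")
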