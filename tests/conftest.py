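import numpy as np
import pandas as pd
import pytest

from pathpin import (
    CONTROL,
    DISEASE,
    ExpressionStudy,
    PathwayCollection,
    PPINetwork,
    SyntheticConfig,
    generate_inputs,
    prepare_inputs,
)


def make_study(values: np.ndarray, n_disease: int, n_control: int,
               genes=None) -> ExpressionStudy:
    """Wrap a matrix as a study; first n_disease columns are disease."""
    n_genes, n_samples = values.shape
    assert n_samples == n_disease + n_control
    samples = [f"D{i}" for i in range(n_disease)] + [f"C{i}" for i in range(n_control)]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    labels = pd.Series([DISEASE] * n_disease + [CONTROL] * n_control, index=samples)
    return ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples), labels=labels
    )


@pytest.fixture(scope="session")
def planted_inputs():
    """One reference synthetic study with planted dysregulated pathways."""
    return generate_inputs(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def planted_targeted(planted_inputs):
    return prepare_inputs(
        planted_inputs.study, planted_inputs.pathways, planted_inputs.ppi
    )


@pytest.fixture()
def tiny_study():
    rng = np.random.default_rng(5)
    return make_study(rng.standard_normal((6, 9)), n_disease=5, n_control=4)


@pytest.fixture()
def toy_ppi():
    net = PPINetwork()
    net.add_interaction("g0", "g1", 0.9)
    net.add_interaction("g1", "g2", 0.5)
    net.add_interaction("g3", "g4", 0.7)
    return net
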