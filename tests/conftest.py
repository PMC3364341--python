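import numpy as np
import pandas as pd
import pytest

from dtiforge.containers import DescriptorMatrix, InteractionCatalog
from dtiforge.model import DTIModel, RFConfig
from dtiforge.pairs import SplitSpec, build_pair_dataset, make_split, scale_features
from dtiforge.synthetic import ci_preset


def make_matrix(ids, dim, seed=0, prefix="f"):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.normal(size=(len(ids), dim)),
        index=ids,
        columns=[f"{prefix}{j}" for j in range(dim)],
    )
    return DescriptorMatrix(frame)


@pytest.fixture
def toy_catalog():
    """3 drugs x 3 targets (dims 5 and 7) with 4 known positives."""
    drugs = make_matrix(["d1", "d2", "d3"], 5, seed=1, prefix="c")
    targets = make_matrix(["t1", "t2", "t3"], 7, seed=2, prefix="p")
    positives = {("d1", "t1"), ("d1", "t2"), ("d2", "t2"), ("d3", "t3")}
    return InteractionCatalog(drugs=drugs, targets=targets, positives=positives)


@pytest.fixture(scope="session")
def ci_world():
    """The default desk-scale synthetic fixture (60 x 60, seed 17)."""
    return ci_preset(seed=17)


@pytest.fixture(scope="session")
def ci_rf(ci_world):
    """RF trained on a scenario-I split of the CI fixture, plus its test set."""
    _, catalog = ci_world
    dataset = build_pair_dataset(catalog, seed=1)
    train, test = make_split(dataset, SplitSpec("I", 0.2, 1))
    train, (test,), _ = scale_features(train, [test])
    results = DTIModel(train, "rf", RFConfig(seed=1)).fit()
    return results, train, test


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
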