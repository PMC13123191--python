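import numpy as np
import pandas as pd
import pytest

from qsarkit.chem import standardize
from qsarkit.fixtures import SyntheticSpec, gen_molecules
from qsarkit.resample import METRICS, ScoreMatrix


def make_score_matrix(arr, metric="r2", names=None) -> ScoreMatrix:
    """Wrap a plain (n_blocks x n_contenders) array as a ScoreMatrix."""
    arr = np.asarray(arr, float)
    names = names or [f"h{j}" for j in range(arr.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [(i, 0) for i in range(arr.shape[0])], names=["fold", "repeat"]
    )
    return ScoreMatrix(list(names), METRICS[metric], pd.DataFrame(arr, index=idx, columns=names))


@pytest.fixture(scope="session")
def sm_factory():
    return make_score_matrix


@pytest.fixture(scope="session")
def linear_dataset():
    """60 molecules in 3 scaffold families; noise-free linear target."""
    spec = SyntheticSpec(n_molecules=60, scaffold_families=3, noise_sd=0.0, seed=11)
    return gen_molecules(spec)


@pytest.fixture(scope="session")
def linear_records(linear_dataset):
    return [
        standardize(s, id=i, target=t)
        for i, s, t in zip(
            linear_dataset["id"], linear_dataset["smiles"], linear_dataset["target"]
        )
    ]
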