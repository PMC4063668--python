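import numpy as np
import pandas as pd
import pytest

from tandemcnv import synthetic_data
from tandemcnv.io_formats import Alignment, FeatureMatrix, ProbeAnnotation, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240619)


@pytest.fixture
def small_truth():
    """Six-probe study with four variable loci, balanced three-population cohort."""
    return synthetic_data.default_truth(
        7, n_test_probes=6, n_ceu=20, n_yri=20, n_chb=16, n_differentiated=2
    )


@pytest.fixture
def tiny_samples():
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(8)],
            "population": ["CEU"] * 4 + ["YRI"] * 4,
            "sex": ["male", "female"] * 4,
            "species": "human",
        }
    ).set_index("sample_id")
    return SampleTable(df)


@pytest.fixture
def one_probe():
    return ProbeAnnotation(
        probe_id="p1",
        target_name="GENE1",
        probe_class="test",
        alignments=[Alignment("chr1", 300_000, 301_000, "+", 100.0)],
    )


def make_matrix(values, probes=None, samples=None, coords=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return FeatureMatrix(pd.DataFrame(values, index=probes, columns=samples), coords)
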