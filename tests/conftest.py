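import numpy as np
import pytest

from hypredict.data import split_dataset
from hypredict.synth import DEFAULT_CONFIG, generate_dataset


@pytest.fixture(scope="session")
def small_table():
    """100-sample synthetic dataset, the field-study scale."""
    return generate_dataset(DEFAULT_CONFIG, n=100, seed=11)


@pytest.fixture(scope="session")
def small_split():
    return split_dataset(100, (0.6, 0.2, 0.2), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def sample_csv(tmp_path):
    """A tiny hand-written CSV with text labels and shuffled column order."""
    path = tmp_path / "samples.csv"
    path.write_text(
        "Hill aspect,Altitude (m),Slope (%),Phenological stage,Organic carbon,"
        "Total nitrogen,Absorbable phosphor,Absorbable potassium,Sand,Silt,Clay,"
        "EC,pH,Hypericin content\n"
        "north,1500,10,vegetative,0.5,0.2,2.0,150,40,38,22,0.05,7.0,1.4\n"
        "2,2500,20,flowering,1.2,0.35,3.5,200,42,36,22,0.09,7.2,1.7\n"
        "west,3500,30,3,2.0,0.5,4.0,250,44,34,22,0.12,7.5,1.9\n"
    )
    return path
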