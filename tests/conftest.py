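import pandas as pd
import pytest

from pacpipe.config import PipelineConfig
from pacpipe.simdata import SimConfig, generate_dataset


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 20-gene simulated cohort shared by read-only tests."""
    out = tmp_path_factory.mktemp("simdata")
    truth = generate_dataset(SimConfig(n_genes=20, seed=7), out)
    return out, truth


@pytest.fixture
def design_3v3():
    samples = [f"{c}_{r}" for c in ("control", "treated") for r in (1, 2, 3)]
    return pd.DataFrame(
        {
            "sample_id": samples,
            "condition": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    )
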