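import numpy as np
import pandas as pd
import pytest

from mosaicn.simulate import SimulationConfig, simulate_ct_table


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=20240101)


@pytest.fixture(scope="session")
def ct_with_truth(default_config):
    """One simulated single-nucleus Ct table with its truth table."""
    return simulate_ct_table(default_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_ct_table(ct_values_by_assay: dict[str, list[float]],
                  unit_id: str = "u1") -> pd.DataFrame:
    """Tiny replicate table for one unit from explicit Ct lists."""
    rows = []
    for assay, values in ct_values_by_assay.items():
        for i, ct in enumerate(values):
            rows.append({
                "unit_id": unit_id, "brain_id": "b1", "region": "CTX",
                "group": "AD", "assay_id": assay, "replicate_index": i,
                "ct": ct,
            })
    return pd.DataFrame(rows)
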