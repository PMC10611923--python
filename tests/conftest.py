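import pandas as pd
import pytest

from h3k9net import SampleInfo, SimulationConfig, SpectralCountTable, simulate_study


def make_table(columns: dict[str, dict[str, int]], samples: dict[str, tuple[str, str]]) -> SpectralCountTable:
    """Build a small wide-form count table from {sample: {protein: count}}."""
    df = pd.DataFrame(columns).fillna(0).astype(int)
    return SpectralCountTable(df, {s: SampleInfo(*samples[s]) for s in samples})


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def bundle(sim_config):
    """One full synthetic study shared by the read-only tests."""
    return simulate_study(sim_config)


@pytest.fixture()
def toy_counts() -> SpectralCountTable:
    """Two baits, one phase: a clear hit, a low-count protein, a balanced
    protein, and a highly enriched keratin."""
    return make_table(
        {
            "EHMT1_G1S": {"AAA1": 20, "BBB2": 3, "CCC3": 10, "KRT18": 40},
            "CBX5_G1S": {"AAA1": 0, "BBB2": 8, "CCC3": 12, "KRT18": 0},
            "IgG_G1S": {"AAA1": 1, "BBB2": 0, "CCC3": 9, "KRT18": 2},
        },
        {
            "EHMT1_G1S": ("EHMT1", "G1S"),
            "CBX5_G1S": ("CBX5", "G1S"),
            "IgG_G1S": ("IgG", "G1S"),
        },
    )
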