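import numpy as np
import pytest

from assemblage.io_tables import CommunityTable
from assemblage.synthetic_data import GuildPlan, simulate_dataset


@pytest.fixture
def tiny_table() -> CommunityTable:
    """3 OTUs x 4 samples, two groups, handmade counts."""
    counts = np.array(
        [
            [10, 0, 3, 7],
            [2, 2, 2, 2],
            [0, 5, 1, 4],
        ]
    )
    samples = ("s1", "s2", "s3", "s4")
    return CommunityTable(
        counts=counts,
        otu_ids=("otuA", "otuB", "otuC"),
        sample_ids=samples,
        groups={"s1": "X", "s2": "X", "s3": "Y", "s4": "Y"},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic mixed-process dataset with planted guilds (2 groups)."""
    return simulate_dataset(
        S=60,
        groups={"A": 6, "B": 6},
        lam=0.5,
        guild_plan=GuildPlan(n_wide=4, n_narrow=4),
        depth=3000,
        seed=42,
        N=300,
    )


@pytest.fixture(scope="session")
def small_table(small_dataset) -> CommunityTable:
    return small_dataset[0]
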