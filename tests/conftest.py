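import numpy as np
import pandas as pd
import pytest

from rootfungi import CommunityTable, SampleMetadata


@pytest.fixture
def toy_table() -> CommunityTable:
    return CommunityTable(
        pd.DataFrame(
            [[5, 3, 1, 1], [10, 0, 0, 0], [1, 1, 0, 0]],
            index=["r1", "r2", "r3"],
            columns=["o1", "o2", "o3", "o4"],
        )
    )


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    rows = []
    for q, (x, y) in enumerate([(0, 0), (10, 0), (0, 10), (10, 10)]):
        pid = f"p{q}"
        rows.append(("soil_" + pid, "soil", pid, x, y, None))
        for i in range(2):
            host = "Pinus" if (q + i) % 2 == 0 else "Betula"
            rows.append((f"root_{pid}_{i}", "root", pid, x, y, host))
    return SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "kind", "position_id", "x", "y", "host_plant"])
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded root/soil dataset with moderate effects."""
    from rootfungi.simulate import GuildArchetype, TruthParams, generate_dataset

    params = TruthParams(
        n_positions=24,
        plants=("Pinus", "Betula", "Acer"),
        samples_per_position_mean=4.0,
        guilds={
            "EcMF": GuildArchetype(8, 0.0, 1.0, 10.0, 0.6, 0.3),
            "Endophyte": GuildArchetype(8, 0.5, 0.1, 5.0, 0.1, 1.0),
        },
        n_latent_factors=2,
        root_depth_mean=5e3,
        soil_depth_mean=2e4,
    )
    return generate_dataset(params, seed=42)
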