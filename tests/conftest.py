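import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from snowcat.diversity import OtuTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(counts: dict[str, list[int]], otus: list[str] | None = None) -> OtuTable:
    """Build a tiny OtuTable from {sample_id: counts}; metadata is synthesised."""
    frame = pd.DataFrame.from_dict(counts, orient="index")
    if otus is not None:
        frame.columns = otus
    else:
        frame.columns = [f"OTU_{i}" for i in range(frame.shape[1])]
    frame = frame.astype(np.int64)
    meta = pd.DataFrame(
        {"fraction": "nonsink", "depth_m": 28, "replicate": 1}, index=frame.index
    )
    return OtuTable(frame, meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default-scenario synthetic study, shared across tests."""
    from snowcat import synthetic

    return synthetic.simulate_dataset(seed=11)
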