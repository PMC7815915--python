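import numpy as np
import pytest

from sfpa import (
    EventTable,
    SimConfig,
    SubjectTimeseries,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Strong-coupling synthetic study at a small scale (shared across tests)."""
    cfg = SimConfig(n_subjects=6, n_trs=240, n_events=12, seed=7)
    return generate_dataset(cfg), cfg


@pytest.fixture()
def toy_subjects():
    """3 subjects x 2 ROIs x 31 TRs of reproducible noise."""
    rng = np.random.default_rng(42)
    return [
        SubjectTimeseries.from_raw(
            f"s{k}", rng.standard_normal((2, 31)), 1.5, ["roiA", "roiB"]
        )
        for k in range(3)
    ]


@pytest.fixture()
def simple_events():
    return EventTable.from_onsets(
        ["e1", "e2", "e3"], [15.0, 25.5, 36.0], 1.5
    )
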