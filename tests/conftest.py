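import numpy as np
import pytest

from goldilocks import (
    AgentParams,
    BoxGeometry,
    build_event_table,
    make_benchmark_dataset,
    make_sequence,
)


@pytest.fixture(scope="session")
def geometry() -> BoxGeometry:
    """Fixed, well-separated box placement for constructed gaze fixtures."""
    return BoxGeometry(((480.0, 200.0), (1440.0, 200.0), (960.0, 880.0)))


@pytest.fixture(scope="session")
def small_dataset():
    """Small but complete simulated dataset (3 subjects x 20 sequences x 15 events)."""
    return make_benchmark_dataset(
        n_subjects=3, n_sequences=20, length=15, seed=42, candidate_pool_size=60
    )


@pytest.fixture(scope="session")
def small_event_table(small_dataset):
    ds = small_dataset
    return build_event_table(ds.trials, ds.sequences.by_id(), ds.traces)


def make_seq(ids, geometry, duration_ms=1500, sequence_id="seq"):
    return make_sequence(ids, geometry, duration_ms=duration_ms, sequence_id=sequence_id)
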