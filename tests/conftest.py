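import numpy as np
import pytest

from neurorace.lif import SpikeRecord
from neurorace.topology import CATopology, generate_topology


@pytest.fixture(scope="session")
def default_topology() -> CATopology:
    """Standard 500-neuron, out-degree-30 assembly at the calibrated weight."""
    return generate_topology(500, 30, seed=1)


@pytest.fixture
def two_neuron_topology() -> CATopology:
    return CATopology(
        n_neurons=2, k_out=1, pre=np.array([0, 1]), post=np.array([1, 0]), weight=0.1, seed=0
    )


def make_record(times, n_neurons=500, t_end=None, ids=None):
    """SpikeRecord from a bare list of spike times (neuron ids synthetic)."""
    times = np.sort(np.asarray(times, dtype=np.int64))
    if ids is None:
        ids = np.zeros(len(times), dtype=np.int64)
        # distinct ids within each ms so the one-spike-per-neuron invariant holds
        for t in np.unique(times):
            m = times == t
            ids[m] = np.arange(m.sum())
    t_end = t_end if t_end is not None else (int(times.max()) if len(times) else 0)
    counts = np.bincount(times, minlength=t_end + 1)
    return SpikeRecord(times=times, neuron_ids=ids, counts_per_ms=counts, n_neurons=n_neurons)
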