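import numpy as np
import pytest

import meacircuit as mc


@pytest.fixture
def small_map():
    """Two electrodes per node, no tunnels."""
    return mc.simulation_electrode_map(2)


@pytest.fixture
def sim_table():
    """A 60 s default simulation with ground truth (seed fixed)."""
    cfg = mc.NetworkSimConfig(seed=11)
    return mc.simulate_spike_trains(cfg, 60.0)


def make_table(spikes: dict, duration: float, emap=None):
    emap = emap or mc.ElectrodeMap([(eid, _label(eid)) for eid in spikes])
    return mc.SpikeTable.from_arrays(
        {k: np.asarray(v, float) for k, v in spikes.items()}, duration, emap
    )


def _label(eid):
    for lab in ("H1", "H2", "H3"):
        if eid.startswith(lab):
            return lab
    if eid.startswith("T"):
        return "TUNNEL"
    return "C"
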