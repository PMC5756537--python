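import numpy as np
import pytest

from iclvol.ephys_sim import CellModel, ChannelModel, make_step_protocol, simulate_trace
from iclvol.ephys_fit import step_iv

EREV = -19.0


@pytest.fixture(scope="session")
def step_protocol():
    return make_step_protocol()


def noise_free_iv(gmax, vh, k, protocol, erev=EREV, leak=0.0, leak_erev=0.0, cell_id=None):
    """Simulate a noise-free cell and return its steady-state I-V curve."""
    ch = ChannelModel(gmax, vh, k, erev_mV=erev,
                      leak_pS_per_pF=leak, leak_erev_mV=leak_erev)
    cell = CellModel(iso=ch, hypo=ch, noise_sd_pA=0.0)
    trace = simulate_trace(cell, protocol, "iso")
    return step_iv(trace, protocol, cell_id=cell_id)


def rel_err(estimate, truth):
    """Relative error with a 1-unit floor in the denominator (Vh may be 0)."""
    return abs(estimate - truth) / max(abs(truth), 1.0)
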