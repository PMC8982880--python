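"""Shared fixtures: paced gate-model traces and derived target windows.

The four reference simulations (TP/ST × FULL/SCI, 11 pulses at 1 Hz) are
computed once per session; targets are windows of those traces, so tests
never re-simulate them.
"""

import numpy as np
import pytest

from icalmc.gate_models import build_gate_model
from icalmc.markov_ical import MCParameterSet, assemble_hybrid
from icalmc.simulate import (ProtocolSpec, IntegratorSettings, run_protocol,
                             extract_window)

WINDOW = (10000.0, 11000.0)


def _gate_trace(model_id, mode):
    return run_protocol(build_gate_model(model_id), ProtocolSpec(mode=mode))


@pytest.fixture(scope="session")
def tp_full_trace():
    return _gate_trace("TP", "FULL")


@pytest.fixture(scope="session")
def tp_sci_trace():
    return _gate_trace("TP", "SCI")


@pytest.fixture(scope="session")
def st_full_trace():
    return _gate_trace("ST", "FULL")


@pytest.fixture(scope="session")
def st_sci_trace():
    return _gate_trace("ST", "SCI")


@pytest.fixture(scope="session")
def tp_full_beat(tp_full_trace):
    return extract_window(tp_full_trace, *WINDOW)


@pytest.fixture(scope="session")
def tp_sci_beat(tp_sci_trace):
    return extract_window(tp_sci_trace, *WINDOW)


@pytest.fixture(scope="session")
def st_full_beat(st_full_trace):
    return extract_window(st_full_trace, *WINDOW)


@pytest.fixture(scope="session")
def st_sci_beat(st_sci_trace):
    return extract_window(st_sci_trace, *WINDOW)


@pytest.fixture(scope="session")
def tp_hybrid_trace():
    """TP hybrid (x = 1) paced 11 s, with full state history attached."""
    model = assemble_hybrid("TP", MCParameterSet.ones())
    return run_protocol(model, ProtocolSpec(), keep_states=True), model
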