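import math

import numpy as np
import pytest

from lamellipod import SimParams, init_state
from lamellipod.state import SimState, B_POLY, B_CAPPED, B_STATIC


@pytest.fixture
def quiet_params():
    """All kinetics off: a frozen network that only advects."""
    return SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                     vnet=0.2, kunifsev=0, kendsev=0, lmaxolig=0, kanneal=0)


def make_filament(state, anchor, direction, length, barbed_state=B_STATIC,
                  parent=-1):
    i = state.new_filament(anchor, direction, length, barbed_state,
                          parent=parent)
    state.ledger.polymerized_total += length
    state.ledger.in_network += length
    return i


@pytest.fixture
def empty_state(quiet_params):
    return SimState(quiet_params, seed=0)


def straight_into_cell(state, d_barbed, length, barbed_state=B_STATIC,
                       x=0.5, z=0.1):
    """A filament along the -d axis with its barbed end at depth d_barbed
    (pointed end deeper in the cell)."""
    ell = state.params.subunit_length
    anchor = (x, d_barbed + (length - 1) * ell, z)
    return make_filament(state, anchor, (0.0, -1.0, 0.0), length,
                         barbed_state)
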