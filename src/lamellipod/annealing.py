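"""Oligomer diffusion kernel, annealing probabilities and execution.

Oligomer positions are not simulated explicitly: the probability density of
finding the end of a non-annealed oligomer displaced by ``(dx, dy)`` from
its creation point after time ``dt`` is the free 2D diffusion Green's
function.  Converting that density to a local concentration (uniform across
the thin z dimension) turns annealing into a bimolecular reaction with rate
constant ``kanneal`` against every available free end.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import SimParams, MOLECULES_PER_UM3_PER_UM
from . import state as _state

END_BARBED = 0
END_POINTED = 1


def diffusion_kernel(dx: float, dy: float, dt: float, Dolig: float) -> float:
    """2D Gaussian probability density (um^-2) for displacement (dx, dy)
    after time dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if Dolig <= 0:
        raise ValueError("Dolig must be positive")
    s = 4.0 * Dolig * dt
    return math.exp(-(dx * dx + dy * dy) / s) / (math.pi * s)


def local_concentration(dx: float, dy: float, age: float,
                        params: SimParams) -> float:
    """Local oligomer concentration (uM) at displacement (dx, dy) from the
    creation point, assuming uniform probability across the z thickness."""
    pd = diffusion_kernel(dx, dy, age, params.Dolig)
    return pd / params.z_thickness / MOLECULES_PER_UM3_PER_UM


@njit(cache=True)
def _pair_scan(ox, od, age, uncapped, ex, ed, ekind, Lx, coef, Dolig,
               u_accept, u_choose):
    """For each oligomer: total annealing probability against all eligible
    ends and one end drawn in proportion to the pairwise probabilities.

    ``coef = kanneal * dt / (z_thickness * molecules_per_um3_per_uM)`` so
    that ``p_ij = coef * PD(dx, dy, age_i)``.  Pointed-end candidates are
    skipped for capped oligomers.  Returns (chosen end index or -1, total
    probability) per oligomer.
    """
    n_o = ox.shape[0]
    n_e = ex.shape[0]
    chosen = np.full(n_o, -1, np.int64)
    totals = np.zeros(n_o)
    for i in range(n_o):
        s = 4.0 * Dolig * age[i]
        norm = coef / (math.pi * s)
        total = 0.0
        for j in range(n_e):
            if ekind[j] == 1 and not uncapped[i]:
                continue
            dx = abs(ox[i] - ex[j])
            if dx > 0.5 * Lx:
                dx = Lx - dx
            r2 = dx * dx + (od[i] - ed[j]) ** 2
            arg = r2 / s
            if arg < 40.0:
                total += norm * math.exp(-arg)
        totals[i] = total
        p_accept = total if total < 1.0 else 1.0
        if total <= 0.0 or u_accept[i] >= p_accept:
            continue
        thresh = u_choose[i] * total
        acc = 0.0
        for j in range(n_e):
            if ekind[j] == 1 and not uncapped[i]:
                continue
            dx = abs(ox[i] - ex[j])
            if dx > 0.5 * Lx:
                dx = Lx - dx
            r2 = dx * dx + (od[i] - ed[j]) ** 2
            arg = r2 / s
            if arg < 40.0:
                acc += norm * math.exp(-arg)
                if acc >= thresh:
                    chosen[i] = j
                    break
        if chosen[i] == -1:         # numerical tail
            chosen[i] = n_e - 1
    return chosen, totals


def candidate_ends(state: "_state.SimState"):
    """Eligible filament ends: free static barbed ends and free pointed
    ends.  Returns (filament slots, end kinds, x, d)."""
    barbed = np.flatnonzero(state.alive
                            & (state.barbed_state == _state.B_STATIC))
    pointed = np.flatnonzero(state.alive & (state.parent < 0))
    slots = np.concatenate([barbed, pointed])
    kinds = np.concatenate([np.zeros(barbed.size, np.int8),
                            np.ones(pointed.size, np.int8)])
    Lx = state.params.Lx
    ex = np.concatenate([state.tip_x[barbed] % Lx, state.pt_x[pointed] % Lx])
    ed = np.concatenate([state.tip_d[barbed], state.pt_d[pointed]])
    return slots, kinds, ex, ed


def execute_anneal(state: "_state.SimState", fil: int, end_kind: int,
                   olig: int) -> None:
    """Join oligomer ``olig`` end-to-end onto filament ``fil``.

    Barbed-end annealing transfers the oligomer's barbed-end state to the
    filament (a polymerizing oligomer re-arms elongation); pointed-end
    annealing extends the filament at the pointed side.  Tags carried by
    the oligomer re-enter the network as new speckle appearances.
    """
    ell = state.params.subunit_length
    Lo = int(state.o_len[olig])
    ostate = int(state.o_state[olig])
    if end_kind == END_BARBED:
        if state.barbed_state[fil] != _state.B_STATIC:
            raise ValueError("annealing requires a free static barbed end")
        a_start = int(state.p_off[fil] + state.length[fil])
        state.length[fil] += Lo
        state.tip_x[fil] += Lo * ell * state.tip_ux[fil]
        state.tip_d[fil] += Lo * ell * state.tip_ud[fil]
        state.tip_z[fil] += Lo * ell * state.tip_uz[fil]
        state.barbed_state[fil] = ostate
        new_tags = [[a_start + rel, tag]
                    for rel, tag in state.olig_tags.get(olig, [])]
    else:
        if state.parent[fil] >= 0:
            raise ValueError("annealing requires a free pointed end")
        if ostate == _state.B_CAPPED:
            raise ValueError("capped oligomers cannot anneal to pointed ends")
        state.p_off[fil] -= Lo
        state.length[fil] += Lo
        new_tags = [[int(state.p_off[fil]) + rel, tag]
                    for rel, tag in state.olig_tags.get(olig, [])]
        # pointed-end position extends along the existing axis
        from .kinetics import _recompute_pt
        _recompute_pt(state, fil)
    for a, tag in new_tags:
        state.add_tag(fil, a, tag)
        _, d, _ = state.position(fil, a)
        state.speckles.appear(tag, state.t, d, "annealed_in")
    state.ledger.in_oligomers -= Lo
    state.ledger.in_network += Lo
    state.release_oligomer(olig)


def annealing_sweep(state: "_state.SimState", params: SimParams, out,
                    rng) -> None:
    """Scan all oligomer/end pairs and execute at most one annealing per
    oligomer, each end claimed at most once, in a randomized oligomer
    order."""
    oli = np.flatnonzero(state.o_alive)
    if oli.size == 0:
        return
    slots, kinds, ex, ed = candidate_ends(state)
    if slots.size == 0:
        return
    order = rng.permutation(oli.size)
    oli = oli[order]
    age = np.maximum(state.t - state.o_t[oli], params.dt)
    uncapped = state.o_state[oli] != _state.B_CAPPED
    coef = params.kanneal * params.dt / (params.z_thickness
                                         * MOLECULES_PER_UM3_PER_UM)
    chosen, _totals = _pair_scan(
        state.o_x[oli], state.o_d[oli], age, uncapped,
        ex, ed, kinds, params.Lx, coef, params.Dolig,
        rng.random(oli.size), rng.random(oli.size))
    used = set()
    Lx = params.Lx
    for k in np.flatnonzero(chosen >= 0):
        j = int(chosen[k])
        if j in used:
            continue                # end already claimed this step
        o = int(oli[k])
        fil = int(slots[j])
        if not state.alive[fil]:
            continue
        used.add(j)
        dx = abs(float(state.o_x[o]) - float(ex[j]))
        dx = min(dx, Lx - dx)
        dist = math.hypot(dx, float(state.o_d[o]) - float(ed[j]))
        size = int(state.o_len[o])
        t_travel = float(age[k])        # the age the kernel was evaluated at
        state.log_event("anneal", ex[j], ed[j], 0.0, int(state.uid[fil]),
                        (size, dist, t_travel))
        execute_anneal(state, fil, int(kinds[j]), o)
        out.annealings += 1
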