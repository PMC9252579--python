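"""Fixed-timestep stochastic event engine.

Each step applies, in fixed order: advection, branching, polymerization,
depolymerization (pointed ends, then rapid barbed ends in the catastrophe
variant), capping/uncapping, debranching, severing, the annealing sweep and
oligomer expiry.  Every reaction is a Bernoulli trial with probability
``rate * dt``; probabilities are small enough that the ordering bias is
negligible, and the fixed order makes runs exactly reproducible for a given
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import SimParams
from .state import (SimState, advect, B_POLY, B_CAPPED, B_STATIC, B_RAPID,
                    B_REPOL)
from . import annealing as _annealing

_DEG = math.pi / 180.0


@dataclass
class StepOutcome:
    """Event counts for one time step."""
    polymerizations: int = 0
    depolymerizations: int = 0
    caps: int = 0
    uncaps: int = 0
    branches: int = 0
    debranches: int = 0
    uniform_severings: int = 0
    end_severings: int = 0
    oligomers_created: int = 0
    oligomers_removed: int = 0
    annealings: int = 0

    def total_events(self) -> int:
        return sum(getattr(self, name) for name in self.__dataclass_fields__)


# ----------------------------------------------------------------------
# geometry helpers: eligible coordinate windows on piecewise-linear chains
# ----------------------------------------------------------------------


@njit(cache=True)
def _windows_kernel(p_off, length, kink_a, anchor_d, a0, ud, kink_d, kud,
                    ell, jmin, jmax, dmin, above):
    """Per-filament eligible coordinate windows.

    A filament's depth is piecewise linear in the subunit coordinate
    (one linear piece per side of the kink).  For each filament this
    returns, per piece, the contiguous range of coordinates inside
    ``[jmin, jmax]`` whose depth is ``>= dmin`` (``above``) or ``< dmin``,
    as (start, count) pairs.
    """
    n = p_off.shape[0]
    el1 = np.zeros(n, np.int64)
    n1 = np.zeros(n, np.int64)
    el2 = np.zeros(n, np.int64)
    n2 = np.zeros(n, np.int64)
    for k in range(n):
        p = p_off[k]
        ab = p + length[k]
        ka = kink_a[k]
        if ka >= 0:
            kb = min(max(ka, p), ab)
        else:
            kb = ab
        # piece 1: [p, kb) with depth anchor_d + (a - a0) * ell * ud
        for piece in range(2):
            if piece == 0:
                lo, hi = p, kb
                c = anchor_d[k]
                r = float(a0[k])
                m = ell * ud[k]
            else:
                if kb >= ab:
                    continue
                lo, hi = kb, ab
                c = kink_d[k]
                r = float(ka)
                m = ell * kud[k]
            el = lo if lo > jmin[k] else jmin[k]
            eh = hi - 1 if hi - 1 < jmax[k] else jmax[k]
            if m != 0.0:
                crossing = r + (dmin - c) / m
                if above:
                    if m > 0.0:
                        cc = int(np.ceil(crossing))
                        if cc > el:
                            el = cc
                    else:
                        ff = int(np.floor(crossing))
                        if ff < eh:
                            eh = ff
                else:
                    if m < 0.0:
                        ff = int(np.floor(crossing)) + 1
                        if ff > el:
                            el = ff
                    else:
                        cc = int(np.ceil(crossing)) - 1
                        if cc < eh:
                            eh = cc
            else:
                ok = (c >= dmin) if above else (c < dmin)
                if not ok:
                    eh = el - 1
            cnt = eh - el + 1
            if cnt < 0:
                cnt = 0
            if piece == 0:
                el1[k] = el
                n1[k] = cnt
            else:
                el2[k] = el
                n2[k] = cnt
    return el1, n1, el2, n2


def _eligible_windows(state: SimState, idx: np.ndarray, jmin, jmax,
                      dmin: float, above=True):
    """Eligible coordinates per filament as up to two inclusive ranges,
    plus the total count."""
    jmin = np.broadcast_to(np.asarray(jmin, np.int64), idx.shape)
    jmax = np.broadcast_to(np.asarray(jmax, np.int64), idx.shape)
    el1, n1, el2, n2 = _windows_kernel(
        state.p_off[idx], state.length[idx], state.kink_a[idx],
        state.anchor_d[idx], state.a0[idx], state.ud[idx],
        state.kink_d[idx], state.kud[idx], state.params.subunit_length,
        np.ascontiguousarray(jmin), np.ascontiguousarray(jmax),
        dmin, above)
    return (el1, n1, el2, n2), n1 + n2


def _sample_window(windows, k, which) -> int:
    """The ``k``-th eligible coordinate of filament ``which``."""
    el1, n1, el2, n2 = windows
    if k < n1[which]:
        return int(el1[which] + k)
    return int(el2[which] + (k - n1[which]))


# ----------------------------------------------------------------------
# branch orientation
# ----------------------------------------------------------------------

_PLANE_LIMIT = {"planar_1deg": math.sin(1.0 * _DEG),
                "quasi2d_10deg": math.sin(10.0 * _DEG),
                "uniform3d": 2.0}
_BACKWARD_COS = math.cos(80.0 * _DEG)


def sample_branch_orientation(parent_dir, params: SimParams, rng,
                              max_tries: int = 4000):
    """Draw a daughter direction at ~70 deg (s.d. 5 deg) from the parent.

    The azimuth around the parent axis is uniform, constrained by
    ``branch_mode`` to lie within the stated angle of the lamellipodial
    xy-plane.  Returns ``None`` when no azimuth satisfies the planarity
    constraint (e.g. a parent nearly normal to the plane).
    """
    px, pd, pz = parent_dir
    # orthonormal basis perpendicular to the parent axis
    if abs(pz) < 0.9:
        ax, ad, az = 0.0, 0.0, 1.0
    else:
        ax, ad, az = 1.0, 0.0, 0.0
    e1x = pd * az - pz * ad
    e1d = pz * ax - px * az
    e1z = px * ad - pd * ax
    n1 = math.sqrt(e1x * e1x + e1d * e1d + e1z * e1z)
    e1x, e1d, e1z = e1x / n1, e1d / n1, e1z / n1
    e2x = pd * e1z - pz * e1d
    e2d = pz * e1x - px * e1z
    e2z = px * e1d - pd * e1x
    zlim = _PLANE_LIMIT[params.branch_mode]
    for _ in range(max_tries):
        theta = rng.normal(70.0, 5.0) * _DEG
        psi = rng.uniform(0.0, 2.0 * math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        cp, sp = math.cos(psi), math.sin(psi)
        vx = ct * px + st * (cp * e1x + sp * e2x)
        vd = ct * pd + st * (cp * e1d + sp * e2d)
        vz = ct * pz + st * (cp * e1z + sp * e2z)
        if abs(vz) <= zlim:
            return (vx, vd, vz)
    return None


def _is_backward(direction) -> bool:
    """Projected angle to the protrusion axis (toward the edge, -d)
    exceeds 80 degrees."""
    vx, vd, _ = direction
    h = math.hypot(vx, vd)
    if h == 0.0:
        return True
    return (-vd) / h < _BACKWARD_COS


# ----------------------------------------------------------------------
# structural event helpers
# ----------------------------------------------------------------------

def _to_oligomer(state: SimState, i: int, out: "StepOutcome") -> None:
    """Detach filament ``i`` from the network as a diffusing oligomer
    (or discard it when annealing is disabled)."""
    p = state.params
    L = int(state.length[i])
    tags = state.tags.get(i, [])
    poff = int(state.p_off[i])
    for a, tag in tags:
        _, d, _ = state.position(i, a)
        state.speckles.disappear(tag, state.t, d, "entered_oligomer")
    x, d = float(state.tip_x[i]), float(state.tip_d[i])
    state.ledger.in_network -= L
    out.oligomers_created += 1
    if p.kanneal > 0.0:
        rel = [[a - poff, tag] for a, tag in tags]
        j = state.new_oligomer(x, d, L, int(state.barbed_state[i]),
                               rel or None)
        state.ledger.in_oligomers += L
        state.log_event("oligomer_created", x, d, state.tip_z[i],
                        int(state.o_uid[j]), L)
    else:
        state.ledger.removed += L
        out.oligomers_removed += 1
        state.log_event("oligomer_discarded", x, d, state.tip_z[i],
                        int(state.uid[i]), L)
    state.release_filament(i)


def _classify_piece(state: SimState, i: int, out: "StepOutcome") -> None:
    """Severed/debranched/shrunk piece: oligomer iff short, not a branch
    and containing no branches."""
    p = state.params
    if (state.length[i] <= p.lmaxolig and state.parent[i] < 0
            and state.n_children[i] == 0 and p.lmaxolig > 0):
        _to_oligomer(state, i, out)


def _release_junction(state: SimState, child: int, out: "StepOutcome",
                      check_parent: bool = True) -> None:
    """Release an Arp2/3 junction: the branch keeps its place in the
    network with a now-free (depolymerizing) pointed end.

    Debranching itself never detaches the branch as an oligomer; a released
    branch leaves the network only later, through severing or through
    pointed-end depolymerization shrinking it to oligomer size.
    """
    par = int(state.parent[child])
    state.remove_child(par, child)
    state.parent[child] = -1
    out.debranches += 1
    state.log_event("debranch", state.pt_x[child], state.pt_d[child],
                    state.pt_z[child], int(state.uid[child]))
    if check_parent:
        _maybe_auto_debranch(state, par, out)


def _maybe_auto_debranch(state: SimState, i: int, out: "StepOutcome") -> None:
    """With kdebr = 0, a branch shrunk to <= 5 subunits with no branches of
    its own detaches (mimicking dissociation of tiny Arp2/3-bound stubs).

    The check is event-triggered on shortening, so nascent growing branches
    are never affected.
    """
    if (state.params.kdebr == 0.0 and state.alive[i]
            and state.parent[i] >= 0 and state.length[i] <= 5
            and state.n_children[i] == 0):
        _release_junction(state, i, out)


def _recompute_tip(state: SimState, i: int) -> None:
    ab1 = int(state.p_off[i] + state.length[i]) - 1
    ka = state.kink_a[i]
    if ka >= 0 and ab1 < ka:
        state.kink_a[i] = -1        # tip retreated before the kink
        ka = -1
    state.tip_x[i], state.tip_d[i], state.tip_z[i] = state.position(i, ab1)
    if ka >= 0 and ab1 >= ka:
        state.tip_ux[i], state.tip_ud[i], state.tip_uz[i] = (
            state.kux[i], state.kud[i], 0.0)
    else:
        state.tip_ux[i], state.tip_ud[i], state.tip_uz[i] = (
            state.ux[i], state.ud[i], state.uz[i])


def _recompute_pt(state: SimState, i: int) -> None:
    poff = int(state.p_off[i])
    state.pt_x[i], state.pt_d[i], state.pt_z[i] = state.position(i, poff)
    ka = state.kink_a[i]
    if ka >= 0 and poff >= ka:
        state.pt_ux[i], state.pt_ud[i], state.pt_uz[i] = (
            state.kux[i], state.kud[i], 0.0)
    else:
        state.pt_ux[i], state.pt_ud[i], state.pt_uz[i] = (
            state.ux[i], state.ud[i], state.uz[i])


# ----------------------------------------------------------------------
# sub-operations
# ----------------------------------------------------------------------

def attempt_branch(state: SimState, params: SimParams, out: StepOutcome,
                   rng) -> None:
    if params.kbr <= 0.0:
        return
    if rng.random() >= params.kbr * params.Lx * params.dt:
        return
    idx = state.filament_indices()
    if idx.size == 0:
        return
    ab1 = state.p_off[idx] + state.length[idx] - 1
    windows, counts = _eligible_windows(
        state, idx, state.p_off[idx], ab1,
        params.branching_region_depth, above=False)
    total = int(counts.sum())
    if total == 0:
        return
    cum = np.cumsum(counts)
    for _ in range(100):
        pick = int(np.searchsorted(cum, rng.integers(total), side="right"))
        a = _sample_window(windows, int(rng.integers(counts[pick])), pick)
        i = int(idx[pick])
        if state.kink_a[i] >= 0 and a >= state.kink_a[i]:
            pdir = (state.kux[i], state.kud[i], 0.0)
        else:
            pdir = (state.ux[i], state.ud[i], state.uz[i])
        v = sample_branch_orientation(pdir, params, rng)
        if v is None:
            continue
        if not params.allow_backward_branching and _is_backward(v):
            continue
        pos = state.position(i, a)
        c = state.new_filament(pos, v, 1, B_POLY, parent=i)
        state.add_child(i, a, c)
        state.ledger.polymerized_total += 1
        state.ledger.in_network += 1
        out.branches += 1
        state.log_event("branch", pos[0], pos[1], pos[2], int(state.uid[c]))
        return


def _polymerize_group(state: SimState, params: SimParams, out: StepOutcome,
                      rng, mask: np.ndarray, rate: float) -> None:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    idx = idx[rng.random(idx.size) < rate * params.dt]
    if idx.size == 0:
        return
    ell = params.subunit_length
    h = params.z_thickness
    nx = state.tip_x[idx] + ell * state.tip_ux[idx]
    nd = state.tip_d[idx] + ell * state.tip_ud[idx]
    nz = state.tip_z[idx] + ell * state.tip_uz[idx]
    z_ok = (nz >= 0.0) & (nz <= h)
    grow = (nd >= 0.0) & z_ok
    g = idx[grow]
    state.length[g] += 1
    state.tip_x[g] = nx[grow]
    state.tip_d[g] = nd[grow]
    state.tip_z[g] = nz[grow]
    n = g.size
    state.ledger.polymerized_total += n
    state.ledger.in_network += n
    out.polymerizations += n
    # tagging of added monomers
    if params.tag_fraction > 0.0 and n:
        tagged = g[rng.random(n) < params.tag_fraction]
        for i in tagged:
            tag = state.speckles.new_tag()
            a = int(state.p_off[i] + state.length[i]) - 1
            state.add_tag(int(i), a, tag)
            state.speckles.appear(tag, state.t, float(state.tip_d[i]),
                                  "polymerized")
    # membrane contact: kink or stall
    if params.kinking:
        for k in np.flatnonzero(~z_ok & (nd >= 0.0)):
            _install_kink(state, int(idx[k]), params, out, rng)


def _install_kink(state: SimState, i: int, params: SimParams,
                  out: StepOutcome, rng) -> None:
    """Continue elongation parallel to the membrane plane, preserving the
    in-plane azimuth.  Installed when the next subunit would cross z = 0 or
    z = z_thickness."""
    if state.kink_a[i] >= 0:
        return                      # already kinked; growth stays in plane
    hxy = math.hypot(state.tip_ux[i], state.tip_ud[i])
    if hxy == 0.0:
        return                      # normal incidence: simply stalled
    kux = state.tip_ux[i] / hxy
    kud = state.tip_ud[i] / hxy
    ell = params.subunit_length
    nd = state.tip_d[i] + ell * kud
    if nd < 0.0:
        return                      # would cross the leading edge: stalled
    plane = 0.0 if state.tip_uz[i] < 0.0 else params.z_thickness
    a_new = int(state.p_off[i] + state.length[i])
    state.kink_a[i] = a_new
    state.kux[i] = kux
    state.kud[i] = kud
    state.kink_x[i] = state.tip_x[i] + ell * kux
    state.kink_d[i] = nd
    state.kink_z[i] = plane
    state.length[i] += 1
    state.tip_x[i] = state.kink_x[i]
    state.tip_d[i] = state.kink_d[i]
    state.tip_z[i] = plane
    state.tip_ux[i], state.tip_ud[i], state.tip_uz[i] = kux, kud, 0.0
    state.ledger.polymerized_total += 1
    state.ledger.in_network += 1
    out.polymerizations += 1
    if params.tag_fraction > 0.0 and rng.random() < params.tag_fraction:
        tag = state.speckles.new_tag()
        state.add_tag(i, a_new, tag)
        state.speckles.appear(tag, state.t, float(state.tip_d[i]),
                              "polymerized")


def attempt_polymerize_all(state: SimState, params: SimParams,
                           out: StepOutcome, rng) -> None:
    bs = state.barbed_state
    _polymerize_group(state, params, out, rng,
                      state.alive & (bs == B_POLY), params.vpol)
    if params.variant == "catastrophe":
        _polymerize_group(state, params, out, rng,
                          state.alive & (bs == B_REPOL), params.vrepol)


def attempt_depolymerize_all(state: SimState, params: SimParams,
                             out: StepOutcome, rng) -> None:
    """Pointed-end depolymerization of all free pointed ends."""
    if params.vdepol <= 0.0:
        return
    mask = state.alive & (state.parent < 0)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    idx = idx[rng.random(idx.size) < params.vdepol * params.dt]
    if idx.size == 0:
        return
    newp = state.p_off[idx] + 1
    newlen = state.length[idx] - 1
    flagged = ((state.min_tag_a[idx] < newp)
               | (state.min_attach_a[idx] < newp)
               | (newlen == 0)
               | ((newlen <= params.lmaxolig) & (params.lmaxolig > 0)
                  & (state.n_children[idx] == 0))
               | ((state.kink_a[idx] >= 0) & (newp >= state.kink_a[idx])))
    simple = idx[~flagged]
    ell = params.subunit_length
    state.p_off[simple] += 1
    state.length[simple] -= 1
    state.pt_x[simple] += ell * state.pt_ux[simple]
    state.pt_d[simple] += ell * state.pt_ud[simple]
    state.pt_z[simple] += ell * state.pt_uz[simple]
    n = simple.size
    state.ledger.in_network -= n
    state.ledger.depolymerized += n
    out.depolymerizations += n
    for i in idx[flagged]:
        if state.alive[i]:
            _depolymerize_one(state, int(i), params, out)


def _depolymerize_one(state: SimState, i: int, params: SimParams,
                      out: StepOutcome) -> None:
    poff = int(state.p_off[i])
    # tags on the removed subunit disappear
    lst = state.tags.get(i)
    if lst:
        while lst and lst[0][0] <= poff:
            a, tag = lst.pop(0)
            _, d, _ = state.position(i, a)
            state.speckles.disappear(tag, state.t, d, "depolymerized")
        state._refresh_tag_cache(i)
    state.p_off[i] += 1
    state.length[i] -= 1
    state.ledger.in_network -= 1
    state.ledger.depolymerized += 1
    out.depolymerizations += 1
    newp = int(state.p_off[i])
    # children whose attachment subunit was depolymerized detach
    ch = state.children.get(i)
    if ch:
        while ch and ch[0][0] < newp:
            _, c = ch[0]
            _release_junction(state, int(c), out)
            ch = state.children.get(i)
        if state.children.get(i) is not None:
            state._refresh_child_cache(i)
    if state.length[i] == 0:
        state.release_filament(i)
        return
    _recompute_pt(state, i)
    if (params.lmaxolig > 0 and state.length[i] <= params.lmaxolig
            and state.n_children[i] == 0 and state.parent[i] < 0):
        _to_oligomer(state, i, out)


def attempt_rapid_depol_all(state: SimState, params: SimParams,
                            out: StepOutcome, rng) -> None:
    """Catastrophe variant: rapid subunit loss from barbed ends."""
    mask = state.alive & (state.barbed_state == B_RAPID)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    idx = idx[rng.random(idx.size) < params.vdepol_cat * params.dt]
    for i in idx:
        if state.alive[i]:      # an earlier event this step may remove it
            _rapid_depol_one(state, int(i), params, out)


def _rapid_depol_one(state: SimState, i: int, params: SimParams,
                     out: StepOutcome) -> None:
    ab1 = int(state.p_off[i] + state.length[i]) - 1
    lst = state.tags.get(i)
    if lst:
        while lst and lst[-1][0] >= ab1:
            a, tag = lst.pop()
            _, d, _ = state.position(i, a)
            state.speckles.disappear(tag, state.t, d, "depolymerized")
        state._refresh_tag_cache(i)
    ch = state.children.get(i)
    if ch:
        while ch and ch[-1][0] >= ab1:
            _, c = ch[-1]
            _release_junction(state, int(c), out)
            ch = state.children.get(i)
        if state.children.get(i) is not None:
            state._refresh_child_cache(i)
    state.length[i] -= 1
    state.ledger.in_network -= 1
    state.ledger.depolymerized += 1
    out.depolymerizations += 1
    if state.length[i] == 0:
        if state.parent[i] >= 0:
            _release_junction(state, i, out, check_parent=False)
        state.release_filament(i)
        return
    _recompute_tip(state, i)
    _maybe_auto_debranch(state, i, out)


def attempt_cap_uncap_all(state: SimState, params: SimParams,
                          out: StepOutcome, rng) -> None:
    bs = state.barbed_state.copy()
    catastrophe = params.variant == "catastrophe"
    if catastrophe:
        cappable = state.alive & ((bs == B_POLY) | (bs == B_STATIC)
                                  | (bs == B_RAPID) | (bs == B_REPOL))
    else:
        cappable = state.alive & ((bs == B_POLY) | (bs == B_STATIC))
    idx = np.flatnonzero(cappable)
    if idx.size and params.kcap > 0.0:
        hit = idx[rng.random(idx.size) < params.kcap * params.dt]
        state.barbed_state[hit] = B_CAPPED
        out.caps += hit.size
    idx = np.flatnonzero(state.alive & (bs == B_CAPPED))
    if idx.size and params.kuncap > 0.0:
        hit = idx[rng.random(idx.size) < params.kuncap * params.dt]
        if catastrophe:
            cat = rng.random(hit.size) < params.pcat
            state.barbed_state[hit[cat]] = B_RAPID
            state.barbed_state[hit[~cat]] = B_REPOL
        else:
            state.barbed_state[hit] = B_STATIC
        out.uncaps += hit.size
    # oligomers cap and uncap with the same rates
    os = state.o_state.copy()
    idx = np.flatnonzero(state.o_alive & ((os == B_POLY) | (os == B_STATIC)))
    if idx.size and params.kcap > 0.0:
        hit = idx[rng.random(idx.size) < params.kcap * params.dt]
        state.o_state[hit] = B_CAPPED
        out.caps += hit.size
    idx = np.flatnonzero(state.o_alive & (os == B_CAPPED))
    if idx.size and params.kuncap > 0.0:
        hit = idx[rng.random(idx.size) < params.kuncap * params.dt]
        state.o_state[hit] = B_STATIC
        out.uncaps += hit.size


def attempt_debranch_all(state: SimState, params: SimParams,
                         out: StepOutcome, rng) -> None:
    if params.kdebr <= 0.0:
        return
    idx = np.flatnonzero(state.alive & (state.parent >= 0))
    if idx.size == 0:
        return
    idx = idx[rng.random(idx.size) < params.kdebr * params.dt]
    for i in idx:
        if state.alive[i] and state.parent[i] >= 0:
            _release_junction(state, int(i), out)


def attempt_sever_all(state: SimState, params: SimParams, out: StepOutcome,
                      rng) -> None:
    if params.kunifsev <= 0.0 and params.kendsev <= 0.0:
        return
    idx = np.flatnonzero(state.alive & (state.length >= 2))
    if idx.size == 0:
        return
    p = state.p_off[idx]
    ab = p + state.length[idx]
    dmin = params.sever_exclusion_depth
    dt = params.dt
    fire_u = fire_e = None
    if params.kunifsev > 0.0:
        w_u, n_u = _eligible_windows(state, idx, p + 1, ab - 1, dmin)
        pu = np.minimum(params.kunifsev * dt * n_u, 1.0)
        fire_u = rng.random(idx.size) < pu
    if params.kendsev > 0.0 and params.lmaxolig > 0:
        jmin = np.maximum(p + 1, ab - params.lmaxolig)
        w_e, n_e = _eligible_windows(state, idx, jmin, ab - 1, dmin)
        if not params.sever_polymerizing_ends:
            n_e = np.where(state.barbed_state[idx] == B_POLY, 0, n_e)
        pe = np.minimum(params.kendsev * dt * n_e, 1.0)
        fire_e = rng.random(idx.size) < pe
    fu = fire_u if fire_u is not None else np.zeros(idx.size, bool)
    fe = fire_e if fire_e is not None else np.zeros(idx.size, bool)
    # one cut per filament per step; the end-severing channel wins ties
    for k in np.flatnonzero(fu | fe):
        if not state.alive[idx[k]]:
            continue
        if fe[k]:
            j = _sample_window(w_e, int(rng.integers(n_e[k])), k)
            out.end_severings += 1
            kind = "sever_end"
        else:
            j = _sample_window(w_u, int(rng.integers(n_u[k])), k)
            out.uniform_severings += 1
            kind = "sever_unif"
        _execute_sever(state, int(idx[k]), j, kind, params, out)


def _execute_sever(state: SimState, i: int, j: int, kind: str,
                   params: SimParams, out: StepOutcome) -> None:
    """Cut filament ``i`` between coordinates ``j - 1`` and ``j``.

    The barbed-side piece keeps the barbed-end state and gains a free
    (depolymerizing) pointed end; the pointed-side piece keeps its pointed
    end and gains a free static barbed end (capped in the catastrophe
    variant).  Short branchless pieces detach as oligomers.
    """
    cut = state.position(i, j)
    state.log_event(kind, cut[0], cut[1], cut[2], int(state.uid[i]), j)
    variant_cap = params.variant == "catastrophe"
    ab = int(state.p_off[i] + state.length[i])
    # --- barbed-side piece in a fresh slot -----------------------------
    b = state.new_filament(cut, (state.ux[i], state.ud[i], state.uz[i]),
                           ab - j,
                           B_CAPPED if variant_cap else state.barbed_state[i])
    # share the parent chain's coordinate frame so positions are unchanged
    state.anchor_x[b] = state.anchor_x[i]
    state.anchor_d[b] = state.anchor_d[i]
    state.anchor_z[b] = state.anchor_z[i]
    state.a0[b] = state.a0[i]
    state.p_off[b] = j
    for name in ("kink_a", "kink_x", "kink_d", "kink_z", "kux", "kud"):
        getattr(state, name)[b] = getattr(state, name)[i]
    state.tip_x[b] = state.tip_x[i]
    state.tip_d[b] = state.tip_d[i]
    state.tip_z[b] = state.tip_z[i]
    state.tip_ux[b] = state.tip_ux[i]
    state.tip_ud[b] = state.tip_ud[i]
    state.tip_uz[b] = state.tip_uz[i]
    _recompute_pt(state, b)
    # --- split children and tags by coordinate -------------------------
    ch = state.children.pop(i, None)
    if ch:
        keep = [e for e in ch if e[0] < j]
        move = [e for e in ch if e[0] >= j]
        if keep:
            state.children[i] = keep
        for _, c in move:
            state.parent[c] = b
        if move:
            state.children[b] = move
            state._refresh_child_cache(b)
    state._refresh_child_cache(i)
    tg = state.tags.pop(i, None)
    if tg:
        keep = [e for e in tg if e[0] < j]
        move = [e for e in tg if e[0] >= j]
        if keep:
            state.tags[i] = keep
        if move:
            state.tags[b] = move
            state._refresh_tag_cache(b)
    state._refresh_tag_cache(i)
    # --- pointed-side piece keeps its slot ------------------------------
    state.length[i] = j - int(state.p_off[i])
    state.barbed_state[i] = B_CAPPED if variant_cap else B_STATIC
    if state.kink_a[i] >= j:
        state.kink_a[i] = -1
    _recompute_tip(state, i)
    # --- classification (evaluated with the topology at cut time) -------
    _classify_piece(state, b, out)
    if state.alive[i]:
        _classify_piece(state, i, out)
    _maybe_auto_debranch(state, i, out)


def expire_oligomers(state: SimState, params: SimParams,
                     out: StepOutcome) -> None:
    idx = np.flatnonzero(state.o_alive)
    if idx.size == 0:
        return
    old = idx[state.t - state.o_t[idx] > params.oligomer_max_age]
    for j in old:
        j = int(j)
        L = int(state.o_len[j])
        state.ledger.in_oligomers -= L
        state.ledger.removed += L
        out.oligomers_removed += 1
        state.log_event("oligomer_expired", state.o_x[j], state.o_d[j], 0.0,
                        int(state.o_uid[j]), L)
        state.release_oligomer(j)


# ----------------------------------------------------------------------
# the step
# ----------------------------------------------------------------------

def step(state: SimState, params: SimParams = None) -> StepOutcome:
    """Advance the state by one time step ``dt``."""
    p = params if params is not None else state.params
    rng = state.rng
    out = StepOutcome()
    advect(state, p)
    attempt_branch(state, p, out, rng)
    attempt_polymerize_all(state, p, out, rng)
    attempt_depolymerize_all(state, p, out, rng)
    if p.variant == "catastrophe":
        attempt_rapid_depol_all(state, p, out, rng)
    attempt_cap_uncap_all(state, p, out, rng)
    attempt_debranch_all(state, p, out, rng)
    attempt_sever_all(state, p, out, rng)
    if p.kanneal > 0.0:
        _annealing.annealing_sweep(state, p, out, rng)
    expire_oligomers(state, p, out)
    state.t += p.dt
    state.step_count += 1
    return out


def simulate(state: SimState, duration: float, check_ledger_every: int = 0):
    """Run for ``duration`` seconds of simulated time; returns the summed
    event counts."""
    p = state.params
    n = int(round(duration / p.dt))
    totals = StepOutcome()
    for k in range(n):
        o = step(state, p)
        for f in totals.__dataclass_fields__:
            setattr(totals, f, getattr(totals, f) + getattr(o, f))
        if check_ledger_every and (k + 1) % check_ledger_every == 0:
            state.check_ledger()
    return totals
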