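"""Simulation state: filaments, oligomers, mass ledger and event log.

Geometry convention
-------------------
The leading edge is the plane ``d = 0`` where ``d`` is the distance from the
edge; the cell interior is ``d > 0`` and the network advects toward larger
``d`` at the imposed speed ``vnet``.  ``x`` is periodic with box length
``Lx``; ``z`` runs between the two membrane planes ``z = 0`` and
``z = z_thickness``.

Filaments are straight subunit chains (optionally with one kink at a
membrane plane).  Each filament occupies the absolute subunit coordinates
``[p_off, p_off + length)``: polymerization appends at the barbed end
(``a = p_off + length``), pointed-end depolymerization increments ``p_off``.
Tagged monomers and branch junctions are stored by absolute coordinate, so
they never need re-indexing as the ends move; the position of coordinate
``a`` follows from a fixed anchor point laid down when the chain segment was
created.

State is held in preallocated numpy arrays (struct-of-arrays) so that the
per-step kinetics can operate on whole populations at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import SimParams

# barbed-end states
B_POLY = 0        # polymerizing
B_CAPPED = 1
B_STATIC = 2      # free after uncapping: no elongation, annealing allowed
B_RAPID = 3       # catastrophe variant: rapid barbed-end depolymerization
B_REPOL = 4       # catastrophe variant: rapid repolymerization

BARBED_STATE_NAMES = {B_POLY: "polymerizing", B_CAPPED: "capped",
                      B_STATIC: "free_static", B_RAPID: "rapid_depol",
                      B_REPOL: "repol"}

_BIG = np.iinfo(np.int64).max // 4


class MassLedger:
    """Integer subunit accounting.

    Invariant: ``polymerized_total == in_network + in_oligomers +
    depolymerized + removed`` at every step.
    """

    __slots__ = ("polymerized_total", "in_network", "in_oligomers",
                 "depolymerized", "removed")

    def __init__(self):
        self.polymerized_total = 0
        self.in_network = 0
        self.in_oligomers = 0
        self.depolymerized = 0
        self.removed = 0

    def balanced(self) -> bool:
        return (self.polymerized_total ==
                self.in_network + self.in_oligomers +
                self.depolymerized + self.removed)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__slots__}

    def __repr__(self):
        return f"MassLedger({self.as_dict()})"


@dataclass
class SpeckleEvent:
    tag: int
    t: float
    d: float
    kind: str


class SpeckleLog:
    """Appearance/disappearance bookkeeping for tagged monomers."""

    def __init__(self):
        self._next_tag = 0
        self.open: dict = {}          # tag -> (t_appear, d_appear, kind)
        self.closed: list = []        # (tag, t0, d0, kind0, t1, d1, kind1)

    def new_tag(self) -> int:
        tag = self._next_tag
        self._next_tag += 1
        return tag

    def appear(self, tag: int, t: float, d: float, kind: str) -> None:
        self.open[tag] = (t, d, kind)

    def disappear(self, tag: int, t: float, d: float, kind: str) -> None:
        t0, d0, kind0 = self.open.pop(tag)
        self.closed.append((tag, t0, d0, kind0, t, d, kind))

    @property
    def n_open(self) -> int:
        return len(self.open)


class SimState:
    """Complete mutable simulation state."""

    #: initial filament-array capacity
    _INIT_CAP = 1024

    def __init__(self, params: SimParams, seed: int = 0):
        self.params = params
        self.t = 0.0
        self.step_count = 0
        self.rng = np.random.default_rng(seed)
        self.ledger = MassLedger()
        self.speckles = SpeckleLog()
        self.event_log: list = []     # (t, kind, x, d, z, uid, aux)
        self._next_uid = 0
        self._init_filament_arrays(self._INIT_CAP)
        self._init_oligomer_arrays(256)
        # sparse per-filament structures keyed by slot index
        self.children: dict = {}      # slot -> sorted list of [attach_a, child_slot]
        self.tags: dict = {}          # slot -> sorted list of [a, tag_id]
        self.olig_tags: dict = {}     # olig slot -> list of [rel_index, tag_id]

    # ------------------------------------------------------------------
    # array management
    # ------------------------------------------------------------------
    def _init_filament_arrays(self, cap: int) -> None:
        self.cap = cap
        z = np.zeros
        self.alive = z(cap, bool)
        self.uid = z(cap, np.int64)
        self.anchor_x = z(cap)
        self.anchor_d = z(cap)
        self.anchor_z = z(cap)
        self.a0 = z(cap, np.int64)          # coordinate located at the anchor
        self.ux = z(cap); self.ud = z(cap); self.uz = z(cap)
        self.kink_a = np.full(cap, -1, np.int64)
        self.kink_x = z(cap); self.kink_d = z(cap); self.kink_z = z(cap)
        self.kux = z(cap); self.kud = z(cap)
        self.p_off = z(cap, np.int64)
        self.length = z(cap, np.int64)
        self.barbed_state = z(cap, np.int8)
        self.parent = np.full(cap, -1, np.int64)
        self.n_children = z(cap, np.int32)
        # maintained end positions and end directions
        self.tip_x = z(cap); self.tip_d = z(cap); self.tip_z = z(cap)
        self.tip_ux = z(cap); self.tip_ud = z(cap); self.tip_uz = z(cap)
        self.pt_x = z(cap); self.pt_d = z(cap); self.pt_z = z(cap)
        self.pt_ux = z(cap); self.pt_ud = z(cap); self.pt_uz = z(cap)
        # caches for cheap event detection during depolymerization
        self.min_tag_a = np.full(cap, _BIG, np.int64)
        self.max_tag_a = np.full(cap, -_BIG, np.int64)
        self.min_attach_a = np.full(cap, _BIG, np.int64)
        self.max_attach_a = np.full(cap, -_BIG, np.int64)
        self._free = list(range(cap - 1, -1, -1))

    def _grow_filaments(self) -> None:
        old = self.cap
        new = old * 2
        for name in ("alive", "uid", "anchor_x", "anchor_d", "anchor_z", "a0",
                     "ux", "ud", "uz", "kink_a", "kink_x", "kink_d", "kink_z",
                     "kux", "kud", "p_off", "length", "barbed_state", "parent",
                     "n_children", "tip_x", "tip_d", "tip_z", "tip_ux",
                     "tip_ud", "tip_uz", "pt_x", "pt_d", "pt_z", "pt_ux",
                     "pt_ud", "pt_uz", "min_tag_a", "max_tag_a",
                     "min_attach_a", "max_attach_a"):
            arr = getattr(self, name)
            grown = np.empty(new, arr.dtype)
            grown[:old] = arr
            if name == "alive":
                grown[old:] = False
            elif name in ("parent", "kink_a"):
                grown[old:] = -1
            elif name in ("min_tag_a", "min_attach_a"):
                grown[old:] = _BIG
            elif name in ("max_tag_a", "max_attach_a"):
                grown[old:] = -_BIG
            else:
                grown[old:] = 0
            setattr(self, name, grown)
        self.cap = new
        self._free.extend(range(new - 1, old - 1, -1))

    def _init_oligomer_arrays(self, cap: int) -> None:
        self.ocap = cap
        z = np.zeros
        self.o_alive = z(cap, bool)
        self.o_uid = z(cap, np.int64)
        self.o_x = z(cap)
        self.o_d = z(cap)
        self.o_t = z(cap)
        self.o_len = z(cap, np.int64)
        self.o_state = z(cap, np.int8)
        self._ofree = list(range(cap - 1, -1, -1))

    def _grow_oligomers(self) -> None:
        old = self.ocap
        new = old * 2
        for name in ("o_alive", "o_uid", "o_x", "o_d", "o_t", "o_len",
                     "o_state"):
            arr = getattr(self, name)
            grown = np.empty(new, arr.dtype)
            grown[:old] = arr
            grown[old:] = False if name == "o_alive" else 0
            setattr(self, name, grown)
        self.ocap = new
        self._ofree.extend(range(new - 1, old - 1, -1))

    # ------------------------------------------------------------------
    # filament creation / removal
    # ------------------------------------------------------------------
    def new_filament(self, anchor, direction, length, barbed_state,
                     parent=-1) -> int:
        """Allocate a filament slot; anchor is the pointed-end position."""
        if not self._free:
            self._grow_filaments()
        i = self._free.pop()
        self.alive[i] = True
        self.uid[i] = self._next_uid
        self._next_uid += 1
        self.anchor_x[i], self.anchor_d[i], self.anchor_z[i] = anchor
        self.a0[i] = 0
        self.ux[i], self.ud[i], self.uz[i] = direction
        self.kink_a[i] = -1
        self.p_off[i] = 0
        self.length[i] = length
        self.barbed_state[i] = barbed_state
        self.parent[i] = parent
        self.n_children[i] = 0
        self.min_tag_a[i] = _BIG
        self.max_tag_a[i] = -_BIG
        self.min_attach_a[i] = _BIG
        self.max_attach_a[i] = -_BIG
        ell = self.params.subunit_length
        self.pt_x[i], self.pt_d[i], self.pt_z[i] = anchor
        self.pt_ux[i], self.pt_ud[i], self.pt_uz[i] = direction
        self.tip_x[i] = anchor[0] + (length - 1) * ell * direction[0]
        self.tip_d[i] = anchor[1] + (length - 1) * ell * direction[1]
        self.tip_z[i] = anchor[2] + (length - 1) * ell * direction[2]
        self.tip_ux[i], self.tip_ud[i], self.tip_uz[i] = direction
        return i

    def release_filament(self, i: int) -> None:
        self.alive[i] = False
        self.parent[i] = -1
        self.children.pop(i, None)
        self.tags.pop(i, None)
        self._free.append(i)

    def position(self, i: int, a: int) -> tuple:
        """Position of absolute subunit coordinate ``a`` on filament ``i``.

        ``x`` is returned unwrapped; apply ``% Lx`` for box coordinates.
        """
        ell = self.params.subunit_length
        ka = self.kink_a[i]
        if ka >= 0 and a >= ka:
            n = a - ka
            return (self.kink_x[i] + n * ell * self.kux[i],
                    self.kink_d[i] + n * ell * self.kud[i],
                    self.kink_z[i])
        n = a - self.a0[i]
        return (self.anchor_x[i] + n * ell * self.ux[i],
                self.anchor_d[i] + n * ell * self.ud[i],
                self.anchor_z[i] + n * ell * self.uz[i])

    def subunit_position(self, i: int, index: int) -> tuple:
        """Position of the subunit at ``index`` counted from the pointed end,
        with the periodic wrap applied in x."""
        if not 0 <= index < self.length[i]:
            raise IndexError(
                f"subunit index {index} out of range [0, {self.length[i]})")
        x, d, z = self.position(i, int(self.p_off[i]) + index)
        return (x % self.params.Lx, d, z)

    # ------------------------------------------------------------------
    # tag / child bookkeeping (lists sorted by coordinate)
    # ------------------------------------------------------------------
    def _refresh_tag_cache(self, i: int) -> None:
        lst = self.tags.get(i)
        if lst:
            self.min_tag_a[i] = lst[0][0]
            self.max_tag_a[i] = lst[-1][0]
        else:
            self.tags.pop(i, None)
            self.min_tag_a[i] = _BIG
            self.max_tag_a[i] = -_BIG

    def add_tag(self, i: int, a: int, tag: int) -> None:
        lst = self.tags.setdefault(i, [])
        if lst and a < lst[-1][0]:
            import bisect
            bisect.insort(lst, [a, tag])
        else:
            lst.append([a, tag])
        self._refresh_tag_cache(i)

    def _refresh_child_cache(self, i: int) -> None:
        lst = self.children.get(i)
        if lst:
            self.min_attach_a[i] = lst[0][0]
            self.max_attach_a[i] = lst[-1][0]
        else:
            self.children.pop(i, None)
            self.min_attach_a[i] = _BIG
            self.max_attach_a[i] = -_BIG
        self.n_children[i] = len(lst) if lst else 0

    def add_child(self, parent: int, attach_a: int, child: int) -> None:
        import bisect
        lst = self.children.setdefault(parent, [])
        bisect.insort(lst, [attach_a, child])
        self._refresh_child_cache(parent)

    def remove_child(self, parent: int, child: int) -> None:
        lst = self.children.get(parent, [])
        for k, (_, c) in enumerate(lst):
            if c == child:
                del lst[k]
                break
        self._refresh_child_cache(parent)

    # ------------------------------------------------------------------
    # oligomers
    # ------------------------------------------------------------------
    def new_oligomer(self, x: float, d: float, length: int, barbed_state: int,
                     tags=None) -> int:
        if not self._ofree:
            self._grow_oligomers()
        j = self._ofree.pop()
        self.o_alive[j] = True
        self.o_uid[j] = self._next_uid
        self._next_uid += 1
        self.o_x[j] = x % self.params.Lx
        self.o_d[j] = d
        self.o_t[j] = self.t
        self.o_len[j] = length
        self.o_state[j] = barbed_state
        if tags:
            self.olig_tags[j] = tags
        return j

    def release_oligomer(self, j: int) -> None:
        self.o_alive[j] = False
        self.olig_tags.pop(j, None)
        self._ofree.append(j)

    # ------------------------------------------------------------------
    def log_event(self, kind: str, x: float, d: float, z: float, uid: int,
                  aux=None) -> None:
        self.event_log.append((self.t, kind, x % self.params.Lx, d, z, uid, aux))

    # ------------------------------------------------------------------
    @property
    def n_filaments(self) -> int:
        return int(self.alive.sum())

    @property
    def n_oligomers(self) -> int:
        return int(self.o_alive.sum())

    def filament_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def check_ledger(self) -> None:
        if not self.ledger.balanced():
            raise AssertionError(f"mass ledger unbalanced: {self.ledger}")
        in_net = int(self.length[self.alive].sum())
        if in_net != self.ledger.in_network:
            raise AssertionError(
                f"in_network ledger {self.ledger.in_network} != "
                f"summed filament length {in_net}")
        in_olig = int(self.o_len[self.o_alive].sum())
        if in_olig != self.ledger.in_oligomers:
            raise AssertionError(
                f"in_oligomers ledger {self.ledger.in_oligomers} != "
                f"summed oligomer length {in_olig}")


def init_state(params: SimParams, n_seeds: int = 50, seed: int = 0) -> SimState:
    """Seed a fresh state with short filaments near the leading edge.

    ``n_seeds`` filaments of 5 subunits are placed with their barbed ends
    inside the branching region, uniformly in ``x`` and ``z``, with random
    in-plane orientations facing the edge.  Barbed ends polymerize, pointed
    ends are free.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    state = SimState(params, seed=seed)
    ell = params.subunit_length
    rng = state.rng
    for _ in range(n_seeds):
        # in-plane direction toward the edge (negative d component)
        phi = rng.uniform(-0.5 * math.pi, 0.5 * math.pi)
        direction = (math.sin(phi), -math.cos(phi), 0.0)
        d_barbed = rng.uniform(0.0, params.branching_region_depth)
        x_barbed = rng.uniform(0.0, params.Lx)
        z = rng.uniform(0.0, params.z_thickness)
        anchor = (x_barbed - 4 * ell * direction[0],
                  d_barbed - 4 * ell * direction[1],
                  z)
        state.new_filament(anchor, direction, 5, B_POLY)
        state.ledger.polymerized_total += 5
        state.ledger.in_network += 5
    return state


def advect(state: SimState, params: SimParams) -> None:
    """Translate the network away from the edge by ``vnet * dt``.

    Only network filaments move: oligomers have detached from the network
    and their diffusion kernel is anchored to the fixed creation point in
    the leading-edge frame (cytoplasmic advection is neglected).
    """
    shift = params.vnet * params.dt
    if shift == 0.0:
        return
    state.anchor_d += shift
    state.kink_d += shift
    state.tip_d += shift
    state.pt_d += shift


def snapshot_dataframe(state: SimState):
    """One row per filament: endpoints, states, topology (for export)."""
    import pandas as pd
    idx = state.filament_indices()
    Lx = state.params.Lx
    return pd.DataFrame({
        "uid": state.uid[idx],
        "length_subunits": state.length[idx],
        "pt_x": state.pt_x[idx] % Lx, "pt_d": state.pt_d[idx],
        "pt_z": state.pt_z[idx],
        "tip_x": state.tip_x[idx] % Lx, "tip_d": state.tip_d[idx],
        "tip_z": state.tip_z[idx],
        "barbed_state": [BARBED_STATE_NAMES[s] for s in
                         state.barbed_state[idx]],
        "parent_uid": [int(state.uid[p]) if p >= 0 else -1
                       for p in state.parent[idx]],
        "n_children": state.n_children[idx],
    })


def oligomer_dataframe(state: SimState):
    import pandas as pd
    idx = np.flatnonzero(state.o_alive)
    return pd.DataFrame({
        "uid": state.o_uid[idx],
        "x": state.o_x[idx], "d": state.o_d[idx],
        "t_created": state.o_t[idx],
        "length_subunits": state.o_len[idx],
        "barbed_state": [BARBED_STATE_NAMES[s] for s in state.o_state[idx]],
        "age": state.t - state.o_t[idx],
    })
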