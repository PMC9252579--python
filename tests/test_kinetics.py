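import math

import numpy as np
import pytest

from lamellipod import SimParams, init_state, preset
from lamellipod.state import (SimState, B_POLY, B_CAPPED, B_STATIC)
from lamellipod import kinetics as kin
from lamellipod.kinetics import (step, simulate, StepOutcome,
                                 sample_branch_orientation,
                                 _eligible_windows, _execute_sever,
                                 _classify_piece)

from conftest import straight_into_cell, make_filament


# ----------------------------------------------------------------------
# polymerization / depolymerization
# ----------------------------------------------------------------------

def test_capped_filament_never_grows(quiet_params):
    p = quiet_params.replace(vpol=150.0)
    st = SimState(p, seed=0)
    i = straight_into_cell(st, 1.0, 10, barbed_state=B_CAPPED)
    simulate(st, 1.0)
    assert st.length[i] == 10


def test_elongation_rate_matches_vpol():
    """Mean elongation of unobstructed polymerizing ends is vpol sub/s."""
    p = SimParams(vpol=150.0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0.0, kanneal=0)
    st = SimState(p, seed=4)
    ids = [straight_into_cell(st, 3.0, 10, barbed_state=B_POLY)
           for _ in range(200)]
    simulate(st, 2.0)
    grown = st.length[st.alive].mean() - 10
    # binomial s.d. ~ sqrt(n p (1-p)) per end
    assert grown / 2.0 == pytest.approx(150.0, rel=0.05)


def test_growth_blocked_at_leading_edge():
    """The new barbed-end position may not cross d = 0."""
    p = SimParams(vpol=150.0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0.0, kanneal=0)
    st = SimState(p, seed=0)
    i = straight_into_cell(st, 0.001, 10, barbed_state=B_POLY)
    simulate(st, 1.0)
    assert st.length[i] == 10            # stalled against the membrane
    assert st.tip_d[i] >= 0.0


def test_z_boundary_stalls_without_kinking():
    p = SimParams(vpol=150.0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0.0, kanneal=0, kinking=False)
    st = SimState(p, seed=0)
    # pointing up at 45 degrees, close to the top plane
    i = make_filament(st, (0.5, 1.0, 0.195), (0.0, -math.sqrt(0.5),
                                              math.sqrt(0.5)), 2, B_POLY)
    simulate(st, 1.0)
    assert st.length[i] <= 4
    assert st.tip_z[i] <= p.z_thickness


def test_kinking_continues_growth_in_plane():
    p = SimParams(vpol=150.0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0.0, kanneal=0, kinking=True)
    st = SimState(p, seed=0)
    u = (math.sqrt(0.3), -math.sqrt(0.2), math.sqrt(0.5))
    i = make_filament(st, (0.5, 1.0, 0.19), u, 2, B_POLY)
    simulate(st, 1.0)
    assert st.length[i] > 50             # keeps elongating after the kink
    assert st.kink_a[i] >= 0
    assert st.tip_z[i] == pytest.approx(p.z_thickness)
    assert st.tip_uz[i] == 0.0
    # post-kink direction preserves the xy azimuth
    azim0 = math.atan2(u[0], -u[1])
    azim1 = math.atan2(st.tip_ux[i], -st.tip_ud[i])
    assert azim1 == pytest.approx(azim0, abs=1e-9)
    # geometry stays consistent: tip equals position of last subunit
    x, d, z = st.position(i, int(st.p_off[i] + st.length[i] - 1))
    assert (x, d, z) == pytest.approx(
        (st.tip_x[i], st.tip_d[i], st.tip_z[i]))


def test_arp_bound_pointed_end_never_depolymerizes():
    p = SimParams(vpol=0, vdepol=100.0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=0)
    st = SimState(p, seed=0)
    par = straight_into_cell(st, 1.0, 200, barbed_state=B_CAPPED)
    child = make_filament(st, st.position(par, 100), (1, 0, 0), 50,
                          B_CAPPED, parent=par)
    st.add_child(par, 100, child)
    L0 = int(st.length[child])
    simulate(st, 0.5)
    assert st.length[child] == L0


def test_depolymerization_emits_tag_disappearance(quiet_params):
    p = quiet_params.replace(vdepol=400.0)
    st = SimState(p, seed=0)
    i = straight_into_cell(st, 1.0, 50, barbed_state=B_CAPPED)
    tag = st.speckles.new_tag()
    st.add_tag(i, int(st.p_off[i]), tag)     # tag at index 0
    st.speckles.appear(tag, 0.0, float(st.pt_d[i]), "polymerized")
    simulate(st, 0.2)
    assert tag not in st.speckles.open
    assert st.speckles.closed[0][6] == "depolymerized"
    st.check_ledger()


def test_shrunken_filament_converts_to_oligomer():
    """A branch-free filament shrinking below the oligomer size detaches
    as an oligomer, moving its subunits between the ledger pools."""
    p = SimParams(vpol=0, vdepol=300.0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=60.0, lmaxolig=150)
    st = SimState(p, seed=0)
    i = straight_into_cell(st, 1.0, 155, barbed_state=B_CAPPED)
    out = StepOutcome()
    for _ in range(2000):
        o = step(st, p)
        if o.oligomers_created:
            break
    assert st.n_filaments == 0
    assert st.n_oligomers == 1
    j = int(np.flatnonzero(st.o_alive)[0])
    assert st.o_len[j] == 150
    assert st.o_state[j] == B_CAPPED         # barbed state retained
    assert st.ledger.in_oligomers == 150
    st.check_ledger()


def test_full_depolymerization_removes_filament(quiet_params):
    p = quiet_params.replace(vdepol=400.0)
    st = SimState(p, seed=0)
    straight_into_cell(st, 1.0, 20, barbed_state=B_CAPPED)
    simulate(st, 1.0)
    assert st.n_filaments == 0
    assert st.ledger.depolymerized == 20
    st.check_ledger()


# ----------------------------------------------------------------------
# capping / uncapping
# ----------------------------------------------------------------------

def test_cap_uncap_cycle_ends_static():
    """Polymerizing -> capped -> uncapped leaves a free static end that
    does not elongate again."""
    p = SimParams(vpol=150.0, vdepol=0, kcap=50.0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=0, dt=0.002)
    st = SimState(p, seed=1)
    i = straight_into_cell(st, 1.0, 10, barbed_state=B_POLY)
    simulate(st, 0.5)
    assert st.barbed_state[i] == B_CAPPED
    L_at_cap = int(st.length[i])
    p2 = p.replace(kcap=0.0, kuncap=50.0)
    st.params = p2
    simulate(st, 0.5)
    assert st.barbed_state[i] == B_STATIC
    simulate(st, 0.5)
    assert st.length[i] == L_at_cap          # never resumes elongation


def test_capping_equilibrium_fraction():
    """Two-state capping/uncapping equilibrium: capped fraction
    kcap / (kcap + kuncap) for a static end population."""
    p = SimParams(vpol=0, vdepol=0, kcap=0.6, kuncap=1.0, kbr=0, kdebr=0,
                  vnet=0, kanneal=0)
    st = SimState(p, seed=5)
    for _ in range(3000):
        straight_into_cell(st, 1.0, 10, barbed_state=B_STATIC)
    simulate(st, 20.0)        # >> 1/(kcap+kuncap) = 0.6 s
    frac = (st.barbed_state[st.alive] == B_CAPPED).mean()
    expect = 0.6 / 1.6
    assert frac == pytest.approx(expect, abs=3 * math.sqrt(
        expect * (1 - expect) / 3000))


def test_kuncap_zero_is_absorbing():
    p = SimParams(vpol=0, vdepol=0, kcap=5.0, kuncap=0.0, kbr=0, kdebr=0,
                  vnet=0, kanneal=0)
    st = SimState(p, seed=2)
    for _ in range(200):
        straight_into_cell(st, 1.0, 10, barbed_state=B_STATIC)
    simulate(st, 5.0)
    assert np.all(st.barbed_state[st.alive] == B_CAPPED)


# ----------------------------------------------------------------------
# branching
# ----------------------------------------------------------------------

def test_branch_orientation_statistics():
    rng = np.random.default_rng(0)
    p = SimParams(branch_mode="uniform3d")
    parent = (0.0, -1.0, 0.0)
    angles = []
    for _ in range(4000):
        v = sample_branch_orientation(parent, p, rng)
        cosang = -v[1]
        angles.append(math.degrees(math.acos(np.clip(cosang, -1, 1))))
    assert np.mean(angles) == pytest.approx(70.0, abs=0.3)
    assert np.std(angles) == pytest.approx(5.0, abs=0.3)


def test_branch_orientation_planarity_constraint():
    rng = np.random.default_rng(1)
    p = SimParams(branch_mode="quasi2d_10deg")
    parent = (math.sin(0.6), -math.cos(0.6), 0.0)
    lim = math.sin(math.radians(10.0))
    for _ in range(500):
        v = sample_branch_orientation(parent, p, rng)
        assert abs(v[2]) <= lim + 1e-12
    p1 = SimParams(branch_mode="planar_1deg")
    lim1 = math.sin(math.radians(1.0))
    for _ in range(200):
        v = sample_branch_orientation(parent, p1, rng)
        assert abs(v[2]) <= lim1 + 1e-12


def test_no_backward_branches_accepted():
    """With backward branching disallowed no accepted daughter exceeds 80
    degrees from the protrusion axis (xy projection)."""
    p = SimParams(kbr=150.0, vpol=0, vdepol=0, kcap=0, kuncap=0, kdebr=0,
                  vnet=0, kanneal=0, branch_mode="quasi2d_10deg",
                  allow_backward_branching=False)
    st = SimState(p, seed=6)
    straight_into_cell(st, 0.01, 10, barbed_state=B_STATIC)
    simulate(st, 4.0)
    kids = st.filament_indices()
    kids = kids[st.parent[kids] >= 0]
    assert kids.size > 50
    theta = np.degrees(np.arctan2(np.abs(st.ux[kids]), -st.ud[kids]))
    assert theta.max() <= 80.0 + 1e-9


def test_no_branching_without_segments_in_region():
    p = SimParams(kbr=400.0, vpol=0, vdepol=0, kcap=0, kuncap=0, kdebr=0,
                  vnet=0, kanneal=0)
    st = SimState(p, seed=0)
    straight_into_cell(st, 0.5, 100, barbed_state=B_STATIC)  # all beyond 27 nm
    out = simulate(st, 2.0)
    assert out.branches == 0


def test_branch_site_selection_proportional_to_region_length():
    """Parents are chosen in proportion to their subunit count inside the
    branching region (two parents with 20 vs 10 eligible subunits)."""
    p = SimParams(kbr=150.0, vpol=0, vdepol=0, kcap=0, kuncap=0, kdebr=0,
                  vnet=0, kanneal=0, branching_region_depth=0.027,
                  allow_backward_branching=False)
    st = SimState(p, seed=7)
    ell = p.subunit_length
    # horizontal filaments at fixed depth inside the region
    a = make_filament(st, (0.1, 0.010, 0.1), (1.0, 0.0, 0.0), 20, B_CAPPED)
    b = make_filament(st, (0.6, 0.010, 0.1), (1.0, 0.0, 0.0), 10, B_CAPPED)
    counts = {a: 0, b: 0}
    out = StepOutcome()
    rng = st.rng
    for _ in range(4000):
        kin.attempt_branch(st, p, out, rng)
        for i in st.filament_indices():
            par = int(st.parent[i])
            if par in counts:
                counts[par] += 1
                # detach and remove the child to keep the setup clean
                kin._release_junction(st, int(i), out, check_parent=False)
                st.ledger.polymerized_total -= 1
                st.ledger.in_network -= 1
                st.release_filament(int(i))
    total = counts[a] + counts[b]
    assert total > 500
    assert counts[a] / total == pytest.approx(2 / 3, abs=0.035)


def test_branch_nucleation_rate():
    """kbr * Lx * dt attempts per step: with parents always available the
    realized rate is kbr * Lx per second."""
    p = SimParams(kbr=150.0, vpol=0, vdepol=0, kcap=0, kuncap=0, kdebr=0,
                  vnet=0, kanneal=0)
    st = SimState(p, seed=8)
    make_filament(st, (0.0, 0.01, 0.1), (1.0, 0.0, 0.0), 370, B_CAPPED)
    out = StepOutcome()
    n_steps = 5000
    for _ in range(n_steps):
        kin.attempt_branch(st, p, out, st.rng)
    expect = p.kbr * p.Lx * p.dt * n_steps
    assert out.branches == pytest.approx(expect, abs=4 * math.sqrt(expect))


# ----------------------------------------------------------------------
# debranching
# ----------------------------------------------------------------------

def _parent_with_child(st, child_len=50, attach_rel=100):
    par = straight_into_cell(st, 1.0, 200, barbed_state=B_CAPPED)
    attach = int(st.p_off[par]) + attach_rel
    child = make_filament(st, st.position(par, attach), (1, 0, 0),
                          child_len, B_CAPPED, parent=par)
    st.add_child(par, attach, child)
    return par, child


def test_debranch_rate_exponential_survival():
    p = SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0.1,
                  vnet=0, kanneal=0)
    st = SimState(p, seed=9)
    pairs = [_parent_with_child(st) for _ in range(400)]
    t_half = math.log(2) / 0.1
    simulate(st, t_half)
    still = sum(1 for _, c in pairs if st.parent[c] >= 0)
    assert still / 400 == pytest.approx(0.5, abs=0.08)


def test_parent_depolymerization_past_junction_frees_child(quiet_params):
    p = quiet_params.replace(vdepol=400.0, lmaxolig=0)
    st = SimState(p, seed=0)
    par, child = _parent_with_child(st, attach_rel=10)
    simulate(st, 0.3)
    assert st.parent[child] == -1            # junction released
    assert st.ledger.balanced()


def test_auto_debranch_of_tiny_branch_when_kdebr_zero():
    """With kdebr = 0, severing a branch down to <= 5 childless subunits
    detaches it; the stub becomes an oligomer."""
    p = SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0.0,
                  vnet=0, kanneal=60.0, lmaxolig=150)
    st = SimState(p, seed=0)
    par, child = _parent_with_child(st, child_len=50)
    out = StepOutcome()
    # cut the child 4 subunits above its base
    cut = int(st.p_off[child]) + 4
    _execute_sever(st, child, cut, "sever_unif", p, out)
    assert out.debranches == 1
    # the 4-subunit stub detaches from the parent but stays a filament
    # with a free pointed end; the 46-mer barbed piece is an oligomer
    assert st.alive[child] and st.parent[child] == -1
    assert st.length[child] == 4
    assert st.n_oligomers == 1
    st.check_ledger()


# ----------------------------------------------------------------------
# severing
# ----------------------------------------------------------------------

def test_no_severing_within_exclusion_zone():
    p = SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=0, kunifsev=0.9, lmaxolig=0)
    st = SimState(p, seed=0)
    straight_into_cell(st, 0.0, 36, barbed_state=B_CAPPED)  # spans < 0.1 um
    out = simulate(st, 4.0)
    assert out.uniform_severings == 0


def test_end_severing_window_and_exclusion():
    """A 300-subunit filament with lmaxolig = 150: the end window is the
    150 bonds nearest the barbed end, intersected with d >= 0.1 um."""
    p = SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=0, kendsev=1e-3, lmaxolig=150)
    st = SimState(p, seed=0)
    # entirely beyond the exclusion zone
    i = straight_into_cell(st, 0.5, 300, barbed_state=B_CAPPED)
    idx = np.array([i])
    pp = st.p_off[idx]
    ab = pp + st.length[idx]
    _, n_end = _eligible_windows(st, idx, np.maximum(pp + 1, ab - 150),
                                 ab - 1, 0.1)
    assert n_end[0] == 150
    # barbed end right at the edge: the window loses the excluded part
    k = straight_into_cell(st, 0.0, 300, barbed_state=B_CAPPED)
    idx = np.array([k])
    pp = st.p_off[idx]
    ab = pp + st.length[idx]
    _, n_end2 = _eligible_windows(st, idx, np.maximum(pp + 1, ab - 150),
                                  ab - 1, 0.1)
    excluded = math.ceil(0.1 / p.subunit_length)
    assert 0 < n_end2[0] <= 150 - excluded + 1


def test_sever_pieces_states_and_oligomer():
    """The barbed piece keeps its barbed state and gains a depolymerizing
    pointed end; the pointed piece gains a free static barbed end; a short
    branchless barbed piece becomes an oligomer."""
    p = SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=60.0, lmaxolig=150)
    st = SimState(p, seed=0)
    i = straight_into_cell(st, 0.5, 400, barbed_state=B_CAPPED)
    out = StepOutcome()
    cut = int(st.p_off[i]) + 300
    _execute_sever(st, i, cut, "sever_end", p, out)
    # pointed piece: 300 subunits, free static barbed end
    assert st.length[i] == 300
    assert st.barbed_state[i] == B_STATIC
    # barbed piece: 100 subunits <= lmaxolig, childless -> oligomer, capped
    assert st.n_oligomers == 1
    j = int(np.flatnonzero(st.o_alive)[0])
    assert st.o_len[j] == 100
    assert st.o_state[j] == B_CAPPED
    st.check_ledger()


def test_sever_between_children_keeps_both_pieces_in_network():
    p = SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=60.0, lmaxolig=150)
    st = SimState(p, seed=0)
    par = straight_into_cell(st, 0.5, 100, barbed_state=B_CAPPED)
    p0 = int(st.p_off[par])
    for rel in (20, 80):
        c = make_filament(st, st.position(par, p0 + rel), (1, 0, 0), 30,
                          B_CAPPED, parent=par)
        st.add_child(par, p0 + rel, c)
    out = StepOutcome()
    _execute_sever(st, par, p0 + 50, "sever_unif", p, out)
    assert out.oligomers_created == 0
    assert st.n_filaments == 4               # two pieces + two children
    # children follow their piece
    pieces = [i for i in st.filament_indices()
              if st.n_children[i] == 1]
    assert len(pieces) == 2
    st.check_ledger()


def test_classify_fragment_boundaries():
    p = SimParams(vpol=0, vdepol=0, kcap=0, kuncap=0, kbr=0, kdebr=0,
                  vnet=0, kanneal=60.0, lmaxolig=150)
    st = SimState(p, seed=0)
    out = StepOutcome()
    # length lmaxolig + 1, childless -> stays a network filament
    i = straight_into_cell(st, 0.5, 151, barbed_state=B_STATIC)
    _classify_piece(st, i, out)
    assert st.alive[i]
    # length 3 with a child -> network filament
    par = straight_into_cell(st, 0.5, 3, barbed_state=B_STATIC)
    c = make_filament(st, st.position(par, int(st.p_off[par]) + 1),
                      (1, 0, 0), 10, B_CAPPED, parent=par)
    st.add_child(par, int(st.p_off[par]) + 1, c)
    _classify_piece(st, par, out)
    assert st.alive[par]
    # length 40, childless, parentless -> oligomer
    k = straight_into_cell(st, 0.5, 40, barbed_state=B_STATIC)
    _classify_piece(st, k, out)
    assert not st.alive[k]
    assert st.n_oligomers == 1
    st.check_ledger()


# ----------------------------------------------------------------------
# step-level invariants
# ----------------------------------------------------------------------

def test_ledger_balances_over_mixed_event_run():
    """10^4 steps with every mechanism active keep exact subunit
    accounting."""
    p = preset("keratocyte_enhanced", kinking=True)
    st = init_state(p, n_seeds=50, seed=11)
    simulate(st, 20.0, check_ledger_every=500)
    st.check_ledger()
    assert st.ledger.polymerized_total > 10000


def test_identical_seeds_identical_runs():
    p = preset("xtc_enhanced")
    a = init_state(p, n_seeds=30, seed=3)
    b = init_state(p, n_seeds=30, seed=3)
    simulate(a, 3.0)
    simulate(b, 3.0)
    assert a.event_log == b.event_log
    assert a.ledger.as_dict() == b.ledger.as_dict()
    assert np.array_equal(a.length[a.alive], b.length[b.alive])


def test_capping_count_matches_binomial_expectation():
    """Over many steps the capping count of a static-end population
    matches the binomial mean within sampling error."""
    p = SimParams(vpol=0, vdepol=0, kcap=0.6, kuncap=0, kbr=0,
                  kdebr=0, vnet=0, kanneal=0)
    st = SimState(p, seed=12)
    straight_into_cell(st, 1.0, 10, barbed_state=B_STATIC)
    # re-arm the end each step so every step is an independent trial
    n, hits = 20000, 0
    for _ in range(n):
        out = step(st, p)
        hits += out.caps
        st.barbed_state[st.alive] = B_STATIC
    pev = 0.6 * p.dt
    assert hits == pytest.approx(n * pev, abs=3 * math.sqrt(
        n * pev * (1 - pev)))
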