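"""Structural readouts and the match classifiers used in parameter scans.

Concentrations use the simulation-box volume per bin
(``Lx * bin_width * z_thickness``) and the conversion 602.214 molecules
per um^3 per uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SimParams, MOLECULES_PER_UM3_PER_UM
from .state import SimState, B_POLY, B_CAPPED, B_STATIC


@dataclass
class ProfileSet:
    """Per-bin structural profiles versus distance from the leading edge."""
    edges: np.ndarray                  # bin edges, um
    factin: np.ndarray                 # F-actin subunit counts
    oligomer: np.ndarray               # oligomeric subunit counts (at origin)
    barbed_free: np.ndarray            # free (polymerizing or static) barbed ends
    barbed_capped: np.ndarray
    pointed_free: np.ndarray
    branches: np.ndarray               # Arp2/3 junction counts
    filaments_crossing: np.ndarray     # filaments crossing each bin midplane
    Lx: float
    z_thickness: float

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def bin_volume(self) -> float:
        return self.Lx * self.bin_width * self.z_thickness

    def concentration(self, counts: np.ndarray) -> np.ndarray:
        """Convert per-bin counts to uM."""
        return counts / (MOLECULES_PER_UM3_PER_UM * self.bin_volume)

    @property
    def factin_uM(self) -> np.ndarray:
        return self.concentration(self.factin)

    @property
    def barbed_per_um_edge(self) -> np.ndarray:
        """Barbed ends (free + capped) per um of leading edge per bin."""
        return (self.barbed_free + self.barbed_capped) / self.Lx

    def to_dataframe(self) -> pd.DataFrame:
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        return pd.DataFrame({
            "d_center": centers,
            "factin_uM": self.factin_uM,
            "oligomer_uM": self.concentration(self.oligomer),
            "barbed_free": self.barbed_free,
            "barbed_capped": self.barbed_capped,
            "pointed_free": self.pointed_free,
            "branches": self.branches,
            "filaments_crossing": self.filaments_crossing,
        })


def _subunit_depths(state: SimState) -> np.ndarray:
    """Depth of every network subunit (vectorized over unkinked filaments;
    kinked chains are corrected individually)."""
    idx = state.filament_indices()
    if idx.size == 0:
        return np.empty(0)
    L = state.length[idx]
    d0 = state.pt_d[idx]
    d1 = state.tip_d[idx]
    step = np.where(L > 1, (d1 - d0) / np.maximum(L - 1, 1), 0.0)
    total = int(L.sum())
    offsets = np.concatenate([[0], np.cumsum(L)[:-1]])
    k = np.arange(total) - np.repeat(offsets, L)
    depths = np.repeat(d0, L) + k * np.repeat(step, L)
    kinked = np.flatnonzero(state.kink_a[idx] >= 0)
    for m in kinked:
        i = int(idx[m])
        sl = slice(int(offsets[m]), int(offsets[m] + L[m]))
        a = np.arange(state.p_off[i], state.p_off[i] + state.length[i])
        ell = state.params.subunit_length
        pre = a < state.kink_a[i]
        dd = np.empty(a.size)
        dd[pre] = state.anchor_d[i] + (a[pre] - state.a0[i]) * ell * state.ud[i]
        dd[~pre] = state.kink_d[i] + (a[~pre] - state.kink_a[i]) * ell * state.kud[i]
        depths[sl] = dd
    return depths


def concentration_profile(state: SimState, bin_width: float = 0.5,
                          d_max: float = None) -> ProfileSet:
    """Bin the network state by distance from the leading edge."""
    p = state.params
    idx = state.filament_indices()
    depths = _subunit_depths(state)
    # pointed-end annealing extrapolates a few subunits past d = 0; that
    # near-edge mass is counted in the first bin so profiles stay exact
    depths = np.clip(depths, 0.0, None)
    if d_max is None:
        d_max = max(float(depths.max()) if depths.size else 1.0, 1.0)
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    edges[-1] = max(edges[-1], d_max * (1 + 1e-12))
    factin, _ = np.histogram(depths, bins=edges)
    oli = np.flatnonzero(state.o_alive)
    oligomer, _ = np.histogram(np.repeat(state.o_d[oli], state.o_len[oli]),
                               bins=edges)
    bs = state.barbed_state[idx]
    # end/junction depths clipped into the box like the subunit depths
    tip_d = np.clip(state.tip_d[idx], 0.0, None)
    pt_d = np.clip(state.pt_d[idx], 0.0, None)
    barbed_free, _ = np.histogram(tip_d[(bs == B_POLY) | (bs == B_STATIC)],
                                  bins=edges)
    barbed_capped, _ = np.histogram(tip_d[bs == B_CAPPED], bins=edges)
    par = state.parent[idx]
    pointed_free, _ = np.histogram(pt_d[par < 0], bins=edges)
    branches, _ = np.histogram(pt_d[par >= 0], bins=edges)
    lo = np.minimum(pt_d, tip_d)
    hi = np.maximum(pt_d, tip_d)
    mids = 0.5 * (edges[:-1] + edges[1:])
    crossing = np.array([(np.count_nonzero((lo <= m) & (hi >= m)))
                         for m in mids])
    return ProfileSet(edges, factin, oligomer, barbed_free, barbed_capped,
                      pointed_free, branches, crossing, p.Lx, p.z_thickness)


def edge_concentration(profile: ProfileSet, depth: float = 0.5) -> float:
    """Mean F-actin concentration (uM) over the first ``depth`` um,
    averaging bins to avoid single-bin noise."""
    centers = 0.5 * (profile.edges[:-1] + profile.edges[1:])
    sel = centers <= depth
    if not sel.any():
        sel = slice(0, 1)
    return float(profile.factin_uM[sel].mean())


def profile_midpoint(profile: ProfileSet, edge_depth: float = 0.5) -> float:
    """Distance at which the F-actin profile first falls to half its
    near-edge value (linearly interpolated between bin centers)."""
    conc = profile.factin_uM
    centers = 0.5 * (profile.edges[:-1] + profile.edges[1:])
    ref = edge_concentration(profile, edge_depth)
    if ref <= 0:
        raise ValueError("empty profile")
    half = 0.5 * ref
    below = np.flatnonzero(conc <= half)
    below = below[centers[below] > edge_depth / 2]
    if below.size == 0:
        raise ValueError("profile never falls to half the edge value")
    k = below[0]
    if k == 0:
        return float(centers[0])
    c0, c1 = conc[k - 1], conc[k]
    x0, x1 = centers[k - 1], centers[k]
    if c0 == c1:
        return float(x1)
    return float(x0 + (c0 - half) / (c0 - c1) * (x1 - x0))


def orientation_order_parameter(state: SimState, depth: float = 1.0):
    """Order parameter O = (N70 - 2 N35) / (N70 + 2 N35) over filaments
    with a segment within ``depth`` of the leading edge.

    N70 counts xy-projected orientations within 20 deg of the protrusion
    axis or between 60 and 80 deg on either side (the -70/0/70 pattern);
    N35 counts orientations between 25 and 45 deg on either side.  O = +1
    for a pure -70/0/70 network and -1 for a pure +/-35 network.  Returns
    None when no filament falls in either band.
    """
    idx = state.filament_indices()
    if idx.size == 0:
        return None
    near = np.minimum(state.pt_d[idx], state.tip_d[idx]) <= depth
    idx = idx[near]
    if idx.size == 0:
        return None
    ux = state.ux[idx]
    ud = state.ud[idx]
    theta = np.degrees(np.arctan2(np.abs(ux), -ud))   # 0 = toward the edge
    n70 = int(((theta <= 20.0) | ((theta >= 60.0) & (theta <= 80.0))).sum())
    n35 = int(((theta >= 25.0) & (theta <= 45.0)).sum())
    denom = n70 + 2 * n35
    if denom == 0:
        return None
    return (n70 - 2 * n35) / denom


def filament_lengths_in_region(state: SimState, d_lo: float,
                               d_hi: float) -> np.ndarray:
    """Contour lengths (um) of filaments with any segment inside
    [d_lo, d_hi]."""
    idx = state.filament_indices()
    lo = np.minimum(state.pt_d[idx], state.tip_d[idx])
    hi = np.maximum(state.pt_d[idx], state.tip_d[idx])
    sel = (hi >= d_lo) & (lo <= d_hi)
    return np.sort(state.length[idx[sel]] * state.params.subunit_length)


def cumulative_length_distribution(state: SimState, region) -> tuple:
    """Empirical CDF of filament contour length in a depth region.

    Returns ``(lengths, cdf)`` with cdf values at the sorted lengths.
    """
    lengths = filament_lengths_in_region(state, *region)
    if lengths.size == 0:
        raise ValueError(f"no filaments intersect region {region}")
    cdf = np.arange(1, lengths.size + 1) / lengths.size
    return lengths, cdf


def median_length_increase(state: SimState, front=(0.0, 1.0),
                           back=(3.0, 4.0)) -> float:
    """Median filament length at 3-4 um minus median at 0-1 um (um)."""
    f = filament_lengths_in_region(state, *front)
    b = filament_lengths_in_region(state, *back)
    if f.size == 0 or b.size == 0:
        raise ValueError("empty length region")
    return float(np.median(b) - np.median(f))


def effective_severing_rate(event_log, window, region_depth: float,
                            Lx: float, z_thickness: float) -> float:
    """Severing events per time per volume, in uM/s, counting both
    channels within ``region_depth`` of the edge over a time window."""
    t0, t1 = window
    n = sum(1 for (t, kind, x, d, z, uid, aux) in event_log
            if kind in ("sever_unif", "sever_end")
            and t0 <= t < t1 and d <= region_depth)
    volume = Lx * region_depth * z_thickness
    return n / (t1 - t0) / (MOLECULES_PER_UM3_PER_UM * volume)


# ----------------------------------------------------------------------
# match classification
# ----------------------------------------------------------------------

#: tomogram reference bins used by the structure criterion
TOMOGRAM_BARBED = {
    "keratocyte": dict(bin_width=0.212, counts=(309.0, 238.0)),
    "xtc": dict(bin_width=0.25, counts=(145.0, 42.5)),
}
TOMOGRAM_BRANCHES_XTC = 37.5      # per um per 0.25 um bin (fibroblast)

_STRUCTURE = {
    "keratocyte": dict(edge_uM=(700.0, 1500.0), midpoint=(5.0, 15.0)),
    "xtc": dict(edge_uM=(400.0, 1300.0), midpoint=(3.0, 10.0)),
}
# The short-lifetime band thresholds are probability densities (1/s) of
# the lifetime distribution normalized on ``bounds``: they bracket a
# moderate short-time peak (the keratocyte range sits above the uniform
# density 1/58 per s, the XTC range well above 1/140 per s).
_SPECKLE = {
    "keratocyte": dict(bounds=(2.0, 60.0), band=(2.0, 4.0),
                       band_density_range=(0.025, 0.055)),
    "xtc": dict(bounds=(4.0, 144.0), band=(4.0, 8.0),
                band_density_range=(0.035, 0.08)),
}
_LENGTH_INCREASE = {"keratocyte": 0.2, "xtc": 0.1}


@dataclass
class SpeckleStats:
    band_fraction: float          # lifetime mass in the short-time band
    gt10_fraction: float          # lifetime mass beyond 10 s
    far_disappear_fraction: float  # disappearances beyond 1 um of the edge


@dataclass
class MatchReport:
    cell_type: str
    structure_ok: bool
    speckle_ok: bool
    length_increase_ok: bool
    support: dict = field(default_factory=dict)

    @property
    def triple_match(self) -> bool:
        return self.structure_ok and self.speckle_ok and self.length_increase_ok

    def to_dict(self) -> dict:
        return dict(cell_type=self.cell_type, structure_ok=self.structure_ok,
                    speckle_ok=self.speckle_ok,
                    length_increase_ok=self.length_increase_ok,
                    triple_match=self.triple_match, support=dict(self.support))


def barbed_ends_in_bins(state: SimState, bin_width: float,
                        n_bins: int) -> np.ndarray:
    """Barbed ends (free + capped) per um of edge in tomogram-style bins."""
    idx = state.filament_indices()
    tip_d = state.tip_d[idx]
    edges = np.arange(0.0, bin_width * (n_bins + 1) - 1e-12, bin_width)
    counts, _ = np.histogram(tip_d, bins=edges)
    return counts / state.params.Lx


def branches_in_bins(state: SimState, bin_width: float,
                     n_bins: int) -> np.ndarray:
    idx = state.filament_indices()
    pt_d = state.pt_d[idx][state.parent[idx] >= 0]
    edges = np.arange(0.0, bin_width * (n_bins + 1) - 1e-12, bin_width)
    counts, _ = np.histogram(pt_d, bins=edges)
    return counts / state.params.Lx


def classify_match(profile: ProfileSet, speckle: SpeckleStats,
                   length_increment: float, cell_type: str,
                   barbed_bins: np.ndarray = None,
                   branch_bins: np.ndarray = None) -> MatchReport:
    """Apply the three scan criteria (structure, speckle dynamics, length
    increase away from the edge) to measured observables.

    ``barbed_bins``/``branch_bins`` are tomogram-style per-um-edge counts
    (first two bins); for keratocytes barbed ends must lie within 50% of
    the measured values per bin, for XTC the barbed-end and branch counts
    must be at least as large as the fibroblast measurements.
    """
    if cell_type not in _STRUCTURE:
        raise ValueError(f"cell_type must be one of {sorted(_STRUCTURE)}")
    s = _STRUCTURE[cell_type]
    support = {}
    edge = edge_concentration(profile)
    support["edge_factin_uM"] = edge
    structure = s["edge_uM"][0] <= edge <= s["edge_uM"][1]
    try:
        mid = profile_midpoint(profile)
        support["midpoint_um"] = mid
        structure &= s["midpoint"][0] <= mid <= s["midpoint"][1]
    except ValueError:
        support["midpoint_um"] = None
        structure = False
    ref = TOMOGRAM_BARBED[cell_type]["counts"]
    if barbed_bins is not None:
        bb = np.asarray(barbed_bins, float)[: len(ref)]
        support["barbed_bins_per_um"] = bb.tolist()
        if cell_type == "keratocyte":
            structure &= bool(np.all((bb >= 0.5 * np.asarray(ref))
                                     & (bb <= 1.5 * np.asarray(ref))))
        else:
            structure &= bool(bb[0] >= ref[0])
            if branch_bins is not None:
                support["branch_bin_per_um"] = float(branch_bins[0])
                structure &= bool(branch_bins[0] >= TOMOGRAM_BRANCHES_XTC)
    sp = _SPECKLE[cell_type]
    lo, hi = sp["band_density_range"]
    band_density = speckle.band_fraction / (sp["band"][1] - sp["band"][0])
    speckle_ok = (lo <= band_density <= hi
                  and speckle.gt10_fraction >= 0.20
                  and speckle.far_disappear_fraction >= 0.25)
    support["band_fraction"] = speckle.band_fraction
    support["band_density_per_s"] = band_density
    support["gt10_fraction"] = speckle.gt10_fraction
    support["far_disappear_fraction"] = speckle.far_disappear_fraction
    support["median_length_increment_um"] = length_increment
    length_ok = length_increment >= _LENGTH_INCREASE[cell_type]
    return MatchReport(cell_type, bool(structure), bool(speckle_ok),
                       bool(length_ok), support)
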