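"""Analytic 2D steady-state dendritic model and rate estimators.

A simplified dendritic nucleation model: straight filaments at +/-35 deg to
the protrusion axis nucleate at the leading edge at rate ``kbr`` (per s per
um of edge), elongate at ``vpol35`` (so the edge-normal extension speed is
``vnet = vpol35 * cos 35``), cap irreversibly at ``kcap`` and then ride
retrograde flow into the cell.  In steady state the uncapped-length
distribution is exponential with mean ``lbar = vpol35 / kcap`` and the
densities of branches, barbed ends and filaments in distance bins from the
edge have closed forms, which can be inverted to estimate ``kbr`` and
``kcap`` from electron-tomogram bin counts.

Internally the model uses the convention that ``y <= 0`` points into the
cell; the public bin interface works with nonnegative distances from the
edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

COS35 = math.cos(math.radians(35.0))


@dataclass(frozen=True)
class AnalyticParams:
    """Parameters of the analytic steady-state model."""
    kbr: float                 # 1/(s um)
    kcap: float                # 1/s
    vnet: float                # um/s
    dy: float                  # um, bin width

    def __post_init__(self):
        for name in ("kbr", "kcap", "vnet", "dy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def vpol35(self) -> float:
        """Filament elongation speed along its axis (um/s)."""
        return self.vnet / COS35

    @property
    def lbar(self) -> float:
        """Mean uncapped filament length (um)."""
        return self.vpol35 / self.kcap


def nu(p: AnalyticParams, l) -> np.ndarray:
    """Steady-state density of uncapped filaments of length ``l`` (per um
    of length per um of edge): (kbr / vpol35) exp(-l / lbar)."""
    return p.kbr / p.vpol35 * np.exp(-np.asarray(l, float) / p.lbar)


def nc(p: AnalyticParams, l) -> np.ndarray:
    """Steady-state density of capped filaments per unit length and unit
    distance from the edge: (kcap kbr / (vnet vpol35)) exp(-l / lbar)."""
    return (p.kcap * p.kbr / (p.vnet * p.vpol35)
            * np.exp(-np.asarray(l, float) / p.lbar))


def nbr(p: AnalyticParams) -> float:
    """Branch density per unit distance from the edge: kbr / vnet."""
    return p.kbr / p.vnet


def branches_per_bin(p: AnalyticParams, i: int) -> float:
    """Branches per um of edge in bin ``i`` (i >= 1): kbr dy / vnet,
    independent of the bin."""
    if i < 1:
        raise ValueError("bins are numbered from 1")
    return p.kbr * p.dy / p.vnet


def barbed_per_bin(p: AnalyticParams, i: int) -> float:
    """Barbed ends per um of edge in bin ``i``: the advected capped pool
    plus, in the first bin only, the uncapped pool kbr / kcap."""
    if i < 1:
        raise ValueError("bins are numbered from 1")
    extra = p.kbr / p.kcap if i == 1 else 0.0
    return extra + p.kbr * p.dy / p.vnet


def filaments_crossing(p: AnalyticParams, y: float) -> float:
    """Filaments crossing the plane at ``y <= 0`` (per um of edge):
    (kbr / kcap) (2 exp(y kcap / vnet) - 1)."""
    if y > 0:
        raise ValueError("y must be <= 0 (into the cell)")
    return p.kbr / p.kcap * (2.0 * math.exp(y * p.kcap / p.vnet) - 1.0)


def filaments_per_bin(p: AnalyticParams, i: int) -> float:
    """Filament crossing count evaluated at the midplane of bin ``i``,
    y = (1/2 - i) dy."""
    if i < 1:
        raise ValueError("bins are numbered from 1")
    return filaments_crossing(p, (0.5 - i) * p.dy)


# ----------------------------------------------------------------------
# tomogram bin fixture
# ----------------------------------------------------------------------

@dataclass
class TomogramBins:
    """Per-bin end/branch/filament counts (per um of leading edge)."""
    cell_type: str
    table: pd.DataFrame      # columns: quantity, bin, d_lo_um, d_hi_um, per_um_edge

    def values(self, quantity: str) -> np.ndarray:
        rows = self.table[self.table["quantity"] == quantity]
        if rows.empty:
            raise KeyError(
                f"no {quantity!r} rows for cell type {self.cell_type!r}")
        return rows.sort_values("bin")["per_um_edge"].to_numpy(float)

    def bin_width(self, quantity: str) -> float:
        rows = self.table[self.table["quantity"] == quantity]
        if rows.empty:
            raise KeyError(
                f"no {quantity!r} rows for cell type {self.cell_type!r}")
        widths = (rows["d_hi_um"] - rows["d_lo_um"]).to_numpy(float)
        return float(widths[0])


def load_tomogram_bins(cell_type: str, path=None) -> TomogramBins:
    """Load the packaged electron-tomogram bin counts (or a user-supplied
    delimited file with the same columns)."""
    if path is None:
        ref = resources.files("lamellipod.data") / "tomogram_bins.csv"
        with resources.as_file(ref) as fp:
            df = pd.read_csv(fp)
    else:
        df = pd.read_csv(path)
    table = df[df["cell_type"] == cell_type].reset_index(drop=True)
    if table.empty:
        raise KeyError(f"no rows for cell type {cell_type!r}")
    return TomogramBins(cell_type, table)


# ----------------------------------------------------------------------
# inverse estimators
# ----------------------------------------------------------------------

def estimate_kbr(bins: TomogramBins, vnet: float, dy: float = None,
                 source: str = "branches_bin") -> float:
    """Estimate the branching rate (1/(s um)) by inverting the per-bin
    branch count N_br = kbr dy / vnet.

    ``source = 'pointed_ends_avg2'`` uses the mean pointed-end count of the
    first two bins as N_br (all pointed ends near the edge assumed to sit
    at branches); ``'branches_bin'`` uses the mean of the branch rows.
    """
    if source == "pointed_ends_avg2":
        counts = bins.values("pointed_ends")[:2]
        nbr_est = float(np.mean(counts))
        dy = bins.bin_width("pointed_ends") if dy is None else dy
    elif source == "branches_bin":
        counts = bins.values("branches")
        nbr_est = float(np.mean(counts))
        dy = bins.bin_width("branches") if dy is None else dy
    else:
        raise ValueError("source must be 'pointed_ends_avg2' or 'branches_bin'")
    return float(nbr_est * vnet / dy)


def estimate_kcap(bins: TomogramBins, kbr: float, vnet: float,
                  dy: float = None, method: str = "barbed_bin1",
                  lbar: float = None) -> float:
    """Estimate the capping rate (1/s) from tomogram bins.

    Methods
    -------
    barbed_bin1
        Invert the bin-1 barbed-end count: kcap = kbr / (NBE1 - kbr dy / vnet).
    filaments_root
        Numerically solve the filament crossing-count expression at the
        bin-2 midplane for kcap.
    ratio
        From the ratio R = NBE1 / NBE2: kcap = vnet / (dy (R - 1)).
    mean_length
        From the mean filament length: kcap = (vnet / cos 35) / lbar.
    """
    if method == "mean_length":
        if lbar is None or lbar <= 0:
            raise ValueError("mean_length method requires lbar > 0")
        return (vnet / COS35) / lbar
    if method == "barbed_bin1":
        nbe = bins.values("barbed_ends")
        dy = bins.bin_width("barbed_ends") if dy is None else dy
        denom = nbe[0] - kbr * dy / vnet
        if denom <= 0:
            raise ValueError("bin-1 barbed ends do not exceed the advected "
                             "pool; cannot invert for kcap")
        return float(kbr / denom)
    if method == "ratio":
        nbe = bins.values("barbed_ends")
        dy = bins.bin_width("barbed_ends") if dy is None else dy
        ratio = nbe[0] / nbe[1]
        if ratio <= 1:
            raise ValueError("barbed-end ratio must exceed 1")
        return float(vnet / (dy * (ratio - 1.0)))
    if method == "filaments_root":
        nfil = bins.values("filaments")
        dy = bins.bin_width("filaments") if dy is None else dy
        target = float(nfil[1])
        y = (0.5 - 2) * dy

        def f(kcap):
            return (kbr / kcap * (2.0 * math.exp(y * kcap / vnet) - 1.0)
                    - target)

        lo, hi = 1e-4, 1e2
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise ValueError("no root bracketed in [1e-4, 1e2] 1/s")
        return float(brentq(f, lo, hi, rtol=1e-6))
    raise ValueError("method must be one of barbed_bin1, filaments_root, "
                     "ratio, mean_length")


def keratocyte_estimates(vnet: float = 0.2) -> dict:
    """The keratocyte rate estimates from the packaged tomogram counts."""
    bins = load_tomogram_bins("keratocyte")
    kbr = estimate_kbr(bins, vnet, source="pointed_ends_avg2")
    return {
        "kbr": kbr,
        "kcap_barbed_bin1": estimate_kcap(bins, kbr, vnet,
                                          method="barbed_bin1"),
        "kcap_filaments_root": estimate_kcap(bins, kbr, vnet,
                                             method="filaments_root"),
    }


def fibroblast_estimates(vnet: float = 0.03,
                         lbar: float = 0.162) -> dict:
    """The fibroblast/XTC rate estimates from the packaged tomogram
    counts (used for the XTC parameter set)."""
    bins = load_tomogram_bins("fibroblast")
    kbr = estimate_kbr(bins, vnet, source="branches_bin")
    return {
        "kbr": kbr,
        "kcap_mean_length": estimate_kcap(bins, kbr, vnet,
                                          method="mean_length", lbar=lbar),
        "kcap_ratio": estimate_kcap(bins, kbr, vnet, method="ratio"),
        "kcap_filaments_root": estimate_kcap(bins, kbr, vnet,
                                             method="filaments_root"),
    }
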