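"""Simulation parameters and named presets.

All rates are first-order (1/s), per subunit-bond (1/(sub*s)) for the two
severing channels, or bimolecular (1/(uM*s)) for annealing.  Lengths are in
micrometers and filament lengths in subunits (one subunit = 2.7 nm of
filament length).  The fixed time step ``dt`` converts every rate into a
per-step Bernoulli probability ``rate * dt``, which must stay well below 1.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: subunit length in micrometers (2.7 nm rise per monomer)
SUBUNIT_LENGTH = 0.0027

#: molecules per um^3 corresponding to a 1 uM concentration
MOLECULES_PER_UM3_PER_UM = 602.214

BRANCH_MODES = ("planar_1deg", "quasi2d_10deg", "uniform3d")
VARIANTS = ("severing", "catastrophe")


@dataclass(frozen=True)
class SimParams:
    """Kinetic rates, geometry and mode flags for a lamellipodium simulation.

    Defaults correspond to the keratocyte parameter set; use :func:`preset`
    for the named parameter sets.
    """

    # -- kinetics -------------------------------------------------------
    vpol: float = 150.0          # subunits/s, barbed-end elongation at the edge
    vdepol: float = 5.0          # subunits/s, free pointed end
    kcap: float = 0.6            # 1/s
    kuncap: float = 1.0          # 1/s
    kbr: float = 150.0           # 1/(s um of leading edge)
    kdebr: float = 0.1           # 1/s
    vnet: float = 0.2            # um/s, network speed relative to leading edge
    kunifsev: float = 0.0        # 1/(sub s), uniform severing per bond
    kendsev: float = 0.0         # 1/(sub s), barbed-end-enhanced severing per bond
    lmaxolig: int = 0            # subunits, maximum oligomer length (0 disables)
    kanneal: float = 60.0        # 1/(uM s)
    Dolig: float = 0.25          # um^2/s
    # -- numerics / geometry -------------------------------------------
    dt: float = 0.002            # s
    Lx: float = 1.0              # um, periodic box length along the edge
    z_thickness: float = 0.2     # um, lamellipodium thickness
    subunit_length: float = SUBUNIT_LENGTH
    branching_region_depth: float = 10 * SUBUNIT_LENGTH   # 27 nm
    sever_exclusion_depth: float = 0.1                    # um, no severing nearer the edge
    oligomer_max_age: float = 20.0                        # s
    # -- mode flags -----------------------------------------------------
    branch_mode: str = "quasi2d_10deg"
    allow_backward_branching: bool = False
    kinking: bool = False
    sever_polymerizing_ends: bool = False
    tag_fraction: float = 0.01
    # -- catastrophe variant -------------------------------------------
    variant: str = "severing"
    vdepol_cat: float = 60.0     # subunits/s, rapid barbed-end depolymerization
    vrepol: float = 60.0         # subunits/s, rapid repolymerization
    pcat: float = 0.5            # probability uncapping triggers rapid depolymerization

    def __post_init__(self) -> None:
        rates = dict(vpol=self.vpol, vdepol=self.vdepol, kcap=self.kcap,
                     kuncap=self.kuncap, kbr=self.kbr, kdebr=self.kdebr,
                     vnet=self.vnet, kunifsev=self.kunifsev,
                     kendsev=self.kendsev, kanneal=self.kanneal,
                     Dolig=self.Dolig, vdepol_cat=self.vdepol_cat,
                     vrepol=self.vrepol)
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.Lx <= 0 or self.z_thickness <= 0:
            raise ValueError("box dimensions must be positive")
        if self.subunit_length <= 0:
            raise ValueError("subunit_length must be positive")
        if self.lmaxolig < 0:
            raise ValueError("lmaxolig must be >= 0")
        if not 0.0 <= self.tag_fraction <= 1.0:
            raise ValueError("tag_fraction must be in [0, 1]")
        if not 0.0 <= self.pcat <= 1.0:
            raise ValueError("pcat must be in [0, 1]")
        if self.branch_mode not in BRANCH_MODES:
            raise ValueError(f"branch_mode must be one of {BRANCH_MODES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        # per-event per-step probabilities must be valid Bernoulli weights
        per_event = {
            "vpol*dt": self.vpol * self.dt,
            "vdepol*dt": self.vdepol * self.dt,
            "kcap*dt": self.kcap * self.dt,
            "kuncap*dt": self.kuncap * self.dt,
            "kdebr*dt": self.kdebr * self.dt,
            "kbr*Lx*dt": self.kbr * self.Lx * self.dt,
            "kendsev*lmaxolig*dt": self.kendsev * max(self.lmaxolig, 1) * self.dt,
            "vdepol_cat*dt": self.vdepol_cat * self.dt,
            "vrepol*dt": self.vrepol * self.dt,
        }
        for name, p in per_event.items():
            if p >= 1.0:
                raise ValueError(
                    f"per-step event probability {name} = {p:.3g} must be < 1")

    # -- convenience ----------------------------------------------------
    @property
    def branch_angle_deg(self) -> float:
        """Mean branch angle of the Arp2/3 junction (degrees)."""
        return 70.0

    @property
    def branch_angle_sd_deg(self) -> float:
        return 5.0

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


# Table-style presets.  The base "keratocyte" and "xtc" sets carry the fixed
# kinetic rates; the severing channel rates and the oligomer length were scan
# parameters, so the base presets leave them at zero.  The *_enhanced presets
# are the optimized parameter combinations with end severing and annealing;
# xtc_enhanced_polysev additionally allows end severing of polymerizing barbed
# ends and xtc_endsev_2x doubles the end-severing rate (with no uniform
# severing), the two variants used for sub-second speckle-lifetime statistics.
_PRESETS: dict = {
    "keratocyte": dict(),
    "xtc": dict(vpol=38.0, vdepol=5.0, kcap=0.2, kuncap=1.0, kbr=30.0,
                kdebr=0.0, vnet=0.05),
    "keratocyte_uniform": dict(kunifsev=5e-4, kendsev=0.0, lmaxolig=80),
    "keratocyte_enhanced": dict(kunifsev=5e-4, kendsev=1e-3, lmaxolig=150),
    "xtc_uniform": dict(vpol=38.0, vdepol=5.0, kcap=0.2, kuncap=1.0,
                        kbr=30.0, kdebr=0.0, vnet=0.05,
                        kunifsev=5e-5, kendsev=0.0, lmaxolig=80),
    "xtc_enhanced": dict(vpol=38.0, vdepol=5.0, kcap=0.2, kuncap=1.0,
                         kbr=30.0, kdebr=0.0, vnet=0.05,
                         kunifsev=5e-6, kendsev=1e-3, lmaxolig=150),
    "xtc_enhanced_polysev": dict(vpol=38.0, vdepol=5.0, kcap=0.2, kuncap=1.0,
                                 kbr=30.0, kdebr=0.0, vnet=0.05,
                                 kunifsev=5e-6, kendsev=1e-3, lmaxolig=150,
                                 sever_polymerizing_ends=True),
    "xtc_endsev_2x": dict(vpol=38.0, vdepol=5.0, kcap=0.2, kuncap=1.0,
                          kbr=30.0, kdebr=0.0, vnet=0.05,
                          kunifsev=0.0, kendsev=2e-3, lmaxolig=150,
                          sever_polymerizing_ends=True),
    "keratocyte_catastrophe": dict(variant="catastrophe", kendsev=0.0,
                                   kanneal=0.0, kunifsev=5e-4, lmaxolig=150,
                                   vdepol_cat=60.0, vrepol=60.0, pcat=0.5),
}


def preset_names() -> list:
    return sorted(_PRESETS)


def preset(name: str, **overrides) -> SimParams:
    """Return a named parameter set, optionally with field overrides."""
    try:
        base = dict(_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    base.update(overrides)
    return SimParams(**base)


def load_config(path) -> SimParams:
    """Read a YAML config file.

    The file may name a ``preset`` and override individual fields, e.g.::

        preset: xtc_enhanced
        Lx: 2.0
        kendsev: 2.0e-3
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping of parameter names")
    name = doc.pop("preset", None)
    if name is not None:
        return preset(name, **doc)
    return SimParams.from_dict(doc)


def save_config(params: SimParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
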