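"""Alternative model: frequent transitions to rapid barbed-end dynamics.

Instead of enhanced end severing and annealing, uncapping sends a barbed
end into rapid depolymerization (probability ``pcat``) or rapid
repolymerization (``1 - pcat``); capping acts as rescue.  The uncapping
rate therefore controls the catastrophe frequency and the capping rate the
rescue rate.  New barbed ends created by severing are capped in this
variant, decoupling catastrophes from severing.

The transitions themselves are implemented in the engine
(:mod:`lamellipod.kinetics`) and switched on by ``variant='catastrophe'``;
this module provides the parameter construction.  The typical length lost
per catastrophe is ``vdepol_cat / kcap`` subunits, chosen by default (60/0.6
= 100 for keratocyte rates) to be comparable to half the maximum oligomer
length of the optimized severing model.
"""

from __future__ import annotations

from .params import SimParams, preset
from .kinetics import (attempt_rapid_depol_all, attempt_cap_uncap_all,
                       attempt_polymerize_all)

__all__ = ["make_catastrophe_params", "attempt_rapid_depol_all",
           "attempt_cap_uncap_all", "attempt_polymerize_all"]


def make_catastrophe_params(base: SimParams = None, *, vdepol_cat: float = 60.0,
                            vrepol: float = None, pcat: float = 0.5,
                            **overrides) -> SimParams:
    """Catastrophe-variant parameters from a base set.

    Enhanced end severing and annealing are switched off (the variant
    replaces them); ``vrepol`` defaults to ``vdepol_cat`` so that rapid
    repolymerization balances catastrophic disassembly.
    """
    if base is None:
        base = preset("keratocyte")
    if vrepol is None:
        vrepol = vdepol_cat
    return base.replace(variant="catastrophe", kendsev=0.0, kanneal=0.0,
                        vdepol_cat=vdepol_cat, vrepol=vrepol, pcat=pcat,
                        **overrides)
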