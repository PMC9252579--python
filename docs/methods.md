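# Model and methods

`lamellipod` simulates the branched (dendritic) actin network of the
lamellipodium — the thin protruding sheet at the front of motile cells —
as a collection of straight filaments in a 3D slab, evolving by stochastic
kinetics at a fixed time step. Its purpose is to test whether filament
severing concentrated near barbed ends, followed by diffusion of the
severed oligomers and their end-to-end re-annealing to free filament ends,
can simultaneously account for (i) single-molecule speckle (SiMS)
statistics of actin — frequent disappearance of recently polymerized
subunits — (ii) the measured structure of the network (F-actin, barbed
end, and branch concentration profiles), and (iii) the increase in
filament length away from the leading edge.

## Geometry and state

The leading edge is the plane `d = 0` (`d` = distance from the edge, into
the cell); the membrane planes `z = 0` and `z = 0.2 um` bound the sheet;
`x` is periodic with box length `Lx` (default 1 um of leading edge). A
constant relative velocity `vnet` advects the network away from the edge,
representing retrograde flow and/or protrusion. There is no boundary at
large `d`: the depth of the lamellipodium is an emergent property of the
kinetics.

Filaments are straight subunit chains (2.7 nm of length per subunit) with
a barbed-end state (polymerizing, capped, or free-static; plus
rapid-depolymerizing/repolymerizing states in the catastrophe variant) and
a pointed end that is either Arp2/3-bound (a branch junction) or free.
Each filament occupies an interval of absolute subunit coordinates; the
chain's spatial frame is fixed at creation, so tags (tracked monomers) and
branch junctions are stored by coordinate and never re-indexed as the ends
move. Filaments that hit a membrane plane either stall or, when kinking
is enabled, continue elongating parallel to the plane at the same in-plane
azimuth (at most one kink per filament).

## Kinetics

Every reaction converts its rate into a per-step Bernoulli probability
`rate * dt` with `dt = 2 ms`; parameter validation rejects any per-event
probability that is not well below 1. Events within one step apply in a
fixed order (advection, branching, polymerization, depolymerization,
capping/uncapping, debranching, severing, annealing, oligomer expiry);
with the small per-step probabilities the ordering bias is second order,
and the fixed order makes runs exactly reproducible by seed.

* **Polymerization** adds one subunit at `vpol` per polymerizing barbed
  end, blocked when the new subunit would cross the edge or a membrane
  plane. At the leading edge, growth of an inclined filament is therefore
  membrane-limited: its realized elongation speed is `vnet / cos(theta)`
  in subunits along its axis, which is exactly the closure assumed by the
  analytic steady-state model below.
* **Depolymerization** removes subunits at `vdepol` from free pointed
  ends. A branch-free, child-free chain that shrinks to the maximum
  oligomer length detaches as a diffusing oligomer (the package resolves
  the ambiguous "depolymerization stops at oligomer qualification" in
  favor of detachment; with annealing disabled such fragments are simply
  removed, matching the no-annealing model variant).
* **Capping/uncapping**: capping (rate `kcap`) stops polymerization and
  forbids annealing; uncapping (rate `kuncap`) leaves a *free static*
  barbed end that does not elongate or shrink but accepts annealing.
* **Branching**: nucleations are attempted at total rate `kbr * Lx`, at a
  location drawn in proportion to filament segment length within the
  27-nm branching region at the edge. The daughter forms at
  70 ± 5 degrees (Gaussian) from the parent, with an azimuth that is
  uniform (`uniform3d`), or constrained to within 10 degrees
  (`quasi2d_10deg`, the default) or 1 degree (`planar_1deg`) of the
  lamellipodial plane. Branches directed more than 80 degrees from the
  protrusion axis (xy projection) are rejected and redrawn up to 100
  times unless backward branching is allowed.
* **Debranching** releases junctions at rate `kdebr`, leaving the branch
  in the network with a free pointed end. Junctions are also released
  when a depolymerizing parent passes the attachment point, and — in
  simulations with `kdebr = 0` — when a branch with no branches of its
  own has shrunk to five subunits or fewer (this check is triggered by
  shortening events, so nascent growing branches are unaffected).
* **Severing** has two channels, each with a per-bond rate: uniform
  (`kunifsev`) over all bonds, and end-enhanced (`kendsev`) over the
  `lmaxolig` bonds nearest the barbed end (skipped for polymerizing ends
  unless `sever_polymerizing_ends`). No severing occurs within 0.1 um of
  the edge. A cut creates a free (depolymerizing) pointed end on the
  barbed-side piece and a free static barbed end on the pointed-side
  piece; a piece of at most `lmaxolig` subunits that is not a branch and
  carries no branches detaches as an oligomer, retaining its barbed-end
  state. At most one cut per filament per step (the end channel wins
  ties), a negligible restriction at the simulated probabilities.

## Oligomers and annealing

Oligomer positions are not simulated explicitly. The probability density
of finding an unannealed oligomer's end displaced `(dx, dy)` from its
creation point after time `t` is the free 2D Gaussian
`PD = (4 pi D t)^-1 exp(-(dx^2 + dy^2) / (4 D t))` with `D = Dolig`;
dividing by the slab thickness and the number density of a 1 uM solution
(602.214 um^-3) converts it to a local concentration, making annealing a
bimolecular reaction with rate constant `kanneal` against every eligible
end: free static barbed ends for any oligomer, free pointed ends only for
uncapped oligomers (oligomers cap and uncap at the filament rates). Each
sweep scans all oligomer/end pairs (minimum image in x), executes at most
one annealing per oligomer with total acceptance `min(sum p, 1)` and the
end drawn in proportion to the pairwise probabilities, and claims each
end at most once per step, in a randomized oligomer order. Annealing
transfers the oligomer's barbed-end state on barbed-end joins (a
polymerizing oligomer re-arms elongation). Oligomers older than 20 s are
removed. Because annealing probabilities are evaluated from the fixed
creation point, oligomer origins are not advected (cytoplasmic advection
of the diffusing fragment is neglected); only network filaments move with
`vnet`.

Validation: the mean-square creation-to-annealing distance on a
well-mixed test network equals `4 D` times the mean annealing time (the
exact second-moment identity of the kernel). Median-based comparisons
against the mean-rate estimate `1/(kanneal * CB)` carry intrinsic factors
of order `ln 2` and, in full simulations, an additional bias because
oligomers are created where end density is high.

## Simulated SiMS

A fraction `tag_fraction` (default 1%) of monomers added by
polymerization is tagged; each incorporation is a speckle appearance, and
a tag disappears when it depolymerizes off an end or becomes part of an
oligomer. An oligomer that re-anneals while carrying tags produces fresh
appearances (`annealed_in`). Lifetime statistics handle right censoring
explicitly: open tracks count as "longer than a cutoff" only once
observed at least that long, and distribution masses use a Kaplan–Meier
survival estimate so that finite runs do not bias the long-lifetime tail.

## Observables and match classification

Structural profiles bin subunits, ends and junctions by distance from the
edge (concentrations use the bin volume `Lx * bin * 0.2 um`). The
orientation order parameter over filaments with a segment within 1 um of
the edge is `O = (N70 - 2 N35) / (N70 + 2 N35)` on xy-projected angles
(`N70`: within 20 deg of the axis or 60–80 deg; `N35`: 25–45 deg), +1 for
a pure -70/0/70 pattern and -1 for a pure ±35 pattern.

The parameter-scan classifier applies three criteria: **structure**
(near-edge F-actin 700–1500 uM for keratocyte parameters, 400–1300 uM for
XTC; profile midpoint — first fall to half the near-edge value, which is
averaged over the first 0.5 um to avoid single-bin noise — within 5–15 um
or 3–10 um respectively; barbed ends within 50% of the keratocyte
tomogram bins, or at least the fibroblast values for XTC); **speckle
dynamics** (the short-lifetime band of the bounds-normalized lifetime
distribution — 2–4 s of 2–60 s, or 4–8 s of 4–144 s — has a probability
*density* within 0.025–0.055 /s or 0.035–0.08 /s; at least 20% of the
normalized mass beyond 10 s; at least 25% of disappearances beyond 1 um);
**length increase** (median filament length at 3–4 um exceeds that at
0–1 um by 0.2 um / 0.1 um). The band thresholds are densities read off
the normalized distribution curves: as plain probabilities they would sit
at or below the uniform-distribution value and could not encode a
short-time peak. "Triple match" means all three criteria hold.

## Catastrophe variant

As an alternative to end severing plus annealing, `variant="catastrophe"`
makes uncapping send a barbed end into rapid depolymerization
(probability `pcat`, rate `vdepol_cat`, default 60 subunits/s) or rapid
repolymerization (`vrepol`, subject to the usual boundary rules),
with capping acting as rescue; severed barbed ends are created capped,
and annealing and end severing are off. The default `vdepol_cat / kcap =
100` subunits lost per catastrophe is comparable to half the maximum
oligomer length of the optimized severing model.

## Analytic steady-state model and rate estimation

A reduced 2D model (filaments at ±35 degrees, nucleation at the edge at
`kbr`, irreversible capping at `kcap`, elongation at
`vpol35 = vnet / cos 35`, advection at `vnet`) has closed forms for the
uncapped length distribution (exponential, mean `vpol35 / kcap`),
branches per distance bin (`kbr dy / vnet`), barbed ends per bin (the
same plus an uncapped pool `kbr / kcap` in bin 1), and the filament count
crossing a plane, `(kbr/kcap)(2 exp(y kcap / vnet) - 1)`. Inverting
these against electron-tomogram bin counts (shipped as a small table:
keratocyte barbed/pointed-end/filament counts and fibroblast
barbed/branch/filament counts per um of edge) yields the rate estimates
used to set the simulation presets: keratocyte `kbr = 152 /s/um`, `kcap`
between 0.32 and 1.03 /s depending on the observable inverted (presets
use 150 and 0.6); fibroblast `kbr = 4.5 /s/um` and `kcap = 0.23 /s` from
the 162-nm median branch length (XTC presets use 30 /s/um and 0.2 /s with
`vnet = 0.05 um/s`). The fibroblast barbed-end-ratio and filament-count
inversions (printed as 0.082, 0.030 and 0.034 /s) are implemented but do
not reproduce from the printed closed forms with `vnet = 0.03 um/s` (they
give 0.050, 0.024 and 0.020 /s); they are excluded from validation.
The filament-count inversion solves the crossing-count expression by
bisection on `kcap` in [1e-4, 1e2] /s to relative tolerance 1e-6; the
expression is only invertible where it is positive (shallow bins).

## Problem sizes, defaults, and what the tests show

Simulations in the test-suite and the reproduction script use 1 um of
leading edge, 50 seed filaments of 5 subunits, and single replicates,
with run lengths chosen per purpose: ~230 s for near-edge sub-second
speckle statistics (which equilibrate with the front few microns), 700 s
for XTC scan cells classified against structure criteria (the in-network
mass plateaus by ~300 s; profiles keep maturing slowly after that), and
300 s for no-annealing cells (their narrow networks equilibrate quickly).
Steady state is declared when the total in-network subunit count changes
by less than 2% over a trailing 50 s window.

The synthetic conditions emulate the study systems (keratocyte and
XTC/fibroblast lamellipodia) but not real-data complications: no ATP
hydrolysis or aging of subunits, no monomer diffusion field, no excluded
volume or filament mechanics, no photobleaching. Passing tests therefore
show internal consistency with the model's own stated kinetics and with
the published summary statistics, not that the mechanism is unique in
real cells.

Known limitations: the oligomer diffusion kernel ignores the leading-edge
boundary and advection; oligomer geometry is unresolved (annealed
material extends the existing filament axis, occasionally extrapolating a
few subunits past `d = 0`, which profiles clip into the first bin);
`Dolig` and `kanneal` are length-independent; and the fraction of
near-edge speckle lifetimes longer than 3 s in the XTC
polymerizing-end-severing configuration comes out 4–6 percentage points
above the published 79%, a stable discrepancy documented in the test
suite (its companions — the 0.5 s, 1 s and doubled-rate fractions and the
effective severing rate of ~0.2 uM/s — reproduce within their stated
tolerances).
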