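"""Run orchestration: replicates, steady-state detection, parameter scans.

A run simulates to ``t_end``; observables are measured over a trailing
window ``[t_end - closure - measure_window, t_end - closure]`` and the run
then continues for ``closure`` seconds so that most speckle tracks opened
in the window can close (remaining open tracks are handled as censored).
Steady state is declared when the total in-network subunit count changes
by less than 2% over a trailing detection window before measurement
begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SimParams
from .state import SimState, init_state
from .kinetics import step
from . import observables as obs
from . import speckles as spk


@dataclass
class RunResult:
    params: SimParams
    seed: int
    cell_type: str
    state: SimState
    profile: obs.ProfileSet
    tracks: pd.DataFrame
    window: tuple
    t_end: float
    steady_state_reached: bool
    history: pd.DataFrame
    match: obs.MatchReport = None
    speckle_stats: obs.SpeckleStats = None

    @property
    def event_log(self):
        return self.state.event_log


def default_seeds(n_runs: int, base_seed: int = 0) -> list:
    """Deterministic per-replicate seeds derived from a base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_runs)]


def speckle_stats_for_match(tracks: pd.DataFrame, cell_type: str,
                            window, region_depth: float,
                            t_now: float) -> obs.SpeckleStats:
    sp = obs._SPECKLE[cell_type]
    try:
        band, gt10 = spk.lifetime_band_fractions(
            tracks, sp["bounds"], [sp["band"], (10.0, np.inf)],
            window=window, region_depth=region_depth, t_now=t_now)
    except ValueError:          # no lifetime mass within the bounds
        band, gt10 = np.nan, np.nan
    closed = tracks[tracks["t_disappear"].notna()]
    closed = closed[(closed["lifetime"] >= sp["bounds"][0] / 2)
                    & (closed["t_appear"] >= window[0])
                    & (closed["t_appear"] < window[1])
                    & (closed["d_appear"] <= region_depth)]
    far = (float((closed["d_disappear"] > 1.0).mean())
           if len(closed) else 0.0)
    return obs.SpeckleStats(float(band), float(gt10), far)


def run_single(params: SimParams, seed: int = 0, t_end: float = 120.0,
               measure_window: float = 20.0, closure: float = 20.0,
               cell_type: str = None, n_seeds: int = None,
               bin_width: float = 0.5, region_depth: float = 12.0,
               ss_window: float = 50.0, classify: bool = True) -> RunResult:
    """One simulation run with steady-state measurement.

    ``n_seeds`` defaults to 50 filament seeds per um of leading edge.
    """
    if n_seeds is None:
        n_seeds = max(1, int(round(50 * params.Lx)))
    state = init_state(params, n_seeds=n_seeds, seed=seed)
    dt = params.dt
    n_total = int(round(t_end / dt))
    t_meas_hi = t_end - closure
    t_meas_lo = t_meas_hi - measure_window
    if t_meas_lo < 0:
        raise ValueError("t_end too short for measurement window + closure")
    record_every = max(1, int(round(1.0 / dt)))
    hist_t, hist_n = [], []
    profile = None
    for k in range(n_total):
        step(state, params)
        if (k + 1) % record_every == 0:
            hist_t.append(state.t)
            hist_n.append(state.ledger.in_network)
        if profile is None and state.t >= t_meas_hi - 1e-9:
            profile = obs.concentration_profile(state, bin_width=bin_width)
            barbed_bins = {ct: obs.barbed_ends_in_bins(
                state, obs.TOMOGRAM_BARBED[ct]["bin_width"], 2)
                for ct in obs.TOMOGRAM_BARBED}
            branch_bins = obs.branches_in_bins(state, 0.25, 2)
            try:
                length_inc = obs.median_length_increase(state)
            except ValueError:
                length_inc = np.nan
    if profile is None:
        raise RuntimeError("measurement snapshot was never taken")
    history = pd.DataFrame({"t": hist_t, "in_network": hist_n})
    # steady-state detection over the trailing window before measurement
    w = min(ss_window, t_meas_lo)
    n_now = np.interp(t_meas_hi, history["t"], history["in_network"])
    n_then = np.interp(t_meas_hi - w, history["t"], history["in_network"])
    steady = bool(abs(n_now - n_then) <= 0.02 * max(n_then, 1))
    tracks = spk.tracks_dataframe(state)
    window = (t_meas_lo, t_meas_hi)
    result = RunResult(params, seed, cell_type, state, profile, tracks,
                       window, t_end, steady, history)
    if classify and cell_type is not None:
        stats = speckle_stats_for_match(tracks, cell_type, window,
                                        region_depth, state.t)
        result.speckle_stats = stats
        result.match = obs.classify_match(
            profile, stats, length_inc, cell_type,
            barbed_bins=barbed_bins[cell_type],
            branch_bins=branch_bins)
    return result


@dataclass
class ReplicateResult:
    runs: list
    pooled_profile: obs.ProfileSet
    pooled_match: obs.MatchReport = None

    @property
    def matches(self):
        return [r.match for r in self.runs if r.match is not None]


def run_replicates(params: SimParams, n_runs: int = 5, seeds=None,
                   base_seed: int = 0, **kwargs) -> ReplicateResult:
    """Independent replicates with pooled observables.

    The pooled profile is the mean of the per-run profiles; pooled speckle
    statistics use the concatenated track tables.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = default_seeds(n_runs, base_seed)
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    runs = [run_single(params, seed=s, **kwargs) for s in seeds]
    p0 = runs[0].profile
    n_bins = min(len(r.profile.factin) for r in runs)
    mean = lambda attr: np.mean(
        [getattr(r.profile, attr)[:n_bins] for r in runs], axis=0)
    pooled = obs.ProfileSet(
        p0.edges[:n_bins + 1], mean("factin"), mean("oligomer"),
        mean("barbed_free"), mean("barbed_capped"), mean("pointed_free"),
        mean("branches"), mean("filaments_crossing"), p0.Lx, p0.z_thickness)
    pooled_match = None
    cell_type = runs[0].cell_type
    if cell_type is not None and runs[0].match is not None:
        tracks = pd.concat([r.tracks for r in runs], ignore_index=True)
        # windows are identical across runs; censoring time is the latest t
        stats = speckle_stats_for_match(
            tracks, cell_type, runs[0].window,
            kwargs.get("region_depth", 12.0),
            max(r.state.t for r in runs))
        incs = [r.match.support["median_length_increment_um"] for r in runs]
        bb = np.mean([r.match.support.get("barbed_bins_per_um",
                                          [np.nan, np.nan])
                      for r in runs], axis=0)
        brb = np.mean([[r.match.support.get("branch_bin_per_um", np.nan)]
                       for r in runs], axis=0)
        pooled_match = obs.classify_match(
            pooled, stats, float(np.nanmean(incs)), cell_type,
            barbed_bins=bb, branch_bins=brb)
    return ReplicateResult(runs, pooled, pooled_match)


def scan(params: SimParams, grid: dict, cell_type: str, n_runs: int = 1,
         base_seed: int = 0, **kwargs) -> pd.DataFrame:
    """Parameter scan over severing rates and maximum oligomer size.

    ``grid`` maps any of ``kunifsev``, ``kendsev``, ``lmaxolig`` (or other
    SimParams fields) to value lists; the full product is run.  Returns one
    row per grid cell with the three match booleans and supporting numbers.
    """
    from itertools import product
    names = list(grid)
    rows = []
    for combo_idx, combo in enumerate(product(*(grid[n] for n in names))):
        cell = dict(zip(names, combo))
        p = params.replace(**cell)
        rep = run_replicates(p, n_runs=n_runs,
                             base_seed=base_seed + 7919 * combo_idx,
                             cell_type=cell_type, **kwargs)
        match = rep.pooled_match if rep.pooled_match is not None \
            else rep.runs[0].match
        row = dict(cell)
        row.update(structure_ok=match.structure_ok,
                   speckle_ok=match.speckle_ok,
                   length_increase_ok=match.length_increase_ok,
                   triple_match=match.triple_match,
                   steady_state=all(r.steady_state_reached for r in rep.runs))
        row.update({f"support_{k}": v for k, v in match.support.items()})
        rows.append(row)
    return pd.DataFrame(rows)
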