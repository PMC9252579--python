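"""Simulated single-molecule speckle (SiMS) statistics.

A fraction ``tag_fraction`` of monomers that polymerize onto the network is
tagged; each tagged incorporation is a speckle appearance.  A speckle
disappears when its monomer depolymerizes off an end or becomes part of a
diffusing oligomer; an oligomer that re-anneals while carrying a tag
produces a fresh appearance.  The engine records these events; this module
turns them into track tables, lifetime distributions and spatial profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .state import SimState

TRACK_COLUMNS = ["tag", "t_appear", "d_appear", "appear_kind",
                 "t_disappear", "d_disappear", "disappear_kind", "lifetime"]


def tracks_dataframe(state: SimState, include_open: bool = True
                     ) -> pd.DataFrame:
    """One row per speckle track.

    Open tracks (no disappearance yet) carry NaN disappearance fields; they
    are reported so that censoring can be handled explicitly downstream.
    """
    rows = [(tag, t0, d0, k0, t1, d1, k1, t1 - t0)
            for tag, t0, d0, k0, t1, d1, k1 in state.speckles.closed]
    if include_open:
        rows += [(tag, t0, d0, k0, np.nan, np.nan, "open", np.nan)
                 for tag, (t0, d0, k0) in state.speckles.open.items()]
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return df.sort_values(["t_appear", "tag"], ignore_index=True)


def _closed(tracks: pd.DataFrame) -> pd.DataFrame:
    return tracks[tracks["t_disappear"].notna()]


def lifetime_distribution(tracks: pd.DataFrame, window=None,
                          region_depth: float = np.inf,
                          bounds=(2.0, 60.0), bin_width: float = 2.0):
    """Normalized probability density of closed-track lifetimes.

    Tracks are selected by appearance time window and appearance distance
    from the edge; the histogram is renormalized to unit mass on
    ``bounds`` (lifetimes below the lower bound, beyond the experimental
    resolution, are excluded).

    Returns ``(bin_edges, density)``.
    """
    sel = _closed(tracks)
    if window is not None:
        t0, t1 = window
        sel = sel[(sel["t_appear"] >= t0) & (sel["t_appear"] < t1)]
    sel = sel[sel["d_appear"] <= region_depth]
    lo, hi = bounds
    lifetimes = sel["lifetime"].to_numpy()
    lifetimes = lifetimes[(lifetimes >= lo) & (lifetimes <= hi)]
    if lifetimes.size == 0:
        raise ValueError("no lifetimes within the normalization bounds")
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(lifetimes, bins=edges)
    density = counts / counts.sum() / bin_width
    return edges, density


def lifetime_fraction_between(tracks: pd.DataFrame, lo: float, hi: float,
                              bounds, window=None,
                              region_depth: float = np.inf) -> float:
    """Fraction of the normalized lifetime mass (within ``bounds``) that
    falls in ``[lo, hi]`` — the quantity used by the speckle-match
    classifier."""
    sel = _closed(tracks)
    if window is not None:
        t0, t1 = window
        sel = sel[(sel["t_appear"] >= t0) & (sel["t_appear"] < t1)]
    sel = sel[sel["d_appear"] <= region_depth]
    lt = sel["lifetime"].to_numpy()
    lt = lt[(lt >= bounds[0]) & (lt <= bounds[1])]
    if lt.size == 0:
        raise ValueError("no lifetimes within the normalization bounds")
    return float(((lt >= lo) & (lt <= hi)).mean())


def short_lifetime_fraction(tracks: pd.DataFrame, cutoffs,
                            region_depth: float = np.inf,
                            window=None, t_now: float = None):
    """Fraction of speckle lifetimes <= each cutoff, for tracks appearing
    within ``region_depth`` of the edge.

    Right censoring is handled per cutoff: an open track observed for at
    least the cutoff duration counts as "longer"; an open track observed
    for less than the cutoff is uninformative and is excluded from that
    cutoff's denominator (``t_now`` is required when open tracks are
    present).
    """
    sel = tracks[tracks["d_appear"] <= region_depth]
    if window is not None:
        t0, t1 = window
        sel = sel[(sel["t_appear"] >= t0) & (sel["t_appear"] < t1)]
    lifetimes = sel["lifetime"].to_numpy()
    open_mask = np.isnan(lifetimes)
    if open_mask.any():
        if t_now is None:
            raise ValueError("t_now required when open tracks are present")
        observed = t_now - sel["t_appear"].to_numpy()
    fractions = []
    for c in np.atleast_1d(cutoffs):
        short = (lifetimes <= c) & ~open_mask
        known = ~open_mask
        if open_mask.any():
            known = known | (observed >= c)
        denom = known.sum()
        fractions.append(float(short.sum() / denom) if denom else np.nan)
    return np.asarray(fractions)


def km_survival(durations: np.ndarray, closed: np.ndarray):
    """Kaplan-Meier survival estimate for right-censored lifetimes.

    ``durations`` holds the lifetime for closed tracks and the observation
    time for open (censored) tracks.  Returns a step function ``S(t)``.
    """
    order = np.argsort(durations, kind="stable")
    d = durations[order]
    e = closed[order]
    uniq = np.unique(d[e])
    n = d.size
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = n - np.searchsorted(d, t, side="left")
        deaths = int((e & (d == t)).sum())
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
        surv.append(s)
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)

    def S(t):
        t = np.asarray(t, float)
        k = np.searchsorted(uniq, t, side="right")
        out = np.where(k == 0, 1.0, surv[np.maximum(k - 1, 0)])
        return out if out.ndim else float(out)

    return S


def lifetime_band_fractions(tracks: pd.DataFrame, bounds, bands,
                            window=None, region_depth: float = np.inf,
                            t_now: float = None):
    """Fractions of the lifetime mass within ``bounds`` falling in each
    ``(lo, hi)`` band, with right censoring handled by Kaplan-Meier.

    ``hi = inf`` measures the tail beyond ``lo`` (clipped at the upper
    normalization bound).  This is the quantity the speckle-dynamics
    classifier thresholds.
    """
    sel = tracks[tracks["d_appear"] <= region_depth]
    if window is not None:
        t0, t1 = window
        sel = sel[(sel["t_appear"] >= t0) & (sel["t_appear"] < t1)]
    lifetimes = sel["lifetime"].to_numpy()
    closed = ~np.isnan(lifetimes)
    if closed.all():
        durations = lifetimes
    else:
        if t_now is None:
            raise ValueError("t_now required when open tracks are present")
        durations = np.where(closed, lifetimes,
                             t_now - sel["t_appear"].to_numpy())
    S = km_survival(durations, closed)
    blo, bhi = bounds
    total = S(blo) - S(bhi)
    if total <= 0:
        raise ValueError("no lifetime mass within the normalization bounds")
    out = []
    for lo, hi in bands:
        lo_c, hi_c = max(lo, blo), min(hi, bhi)
        out.append(float((S(lo_c) - S(hi_c)) / total))
    return np.asarray(out)


def location_profiles(tracks: pd.DataFrame, min_lifetime: float = 2.0,
                      bin_width: float = 1.0, d_max: float = 12.0):
    """Normalized appearance and disappearance densities versus distance
    from the leading edge, for closed tracks with lifetimes of at least
    ``min_lifetime``."""
    sel = _closed(tracks)
    sel = sel[sel["lifetime"] >= min_lifetime]
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    app, _ = np.histogram(sel["d_appear"], bins=edges)
    dis, _ = np.histogram(sel["d_disappear"], bins=edges)
    app = app / app.sum() / bin_width if app.sum() else app.astype(float)
    dis = dis / dis.sum() / bin_width if dis.sum() else dis.astype(float)
    return edges, app, dis


def export_tracks(tracks: pd.DataFrame, path) -> None:
    """Write a delimited track table (one row per speckle event pair),
    compatible in spirit with SpeckleTrackerJ output tables."""
    tracks.to_csv(path, sep="\t", index=False)
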