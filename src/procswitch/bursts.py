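"""Segmentation of unwinding traces into bursts and burst statistics.

A burst is one attempt by the helicase to unwind the hairpin: significant
forward progress (>5 bp) followed by significant backward motion (>5 bp),
usually back to the hairpin base.  Bursts are classified low- or
high-processivity against a 25 bp threshold.  Segmentation runs on the
melt-masked, robust-loess-smoothed trace with 5 bp excursion hysteresis;
the thresholds encode the published manual criteria and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Trace
from .steps import MeltEvent

#: bp threshold separating low- from high-processivity bursts.
HIGH_THRESHOLD_BP = 25.0


@dataclass
class Burst:
    t_start: float
    t_end: float
    processivity: float          # bp, max position within the burst
    duration: float              # s
    category: str                # 'low' | 'high'
    unwinding_portion: tuple[float, float] | None = None
    complete: bool = True        # False when the closing retraction is missing

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


def mask_melt_events(trace: Trace, melt_events: list[MeltEvent]) -> np.ndarray:
    """Return positions with melting spans replaced by linear interpolation
    between the flanking samples, so transient melting does not contaminate
    burst statistics."""
    y = np.array(trace.position, dtype=float)
    t = trace.time
    for ev in melt_events:
        i0 = int(np.searchsorted(t, ev.t_melt, side="left"))
        i1 = int(np.searchsorted(t, ev.t_anneal, side="right"))
        a = max(i0 - 1, 0)
        b = min(i1, y.size - 1)
        if i0 >= i1 or b <= a:
            continue
        y[i0:i1] = np.interp(t[i0:i1], [t[a], t[b]], [y[a], y[b]])
    return y


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


def smooth_robust(trace: Trace, window_points: int = 51,
                  robust_iterations: int = 2) -> Trace:
    """Robust local quadratic regression ('rloess'-style) smoothing.

    Each point is replaced by the value at the centre of a second-degree
    polynomial fitted over a ``window_points`` window with tricube distance
    weights; outliers are downweighted by bisquare robust reweighting
    (``robust_iterations`` passes).  Exact for quadratic inputs away from
    the edges; a single-sample spike is suppressed by the robust weights.
    """
    y = np.asarray(trace.position, dtype=float)
    n = y.size
    w = min(window_points if window_points % 2 == 1 else window_points + 1, n)
    half = w // 2
    robust_w = np.ones(n)
    fitted = y.copy()
    scale = max(np.ptp(y), 1.0)
    for _ in range(robust_iterations + 1):
        fitted = _loess_pass(y, w, half, robust_w)
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 1e-9 * scale:
            break            # (near-)exact fit: nothing to reweight
        u = resid / (6.0 * s)
        robust_w = np.clip(1.0 - u ** 2, 0.0, None) ** 2
    return Trace(time=trace.time, position=fitted, force=trace.force,
                 sampling_rate=trace.sampling_rate,
                 metadata={**trace.metadata, "smoothed": window_points})


def _loess_pass(y: np.ndarray, w: int, half: int,
                robust_w: np.ndarray) -> np.ndarray:
    n = y.size
    fitted = np.empty(n)
    offsets = np.arange(w) - half
    X = np.column_stack([np.ones(w), offsets, offsets ** 2])
    dist_w = _tricube(offsets / (half + 1.0))
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view
        Yw = sliding_window_view(y, w)                 # (m, w)
        Rw = sliding_window_view(robust_w, w)
        W = dist_w[None, :] * Rw                       # (m, w)
        # weighted normal equations, batched
        XW = X[None, :, :] * W[:, :, None]             # (m, w, 3)
        A = np.einsum("mwi,wj->mij", XW, X)            # (m, 3, 3)
        b = np.einsum("mwi,mw->mi", XW, Yw)            # (m, 3)
        A += 1e-12 * np.eye(3)[None, :, :]
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        fitted[half:n - half] = beta[:, 0]
        edge_idx = list(range(half)) + list(range(n - half, n))
    else:
        edge_idx = list(range(n))
    for i in edge_idx:
        a, b_ = max(0, i - half), min(n, i + half + 1)
        off = np.arange(a, b_) - i
        Xe = np.column_stack([np.ones(off.size), off, off ** 2])
        We = _tricube(off / (np.abs(off).max() + 1.0)) * robust_w[a:b_]
        A = Xe.T @ (We[:, None] * Xe) + 1e-12 * np.eye(3)
        beta = np.linalg.solve(A, Xe.T @ (We * y[a:b_]))
        fitted[i] = beta[0]
    return fitted


def _hysteresis_extrema(y: np.ndarray, thresh: float):
    """Alternating (kind, index) turning points with amplitude > thresh."""
    extrema = []
    direction = 0                # 0 unknown, +1 rising, -1 falling
    mn_i = mx_i = 0
    mn = mx = y[0]
    for i in range(1, y.size):
        v = y[i]
        if v < mn:
            mn, mn_i = v, i
        if v > mx:
            mx, mx_i = v, i
        if direction >= 0 and mx - v > thresh:
            extrema.append(("peak", mx_i))
            direction = -1
            mn, mn_i = v, i
        elif direction <= 0 and v - mn > thresh:
            if direction == 0 or not extrema or extrema[-1][0] == "peak":
                extrema.append(("valley", mn_i))
            direction = +1
            mx, mx_i = v, i
    if direction == -1 and extrema and extrema[-1][0] == "peak":
        # trace returned to baseline and stayed (rezip then dissociation):
        # close at the first sample near the post-peak minimum
        p = extrema[-1][1]
        tail = y[p:]
        close = p + int(np.argmax(tail <= tail.min() + 1.0))
        extrema.append(("valley", close))
    return extrema, direction


def segment_bursts(trace: Trace, melt_events: list[MeltEvent] | None = None,
                   min_excursion: float = 5.0,
                   smooth_window: int = 51,
                   stall_exit_bp: float = 10.0) -> list[Burst]:
    """Segment a trace into unwinding bursts.

    Melting spans are masked first, the trace is smoothed, and alternating
    up (>``min_excursion``) / down (>``min_excursion``) excursions delimit
    bursts.  Trailing forward activity without the closing retraction is
    flagged incomplete (excluded from duration statistics by
    :func:`summarize`).  Flat traces yield an empty list.
    """
    melt_events = melt_events or []
    masked = mask_melt_events(trace, melt_events)
    masked_trace = Trace(time=trace.time, position=masked, force=trace.force,
                         sampling_rate=trace.sampling_rate,
                         metadata=dict(trace.metadata))
    smoothed = smooth_robust(masked_trace, smooth_window)
    y = smoothed.position
    t = smoothed.time
    extrema, direction = _hysteresis_extrema(y, min_excursion)
    bursts: list[Burst] = []
    # walk valley -> peak -> valley triples
    for j, (kind, idx) in enumerate(extrema):
        if kind != "peak":
            continue
        v_before = next((extrema[i][1] for i in range(j - 1, -1, -1)
                         if extrema[i][0] == "valley"), 0)
        v_after = next((extrema[i][1] for i in range(j + 1, len(extrema))
                        if extrema[i][0] == "valley"), None)
        complete = v_after is not None
        end_idx = v_after if complete else y.size - 1
        seg = y[v_before:end_idx + 1]
        burst = Burst(t_start=float(t[v_before]), t_end=float(t[end_idx]),
                      processivity=float(seg.max()),
                      duration=float(t[end_idx] - t[v_before]),
                      category=("high" if seg.max() > HIGH_THRESHOLD_BP
                                else "low"),
                      complete=complete)
        burst.unwinding_portion = select_unwinding_portion(
            burst, smoothed, stall_exit_bp=stall_exit_bp)
        bursts.append(burst)
    return bursts


def burst_processivity(burst: Burst, trace: Trace,
                       presmoothed: bool = False) -> float:
    """Maximum base pairs open between the burst start and end times."""
    y = trace.position if presmoothed else smooth_robust(trace).position
    mask = (trace.time >= burst.t_start) & (trace.time <= burst.t_end)
    return float(np.asarray(y)[mask].max())


def select_unwinding_portion(burst: Burst, smoothed: Trace,
                             stall_exit_bp: float = 10.0
                             ) -> tuple[float, float]:
    """Unwinding window of a burst by its processivity class.

    High-processivity bursts: start to the time of maximum unwinding.
    Low-processivity bursts that stall (processivity >= ``stall_exit_bp``):
    start to the last point above ``stall_exit_bp`` (keeps the stall,
    drops the rapid rezip).  Bursts below ``stall_exit_bp``: the first 75%
    of the burst duration.
    """
    t = smoothed.time
    y = np.asarray(smoothed.position)
    mask = (t >= burst.t_start) & (t <= burst.t_end)
    tt, yy = t[mask], y[mask]
    if burst.processivity > HIGH_THRESHOLD_BP:
        end = float(tt[int(np.argmax(yy))])
    elif burst.processivity >= stall_exit_bp:
        above = np.flatnonzero(yy > stall_exit_bp)
        end = float(tt[above[-1]]) if above.size else float(
            burst.t_start + 0.75 * burst.duration)
    else:
        end = float(burst.t_start + 0.75 * burst.duration)
    end = min(max(end, burst.t_start + smoothed.dt), burst.t_end)
    return (burst.t_start, end)


def velocity_profile(bursts: list[Burst], trace: Trace,
                     window_points: int = 50, bin_bp: float = 2.0,
                     presmoothed_trace: Trace | None = None) -> pd.DataFrame:
    """Local unwinding velocity vs. hairpin position.

    Within each burst's unwinding portion, the local velocity is the slope
    of a straight-line fit over half-overlapping ``window_points`` windows;
    window velocities are aggregated across bursts into ``bin_bp`` position
    bins with standard errors.
    """
    if not bursts:
        return pd.DataFrame(
            columns=["position_bp", "velocity_bp_s", "sem", "n"])
    sm = presmoothed_trace if presmoothed_trace is not None \
        else smooth_robust(trace)
    t = sm.time
    y = np.asarray(sm.position)
    samples = []
    step = max(window_points // 2, 1)
    for burst in bursts:
        if burst.unwinding_portion is None:
            burst.unwinding_portion = select_unwinding_portion(burst, sm)
        t0, t1 = burst.unwinding_portion
        mask = (t >= t0) & (t <= t1)
        tt, yy = t[mask], y[mask]
        for a in range(0, tt.size - window_points + 1, step):
            tw = tt[a:a + window_points]
            yw = yy[a:a + window_points]
            slope = np.polyfit(tw, yw, 1)[0]
            samples.append((float(yw.mean()), float(slope)))
    if not samples:
        return pd.DataFrame(
            columns=["position_bp", "velocity_bp_s", "sem", "n"])
    pos, vel = np.array(samples).T
    bins = np.floor(pos / bin_bp).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = vel[bins == b]
        rows.append({"position_bp": (b + 0.5) * bin_bp,
                     "velocity_bp_s": sel.mean(),
                     "sem": (sel.std(ddof=1) / np.sqrt(sel.size)
                             if sel.size > 1 else np.nan),
                     "n": sel.size})
    return pd.DataFrame(rows)


def summarize(bursts_by_condition: dict,
              n_molecules_by_condition: dict) -> pd.DataFrame:
    """Per-condition burst bookkeeping table.

    Columns mirror the standard data-statistics layout: molecule and burst
    counts, bursts per molecule, low/high split against the 25 bp
    threshold, the high fraction with binomial standard error, and mean
    processivity / duration with s.e.m. (durations over complete bursts
    only).  Identities n_low + n_high = n_bursts and
    fraction_high = n_high / n_bursts hold on any input.
    """
    rows = []
    for cond, bursts in bursts_by_condition.items():
        n_mol = n_molecules_by_condition.get(cond, 0)
        n = len(bursts)
        n_high = sum(1 for b in bursts if b.category == "high")
        n_low = n - n_high
        proc = np.array([b.processivity for b in bursts])
        dur = np.array([b.duration for b in bursts if b.complete])
        frac = n_high / n if n else np.nan
        rows.append({
            "condition": cond,
            "n_molecules": n_mol,
            "n_bursts": n,
            "bursts_per_molecule": n / n_mol if n_mol else np.nan,
            "n_low": n_low,
            "n_high": n_high,
            "fraction_high": frac,
            "fraction_high_se": (np.sqrt(frac * (1 - frac) / n)
                                 if n else np.nan),
            "mean_processivity_bp": proc.mean() if n else 0.0,
            "processivity_sem": (proc.std(ddof=1) / np.sqrt(n)
                                 if n > 1 else np.nan),
            "mean_duration_s": dur.mean() if dur.size else 0.0,
            "duration_sem": (dur.std(ddof=1) / np.sqrt(dur.size)
                             if dur.size > 1 else np.nan),
        })
    return pd.DataFrame(rows)
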