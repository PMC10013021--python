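"""Breath detection and windowed breathing features.

Four features are computed from the normalized effort trace with a
moving-window approach:

i.   Respiratory rate (RR): inspiratory peaks in a 10-s window x 6,
     breaths/min.
ii.  Inter-breath interval (IBI): seconds between consecutive breaths.
iii. Ventilation CVar: a minute-ventilation proxy (sum of positive
     amplitude changes over 10 s, x 6), whose coefficient of variation
     is taken over a 30-s window.
iv.  Variability index: (ventilation CVar + IBI CVar) / 2.

Feature windows step by 30 s aligned to epoch boundaries so that every
value maps 1:1 onto a hypnogram epoch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BreathSeries, FeatureTrack, RespSignal

__all__ = [
    "detect_breaths",
    "respiratory_rate",
    "ventilation_proxy",
    "cvar",
    "ibi_cvar",
    "variability_index",
    "epoch_features",
]

MIN_PEAK_PROMINENCE = 0.3  # normalized amplitude units
MIN_PEAK_SPACING_S = 1.0  # 60 breaths/min physiological ceiling
MIN_USABLE_FRACTION = 0.8  # windows with less usable data yield NaN


def detect_breaths(
    resp: RespSignal,
    prominence: float = MIN_PEAK_PROMINENCE,
    min_spacing_s: float = MIN_PEAK_SPACING_S,
    smooth_hz: float = 1.5,
) -> BreathSeries:
    """Detect inspiratory peaks on a normalized effort trace.

    The trace is zero-phase low-pass filtered at ``smooth_hz`` (above
    the 1 Hz physiological breathing ceiling, so breath peaks are
    preserved while sensor noise cannot spawn spurious maxima), then
    local maxima with prominence >= ``prominence`` and spacing >=
    ``min_spacing_s`` are kept; peaks falling in masked (unusable)
    regions are discarded.  A fully-masked signal yields an empty series.
    """
    if resp.quality_mask is not None and not resp.quality_mask.any():
        return BreathSeries(peak_times=np.array([]), t0=resp.t0)
    x = resp.samples
    if smooth_hz and smooth_hz < resp.fs / 2.0:
        b, a = sps.butter(2, smooth_hz / (resp.fs / 2.0), btype="low")
        x = sps.filtfilt(b, a, x)
    idx, _ = sps.find_peaks(
        x,
        prominence=prominence,
        distance=max(int(round(min_spacing_s * resp.fs)), 1),
    )
    if resp.quality_mask is not None:
        idx = idx[resp.quality_mask[idx]]
    return BreathSeries(peak_times=idx / resp.fs, t0=resp.t0)


def _window_grid(duration_s: float, step_s: float) -> np.ndarray:
    """Window-center times: one per step, centered within each step."""
    n = int(duration_s // step_s)
    return (np.arange(n) + 0.5) * step_s


def respiratory_rate(
    breaths: BreathSeries,
    duration_s: float,
    window_s: float = 10.0,
    step_s: float = 10.0,
) -> FeatureTrack:
    """Windowed respiratory rate: peak count in ``window_s`` x (60 / window_s).

    With the conventional 10-s window the value is count x 6, in
    breaths/min.  Empty windows yield 0.
    """
    centers = _window_grid(duration_s, step_s)
    half = window_s / 2.0
    pk = breaths.peak_times
    counts = np.searchsorted(pk, centers + half) - np.searchsorted(pk, centers - half)
    return FeatureTrack(
        times=centers, values=counts * (60.0 / window_s), name="rr_bpm"
    )


def ventilation_proxy(
    resp: RespSignal,
    window_s: float = 10.0,
    step_s: float = 10.0,
    min_usable: float = MIN_USABLE_FRACTION,
) -> FeatureTrack:
    """Minute-ventilation proxy: 6 x sum of positive sample-to-sample
    amplitude changes (inspiratory upstrokes) per 10-s window, a.u./min.

    Windows with less than ``min_usable`` usable samples are NaN.
    """
    x = resp.samples
    rises = np.maximum(np.diff(x, prepend=x[:1]), 0.0)
    centers = _window_grid(resp.duration_s, step_s)
    vals = np.full(centers.shape, np.nan)
    w = int(round(window_s * resp.fs))
    scale = 60.0 / window_s
    for k, c in enumerate(centers):
        i0 = int(round((c - window_s / 2.0) * resp.fs))
        i1 = min(i0 + w, resp.n_samples)
        i0 = max(i0, 0)
        if i1 <= i0:
            continue
        if resp.quality_mask[i0:i1].mean() < min_usable:
            continue
        # skip the first rise of the window: it reaches back before i0
        vals[k] = scale * float(rises[i0 + 1 : i1].sum())
    return FeatureTrack(times=centers, values=vals, name="ventilation_proxy")


def cvar(
    track: FeatureTrack, window_s: float = 30.0, step_s: float = 30.0
) -> FeatureTrack:
    """Coefficient of variation (sample SD / mean) of a feature track
    over moving windows.

    Requires >= 2 finite values per window and a nonzero window mean;
    otherwise the window is NaN (flagged missing, not an error).
    """
    duration = track.times[-1] + step_s / 2.0 if len(track) else 0.0
    centers = _window_grid(duration, step_s)
    vals = np.full(centers.shape, np.nan)
    half = window_s / 2.0
    for k, c in enumerate(centers):
        sel = (track.times >= c - half) & (track.times < c + half)
        v = track.values[sel]
        v = v[np.isfinite(v)]
        if len(v) < 2:
            continue
        m = v.mean()
        if m == 0:
            continue
        vals[k] = v.std(ddof=1) / m
    return FeatureTrack(times=centers, values=vals, name=f"cvar({track.name})")


def ibi_cvar(
    breaths: BreathSeries,
    duration_s: float,
    window_s: float = 30.0,
    step_s: float = 30.0,
) -> FeatureTrack:
    """CV of inter-breath intervals whose terminating peak falls in each
    window (sample SD, n-1 denominator)."""
    centers = _window_grid(duration_s, step_s)
    vals = np.full(centers.shape, np.nan)
    pk = breaths.peak_times
    ib = breaths.ibis
    half = window_s / 2.0
    for k, c in enumerate(centers):
        sel = (pk[1:] >= c - half) & (pk[1:] < c + half)
        v = ib[sel]
        v = v[(v >= 1.0) & (v <= 15.0)]
        if len(v) < 2 or v.mean() == 0:
            continue
        vals[k] = v.std(ddof=1) / v.mean()
    return FeatureTrack(times=centers, values=vals, name="ibi_cvar")


def variability_index(
    vent_cvar: FeatureTrack, ibi_cv: FeatureTrack
) -> FeatureTrack:
    """Respiratory variability index: mean of ventilation CVar and IBI
    CVar per window.  NaN wherever either input is missing."""
    if not vent_cvar.aligned_with(ibi_cv):
        raise ValueError("CVar tracks are not on a common window grid")
    return FeatureTrack(
        times=vent_cvar.times,
        values=(vent_cvar.values + ibi_cv.values) / 2.0,
        name="variability_index",
    )


def epoch_features(
    resp: RespSignal, epoch_len_s: float = 30.0
) -> pd.DataFrame:
    """Per-epoch breathing feature table aligned to the 30-s stage grid.

    Columns: epoch_start (wall clock), rr_bpm (mean of the epoch's 10-s
    windows), ibi_s (median IBI in the epoch), vent_cvar, ibi_cvar,
    variability_index, ventilation_proxy (epoch mean).
    """
    breaths = detect_breaths(resp)
    dur = resp.duration_s
    rr = respiratory_rate(breaths, dur)
    vent = ventilation_proxy(resp)
    vcv = cvar(vent, window_s=epoch_len_s, step_s=epoch_len_s)
    icv = ibi_cvar(breaths, dur, window_s=epoch_len_s, step_s=epoch_len_s)
    vidx = variability_index(vcv, icv)
    n_ep = int(dur // epoch_len_s)
    rows = []
    pk = breaths.peak_times
    ib = breaths.ibis
    for e in range(n_ep):
        lo, hi = e * epoch_len_s, (e + 1) * epoch_len_s
        rr_sel = rr.values[(rr.times >= lo) & (rr.times < hi)]
        rr_sel = rr_sel[np.isfinite(rr_sel)]
        ib_sel = ib[(pk[1:] >= lo) & (pk[1:] < hi)]
        ib_sel = ib_sel[(ib_sel >= 1.0) & (ib_sel <= 15.0)]
        v_sel = vent.values[(vent.times >= lo) & (vent.times < hi)]
        v_sel = v_sel[np.isfinite(v_sel)]
        rows.append(
            {
                "epoch_start": resp.t0 + pd.Timedelta(seconds=lo),
                "rr_bpm": rr_sel.mean() if len(rr_sel) else np.nan,
                "ibi_s": float(np.median(ib_sel)) if len(ib_sel) else np.nan,
                "vent_cvar": vcv.values[e] if e < len(vcv) else np.nan,
                "ibi_cvar": icv.values[e] if e < len(icv) else np.nan,
                "variability_index": vidx.values[e] if e < len(vidx) else np.nan,
                "ventilation_proxy": v_sel.mean() if len(v_sel) else np.nan,
            }
        )
    return pd.DataFrame(rows)
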