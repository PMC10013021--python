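"""Heart-rate-variability and cardiopulmonary-coupling features.

Time-domain (mean NN, RMSSD) and frequency-domain (VLF/LF/HF band
powers of the 4 Hz-resampled NN series, Welch periodogram) HRV features,
plus cardiopulmonary coupling (CPC): coherence-weighted cross-spectral
power between the NN series and the respiratory-effort trace, summed in
a low (0.01-0.1 Hz) and a high (0.1-0.4 Hz) coupling band.

Band edges follow the HRV task-force convention (VLF 0.003-0.04, LF
0.04-0.15, HF 0.15-0.4 Hz).  The respiratory input to CPC is the
measured belt signal rather than an ECG-derived surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import RespSignal, RPeakSeries

__all__ = [
    "NNSeries",
    "HRVFeatures",
    "CPCFeatures",
    "nn_filter",
    "rmssd",
    "band_powers",
    "cpc",
]

RESAMPLE_HZ = 4.0
WELCH_SEG_S = 120.0  # 2-min Welch sub-segments, 50% overlap, Hann taper

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
CPC_LOW_BAND = (0.01, 0.1)
CPC_HIGH_BAND = (0.1, 0.4)


@dataclass
class NNSeries:
    """Physiologically filtered normal-to-normal intervals.

    ``nn_times`` (s) mark the *end* of each accepted interval;
    ``nn_intervals`` are in milliseconds.
    """

    nn_times: np.ndarray
    nn_intervals: np.ndarray

    def __post_init__(self) -> None:
        self.nn_times = np.asarray(self.nn_times, dtype=float)
        self.nn_intervals = np.asarray(self.nn_intervals, dtype=float)
        if self.nn_times.shape != self.nn_intervals.shape:
            raise ValueError("times and intervals must have equal length")

    def __len__(self) -> int:
        return len(self.nn_intervals)

    def window(self, t_lo: float, t_hi: float) -> "NNSeries":
        sel = (self.nn_times >= t_lo) & (self.nn_times < t_hi)
        return NNSeries(self.nn_times[sel], self.nn_intervals[sel])


@dataclass
class HRVFeatures:
    mean_nn_ms: float
    rmssd_ms: float
    vlf: float  # ms^2
    lf: float
    hf: float
    total_power: float = np.nan


@dataclass
class CPCFeatures:
    lfc: float  # coherence-weighted cross power, low coupling band
    hfc: float


def nn_filter(
    r: RPeakSeries,
    rr_range_ms: tuple[float, float] = (300.0, 2000.0),
    max_rel_change: float = 0.2,
    min_quality: float = 0.5,
) -> NNSeries:
    """Clean an R-peak train into normal-to-normal intervals.

    Drops intervals outside ``rr_range_ms`` and intervals differing more
    than ``max_rel_change`` from the previously *accepted* interval (the
    first in-range interval seeds the comparison).  Peaks with a quality
    score below ``min_quality`` are excluded up front.  Empty input
    yields an empty series.
    """
    times = r.peak_times
    if r.quality is not None:
        times = times[r.quality >= min_quality]
    if len(times) < 2:
        return NNSeries(np.array([]), np.array([]))
    rr = np.diff(times) * 1000.0
    ends = times[1:]
    keep_t, keep_rr = [], []
    prev: float | None = None
    for t, v in zip(ends, rr):
        if not rr_range_ms[0] <= v <= rr_range_ms[1]:
            continue
        if prev is not None and abs(v - prev) / prev > max_rel_change:
            continue
        keep_t.append(t)
        keep_rr.append(v)
        prev = v
    return NNSeries(np.asarray(keep_t), np.asarray(keep_rr))


def rmssd(nn: NNSeries, window: tuple[float, float] | None = None) -> float:
    """Root mean square of successive NN-interval differences, ms.

    NaN (missing) when fewer than 3 intervals are available.
    """
    series = nn.window(*window) if window is not None else nn
    if len(series) < 3:
        return float("nan")
    d = np.diff(series.nn_intervals)
    return float(np.sqrt(np.mean(d**2)))


def _resample_nn(nn: NNSeries, t_lo: float, t_hi: float, fs: float = RESAMPLE_HZ):
    grid = np.arange(t_lo, t_hi, 1.0 / fs)
    vals = np.interp(grid, nn.nn_times, nn.nn_intervals)
    return grid, vals


def _band_power(f: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> float:
    sel = (f >= band[0]) & (f < band[1])
    if not sel.any():
        return 0.0
    df = f[1] - f[0] if len(f) > 1 else 1.0
    return float(pxx[sel].sum() * df)


def band_powers(
    nn: NNSeries,
    window: tuple[float, float] | None = None,
    min_coverage: float = 0.6,
) -> HRVFeatures:
    """Frequency-domain HRV features over an analysis window.

    The NN series is linearly interpolated to 4 Hz, linearly detrended,
    and a Welch periodogram (2-min Hann segments, 50% overlap) is
    integrated over the VLF, LF and HF bands.  Requires NN coverage of
    at least ``min_coverage`` of the window (sum of accepted intervals
    over window length); otherwise all features are NaN.
    """
    if window is None:
        if len(nn) == 0:
            return HRVFeatures(*([np.nan] * 5))
        window = (float(nn.nn_times[0]), float(nn.nn_times[-1]))
    t_lo, t_hi = window
    sub = nn.window(t_lo - 2.0, t_hi + 2.0)
    span = t_hi - t_lo
    if span <= 0 or len(sub) < 4:
        return HRVFeatures(*([np.nan] * 5))
    coverage = sub.nn_intervals.sum() / 1000.0 / span
    if coverage < min_coverage:
        return HRVFeatures(*([np.nan] * 5))
    inwin = sub.window(t_lo, t_hi)
    mean_nn = float(np.mean(inwin.nn_intervals)) if len(inwin) else np.nan
    rm = rmssd(sub, (t_lo, t_hi))
    grid, vals = _resample_nn(sub, t_lo, t_hi)
    vals = sps.detrend(vals)
    nper = min(len(vals), int(WELCH_SEG_S * RESAMPLE_HZ))
    f, pxx = sps.welch(
        vals, fs=RESAMPLE_HZ, nperseg=nper, noverlap=nper // 2, window="hann"
    )
    total = _band_power(f, pxx, (0.0, RESAMPLE_HZ / 2.0))
    return HRVFeatures(
        mean_nn_ms=mean_nn,
        rmssd_ms=rm,
        vlf=_band_power(f, pxx, VLF_BAND),
        lf=_band_power(f, pxx, LF_BAND),
        hf=_band_power(f, pxx, HF_BAND),
        total_power=total,
    )


def cpc(
    nn: NNSeries,
    resp: RespSignal,
    window: tuple[float, float] | None = None,
    min_coverage: float = 0.6,
) -> CPCFeatures:
    """Cardiopulmonary coupling over an analysis window (default 600 s
    recommended).

    Both the NN series (interpolated) and the belt signal (polyphase
    decimation) are brought to 4 Hz; coupling is the product of
    cross-spectral magnitude and squared coherence, Welch-averaged over
    2-min sub-segments, summed over the low (0.01-0.1 Hz) and high
    (0.1-0.4 Hz) coupling bands.  Missing (NaN) when the series do not
    overlap or either is degenerate (zero variance).
    """
    if window is None:
        if len(nn) == 0:
            return CPCFeatures(np.nan, np.nan)
        window = (float(nn.nn_times[0]), float(nn.nn_times[-1]))
    t_lo = max(window[0], 0.0)
    t_hi = min(window[1], resp.duration_s)
    if t_hi - t_lo < 60.0 or len(nn.window(t_lo, t_hi)) < 4:
        return CPCFeatures(np.nan, np.nan)
    coverage = nn.window(t_lo, t_hi).nn_intervals.sum() / 1000.0 / (t_hi - t_lo)
    if coverage < min_coverage:
        return CPCFeatures(np.nan, np.nan)
    grid, nn_vals = _resample_nn(nn, t_lo, t_hi)
    # Belt signal: 10 Hz -> 4 Hz polyphase resampling, then align.
    up, down = 2, 5
    if resp.fs != 10.0:
        from fractions import Fraction

        frac = Fraction(int(RESAMPLE_HZ * 1000), int(resp.fs * 1000))
        up, down = frac.numerator, frac.denominator
    resp4 = sps.resample_poly(resp.samples, up, down)
    i0 = int(round(t_lo * RESAMPLE_HZ))
    resp_vals = resp4[i0 : i0 + len(grid)]
    n = min(len(resp_vals), len(nn_vals))
    if n < 8:
        return CPCFeatures(np.nan, np.nan)
    nn_vals, resp_vals = nn_vals[:n], resp_vals[:n]
    if np.var(resp_vals) == 0 or np.var(nn_vals) == 0:
        return CPCFeatures(np.nan, np.nan)
    nn_vals = sps.detrend(nn_vals)
    resp_vals = sps.detrend(resp_vals)
    nper = min(n, int(WELCH_SEG_S * RESAMPLE_HZ))
    kw = dict(fs=RESAMPLE_HZ, nperseg=nper, noverlap=nper // 2, window="hann")
    f, pxy = sps.csd(nn_vals, resp_vals, **kw)
    _, coh = sps.coherence(nn_vals, resp_vals, **kw)
    prod = np.abs(pxy) * coh
    lo = (f >= CPC_LOW_BAND[0]) & (f < CPC_LOW_BAND[1])
    hi = (f >= CPC_HIGH_BAND[0]) & (f < CPC_HIGH_BAND[1])
    return CPCFeatures(lfc=float(prod[lo].sum()), hfc=float(prod[hi].sum()))
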