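"""Biosignal preprocessing: belt-signal quality control, normalization,
and R-peak extraction from ECG.

Belt QC removes two artifact classes: *non-wear* (high and nearly
constant amplitude, e.g. the belt lying stretched on a rail) and *low
signal quality* (no reliable breath detection).  Normalization divides
by the standard deviation of the 1%-99% quantile-clipped signal so a few
extreme excursions cannot dominate the scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal as sps

from .core import RespSignal, RPeakSeries

__all__ = [
    "detect_nonwear",
    "detect_low_quality",
    "apply_qc",
    "normalize",
    "pan_tompkins",
]


def _window_slices(n: int, w: int) -> list[slice]:
    return [slice(i, min(i + w, n)) for i in range(0, n, w)]


def detect_nonwear(
    resp: RespSignal,
    window_s: float = 30.0,
    amp_thresh: float | None = None,
    flatness_thresh: float | None = None,
) -> np.ndarray:
    """Mask of samples flagged as belt-not-worn (True = artifact).

    A window is flagged when its mean absolute amplitude exceeds
    ``amp_thresh`` AND its variance is below ``flatness_thresh`` (high
    *and* constant).  Default thresholds are robust to the artifact
    itself: amp_thresh = 5 x the median across windows of the mean
    absolute amplitude; flatness_thresh = 0.1 x the median window
    variance.
    """
    if resp.n_samples == 0:
        raise ValueError("empty signal")
    if window_s < 10.0:
        raise ValueError("window_s must be >= 10 s")
    x = resp.samples
    w = max(int(round(window_s * resp.fs)), 1)
    slices = _window_slices(resp.n_samples, w)
    amps = np.array([np.mean(np.abs(x[sl])) for sl in slices])
    variances = np.array([np.var(x[sl]) for sl in slices])
    if amp_thresh is None:
        amp_thresh = 5.0 * float(np.median(amps))
    if flatness_thresh is None:
        flatness_thresh = 0.1 * float(np.median(variances))
    mask = np.zeros(resp.n_samples, dtype=bool)
    for sl, a, v in zip(slices, amps, variances):
        if a > amp_thresh and v <= flatness_thresh:
            mask[sl] = True
    return mask


def detect_low_quality(
    resp: RespSignal,
    window_s: float = 60.0,
    rate_bounds_bpm: tuple[float, float] = (4.0, 60.0),
    max_gap_s: float = 15.0,
    band_hz: tuple[float, float] = (0.05, 1.0),
    min_band_fraction: float = 0.5,
) -> np.ndarray:
    """Mask of samples without reliable breath detection (True = bad).

    A window is flagged when any of: the detected-breath rate falls
    outside ``rate_bounds_bpm``; no inspiratory peak is found for more
    than ``max_gap_s``; or less than ``min_band_fraction`` of the
    window's spectral power lies in the respiratory band ``band_hz``
    (breath detection on broadband or flat signals is not trustworthy).
    """
    from .resp import detect_breaths  # breath detector lives downstream

    if resp.n_samples == 0:
        raise ValueError("empty signal")
    breaths = detect_breaths(replace(resp, quality_mask=None))
    pk = breaths.peak_times
    w = max(int(round(window_s * resp.fs)), 1)
    mask = np.zeros(resp.n_samples, dtype=bool)
    lo, hi = rate_bounds_bpm
    for sl in _window_slices(resp.n_samples, w):
        t_lo = sl.start / resp.fs
        t_hi = (sl.stop if sl.stop is not None else resp.n_samples) / resp.fs
        dur_min = (t_hi - t_lo) / 60.0
        n_pk = int(np.count_nonzero((pk >= t_lo) & (pk < t_hi)))
        rate = n_pk / dur_min if dur_min > 0 else 0.0
        if rate < lo or rate > hi:
            mask[sl] = True
            continue
        seg = resp.samples[sl]
        if len(seg) >= 16 and np.var(seg) > 0:
            f, pxx = sps.welch(
                seg, fs=resp.fs, nperseg=min(len(seg), int(30 * resp.fs))
            )
            inband = (f >= band_hz[0]) & (f <= band_hz[1])
            frac = float(pxx[inband].sum() / pxx.sum()) if pxx.sum() > 0 else 0.0
            if frac < min_band_fraction:
                mask[sl] = True
    # Inter-peak gaps longer than max_gap_s, including run-in/run-out.
    edges = np.concatenate(([0.0], pk, [resp.duration_s]))
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a > max_gap_s:
            i0, i1 = int(a * resp.fs), int(np.ceil(b * resp.fs))
            mask[i0:i1] = True
    return mask


def apply_qc(resp: RespSignal, **kwargs) -> RespSignal:
    """Run both QC detectors and clear the corresponding mask bits."""
    bad = detect_nonwear(resp) | detect_low_quality(resp)
    return replace(resp, quality_mask=resp.quality_mask & ~bad)


def normalize(resp: RespSignal) -> RespSignal:
    """Center and scale the effort trace.

    Output = (x - mean(x)) / sd(clip(x, q1%, q99%)), with both statistics
    computed over usable (quality_mask) samples only; the scale is the
    standard deviation of the quantile-clipped usable samples, making the
    result robust to rare extreme excursions.  Affine-invariant for
    positive gain.
    """
    usable = resp.samples[resp.quality_mask]
    if usable.size < 100:
        raise ValueError("need >= 100 usable samples to normalize")
    q1, q99 = np.quantile(usable, [0.01, 0.99])
    sd = float(np.std(np.clip(usable, q1, q99)))
    if sd == 0.0:
        raise ValueError("degenerate signal: zero clipped standard deviation")
    out = (resp.samples - float(np.mean(usable))) / sd
    return replace(resp, samples=out)


def pan_tompkins(ecg: np.ndarray, fs: float) -> RPeakSeries:
    """Classic Pan-Tompkins QRS detector.

    Stages: 5-15 Hz band-pass, derivative, squaring, 150-ms moving-window
    integration, adaptive dual thresholds (signal/noise running
    estimates) with a 200-ms refractory period and a half-threshold
    searchback for missed beats.  Returns R-peak times in seconds,
    refined to the band-passed signal's local maximum.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100.0:
        raise ValueError("fs must be >= 100 Hz")
    if len(ecg) < 5 * fs:
        raise ValueError("signal must be at least 5 s long")
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    bp = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    w = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refractory = int(round(0.200 * fs))
    # Candidate fiducial marks: local maxima of the integrated signal.
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return RPeakSeries(peak_times=np.array([]))
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5 if len(mwi) else 0.0
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    peaks: list[int] = []
    last = -np.inf
    rr_hist: list[float] = []
    for idx in cand:
        v = mwi[idx]
        thr = npki + 0.25 * (spki - npki)
        if v > thr and idx - last >= refractory:
            # Searchback: if the expected beat was missed, a lower
            # threshold would have caught an intermediate candidate; the
            # adaptive estimates handle this via the half threshold below.
            peaks.append(idx)
            spki = 0.125 * v + 0.875 * spki
            if peaks and len(peaks) > 1:
                rr_hist.append(peaks[-1] - peaks[-2])
                rr_hist = rr_hist[-8:]
            last = idx
        else:
            npki = 0.125 * v + 0.875 * npki
            # Searchback for a missed beat at 1.66x the running RR.
            if rr_hist and peaks and idx - peaks[-1] > 1.66 * np.mean(rr_hist):
                if v > npki + 0.125 * (spki - npki) and idx - last >= refractory:
                    peaks.append(idx)
                    spki = 0.25 * v + 0.75 * spki
                    rr_hist.append(peaks[-1] - peaks[-2])
                    rr_hist = rr_hist[-8:]
                    last = idx
    if not peaks:
        return RPeakSeries(peak_times=np.array([]))
    # Refine to the local max of the band-passed signal (R wave apex).
    half = int(round(0.075 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(bp))
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    return RPeakSeries(peak_times=refined / fs)
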