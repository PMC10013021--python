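"""Reading and writing the pipeline's on-disk formats.

Plain-text formats throughout: hypnograms as two-column CSV
(epoch_start_iso8601, stage), R-peaks as two-column CSV (time_s, rr_ms),
respiratory traces as CSV (time_s, value) with fs/t0 in a header
comment, QC masks as run-length interval CSV (start_s, end_s, reason).
EDF recordings are read through mne when it is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, RPeakSeries, RespSignal

__all__ = [
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_rpeaks_csv",
    "write_rpeaks_csv",
    "read_resp_csv",
    "write_resp_csv",
    "read_resp_edf",
    "write_mask_intervals",
]


def write_hypnogram_csv(hyp: Hypnogram, path: str | Path) -> None:
    df = hyp.to_frame()
    df["epoch_start"] = df["epoch_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path, source: str = "file") -> Hypnogram:
    df = pd.read_csv(path)
    starts = pd.to_datetime(df["epoch_start"], format="ISO8601")
    if len(starts) > 1:
        steps = starts.diff().dropna().dt.total_seconds().unique()
        if len(steps) != 1:
            raise ValueError("hypnogram epochs are not on a uniform grid")
        epoch_len = float(steps[0])
    else:
        epoch_len = 30.0
    return Hypnogram(
        start=starts.iloc[0],
        stages=df["stage"].to_numpy(dtype=object),
        epoch_len_s=epoch_len,
        source=source,
    )


def write_rpeaks_csv(r: RPeakSeries, path: str | Path) -> None:
    t = r.peak_times
    rr = np.concatenate(([np.nan], np.diff(t) * 1000.0))
    pd.DataFrame({"time_s": t, "rr_ms": rr}).to_csv(path, index=False)


def read_rpeaks_csv(path: str | Path) -> RPeakSeries:
    df = pd.read_csv(path)
    return RPeakSeries(peak_times=df["time_s"].to_numpy(dtype=float))


def write_resp_csv(resp: RespSignal, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={resp.fs} t0={resp.t0.isoformat()}\n")
    pd.DataFrame(
        {"time_s": np.round(resp.times_s, 3), "value": resp.samples}
    ).to_csv(path, index=False, mode="a", float_format="%.6g")


def read_resp_csv(path: str | Path) -> RespSignal:
    with open(path) as fh:
        header = fh.readline()
    meta = {}
    if header.startswith("#"):
        for tok in header[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        df = pd.read_csv(path, skiprows=1)
    else:
        df = pd.read_csv(path)
    fs = float(meta.get("fs_hz", 0)) or (
        1.0 / float(np.median(np.diff(df["time_s"])))
    )
    t0 = pd.Timestamp(meta["t0"]) if "t0" in meta else pd.Timestamp("2000-01-01")
    return RespSignal(samples=df["value"].to_numpy(dtype=float), fs=fs, t0=t0)


def read_resp_edf(path: str | Path, channel: str = "RESP_EFFORT") -> RespSignal:
    """Read one respiratory channel from an EDF recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), include=[channel], preload=True,
                              verbose="error")
    data = raw.get_data(picks=[channel])[0]
    t0 = pd.Timestamp(raw.info["meas_date"]).tz_localize(None)
    return RespSignal(samples=data, fs=float(raw.info["sfreq"]), t0=t0)


def write_mask_intervals(
    mask: np.ndarray, fs: float, path: str | Path, reason: str = "artifact"
) -> None:
    """Write a boolean per-sample mask as run-length intervals."""
    mask = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    starts, stops = edges[::2], edges[1::2]
    pd.DataFrame(
        {"start_s": starts / fs, "end_s": stops / fs, "reason": reason}
    ).to_csv(path, index=False)
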