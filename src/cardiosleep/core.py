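"""Shared domain types for cardiorespiratory sleep analysis.

The analysis operates on four kinds of objects: epoch-level hypnograms
(one sleep stage per 30-s epoch), raw respiratory-effort traces from a
chest belt, R-peak (heartbeat) event series, and windowed feature tracks.
All are thin dataclasses over numpy arrays with wall-clock anchoring, so
that 08:00-anchored segmentation and day/night splits are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

# Sleep stages. W < N1 < N2 < N3 is the ordinal NREM depth progression;
# R (REM) sits outside the ordinal scale. MISSING marks epochs without
# usable signal and is never produced by the simulator's ground truth.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
MISSING: str = "MISSING"
SLEEP_STAGES: frozenset[str] = frozenset({"N1", "N2", "N3", "R"})
VALID_LABELS: frozenset[str] = frozenset(STAGES) | {MISSING}

EPOCH_LEN_S: float = 30.0


def stage_index(stage: str) -> int:
    """Position of a stage in the canonical (W, N1, N2, N3, R) order."""
    return STAGES.index(stage)


@dataclass
class Hypnogram:
    """Sequence of 30-s epoch sleep stages on a uniform wall-clock grid.

    Parameters
    ----------
    start : pd.Timestamp
        Wall-clock time of the first epoch's start.
    stages : np.ndarray of str
        One label per epoch, each in {W, N1, N2, N3, R, MISSING}.
    epoch_len_s : float
        Epoch length in seconds (30 by convention).
    source : str
        Provenance tag, e.g. "truth", "hrv-model", "breathing-model",
        "expert".
    """

    start: pd.Timestamp
    stages: np.ndarray
    epoch_len_s: float = EPOCH_LEN_S
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.stages = np.asarray(self.stages, dtype=object)
        bad = set(np.unique(self.stages)) - VALID_LABELS
        if bad:
            raise ValueError(f"invalid stage labels: {sorted(bad)}")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def epoch_starts(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_len_s, unit="s"
        )

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        """Stage of the epoch containing offset ``t_s`` seconds from start."""
        i = int(t_s // self.epoch_len_s)
        i = min(max(i, 0), self.n_epochs - 1)
        return self.stages[i]

    def slice_epochs(self, lo: int, hi: int) -> "Hypnogram":
        """Half-open epoch slice [lo, hi) as a new Hypnogram."""
        return replace(
            self,
            start=self.start + pd.Timedelta(seconds=lo * self.epoch_len_s),
            stages=self.stages[lo:hi].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_start": self.epoch_starts, "stage": self.stages}
        )


@dataclass
class RespSignal:
    """Respiratory-effort belt trace (uncalibrated amplitude units).

    ``quality_mask`` is True where the sample is usable; QC steps only
    ever clear mask bits, never set them.
    """

    samples: np.ndarray
    fs: float = 10.0
    t0: pd.Timestamp = pd.Timestamp("2000-01-01 20:00:00")
    quality_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.t0 = pd.Timestamp(self.t0)
        if self.quality_mask is None:
            self.quality_mask = np.ones(self.samples.shape, dtype=bool)
        else:
            self.quality_mask = np.asarray(self.quality_mask, dtype=bool)
            if self.quality_mask.shape != self.samples.shape:
                raise ValueError("quality_mask length must match samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class RPeakSeries:
    """R-peak (heartbeat) occurrence times in seconds from ``t0``."""

    peak_times: np.ndarray
    t0: pd.Timestamp = pd.Timestamp("2000-01-01 20:00:00")
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        self.t0 = pd.Timestamp(self.t0)
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    @property
    def rr_ms(self) -> np.ndarray:
        """Successive R-R intervals in milliseconds (unfiltered)."""
        return np.diff(self.peak_times) * 1000.0


@dataclass
class BreathSeries:
    """Detected inspiratory-peak times (s) and inter-breath intervals."""

    peak_times: np.ndarray
    t0: pd.Timestamp = pd.Timestamp("2000-01-01 20:00:00")

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n_breaths(self) -> int:
        return len(self.peak_times)

    @property
    def ibis(self) -> np.ndarray:
        """All successive inter-breath intervals, seconds."""
        return np.diff(self.peak_times)

    @property
    def ibis_filtered(self) -> np.ndarray:
        """IBIs restricted to the physiological 1-15 s range."""
        d = self.ibis
        return d[(d >= 1.0) & (d <= 15.0)]


@dataclass
class FeatureTrack:
    """Windowed feature values at strictly increasing window-center times."""

    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def aligned_with(self, other: "FeatureTrack") -> bool:
        return self.times.shape == other.times.shape and np.allclose(
            self.times, other.times
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.times, name=self.name)
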