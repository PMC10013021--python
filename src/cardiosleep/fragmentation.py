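"""Sleep-fragmentation metrics on a 24-h segment.

Six metrics, computed from the HRV-model hypnogram by convention:
day (08:00-20:00) and night (20:00-08:00) sleep proportions, the share
of sleep (and of REM sleep) occurring in the day, and counts of sleep
periods lasting at least 1 min and at least 5 min per 24 h.  A sleep
period is a maximal run of consecutive sleep-staged epochs with no
MISSING gap (gaps conservatively break runs).  At 30-s epochs the
1-min threshold means runs of >= 2 epochs and the 5-min threshold runs
of >= 10 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, SLEEP_STAGES, Hypnogram
from .indices import Segment24h

__all__ = ["FragmentationRecord", "frag_metrics", "rem_day_share", "sleep_runs"]


@dataclass
class FragmentationRecord:
    day_sleep_pct: float
    night_sleep_pct: float
    day_share_of_sleep_pct: float
    day_share_of_rem_pct: float
    n_periods_1min: float  # normalized to 24 h of available data
    n_periods_5min: float
    n_periods_1min_raw: int = 0
    n_periods_5min_raw: int = 0


def sleep_runs(stages: np.ndarray) -> list[int]:
    """Lengths (in epochs) of maximal consecutive sleep runs; MISSING
    and wake both terminate a run."""
    runs: list[int] = []
    n = 0
    for s in stages:
        if s in SLEEP_STAGES:
            n += 1
        else:
            if n:
                runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


def rem_day_share(hyp: Hypnogram, day_mask: np.ndarray) -> float:
    """Percent of REM epochs that occur in the day half; NaN (missing,
    not zero) when no REM was staged."""
    is_rem = hyp.stages == "R"
    n_rem = int(is_rem.sum())
    if n_rem == 0:
        return float("nan")
    return 100.0 * int(np.sum(is_rem & day_mask)) / n_rem


def frag_metrics(seg: Segment24h, hyp: Hypnogram | None = None) -> FragmentationRecord:
    """Fragmentation metrics for one segment.

    ``hyp`` defaults to the segment's HRV-model hypnogram.  Day/night
    denominators use *available* (non-MISSING) epochs in each half;
    period counts are normalized to a full 24 h (count x 24/available_h)
    since partial head/tail segments would otherwise bias counts low;
    raw counts are kept alongside.
    """
    if hyp is None:
        hyp = seg.hyp_hrv
    stages = hyp.stages
    day = seg.day_mask()
    defined = stages != MISSING
    is_sleep = defined & np.isin(stages, list(SLEEP_STAGES))
    n_day_avail = int(np.sum(defined & day))
    n_night_avail = int(np.sum(defined & ~day))
    n_day_sleep = int(np.sum(is_sleep & day))
    n_night_sleep = int(np.sum(is_sleep & ~day))
    n_sleep = n_day_sleep + n_night_sleep
    day_sleep_pct = 100.0 * n_day_sleep / n_day_avail if n_day_avail else np.nan
    night_sleep_pct = (
        100.0 * n_night_sleep / n_night_avail if n_night_avail else np.nan
    )
    day_share = 100.0 * n_day_sleep / n_sleep if n_sleep else np.nan
    rem_share = rem_day_share(hyp, day)
    runs = sleep_runs(stages)
    epoch_min = hyp.epoch_len_s / 60.0
    raw1 = sum(1 for r in runs if r * epoch_min >= 1.0)
    raw5 = sum(1 for r in runs if r * epoch_min >= 5.0)
    avail_h = float(defined.sum()) * hyp.epoch_len_s / 3600.0
    scale = 24.0 / avail_h if avail_h > 0 else np.nan
    return FragmentationRecord(
        day_sleep_pct=day_sleep_pct,
        night_sleep_pct=night_sleep_pct,
        day_share_of_sleep_pct=day_share,
        day_share_of_rem_pct=rem_share,
        n_periods_1min=raw1 * scale if avail_h > 0 else np.nan,
        n_periods_5min=raw5 * scale if avail_h > 0 else np.nan,
        n_periods_1min_raw=raw1,
        n_periods_5min_raw=raw5,
    )
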