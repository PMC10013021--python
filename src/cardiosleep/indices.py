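"""24-hour segmentation and sleep indices.

Recordings are split into 24-h segments anchored at 08:00 local clock
time (day = 08:00-20:00, night = 20:00-08:00).  For each segment and
each model hypnogram, eight sleep indices are computed:

1. total sleep duration (h); 2. concordant sleep duration (h);
3. discordant sleep duration (h); 4. discordant proportion of total
sleep (%); 5. sleep fraction of available data (%); 6. stage R/N1/N2/
N3/N2+N3 percentages of sleep; 7. sleep fragmentation index, SFI:
transitions (N2,N3,R) -> (N1,W) per hour of sleep; 8. wake transitions
per hour of sleep: (N1,N2,N3,R) -> W.

The two models' records are combined as x_mean = (x_HRV + x_breathing)/2,
and three sensitivity approaches control segment inclusion and basis:
A1 any sleep / total-sleep basis; A2 >= 2 h concordant sleep /
total-sleep basis; A3 >= 2 h concordant sleep / concordant-sleep basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import CONCORDANT, DISCORDANT, concordance_series
from .core import MISSING, SLEEP_STAGES, Hypnogram

__all__ = [
    "Segment24h",
    "SleepIndexRecord",
    "segment",
    "sleep_indices",
    "mean_indices",
    "sensitivity_select",
    "patient_aggregate",
    "report_percent_change",
    "APPROACHES",
]

APPROACHES = ("A1", "A2", "A3")
DAY_START_H, NIGHT_START_H = 8, 20

_SFI_FROM = frozenset({"N2", "N3", "R"})
_SFI_TO = frozenset({"N1", "W"})
_SCALAR_FIELDS = (
    "tst_h", "concordant_sleep_h", "discordant_sleep_h", "discordant_pct",
    "sleep_fraction_pct", "sfi", "wake_trans_per_h",
)
_STAGE_KEYS = ("R", "N1", "N2", "N3", "N2N3")


@dataclass
class Segment24h:
    """One 08:00-anchored 24-h window of paired hypnograms."""

    start: pd.Timestamp  # the 08:00 anchor
    hyp_hrv: Hypnogram
    hyp_br: Hypnogram
    pair_labels: np.ndarray
    patient_id: str = ""

    @property
    def available_h(self) -> float:
        defined = (self.hyp_hrv.stages != MISSING) & (self.hyp_br.stages != MISSING)
        return float(defined.sum()) * self.hyp_hrv.epoch_len_s / 3600.0

    @property
    def concordant_sleep_h(self) -> float:
        """Hours of epochs labelled concordant where both models stage
        sleep (the A2/A3 inclusion quantity)."""
        both_sleep = np.array(
            [a in SLEEP_STAGES and b in SLEEP_STAGES
             for a, b in zip(self.hyp_hrv.stages, self.hyp_br.stages)]
        )
        n = int(np.sum(both_sleep & (self.pair_labels == CONCORDANT)))
        return n * self.hyp_hrv.epoch_len_s / 3600.0

    def day_mask(self) -> np.ndarray:
        """True for epochs starting within [08:00, 20:00)."""
        hours = self.hyp_hrv.epoch_starts.hour
        return np.asarray((hours >= DAY_START_H) & (hours < NIGHT_START_H))


@dataclass
class SleepIndexRecord:
    """The eight sleep indices for one hypnogram on one segment."""

    tst_h: float
    concordant_sleep_h: float
    discordant_sleep_h: float
    discordant_pct: float
    sleep_fraction_pct: float
    stage_pct: dict[str, float]
    sfi: float
    wake_trans_per_h: float
    basis: str = "total"
    model: str = ""

    def to_series(self) -> pd.Series:
        d = {k: getattr(self, k) for k in _SCALAR_FIELDS}
        for s in _STAGE_KEYS:
            d[f"stage_pct_{s}"] = self.stage_pct.get(s, np.nan)
        return pd.Series(d)

    @classmethod
    def from_series(cls, s: pd.Series, basis: str = "total",
                    model: str = "") -> "SleepIndexRecord":
        return cls(
            **{k: float(s[k]) for k in _SCALAR_FIELDS},
            stage_pct={k: float(s[f"stage_pct_{k}"]) for k in _STAGE_KEYS},
            basis=basis, model=model,
        )


def _anchor_0800(ts: pd.Timestamp) -> pd.Timestamp:
    """Most recent 08:00 at or before ts."""
    anchor = ts.normalize() + pd.Timedelta(hours=DAY_START_H)
    if ts < anchor:
        anchor -= pd.Timedelta(days=1)
    return anchor


def segment(
    hyp_hrv: Hypnogram,
    hyp_br: Hypnogram,
    labels: np.ndarray | None = None,
    patient_id: str = "",
) -> list[Segment24h]:
    """Split paired hypnograms into consecutive 08:00-anchored 24-h
    segments (half-open: an epoch starting exactly at 08:00 opens the
    new segment).  Partial head/tail segments are retained."""
    if labels is None:
        labels, _ = concordance_series(hyp_hrv, hyp_br)
    starts = hyp_hrv.epoch_starts
    anchors = np.array([_anchor_0800(t) for t in starts])
    out: list[Segment24h] = []
    for anchor in pd.unique(anchors):
        idx = np.nonzero(anchors == anchor)[0]
        lo, hi = idx[0], idx[-1] + 1
        out.append(
            Segment24h(
                start=pd.Timestamp(anchor),
                hyp_hrv=hyp_hrv.slice_epochs(lo, hi),
                hyp_br=hyp_br.slice_epochs(lo, hi),
                pair_labels=labels[lo:hi].copy(),
                patient_id=patient_id,
            )
        )
    return out


def sleep_indices(
    hyp: Hypnogram,
    labels: np.ndarray,
    basis: str = "total",
    available_h: float | None = None,
    model: str = "",
) -> SleepIndexRecord:
    """Compute the eight sleep indices for one model hypnogram.

    ``basis="total"`` counts every epoch this model stages as sleep;
    ``basis="concordant"`` restricts sleep epochs (and transition
    counting) to epochs whose pair label is CONCORDANT.  Transitions
    across MISSING (or, under the concordant basis, non-concordant)
    gaps are not counted.  With zero sleep the duration indices are 0
    and the rate/percentage indices are NaN.
    """
    if basis not in ("total", "concordant"):
        raise ValueError("basis must be 'total' or 'concordant'")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != hyp.n_epochs:
        raise ValueError("labels not aligned with hypnogram")
    stages = hyp.stages
    epoch_h = hyp.epoch_len_s / 3600.0
    defined = stages != MISSING
    if basis == "concordant":
        defined &= labels == CONCORDANT
    is_sleep = defined & np.isin(stages, list(SLEEP_STAGES))
    n_sleep = int(is_sleep.sum())
    tst_h = n_sleep * epoch_h
    conc_h = int(np.sum(is_sleep & (labels == CONCORDANT))) * epoch_h
    disc_h = int(np.sum(is_sleep & (labels == DISCORDANT))) * epoch_h
    if available_h is None:
        available_h = float(defined.sum()) * epoch_h
    sleep_fraction = 100.0 * tst_h / available_h if available_h > 0 else np.nan
    if n_sleep > 0:
        stage_pct = {
            s: 100.0 * int(np.sum(is_sleep & (stages == s))) / n_sleep
            for s in ("R", "N1", "N2", "N3")
        }
        stage_pct["N2N3"] = stage_pct["N2"] + stage_pct["N3"]
        discordant_pct = 100.0 * disc_h / tst_h
        n_sfi = n_wake = 0
        for i in range(hyp.n_epochs - 1):
            if not (defined[i] and defined[i + 1]):
                continue
            a, b = stages[i], stages[i + 1]
            if a in _SFI_FROM and b in _SFI_TO:
                n_sfi += 1
            if a in SLEEP_STAGES and b == "W":
                n_wake += 1
        sfi = n_sfi / tst_h
        wake_trans = n_wake / tst_h
    else:
        stage_pct = {s: np.nan for s in _STAGE_KEYS}
        discordant_pct = np.nan
        sfi = np.nan
        wake_trans = np.nan
    return SleepIndexRecord(
        tst_h=tst_h,
        concordant_sleep_h=conc_h,
        discordant_sleep_h=disc_h,
        discordant_pct=discordant_pct,
        sleep_fraction_pct=sleep_fraction,
        stage_pct=stage_pct,
        sfi=sfi,
        wake_trans_per_h=wake_trans,
        basis=basis,
        model=model,
    )


def mean_indices(a: SleepIndexRecord, b: SleepIndexRecord) -> SleepIndexRecord:
    """Model-mean record: x_mean = (x_HRV + x_breathing) / 2 elementwise.

    An index missing (NaN) in either record is missing in the mean.
    """
    if a.basis != b.basis:
        raise ValueError("cannot average records with different bases")
    m = (a.to_series() + b.to_series()) / 2.0
    return SleepIndexRecord.from_series(m, basis=a.basis, model="mean")


def segment_records(
    seg: Segment24h, basis: str = "total"
) -> dict[str, SleepIndexRecord]:
    """Per-model and model-mean index records for one segment."""
    avail = seg.available_h
    rec_hrv = sleep_indices(
        seg.hyp_hrv, seg.pair_labels, basis=basis, available_h=avail, model="hrv"
    )
    rec_br = sleep_indices(
        seg.hyp_br, seg.pair_labels, basis=basis, available_h=avail, model="breathing"
    )
    return {
        "hrv": rec_hrv,
        "breathing": rec_br,
        "mean": mean_indices(rec_hrv, rec_br),
    }


def sensitivity_select(
    segments: list[Segment24h], approach: str
) -> list[tuple[Segment24h, dict[str, SleepIndexRecord]]]:
    """Apply one sensitivity approach to a list of segments.

    A1: keep segments with any sleep (either model), total-sleep basis.
    A2: keep segments with >= 2 h of concordant sleep, total-sleep basis.
    A3: same inclusion as A2, concordant-sleep basis.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; valid: {APPROACHES}")
    basis = "concordant" if approach == "A3" else "total"
    out = []
    for seg in segments:
        recs_total = segment_records(seg, basis="total")
        if approach == "A1":
            if recs_total["hrv"].tst_h <= 0 and recs_total["breathing"].tst_h <= 0:
                continue
        else:
            if seg.concordant_sleep_h < 2.0:
                continue
        recs = recs_total if basis == "total" else segment_records(seg, basis=basis)
        out.append((seg, recs))
    return out


def patient_aggregate(records: list[SleepIndexRecord]) -> SleepIndexRecord:
    """Arithmetic mean of index records across a patient's 24-h segments,
    skipping missing values per index."""
    if not records:
        raise ValueError("need at least one record")
    df = pd.DataFrame([r.to_series() for r in records])
    return SleepIndexRecord.from_series(
        df.mean(skipna=True), basis=records[0].basis, model=records[0].model
    )


def report_percent_change(x_ref: float, x_new: float) -> float:
    """Relative change in percent, rounded to one decimal for display."""
    if x_ref <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (x_new - x_ref) / x_ref, 1)
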