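"""Swimmer-plot rendering of multi-day staging results.

One horizontal lane per patient, time on the x axis.  Where the two
model hypnograms are concordant the lane is colored by stage class
(NREM / REM / wake), split into a breathing-model top half and an
HRV-model bottom half; discordant epochs are drawn in a distinct
highlight color.  Patients are sorted by their discordant proportion.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Patch

from .concordance import CONCORDANT, DISCORDANT
from .core import MISSING, Hypnogram

__all__ = ["swimmer_plot"]

_COLORS = {"NREM": "#2c5f8a", "R": "#58b368", "W": "#d9d9d9",
           "DISCORDANT": "#f28e2b"}


def _stage_class(stage: str) -> str | None:
    if stage == MISSING:
        return None
    if stage in ("N1", "N2", "N3"):
        return "NREM"
    return stage  # W or R


def swimmer_plot(
    patients: list[tuple[str, Hypnogram, Hypnogram, np.ndarray]],
    out_path: str | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Render the swimmer plot.

    ``patients`` is a list of (patient_id, hyp_hrv, hyp_br, pair_labels).
    Lanes are sorted by descending discordant proportion.
    """
    def disc_prop(labels: np.ndarray) -> float:
        n_def = np.sum(labels != "UNDEFINED")
        return float(np.sum(labels == DISCORDANT) / n_def) if n_def else 0.0

    patients = sorted(patients, key=lambda p: disc_prop(p[3]), reverse=True)
    if ax is None:
        _, ax = plt.subplots(
            figsize=(10, max(2.0, 0.4 * len(patients))), constrained_layout=True
        )
    t_origin = min(p[1].start for p in patients)
    for lane, (pid, hrv, br, labels) in enumerate(patients):
        offset_h = (hrv.start - t_origin).total_seconds() / 3600.0
        w_h = hrv.epoch_len_s / 3600.0
        for i in range(hrv.n_epochs):
            x = offset_h + i * w_h
            if labels[i] == DISCORDANT:
                ax.broken_barh([(x, w_h)], (lane - 0.4, 0.8),
                               color=_COLORS["DISCORDANT"], linewidth=0)
                continue
            if labels[i] != CONCORDANT:
                continue
            for half, stage in ((0.0, br.stages[i]), (-0.4, hrv.stages[i])):
                cls = _stage_class(stage)
                if cls is None:
                    continue
                ax.broken_barh([(x, w_h)], (lane + half, 0.4),
                               color=_COLORS[cls], linewidth=0)
        ax.text(-0.5, lane, str(pid), ha="right", va="center", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel(f"hours since {t_origin:%Y-%m-%d %H:%M}")
    ax.set_ylim(-1, len(patients))
    ax.legend(
        handles=[Patch(color=c, label=l) for l, c in
                 [("NREM (concordant)", _COLORS["NREM"]),
                  ("REM (concordant)", _COLORS["R"]),
                  ("Wake (concordant)", _COLORS["W"]),
                  ("Discordant", _COLORS["DISCORDANT"])]],
        loc="upper right", fontsize=8,
    )
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150)
    return ax
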