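"""Epoch-level concordance between two model hypnograms.

Two stagers (one driven by heart-rate variability, one by respiratory
effort) each assign a stage to every 30-s epoch.  Because NREM depth is
a continuum (W < N1 < N2 < N3), the pair is *concordant* when the
stages agree to within one ordinal step; REM is concordant only when
both models assign R.  The resulting unordered-pair partition is:

  concordant: (W,W) (N1,N1) (N2,N2) (N3,N3) (R,R) (W,N1) (N1,N2) (N2,N3)
  discordant: (W,N2) (W,N3) (W,R) (N1,N3) (R,N1) (R,N2) (R,N3)

Epochs where either model lacks signal (MISSING) are UNDEFINED and
excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .core import MISSING, STAGES, Hypnogram, stage_index

__all__ = [
    "CONCORDANT",
    "DISCORDANT",
    "UNDEFINED",
    "CONCORDANT_PAIRS",
    "DISCORDANT_PAIRS",
    "classify_pair",
    "concordance_series",
    "ConcordanceSummary",
    "kappa_vs_reference",
]

CONCORDANT = "CONCORDANT"
DISCORDANT = "DISCORDANT"
UNDEFINED = "UNDEFINED"

CONCORDANT_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("W", "W"), ("N1", "N1"), ("N2", "N2"), ("N3", "N3"), ("R", "R"),
        ("W", "N1"), ("N1", "N2"), ("N2", "N3"),
    ]
)
DISCORDANT_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("W", "N2"), ("W", "N3"), ("W", "R"),
        ("N1", "N3"), ("R", "N1"), ("R", "N2"), ("R", "N3"),
    ]
)


def classify_pair(a: str, b: str) -> str:
    """Classify one simultaneous stage pair; symmetric in (a, b)."""
    if a == MISSING or b == MISSING:
        return UNDEFINED
    if a == "R" or b == "R":
        return CONCORDANT if a == b else DISCORDANT
    return CONCORDANT if abs(stage_index(a) - stage_index(b)) <= 1 else DISCORDANT


@dataclass
class ConcordanceSummary:
    n_concordant: int
    n_discordant: int
    n_undefined: int

    @property
    def n_defined(self) -> int:
        return self.n_concordant + self.n_discordant

    @property
    def proportion_concordant(self) -> float:
        if self.n_defined == 0:
            return float("nan")
        return self.n_concordant / self.n_defined

    @property
    def proportion_discordant(self) -> float:
        if self.n_defined == 0:
            return float("nan")
        return self.n_discordant / self.n_defined


def _check_aligned(a: Hypnogram, b: Hypnogram) -> None:
    if a.n_epochs != b.n_epochs or a.start != b.start or a.epoch_len_s != b.epoch_len_s:
        raise ValueError(
            "hypnograms are not aligned to the same 30-s epoch grid; "
            "align them before comparison"
        )
    if a.n_epochs == 0:
        raise ValueError("no overlapping epochs")


def concordance_series(
    hrv: Hypnogram, br: Hypnogram
) -> tuple[np.ndarray, ConcordanceSummary]:
    """Per-epoch concordance labels plus counts/proportions.

    Only epochs where both models produce a stage (both non-MISSING)
    enter the denominators.
    """
    _check_aligned(hrv, br)
    labels = np.array(
        [classify_pair(a, b) for a, b in zip(hrv.stages, br.stages)],
        dtype=object,
    )
    return labels, ConcordanceSummary(
        n_concordant=int(np.sum(labels == CONCORDANT)),
        n_discordant=int(np.sum(labels == DISCORDANT)),
        n_undefined=int(np.sum(labels == UNDEFINED)),
    )


def kappa_vs_reference(
    model: Hypnogram,
    ref: Hypnogram,
    stage_map: str = "full",
    epoch_mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray, list[str]]:
    """Cohen's kappa and confusion matrix of a model against a reference
    (e.g. expert) hypnogram.

    ``stage_map="full"`` scores over (W, N1, N2, N3, R);
    ``stage_map="pooled-nrem"`` pools N1/N2/N3 into NREM, scoring over
    (W, NREM, R).  ``epoch_mask`` optionally restricts scoring (e.g. to
    concordant epochs only).  Returns (kappa, matrix, label order);
    kappa is NaN for a degenerate single-class comparison.
    """
    _check_aligned(model, ref)
    if stage_map == "full":
        order = list(STAGES)
        mapper = {s: s for s in STAGES}
    elif stage_map == "pooled-nrem":
        order = ["W", "NREM", "R"]
        mapper = {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "R": "R"}
    else:
        raise ValueError("stage_map must be 'full' or 'pooled-nrem'")
    keep = (model.stages != MISSING) & (ref.stages != MISSING)
    if epoch_mask is not None:
        keep &= np.asarray(epoch_mask, dtype=bool)
    y_m = [mapper[s] for s in model.stages[keep]]
    y_r = [mapper[s] for s in ref.stages[keep]]
    cm = confusion_matrix(y_r, y_m, labels=order)
    if len(set(y_m) | set(y_r)) < 2:
        return float("nan"), cm, order
    kappa = cohen_kappa_score(y_r, y_m, labels=order)
    return float(kappa), cm, order
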