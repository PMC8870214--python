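"""Event-level cytometry to per-sample marker summaries.

A marker is summarised on the gated abnormal (tumour B) population:
percent of events above the event-level gate, median fluorescence (MFI)
and an intensity class (dim: MFI < 500, bright: MFI > 1000, moderate in
between); a marker is called positive when >= 20% of abnormal cells
express it.  Tumour infiltration is the percentage of abnormal cells among
total lymphocytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import EventTable
from .markers import (
    BRIGHT_MFI,
    CD4_CD8_CUTOFF,
    DIM_MFI,
    LYMPHOCYTE_POPULATIONS,
    NORMAL_B,
    POSITIVITY_PCT,
    T4,
    T8,
    TUMOR_B,
)


@dataclass
class MarkerSummary:
    marker: str
    percent_positive: float  # % of tumour events above the event gate
    mfi: float  # median fluorescence of tumour events
    n_events: int
    intensity_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValueError("percent_positive outside [0, 100]")
        if self.mfi < 0:
            raise ValueError("mfi must be >= 0")


@dataclass
class SampleProfile:
    sample_id: str
    summaries: dict[str, MarkerSummary] = field(default_factory=dict)
    infiltration_pct: float = 0.0  # abnormal cells among lymphocytes
    cd4_cd8_ratio: float | None = None
    pct_abnormal_of_all_events: float = 0.0  # abnormal cells on sample

    def positive(self, marker: str) -> bool | None:
        """Positivity call for ``marker``; None when not assayed."""
        s = self.summaries.get(marker)
        return None if s is None else marker_positive(s)


def intensity_class(mfi: float, percent_positive: float) -> str:
    """Intensity class from the MFI bands.

    Reported as "negative" whenever the 20% positivity rule fails,
    regardless of MFI.
    """
    if percent_positive < POSITIVITY_PCT:
        return "negative"
    if mfi < DIM_MFI:
        return "dim"
    if mfi > BRIGHT_MFI:
        return "bright"
    return "moderate"


def summarize_marker(
    events: EventTable, marker: str, event_cutoff: float
) -> MarkerSummary:
    """Summarise one marker on the tumour-B events of a sample."""
    column = events.column(marker)  # KeyError if absent
    tumor = events.population_mask(TUMOR_B)
    n = int(tumor.sum())
    if n == 0:
        raise ValueError(f"sample {events.sample_id}: no tumor_B events")
    x = column[tumor]
    pct = 100.0 * float((x > event_cutoff).sum()) / n
    mfi = float(np.median(x))  # even count: mean of the two central values
    return MarkerSummary(marker, pct, mfi, n, intensity_class(mfi, pct))


def marker_positive(summary: MarkerSummary) -> bool:
    """Positivity rule: >= 20% of abnormal cells express the marker."""
    return summary.percent_positive >= POSITIVITY_PCT


def tumor_infiltration(events: EventTable) -> float:
    """Abnormal cells as a percentage of total lymphocytes."""
    lymph = events.population_mask(*LYMPHOCYTE_POPULATIONS)
    n_lymph = int(lymph.sum())
    if n_lymph == 0:
        raise ValueError(f"sample {events.sample_id}: no lymphocyte events")
    n_tumor = int(events.population_mask(TUMOR_B).sum())
    return 100.0 * n_tumor / n_lymph


def cd4_cd8_ratio(events: EventTable) -> tuple[float, str]:
    """CD4/CD8 T-cell ratio and its survival stratum (cut-off: ratio > 2)."""
    n_t8 = int(events.population_mask(T8).sum())
    if n_t8 == 0:
        raise ValueError(f"sample {events.sample_id}: ratio undefined (no T8 events)")
    n_t4 = int(events.population_mask(T4).sum())
    ratio = n_t4 / n_t8
    return ratio, ("gt2" if ratio > CD4_CD8_CUTOFF else "le2")


def percentile_cutoffs(events: EventTable, q: float = 99.0) -> dict[str, float]:
    """Per-marker event gate: the q-th percentile of the sample's normal-B
    (internal negative) events."""
    nb = events.population_mask(NORMAL_B)
    if not nb.any():
        raise ValueError(f"sample {events.sample_id}: no normal_B events for gating")
    return {
        m: float(np.percentile(events.values[nb, j], q))
        for j, m in enumerate(events.markers)
    }


def summarize_sample(
    events: EventTable,
    cutoffs: dict[str, float] | float | None = None,
) -> SampleProfile:
    """Full per-sample profile: marker summaries, infiltration, T-cell ratio.

    ``cutoffs`` may be a per-marker mapping, a single fixed gate for all
    markers, or None for the default percentile strategy (99th percentile
    of the sample's normal-B events, per marker).
    """
    if cutoffs is None:
        cutoffs = percentile_cutoffs(events)
    elif np.isscalar(cutoffs):
        cutoffs = {m: float(cutoffs) for m in events.markers}
    profile = SampleProfile(sample_id=events.sample_id)
    for m in events.markers:
        profile.summaries[m] = summarize_marker(events, m, cutoffs[m])
    profile.infiltration_pct = tumor_infiltration(events)
    try:
        profile.cd4_cd8_ratio = cd4_cd8_ratio(events)[0]
    except ValueError:
        profile.cd4_cd8_ratio = None
    n = len(events.population)
    profile.pct_abnormal_of_all_events = (
        100.0 * int(events.population_mask(TUMOR_B).sum()) / n if n else 0.0
    )
    return profile


__all__ = [
    "MarkerSummary",
    "SampleProfile",
    "cd4_cd8_ratio",
    "intensity_class",
    "marker_positive",
    "percentile_cutoffs",
    "summarize_marker",
    "summarize_sample",
    "tumor_infiltration",
]
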