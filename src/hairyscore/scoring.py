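"""The immunologic HCL score and its diagnostic evaluation.

The classical score gives one point each for CD11c, CD25, CD103 and CD123
positivity; a score >= 3 calls HCL.  The CD26-extended 5-marker score adds
one point for CD26; its call threshold is >= 4 of 5 — the unique threshold
consistent with the extended score simultaneously reaching 100% sensitivity
and 100% specificity on the reference cohort (see the threshold-audit test).

Diagnostic evaluation uses evaluable denominators: a patient missing any
constituent marker call is excluded from that variant's confusion matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .cohort import PatientRecord
from .flow import SampleProfile
from .markers import CHCL, SCORE4_MARKERS, SCORE5_MARKERS

SCORE4_CALL_THRESHOLD = 3  # score >= 3 -> HCL
SCORE5_CALL_THRESHOLD = 4  # score >= 4 -> HCL

#: patient-level marker call: True/False, or None when not assayed
Calls = Mapping[str, "bool | None"]


@dataclass
class ScoreResult:
    patient_id: str
    score4: int | None
    score5: int | None
    evaluable4: bool
    evaluable5: bool
    predicted4: str  # HCL | not_HCL | unevaluable
    predicted5: str


@dataclass
class DiagnosticReport:
    variant: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float  # % over evaluable positives, half-up to 1 decimal
    specificity: float  # % over evaluable negatives
    n_excluded_unevaluable: int


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (matches printed-percentage conventions)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def marker_calls(
    source: SampleProfile | Calls,
    patient: PatientRecord | None = None,
) -> dict[str, bool | None]:
    """Patient-level positivity calls for the score markers.

    From a sample profile, a marker's call is its summary positivity, or
    None when the marker was not in the sample's panel.  A patient's
    ``recorded_markers`` (status known from clinical records or another
    sample) fill in markers missing from the panel; they never override an
    assayed call.
    """
    if isinstance(source, SampleProfile):
        calls: dict[str, bool | None] = {
            m: source.positive(m) for m in SCORE5_MARKERS
        }
    else:
        calls = {m: source.get(m) for m in SCORE5_MARKERS}
    if patient is not None:
        for m, status in patient.recorded_markers.items():
            if m in calls and calls[m] is None:
                calls[m] = bool(status)
    return calls


def _score(calls: Calls, markers: tuple[str, ...]) -> tuple[int | None, bool]:
    if any(calls.get(m) is None for m in markers):
        return None, False
    return sum(bool(calls[m]) for m in markers), True


def hcl_score(
    source: SampleProfile | Calls,
    patient: PatientRecord | None = None,
    patient_id: str | None = None,
) -> ScoreResult:
    """Compute both score variants for one patient.

    ``source`` is either a :class:`SampleProfile` or a marker->bool/None
    mapping; missing constituent markers make the variant unevaluable (no
    error).
    """
    calls = marker_calls(source, patient)
    if patient_id is None:
        if patient is not None:
            patient_id = patient.patient_id
        elif isinstance(source, SampleProfile):
            patient_id = source.sample_id
        else:
            patient_id = "?"
    score4, ev4 = _score(calls, SCORE4_MARKERS)
    score5, ev5 = _score(calls, SCORE5_MARKERS)
    predicted4 = (
        "unevaluable"
        if not ev4
        else ("HCL" if score4 >= SCORE4_CALL_THRESHOLD else "not_HCL")
    )
    predicted5 = (
        "unevaluable"
        if not ev5
        else ("HCL" if score5 >= SCORE5_CALL_THRESHOLD else "not_HCL")
    )
    return ScoreResult(patient_id, score4, score5, ev4, ev5, predicted4, predicted5)


def evaluate_score(
    results: Iterable[ScoreResult],
    truth: Mapping[str, str],
    variant: str = "four",
    positive_groups: frozenset[str] | set[str] = frozenset({CHCL}),
) -> DiagnosticReport:
    """Confusion matrix and sensitivity/specificity for one score variant.

    ``truth`` maps patient_id to diagnosis group; patients in
    ``positive_groups`` are the disease-positive class (default: cHCL,
    with vHCL/SDRPL and HCL-like NOS pooled as HCL-like negatives).
    Unevaluable patients are excluded from numerator and denominator.
    """
    if variant not in ("four", "five"):
        raise ValueError(f"unknown score variant {variant!r}")
    tp = fn = tn = fp = excluded = 0
    for r in results:
        predicted = r.predicted4 if variant == "four" else r.predicted5
        if predicted == "unevaluable":
            excluded += 1
            continue
        is_pos = truth[r.patient_id] in positive_groups
        called_hcl = predicted == "HCL"
        if is_pos:
            tp += called_hcl
            fn += not called_hcl
        else:
            fp += called_hcl
            tn += not called_hcl
    if tp + fn == 0:
        raise ValueError("no evaluable disease-positive patients")
    if tn + fp == 0:
        raise ValueError("no evaluable disease-negative patients")
    sens = round_half_up(100.0 * tp / (tp + fn))
    spec = round_half_up(100.0 * tn / (tn + fp))
    return DiagnosticReport(variant, tp, fn, tn, fp, sens, spec, excluded)


def score_distribution(
    results: Iterable[ScoreResult],
    truth: Mapping[str, str],
    groups: set[str] | frozenset[str],
    variant: str = "four",
) -> dict[int, int]:
    """Histogram of scores over the evaluable patients of ``groups``."""
    hist: Counter[int] = Counter()
    for r in results:
        if truth[r.patient_id] not in groups:
            continue
        score = r.score4 if variant == "four" else r.score5
        evaluable = r.evaluable4 if variant == "four" else r.evaluable5
        if evaluable:
            hist[score] += 1
    return dict(hist)


def score_cohort(
    patients: Iterable[PatientRecord],
    profiles: Mapping[str, SampleProfile],
) -> list[ScoreResult]:
    """Score every patient from its reference sample profile.

    ``profiles`` maps patient_id to that patient's reference
    :class:`SampleProfile`; patients without a profile are scored from
    recorded calls alone.
    """
    out = []
    for p in patients:
        profile = profiles.get(p.patient_id)
        source: SampleProfile | Calls = profile if profile is not None else {}
        out.append(hcl_score(source, patient=p))
    return out


__all__ = [
    "DiagnosticReport",
    "SCORE4_CALL_THRESHOLD",
    "SCORE5_CALL_THRESHOLD",
    "ScoreResult",
    "evaluate_score",
    "hcl_score",
    "marker_calls",
    "round_half_up",
    "score_cohort",
    "score_distribution",
]
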