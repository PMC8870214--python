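"""Deterministic 82-patient fixture cohort.

One fixed cohort (68 cHCL, 5 vHCL/SDRPL, 9 HCL-like NOS) whose marker
panel, genotype, light-chain and score marginals reproduce the reference
cohort tallies simultaneously:

* 65 cHCL with 4-marker score 4 and 3 with score 3 (2 lacking CD123,
  1 lacking CD103); all cHCL CD25- and CD11c-positive;
* CD123 positive in 60/62 in-panel cHCL, CD103 in 66/67; six cHCL carry a
  recorded-positive CD123 call outside the reference sample's panel and
  one a recorded-positive CD103 call (their scores are known although the
  marker is absent from the in-panel tallies);
* CD26 in panel for 36 cHCL, 35 positive; the three score-3 cHCL are all
  CD26-positive; every HCL-like patient is CD26-assayed, 13/14 negative;
* 11/14 HCL-like patients score <3 (4/5 vHCL/SDRPL, 7/9 NOS), three score
  exactly 3 and are CD26-negative; exactly one NOS patient is
  CD26-positive with a 4-marker score of 2;
* BRAF-V600E mutated in 46/52 sequenced cHCL, wild type in all HCL-like;
* light chains kappa 47 / lambda 31 / undetectable 4; CD5 7/68,
  CD10 12/68, CD38 24/67, CD23 22/68, CD43 19/65 positive in cHCL;
  CD27 positive in 11/46 cHCL, 2/5 vHCL/SDRPL, 2/7 NOS.

``NOS-002`` is the analogue of the case initially labelled HCL-like NOS
for lack of CD25 but carrying an otherwise cHCL-like marker and genotype
profile; unsupervised reclassification should pull it into the HCL group.

:func:`verify_fixture` recomputes every marginal above from summarised
event data and raises :class:`FixtureError` on any mismatch.
"""

from __future__ import annotations

import math

import numpy as np

from .cohort import (
    Cohort,
    EventTable,
    MarkerCall,
    PatientRecord,
    SampleRecord,
    simulate_events,
)
from .config import CohortConfig, default_config
from .flow import summarize_sample
from .markers import CHCL, GENES, HCL_LIKE_NOS, PANEL, VHCL_SDRPL
from .scoring import score_cohort

_FIXTURE_SEED = 20220218  # constant: fixture must be byte-identical across runs


class FixtureError(AssertionError):
    """Internal consistency failure while building the fixture cohort."""


# intensity classes for positive calls
_CHCL_INTENSITY = {"CD11c": "bright"}
_ALTERNATING = ("CD5", "CD10", "CD23", "CD27", "CD38", "CD43")
_HCLL_INTENSITY = {
    "CD11c": "moderate", "CD103": "dim", "CD123": "dim", "CD25": "dim",
    "CD79b": "dim", "CD27": "dim",
}


def _calls(
    positive: set[str],
    off_panel: set[str],
    intensity: dict[str, str],
    default_class: str = "moderate",
) -> dict[str, MarkerCall]:
    calls: dict[str, MarkerCall] = {}
    for m in PANEL:
        if m in off_panel:
            calls[m] = MarkerCall(False)
        elif m in positive:
            calls[m] = MarkerCall(True, True, intensity.get(m, default_class))
        else:
            calls[m] = MarkerCall(True, False)
    return calls


def _survival(endpoint_medians: dict[str, float], i: int, n: int):
    """Deterministic per-patient endpoint times from exponential quantiles."""
    u = (i + 0.5) / n
    out = {}
    for ep, median in endpoint_medians.items():
        dur = round(-math.log(1.0 - u) * median / math.log(2.0), 2)
        out[ep] = (dur, 0 if i % 5 == 4 else 1)
    return out


def _blood(base: dict[str, tuple[float, float]], i: int) -> dict[str, float]:
    jitter = 0.7 + 0.6 * ((i % 5) / 4.0)
    return {a: round(max(mean * jitter, 0.01), 2) for a, (mean, _) in base.items()}


def _chcl_patient(i: int, config: CohortConfig) -> PatientRecord:
    pos = {"CD19", "CD20", "CD79b", "FMC7", "CD11c", "CD25", "CD103", "CD123", "CD26"}
    off_panel: set[str] = set()
    recorded: dict[str, bool] = {}
    if i in (0, 1):
        pos.discard("CD123")  # the two in-panel CD123-negative cHCL
    if i == 2:
        pos.discard("CD103")  # the single in-panel CD103-negative cHCL
    if 3 <= i <= 8:
        off_panel.add("CD123")  # assayed clinically, not in the reference panel
        recorded["CD123"] = True
    if i == 9:
        off_panel.add("CD103")
        recorded["CD103"] = True
    if i > 35:
        off_panel.add("CD26")
    if i == 10:
        pos.discard("CD26")  # the single CD26-negative tested cHCL (score 4)
    if i == 67:
        off_panel.add("CD38")
    if 11 <= i <= 34:
        pos.add("CD38")
    if i > 64:
        off_panel.add("CD43")
    if 11 <= i <= 29:
        pos.add("CD43")
    if i > 45:
        off_panel.add("CD27")
    if 20 <= i <= 30:
        pos.add("CD27")
    if 30 <= i <= 51:
        pos.add("CD23")
    if 40 <= i <= 46:
        pos.add("CD5")
    if 45 <= i <= 56:
        pos.add("CD10")
    intensity = dict(_CHCL_INTENSITY)
    klass = "dim" if i % 2 == 0 else "bright"
    for m in _ALTERNATING:
        intensity[m] = klass
    braf_wt = {20, 21, 48, 49, 50, 51}
    if i <= 51:
        genotype = {
            "BRAF_V600E": "wild_type" if i in braf_wt else "mutated",
            "MAP2K1": "mutated" if i in (48, 49) else "wild_type",
            "KLF2": "wild_type",
        }
    else:
        genotype = {g: "untested" for g in GENES}
    light = "kappa" if i < 40 else ("lambda" if i < 65 else "undetectable")
    medians = {
        ep: config.survival_params[f"{ep}:{CHCL}"][0] for ep in ("ttnt", "pfs", "os")
    }
    return PatientRecord(
        patient_id=f"HCL-{i + 1:03d}",
        group=CHCL,
        sex="M" if i < 53 else "F",
        age_years=round(32 + (i * 55.0) / 67, 1),
        light_chain=light,
        genotype=genotype,
        ighv4_34="yes" if i in (48, 49) else ("no" if i <= 51 else "untested"),
        blood_counts=_blood(config.blood_count_params[CHCL], i),
        cd4_cd8_ratio=(2.5, 1.2, 3.1, 0.9, 2.3, 1.6, 4.0)[i % 7],
        survival=_survival(medians, i, 68),
        marker_truth=_calls(pos, off_panel, intensity),
        recorded_markers=recorded,
    )


_VHCL_SCORE = (
    # (positive score markers, CD27, CD79b)
    ({"CD11c", "CD103", "CD25"}, False, True),   # score 3, CD123-negative
    ({"CD11c", "CD123"}, True, True),            # score 2
    ({"CD11c", "CD103"}, True, True),            # score 2
    ({"CD11c", "CD103"}, False, False),          # score 2
    ({"CD11c", "CD103"}, False, False),          # score 2
)

_NOS_SCORE = (
    ({"CD11c", "CD25", "CD123"}, False, True),   # score 3, CD103-negative
    ({"CD11c", "CD103", "CD123"}, False, True),  # score 3, CD25-negative (NOS-002)
    ({"CD11c", "CD25", "CD26"}, False, True),    # score 2, the CD26-positive NOS
    ({"CD11c", "CD103"}, True, True),            # score 2
    ({"CD11c", "CD103"}, True, True),            # score 2
    ({"CD11c"}, False, True),                    # score 1
    ({"CD11c"}, False, True),                    # score 1
    ({"CD11c"}, False, False),                   # score 1
    ({"CD11c"}, False, False),                   # score 1
)


def _hcl_like_patient(group: str, j: int, config: CohortConfig) -> PatientRecord:
    table = _VHCL_SCORE if group == VHCL_SDRPL else _NOS_SCORE
    score_pos, cd27, cd79b = table[j]
    pos = {"CD19", "CD20", "FMC7"} | score_pos
    if cd27:
        pos.add("CD27")
    if cd79b:
        pos.add("CD79b")
    off_panel: set[str] = set()
    if group == HCL_LIKE_NOS and j >= 7:
        off_panel.add("CD27")  # CD27 assayed in 7 of 9 NOS
    intensity = dict(_HCLL_INTENSITY)
    genotype = {g: "wild_type" for g in GENES}
    ighv = "no"
    if group == VHCL_SDRPL:
        pid = f"VAR-{j + 1:03d}"
        if j in (0, 1):
            genotype["MAP2K1"] = "mutated"
        if j == 2:
            genotype["KLF2"] = "mutated"
        light = "kappa" if j < 3 else "lambda"
        sex = "M" if j < 4 else "F"
    else:
        pid = f"NOS-{j + 1:03d}"
        if j == 1:
            # NOS-002: cHCL-like expression intensity and genotype
            intensity = dict(intensity, CD11c="bright", CD103="moderate",
                             CD123="moderate")
        if j in (5, 6):
            genotype["MAP2K1"] = "mutated"
            ighv = "yes"
        if j == 7:
            genotype["KLF2"] = "mutated"
        light = "kappa" if j < 4 else ("lambda" if j < 8 else "undetectable")
        sex = "M" if j < 6 else "F"
    medians = {
        ep: config.survival_params[f"{ep}:{group}"][0] for ep in ("ttnt", "pfs", "os")
    }
    n_group = len(table)
    return PatientRecord(
        patient_id=pid,
        group=group,
        sex=sex,
        age_years=round(45 + 6.0 * j, 1),
        light_chain=light,
        genotype=genotype,
        ighv4_34=ighv,
        blood_counts=_blood(config.blood_count_params[group], j),
        cd4_cd8_ratio=(1.5, 2.4, 1.1, 2.2, 1.8)[j % 5],
        survival=_survival(medians, j, n_group),
        marker_truth=_calls(pos, off_panel, intensity),
    )


def _fixture_infiltration(patient: PatientRecord, index: int) -> float:
    if patient.group == CHCL:
        # eight high-infiltration cHCL echo the gray-zone contrast
        return 55.0 + 3.0 * (index % 8) if index < 8 else 8.0 + (index % 30)
    if patient.patient_id == "NOS-002":
        return 42.0
    return 18.0 + 4.0 * (index % 6)


def build_fixture_cohort(
    config: CohortConfig | None = None, verify: bool = True
) -> Cohort:
    """Build the deterministic fixture cohort (patients, samples, events).

    Event tables are simulated from the fixed per-patient marker calls with
    a constant seed, so repeated builds are identical.  With
    ``verify=True`` every marginal in the module docstring is re-derived
    from the summarised event data and checked.
    """
    config = config or default_config()
    patients = [_chcl_patient(i, config) for i in range(68)]
    patients += [_hcl_like_patient(VHCL_SDRPL, j, config) for j in range(5)]
    patients += [_hcl_like_patient(HCL_LIKE_NOS, j, config) for j in range(9)]
    samples: list[SampleRecord] = []
    events: list[EventTable] = []
    for idx, p in enumerate(patients):
        device = (
            "FACSCalibur"
            if p.group == CHCL and 3 <= idx <= 8
            else "FACSCANTO-II"
        )
        sid = f"S-{p.patient_id}"
        samples.append(
            SampleRecord(
                sample_id=sid,
                patient_id=p.patient_id,
                tissue="blood" if idx % 3 else "marrow",
                timepoint="relapse" if idx % 4 == 1 else "diagnosis",
                device=device,
            )
        )
        rng = np.random.default_rng([_FIXTURE_SEED, idx])
        group_idx = idx if p.group == CHCL else idx - (68 if p.group == VHCL_SDRPL else 73)
        infiltration = _fixture_infiltration(p, group_idx)
        events.append(
            simulate_events(
                sid, p.marker_truth, config, infiltration, p.cd4_cd8_ratio, rng
            )
        )
    if verify:
        verify_fixture(patients, samples, events)
    return patients, samples, events


# ---------------------------------------------------------------------------
# marginal verification


def _check(report: dict, key: str, observed, expected) -> None:
    report[key] = observed
    if observed != expected:
        raise FixtureError(f"fixture marginal {key}: observed {observed}, "
                           f"expected {expected}")


def verify_fixture(patients, samples, events) -> dict:
    """Recompute all fixture marginals from event data; raise on mismatch.

    Returns the tally report, including both readings of the HCL-like
    low-score share (11 of the 14 computable HCL-like patients; the
    14-denominator reading is the one consistent with a specificity of
    78.6%).
    """
    report: dict = {}
    profiles = {}
    pid_of = {s.sample_id: s.patient_id for s in samples}
    for ev in events:
        profiles[pid_of[ev.sample_id]] = summarize_sample(ev)
    by_group: dict[str, list[PatientRecord]] = {}
    for p in patients:
        by_group.setdefault(p.group, []).append(p)
    _check(report, "group_sizes",
           {g: len(v) for g, v in sorted(by_group.items())},
           {CHCL: 68, HCL_LIKE_NOS: 9, VHCL_SDRPL: 5})

    def tally(group: str, marker: str) -> tuple[int, int]:
        pos = tested = 0
        for p in by_group[group]:
            s = profiles[p.patient_id].summaries.get(marker)
            if s is None:
                continue
            tested += 1
            pos += s.percent_positive >= 20.0
        return pos, tested

    for marker, expected in {
        "CD25": (68, 68), "CD11c": (68, 68), "CD123": (60, 62),
        "CD103": (66, 67), "CD26": (35, 36), "CD38": (24, 67),
        "CD43": (19, 65), "CD27": (11, 46), "CD23": (22, 68),
        "CD5": (7, 68), "CD10": (12, 68),
    }.items():
        _check(report, f"cHCL.{marker}", tally(CHCL, marker), expected)
    _check(report, "vHCL_SDRPL.CD25", tally(VHCL_SDRPL, "CD25"), (1, 5))
    _check(report, "vHCL_SDRPL.CD123", tally(VHCL_SDRPL, "CD123"), (1, 5))
    _check(report, "vHCL_SDRPL.CD103", tally(VHCL_SDRPL, "CD103"), (4, 5))
    _check(report, "vHCL_SDRPL.CD27", tally(VHCL_SDRPL, "CD27"), (2, 5))
    _check(report, "HCL_like_NOS.CD25", tally(HCL_LIKE_NOS, "CD25"), (2, 9))
    _check(report, "HCL_like_NOS.CD123", tally(HCL_LIKE_NOS, "CD123"), (2, 9))
    _check(report, "HCL_like_NOS.CD103", tally(HCL_LIKE_NOS, "CD103"), (3, 9))
    _check(report, "HCL_like_NOS.CD27", tally(HCL_LIKE_NOS, "CD27"), (2, 7))
    _check(report, "HCL_like_NOS.CD26", tally(HCL_LIKE_NOS, "CD26"), (1, 9))
    _check(report, "vHCL_SDRPL.CD26", tally(VHCL_SDRPL, "CD26"), (0, 5))

    # scores (profile calls plus recorded out-of-panel calls)
    results = score_cohort(patients, profiles)
    score4_chcl: dict[int, int] = {}
    for p, r in zip(patients, results):
        if p.group == CHCL:
            if not r.evaluable4:
                raise FixtureError(f"{p.patient_id}: cHCL score must be evaluable")
            score4_chcl[r.score4] = score4_chcl.get(r.score4, 0) + 1
    _check(report, "cHCL.score4", score4_chcl, {4: 65, 3: 3})
    hcl_like = [r for p, r in zip(patients, results) if p.group != CHCL]
    _check(report, "HCL_like.evaluable5", sum(r.evaluable5 for r in hcl_like), 14)
    lt3 = sum(r.score4 < 3 for r in hcl_like)
    eq3 = [r for r in hcl_like if r.score4 == 3]
    _check(report, "HCL_like.score4_lt3", lt3, 11)
    _check(report, "HCL_like.score4_eq3", len(eq3), 3)
    report["HCL_like.low_score_share"] = round(100.0 * lt3 / len(hcl_like), 1)
    for r in eq3:
        if r.score5 != 3:
            raise FixtureError(f"{r.patient_id}: score-3 HCL-like must be CD26-negative")
    cd26_pos_nos = [
        p.patient_id
        for p, r in zip(patients, results)
        if p.group == HCL_LIKE_NOS
        and profiles[p.patient_id].positive("CD26")
    ]
    _check(report, "NOS.cd26_positive", len(cd26_pos_nos), 1)
    only = next(r for r in results if r.patient_id == cd26_pos_nos[0])
    if only.score4 > 2:
        raise FixtureError("the CD26-positive NOS patient must have score <= 2")

    # genotypes and light chains
    braf = [p.genotype["BRAF_V600E"] for p in by_group[CHCL]]
    _check(report, "cHCL.BRAF", (braf.count("mutated"), braf.count("wild_type"),
                                 braf.count("untested")), (46, 6, 16))
    for g in (VHCL_SDRPL, HCL_LIKE_NOS):
        if any(p.genotype["BRAF_V600E"] == "mutated" for p in by_group[g]):
            raise FixtureError("BRAF must be wild type in all HCL-like patients")
    chains = [p.light_chain for p in patients]
    _check(report, "light_chains",
           (chains.count("kappa"), chains.count("lambda"),
            chains.count("undetectable")), (47, 31, 4))
    sexes = [p.sex for p in patients]
    _check(report, "sex", (sexes.count("M"), sexes.count("F")), (63, 19))
    return report


__all__ = ["FixtureError", "build_fixture_cohort", "verify_fixture"]
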