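"""Synthetic cohort generation.

Generates per-patient clinical/genotype records, per-sample metadata and
event-level cytometry tables with the statistical structure the downstream
analysis assumes: per-group marker positivity rates, intensity classes
realised as log-normal fluorescence mixtures, assay missingness, blood
counts and exponential survival times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import CohortConfig
from .markers import (
    GENES,
    GROUPS,
    NORMAL_B,
    OTHER,
    PANEL,
    POPULATIONS,
    T4,
    T8,
    TUMOR_B,
)

ENDPOINTS = ("ttnt", "pfs", "os")


@dataclass
class MarkerCall:
    """Generator ground truth for one (patient, marker)."""

    tested: bool
    positive: bool | None = None  # None when untested
    intensity: str | None = None  # class drawn for a positive call

    def as_token(self) -> str:
        if not self.tested:
            return "untested"
        if not self.positive:
            return "neg"
        return f"pos:{self.intensity}"

    @classmethod
    def from_token(cls, token: str) -> "MarkerCall":
        if token == "untested":
            return cls(False)
        if token == "neg":
            return cls(True, False)
        if token.startswith("pos:"):
            return cls(True, True, token.split(":", 1)[1])
        raise ValueError(f"bad marker call token {token!r}")


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    sex: str
    age_years: float
    light_chain: str  # kappa | lambda | undetectable
    genotype: dict[str, str]  # gene -> mutated | wild_type | untested
    ighv4_34: str  # yes | no | untested
    blood_counts: dict[str, float]
    cd4_cd8_ratio: float | None
    survival: dict[str, tuple[float, int]]  # endpoint -> (months, event flag)
    marker_truth: dict[str, MarkerCall] = field(default_factory=dict)
    #: score-marker status known from clinical records for markers absent
    #: from the reference sample's panel
    recorded_markers: dict[str, bool] = field(default_factory=dict)
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ep, (dur, ev) in self.survival.items():
            if dur < 0:
                raise ValueError(f"{self.patient_id}: negative {ep} duration")
            if ev not in (0, 1):
                raise ValueError(f"{self.patient_id}: {ep} event flag not 0/1")
        for gene, status in self.genotype.items():
            if status not in ("mutated", "wild_type", "untested"):
                raise ValueError(f"{self.patient_id}: bad genotype {status!r}")


@dataclass
class SampleRecord:
    sample_id: str
    patient_id: str
    tissue: str  # blood | marrow | spleen
    timepoint: str  # diagnosis | relapse
    device: str


@dataclass
class EventTable:
    """Per-cell fluorescence for one sample.

    ``values`` is events x markers (arbitrary fluorescence units, >= 0);
    ``population`` labels each event as tumor_B / normal_B / T4 / T8 / other.
    Markers absent from this sample's panel are simply absent from
    ``markers``.
    """

    sample_id: str
    markers: list[str]
    values: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.population = np.asarray(self.population)
        if self.values.shape != (len(self.population), len(self.markers)):
            raise ValueError("event matrix shape does not match labels/markers")
        if (self.values < 0).any():
            raise ValueError("fluorescence values must be nonnegative")

    def column(self, marker: str) -> np.ndarray:
        try:
            j = self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in sample {self.sample_id}")
        return self.values[:, j]

    def population_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.population, labels)


Cohort = tuple[list[PatientRecord], list[SampleRecord], list[EventTable]]


# ---------------------------------------------------------------------------
# event-level simulation


def _population_counts(
    n_events: int, infiltration_pct: float, cd4_cd8_ratio: float
) -> dict[str, int]:
    """Split ``n_events`` into populations.

    70% of events are lymphocytes; tumour cells make up ``infiltration_pct``
    of the lymphocytes; the residual lymphocytes are 30% normal B cells and
    70% T cells split by the CD4/CD8 ratio.  Every population keeps at least
    one event so downstream ratios stay defined.
    """
    n_lymph = int(round(0.7 * n_events))
    n_tumor = int(round(infiltration_pct / 100.0 * n_lymph))
    n_tumor = min(max(n_tumor, 1), n_lymph - 3)
    rest = n_lymph - n_tumor
    n_nb = max(int(round(0.3 * rest)), 1)
    n_t = rest - n_nb
    n_t8 = max(int(round(n_t / (1.0 + cd4_cd8_ratio))), 1)
    n_t4 = max(n_t - n_t8, 1)
    n_other = n_events - (n_tumor + n_nb + n_t4 + n_t8)
    return {TUMOR_B: n_tumor, NORMAL_B: n_nb, T4: n_t4, T8: n_t8, OTHER: n_other}


def simulate_events(
    sample_id: str,
    marker_calls: dict[str, MarkerCall],
    config: CohortConfig,
    infiltration_pct: float,
    cd4_cd8_ratio: float,
    rng: np.random.Generator,
) -> EventTable:
    """Draw an event table realising the given per-marker calls.

    Tumour events for a positive call are a two-component log-normal
    mixture: ``positive_event_fraction`` of events from the call's
    intensity class, the remainder from the negative component.  All
    non-tumour populations draw from the negative component for every
    marker (the internal-negative convention used by the percentile gate).
    """
    counts = _population_counts(
        config.events_per_sample, infiltration_pct, cd4_cd8_ratio
    )
    population = np.concatenate(
        [np.repeat(pop, counts[pop]) for pop in POPULATIONS]
    )
    markers = [m for m in PANEL if m in marker_calls and marker_calls[m].tested]
    n = len(population)
    values = np.empty((n, len(markers)))
    mu_neg, sd_neg = config.mfi_class_params["negative"]
    tumor = population == TUMOR_B
    n_tumor = int(tumor.sum())
    for j, m in enumerate(markers):
        call = marker_calls[m]
        values[:, j] = rng.lognormal(mu_neg, sd_neg, size=n)
        if call.positive:
            frac = config.positive_event_fraction
            klass = call.intensity or "moderate"
        else:
            frac = config.negative_event_leak
            klass = "dim"
        k = int(round(frac * n_tumor))
        if k > 0:
            mu, sd = config.mfi_class_params[klass]
            pos_idx = np.flatnonzero(tumor)[rng.permutation(n_tumor)[:k]]
            values[pos_idx, j] = rng.lognormal(mu, sd, size=k)
    return EventTable(sample_id, markers, values, population)


# ---------------------------------------------------------------------------
# survival times


def generate_survival(
    stratum: str,
    n: int,
    config: CohortConfig,
    seed: int | np.random.Generator,
) -> list[tuple[float, int]]:
    """Exponential event times for one survival stratum.

    The event-time distribution is exponential with the stratum's
    configured median (rate = ln 2 / median).  Censoring is independent
    exponential, with its rate chosen so the probability of being censored
    equals the configured censoring probability; the observed duration is
    the minimum of the two times.
    """
    if stratum not in config.survival_params:
        raise KeyError(f"unknown survival stratum {stratum!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    median, p_cens = config.survival_params[stratum]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scale_t = median / math.log(2.0)
    t = rng.exponential(scale_t, size=n)
    if p_cens <= 0.0:
        return [(float(ti), 1) for ti in t]
    # P(C < T) = p_cens  for independent exponentials
    scale_c = scale_t * (1.0 - p_cens) / p_cens
    c = rng.exponential(scale_c, size=n)
    dur = np.minimum(t, c)
    event = (t <= c).astype(int)
    return list(zip(dur.tolist(), event.tolist()))


# ---------------------------------------------------------------------------
# cohort generation


def _draw_choice(rng, options, probs):
    return options[rng.choice(len(options), p=probs)]


def generate_cohort(config: CohortConfig, with_events: bool = True) -> Cohort:
    """Draw a full stochastic cohort.

    Reproducible: identical ``(config, seed)`` give identical output.  With
    ``with_events=False`` only patient and sample records are produced
    (useful for large calibration runs where event tables are not needed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    samples: list[SampleRecord] = []
    events: list[EventTable] = []
    for group in GROUPS:
        size = config.group_sizes.get(group, 0)
        for i in range(size):
            pid = f"{group}-{i + 1:03d}"
            sex = "M" if rng.random() < 63 / 82 else "F"
            age = float(np.clip(rng.normal(59.6, 13.0), 30.0, 95.0))
            light_chain = _draw_choice(
                rng,
                ("kappa", "lambda", "undetectable"),
                (47 / 82, 31 / 82, 4 / 82),
            )
            genotype = {}
            for gene in GENES:
                tested = rng.random() < config.tested_fractions.get((group, gene), 1.0)
                if not tested:
                    genotype[gene] = "untested"
                else:
                    p = config.genotype_probs[group][gene]
                    genotype[gene] = "mutated" if rng.random() < p else "wild_type"
            ighv = (
                "untested"
                if rng.random() < 0.4
                else ("yes" if rng.random() < 0.15 else "no")
            )
            blood = {
                analyte: float(max(rng.normal(mean, sd), 0.01))
                for analyte, (mean, sd) in config.blood_count_params[group].items()
            }
            cd4_cd8 = float(rng.lognormal(math.log(1.8), 0.5))
            survival = {
                ep: generate_survival(f"{ep}:{group}", 1, config, rng)[0]
                for ep in ENDPOINTS
            }
            marker_truth = {}
            for m in PANEL:
                tested = rng.random() < config.tested_fractions.get((group, m), 1.0)
                if not tested:
                    marker_truth[m] = MarkerCall(False)
                    continue
                positive = rng.random() < config.marker_positivity[group][m]
                intensity = None
                if positive:
                    dist = config.intensity_profile[group][m]
                    classes = sorted(dist)
                    intensity = _draw_choice(
                        rng, classes, [dist[c] for c in classes]
                    )
                marker_truth[m] = MarkerCall(True, positive, intensity)
            mean_inf, sd_inf = config.infiltration_params[group]
            infiltration = float(np.clip(rng.normal(mean_inf, sd_inf), 2.0, 95.0))
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    group=group,
                    sex=sex,
                    age_years=round(age, 1),
                    light_chain=light_chain,
                    genotype=genotype,
                    ighv4_34=ighv,
                    blood_counts={k: round(v, 2) for k, v in blood.items()},
                    cd4_cd8_ratio=round(cd4_cd8, 2),
                    survival={
                        ep: (round(d, 2), e) for ep, (d, e) in survival.items()
                    },
                    marker_truth=marker_truth,
                )
            )
            sid = f"S-{pid}"
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    patient_id=pid,
                    tissue="blood" if rng.random() < 0.65 else "marrow",
                    timepoint="diagnosis" if rng.random() < 55 / 102 else "relapse",
                    device="FACSCANTO-II" if rng.random() < 86 / 102 else "FACSCalibur",
                )
            )
            if with_events:
                events.append(
                    simulate_events(
                        sid, marker_truth, config, infiltration, cd4_cd8, rng
                    )
                )
    return patients, samples, events


__all__ = [
    "Cohort",
    "ENDPOINTS",
    "EventTable",
    "MarkerCall",
    "PatientRecord",
    "SampleRecord",
    "generate_cohort",
    "generate_survival",
    "simulate_events",
]
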