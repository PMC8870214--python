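"""Tabular I/O: CSV schemas for patients, samples, events, profiles and
scores, plus the per-run manifest.

All files are UTF-8 CSV with a header row and dot decimals.  Untested
assays are written as explicit tokens ("untested", empty cells), never
imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    ENDPOINTS,
    EventTable,
    MarkerCall,
    PatientRecord,
    SampleRecord,
)
from .flow import MarkerSummary, SampleProfile
from .markers import GENES, PANEL
from .scoring import ScoreResult

_BLOOD_ANALYTES = ("ALC", "AMC", "ANC", "PC", "Hb")


class SchemaError(ValueError):
    """Malformed tabular input."""


# ---------------------------------------------------------------------------
# patients


def write_patients(patients: list[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "group": p.group,
            "sex": p.sex,
            "age_years": p.age_years,
            "light_chain": p.light_chain,
            "ighv4_34": p.ighv4_34,
            "cd4_cd8_ratio": "" if p.cd4_cd8_ratio is None else p.cd4_cd8_ratio,
        }
        for gene in GENES:
            row[f"genotype_{gene}"] = p.genotype.get(gene, "untested")
        for a in _BLOOD_ANALYTES:
            row[f"blood_{a}"] = p.blood_counts.get(a, "")
        for ep in ENDPOINTS:
            dur, ev = p.survival.get(ep, ("", ""))
            row[f"{ep}_months"], row[f"{ep}_event"] = dur, ev
        for m in PANEL:
            call = p.marker_truth.get(m)
            row[f"marker_{m}"] = call.as_token() if call else "untested"
        for m, status in p.recorded_markers.items():
            row[f"recorded_{m}"] = "pos" if status else "neg"
        row.update(p.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_patients(path) -> list[PatientRecord]:
    """Read patients.csv into typed records.

    Unknown columns are preserved in ``extras``; duplicate patient ids and
    malformed rows raise :class:`SchemaError` with the offending line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "group", "sex", "age_years", "light_chain"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate patient_id {dup!r}")
    known_prefixes = ("genotype_", "blood_", "marker_", "recorded_")
    known = required | {"ighv4_34", "cd4_cd8_ratio"} | {
        f"{ep}_{k}" for ep in ENDPOINTS for k in ("months", "event")
    }
    patients = []
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        try:
            genotype = {
                g: (row.get(f"genotype_{g}") or "untested") for g in GENES
            }
            blood = {
                a: float(row[f"blood_{a}"])
                for a in _BLOOD_ANALYTES
                if row.get(f"blood_{a}", "") != ""
            }
            survival = {}
            for ep in ENDPOINTS:
                dur = row.get(f"{ep}_months", "")
                if dur != "":
                    survival[ep] = (float(dur), int(row[f"{ep}_event"]))
            truth = {}
            for m in PANEL:
                token = row.get(f"marker_{m}", "")
                if token:
                    truth[m] = MarkerCall.from_token(token)
            recorded = {
                c.removeprefix("recorded_"): row[c] == "pos"
                for c in df.columns
                if c.startswith("recorded_") and row[c] != ""
            }
            ratio = row.get("cd4_cd8_ratio", "")
            extras = {
                c: row[c]
                for c in df.columns
                if c not in known and not c.startswith(known_prefixes)
            }
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    group=row["group"],
                    sex=row["sex"],
                    age_years=float(row["age_years"]),
                    light_chain=row["light_chain"],
                    genotype=genotype,
                    ighv4_34=row.get("ighv4_34") or "untested",
                    blood_counts=blood,
                    cd4_cd8_ratio=None if ratio == "" else float(ratio),
                    survival=survival,
                    marker_truth=truth,
                    recorded_markers=recorded,
                    extras=extras,
                )
            )
        except (ValueError, KeyError) as err:
            raise SchemaError(f"{path}: malformed row at line {lineno}: {err}") from err
    return patients


# ---------------------------------------------------------------------------
# samples and events


def write_samples(samples: list[SampleRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_samples(path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [SampleRecord(**row) for row in df.to_dict("records")]


def write_events(events: list[EventTable], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ev in events:
        df = pd.DataFrame(ev.values, columns=ev.markers)
        df.insert(0, "population", ev.population)
        df.to_csv(out_dir / f"{ev.sample_id}.csv", index=False,
                  encoding="utf-8", float_format="%.4f")


def read_events(path) -> EventTable:
    path = Path(path)
    df = pd.read_csv(path)
    if "population" not in df.columns:
        raise SchemaError(f"{path}: missing 'population' column")
    markers = [c for c in df.columns if c != "population"]
    return EventTable(
        sample_id=path.stem,
        markers=markers,
        values=df[markers].to_numpy(dtype=float),
        population=df["population"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# profiles and scores


def write_profiles(profiles: dict[str, SampleProfile], path) -> None:
    """One row per sample x marker, with per-sample columns repeated."""
    rows = []
    for sid, prof in profiles.items():
        for m, s in prof.summaries.items():
            rows.append(
                {
                    "sample_id": sid,
                    "marker": m,
                    "percent_positive": round(s.percent_positive, 4),
                    "mfi": round(s.mfi, 4),
                    "n_events": s.n_events,
                    "intensity_class": s.intensity_class,
                    "infiltration_pct": round(prof.infiltration_pct, 4),
                    "cd4_cd8_ratio": (
                        "" if prof.cd4_cd8_ratio is None
                        else round(prof.cd4_cd8_ratio, 4)
                    ),
                    "pct_abnormal_of_all_events": round(
                        prof.pct_abnormal_of_all_events, 4
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_profiles(path) -> dict[str, SampleProfile]:
    df = pd.read_csv(path, keep_default_na=False)
    profiles: dict[str, SampleProfile] = {}
    for row in df.to_dict("records"):
        sid = row["sample_id"]
        prof = profiles.setdefault(sid, SampleProfile(sample_id=sid))
        prof.summaries[row["marker"]] = MarkerSummary(
            marker=row["marker"],
            percent_positive=float(row["percent_positive"]),
            mfi=float(row["mfi"]),
            n_events=int(row["n_events"]),
            intensity_class=row["intensity_class"],
        )
        prof.infiltration_pct = float(row["infiltration_pct"])
        ratio = row["cd4_cd8_ratio"]
        prof.cd4_cd8_ratio = None if ratio == "" else float(ratio)
        prof.pct_abnormal_of_all_events = float(row["pct_abnormal_of_all_events"])
    return profiles


def write_scores(results: list[ScoreResult], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        path, index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# run manifest


def config_hash(config) -> str:
    data = dataclasses.asdict(config)
    data.pop("provenance", None)
    data["tested_fractions"] = {
        f"{g}:{assay}": v for (g, assay), v in data["tested_fractions"].items()
    }
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir,
    command: str,
    seed: int | None,
    cfg_hash: str,
    inputs: list[str],
    outputs: list[str],
) -> Path:
    manifest = {
        "command": command,
        "config_hash": cfg_hash,
        "seed": seed,
        "inputs": sorted(map(str, inputs)),
        "outputs": sorted(map(str, outputs)),
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


__all__ = [
    "SchemaError",
    "config_hash",
    "read_events",
    "read_patients",
    "read_profiles",
    "read_samples",
    "write_events",
    "write_manifest",
    "write_patients",
    "write_profiles",
    "write_samples",
    "write_scores",
]
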