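"""CSV schemas, validated readers/writers for cohort tables.

Dialect: comma-separated, UTF-8, "." decimal separator, blank = missing,
header row required. Readers collect every row-level problem and raise one
:class:`SchemaError` naming all offending rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .echo import EchoAssessment
from .scoring import (
    ITEM_NAMES,
    SCHEDULE_HOURS,
    InfantRecord,
    ScoreBreakdown,
    TimepointObservation,
    VentMode,
)

__all__ = [
    "SchemaError",
    "read_infants",
    "read_observations",
    "read_echo",
    "read_labels",
    "read_cohort",
    "write_scores",
    "read_scores",
    "SCORES_COLUMNS",
]


class SchemaError(ValueError):
    """Input CSV violates the schema; message lists every offending row."""


INFANTS_COLUMNS = [
    "infant_id", "gestational_age_weeks", "birth_weight_g", "chorioamnionitis",
    "antenatal_steroid_complete", "cord_base_deficit_mmol_l", "fio2_admission_pct",
]
OBSERVATIONS_COLUMNS = [
    "infant_id", "hour", "heart_rate_bpm", "hypotension_inotropes", "vent_mode",
    "pip_cmh2o", "fio2_pct", "ph", "base_deficit_mmol_l", "pco2_mmhg",
    "surfactant_doses_cum",
]
ECHO_COLUMNS = ["infant_id", "hour", "la_ao", "duct_diameter_mm", "weight_kg"]
LABELS_COLUMNS = ["infant_id", "label"]

#: Fixed column order of scores.csv.
SCORES_COLUMNS = ["infant_id", "hour", *ITEM_NAMES, "total", "flags"]


def _load(path, required: Sequence[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name}: file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")
    return df


def _raise_if(errors: list[str], name: str) -> None:
    if errors:
        msg = "\n  ".join(errors[:50])
        more = f"\n  ... and {len(errors) - 50} more" if len(errors) > 50 else ""
        raise SchemaError(f"{name}: {len(errors)} invalid row(s):\n  {msg}{more}")


def _opt(value):
    return None if pd.isna(value) else value


def read_infants(path) -> list[InfantRecord]:
    df = _load(path, INFANTS_COLUMNS, "infants.csv")
    errors, records = [], []
    seen = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            iid = str(row["infant_id"])
            if iid in seen:
                raise ValueError(f"duplicate infant_id {iid!r}")
            seen.add(iid)
            records.append(InfantRecord(
                infant_id=iid,
                gestational_age=float(row["gestational_age_weeks"]),
                birth_weight=float(row["birth_weight_g"]),
                chorioamnionitis=bool(int(row["chorioamnionitis"])),
                antenatal_steroid_complete=bool(int(row["antenatal_steroid_complete"])),
                cord_base_deficit=float(row["cord_base_deficit_mmol_l"]),
                fio2_admission=float(row["fio2_admission_pct"]),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    _raise_if(errors, "infants.csv")
    return records


def read_observations(path) -> list[TimepointObservation]:
    df = _load(path, OBSERVATIONS_COLUMNS, "observations.csv")
    errors, out = [], []
    seen = set()
    for i, row in df.iterrows():
        line = i + 2
        try:
            iid = str(row["infant_id"])
            hour = int(row["hour"])
            if (iid, hour) in seen:
                raise ValueError(f"duplicate (infant_id, hour) = ({iid!r}, {hour})")
            seen.add((iid, hour))
            mode_raw = row["vent_mode"]
            try:
                mode = VentMode(str(mode_raw).strip().lower())
            except ValueError:
                raise ValueError(f"unknown vent_mode {mode_raw!r}")
            hypo = _opt(row["hypotension_inotropes"])
            surf = _opt(row["surfactant_doses_cum"])
            out.append(TimepointObservation(
                infant_id=iid,
                hour=hour,
                heart_rate=_opt(row["heart_rate_bpm"]),
                hypotension_inotropes=None if hypo is None else bool(int(hypo)),
                vent_mode=mode,
                pip=_opt(row["pip_cmh2o"]),
                fio2=_opt(row["fio2_pct"]),
                ph=_opt(row["ph"]),
                base_deficit=_opt(row["base_deficit_mmol_l"]),
                pco2=_opt(row["pco2_mmhg"]),
                surfactant_doses=None if surf is None else int(surf),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    _raise_if(errors, "observations.csv")
    return out


def read_echo(path) -> list[EchoAssessment]:
    df = _load(path, ECHO_COLUMNS, "echo.csv")
    errors, out = [], []
    for i, row in df.iterrows():
        line = i + 2
        try:
            out.append(EchoAssessment(
                infant_id=str(row["infant_id"]),
                hour=int(row["hour"]),
                la_ao=float(row["la_ao"]),
                duct_diameter=float(row["duct_diameter_mm"]),
                weight=float(row["weight_kg"]),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    _raise_if(errors, "echo.csv")
    return out


def read_labels(path) -> dict[str, str]:
    df = _load(path, LABELS_COLUMNS, "labels.csv")
    errors = []
    labels: dict[str, str] = {}
    for i, row in df.iterrows():
        line = i + 2
        iid, lab = str(row["infant_id"]), str(row["label"]).strip().lower()
        if lab not in ("case", "control"):
            errors.append(f"line {line}: label must be 'case' or 'control', got {row['label']!r}")
        elif iid in labels:
            errors.append(f"line {line}: duplicate infant_id {iid!r}")
        else:
            labels[iid] = lab
    _raise_if(errors, "labels.csv")
    return labels


def read_cohort(infants_path, observations_path, echo_path=None, labels_path=None):
    """Read and cross-validate the cohort tables.

    Returns ``(infants, observations, echoes, labels)``; echo and labels are
    ``None`` when their paths are not given. Observations referencing unknown
    infants are a schema error.
    """
    infants = read_infants(infants_path)
    observations = read_observations(observations_path)
    known = {r.infant_id for r in infants}
    orphans = sorted({o.infant_id for o in observations} - known)
    if orphans:
        raise SchemaError(f"observations.csv references unknown infants: {orphans}")
    echoes = read_echo(echo_path) if echo_path is not None else None
    labels = read_labels(labels_path) if labels_path is not None else None
    return infants, observations, echoes, labels


def write_scores(breakdowns: Sequence[ScoreBreakdown], path) -> pd.DataFrame:
    """Write scores.csv (fixed column order) and return the frame."""
    rows = []
    for b in breakdowns:
        row = {"infant_id": b.infant_id, "hour": b.hour}
        row.update(b.item_points)
        row["total"] = b.total
        row["flags"] = ";".join(b.flags)
        rows.append(row)
    df = pd.DataFrame(rows, columns=SCORES_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_scores(path) -> pd.DataFrame:
    df = _load(path, ["infant_id", "hour", "total"], "scores.csv")
    bad = df[~df["hour"].isin(SCHEDULE_HOURS)]
    if len(bad):
        raise SchemaError(f"scores.csv: invalid hours {sorted(bad['hour'].unique())}")
    return df
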