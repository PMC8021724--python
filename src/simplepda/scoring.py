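"""SIMPLE score: 14 weighted clinical items for early hsPDA prediction.

The score (Scoring preterm Infants for PDA cLinically without
Echocardiographic evaluation) sums 14 items, each worth 0–3 points,
covering perinatal risk factors (chorioamnionitis, antenatal steroids,
birth weight, cord blood gas) and the infant's clinical/ventilatory state
at scheduled postnatal hours (6, 12, 18, 24, 48, 72 h). The maximum
attainable total is 29.

Bin-boundary convention: every shared bin endpoint is assigned to the
lower-severity bin (e.g. birth weight 1000 g scores 1, PCO2 45 mmHg
scores 0). Outer bins printed as strict inequalities stay strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "VentMode",
    "InfantRecord",
    "TimepointObservation",
    "AdmissionBaseline",
    "ScoreBreakdown",
    "SCHEDULE_HOURS",
    "ITEM_NAMES",
    "ITEM_MAXIMA",
    "MAX_TOTAL",
    "score_birth_weight",
    "score_cord_gas",
    "score_metabolic_acidosis",
    "score_respiratory_acidosis",
    "score_ventilation",
    "score_tachycardia",
    "score_max_pip",
    "score_reduction",
    "score_fio2_admission",
    "score_surfactant",
    "compute_simple",
    "score_trajectory",
]

#: Scheduled assessment hours (postnatal hours of life).
SCHEDULE_HOURS = (6, 12, 18, 24, 48, 72)

#: Canonical item order used in breakdowns and CSV output.
ITEM_NAMES = (
    "chorioamnionitis",
    "antenatal_steroid",
    "birth_weight",
    "cord_base_deficit",
    "hypotension",
    "tachycardia",
    "invasive_mv",
    "metabolic_acidosis",
    "respiratory_acidosis",
    "max_pip",
    "pip_reduction",
    "fio2_admission",
    "fio2_reduction",
    "surfactant",
)

#: Per-item maximum points, in ITEM_NAMES order.
ITEM_MAXIMA = (1, 1, 3, 2, 1, 2, 3, 3, 3, 2, 2, 2, 2, 2)

#: Maximum attainable total score.
MAX_TOTAL = sum(ITEM_MAXIMA)


class ScoreInputError(ValueError):
    """Raised for physiologically impossible or malformed scoring inputs."""


class VentMode(str, Enum):
    """Ventilation state: no invasive support, conventional MV, or HFOV."""

    NONE = "none"
    CONVENTIONAL = "conventional"
    HFOV = "hfov"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ScoreInputError(msg)


def _finite(x: float, name: str) -> None:
    _require(x is not None and math.isfinite(float(x)), f"{name} must be finite, got {x!r}")


@dataclass(frozen=True)
class InfantRecord:
    """Static perinatal and admission data for one infant.

    ``cord_base_deficit`` is stored as a non-negative magnitude: a deficit of
    14 mmol/L (base excess −14) is entered as 14. ``fio2_admission`` is the
    fraction of inspired oxygen at NICU admission, in percent (21–100).
    """

    infant_id: str
    gestational_age: float
    birth_weight: float
    chorioamnionitis: bool
    antenatal_steroid_complete: bool
    cord_base_deficit: float
    fio2_admission: float

    def __post_init__(self) -> None:
        _finite(self.birth_weight, "birth_weight")
        _require(self.birth_weight > 0, f"birth_weight must be positive, got {self.birth_weight}")
        _finite(self.cord_base_deficit, "cord_base_deficit")
        _require(
            self.cord_base_deficit >= 0,
            "cord_base_deficit is a magnitude and must be >= 0 "
            f"(got {self.cord_base_deficit}); enter a deficit of 14 mmol/L as 14",
        )
        _finite(self.fio2_admission, "fio2_admission")
        _require(
            21 <= self.fio2_admission <= 100,
            f"fio2_admission must be in [21, 100] percent, got {self.fio2_admission}",
        )


@dataclass(frozen=True)
class TimepointObservation:
    """Dynamic clinical state at one scheduled assessment hour.

    Fields may be ``None`` when unrecorded; the trajectory API applies a
    carry-forward rule and flags the affected items. ``pip`` must be ``None``
    when ``vent_mode`` is :attr:`VentMode.NONE`. ``surfactant_doses`` is the
    cumulative number of doses given up to this hour.
    """

    infant_id: str
    hour: int
    heart_rate: Optional[float] = None
    hypotension_inotropes: Optional[bool] = None
    vent_mode: VentMode = VentMode.NONE
    pip: Optional[float] = None
    fio2: Optional[float] = None
    ph: Optional[float] = None
    base_deficit: Optional[float] = None
    pco2: Optional[float] = None
    surfactant_doses: Optional[int] = None

    def __post_init__(self) -> None:
        _require(self.hour in SCHEDULE_HOURS, f"hour must be one of {SCHEDULE_HOURS}, got {self.hour}")
        if not isinstance(self.vent_mode, VentMode):
            object.__setattr__(self, "vent_mode", VentMode(self.vent_mode))
        if self.vent_mode is VentMode.NONE:
            _require(self.pip is None, f"pip must be absent when not invasively ventilated (hour {self.hour})")
        if self.pip is not None:
            _require(self.pip >= 0, f"pip must be non-negative, got {self.pip}")
        if self.fio2 is not None:
            _require(21 <= self.fio2 <= 100, f"fio2 must be in [21, 100] percent, got {self.fio2}")
        if self.surfactant_doses is not None:
            _require(
                float(self.surfactant_doses).is_integer() and self.surfactant_doses >= 0,
                f"surfactant_doses must be a non-negative integer, got {self.surfactant_doses}",
            )


@dataclass(frozen=True)
class AdmissionBaseline:
    """Admission settings serving as 'prior assessment' for the 6 h scores.

    FiO2 at admission is always known from the infant record; an admission
    PIP may be supplied when the infant was intubated at admission, otherwise
    the 6 h PIP-reduction item is scored under the missing-data rule.
    """

    fio2: float
    pip: Optional[float] = None


@dataclass
class ScoreBreakdown:
    """Per-item points and total for one infant at one assessment hour."""

    infant_id: str
    hour: int
    item_points: Mapping[str, int]
    total: int
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert set(self.item_points) == set(ITEM_NAMES)
        assert self.total == sum(self.item_points.values())


# ---------------------------------------------------------------------------
# Item scorers. Shared bin endpoints always go to the lower-severity bin.
# ---------------------------------------------------------------------------

def score_birth_weight(bw: float) -> int:
    """Birth weight (g): >1250 → 0; 1000–1250 → 1; 750–<1000 → 2; <750 → 3."""
    _finite(bw, "birth_weight")
    _require(bw > 0, f"birth_weight must be positive, got {bw}")
    if bw > 1250:
        return 0
    if bw >= 1000:
        return 1
    if bw >= 750:
        return 2
    return 3


def score_cord_gas(bd_magnitude: float) -> int:
    """Cord blood gas base deficit (mmol/L magnitude): <12 → 0; 12–16 → 1; >16 → 2."""
    _finite(bd_magnitude, "cord base deficit")
    _require(bd_magnitude >= 0, f"base deficit magnitude must be >= 0, got {bd_magnitude}")
    if bd_magnitude < 12:
        return 0
    if bd_magnitude <= 16:
        return 1
    return 2


def _metabolic_ph_points(ph: float) -> int:
    if ph > 7.35:
        return 0
    if ph >= 7.25:
        return 1
    if ph >= 7.10:
        return 2
    return 3


def _metabolic_bd_points(bd: float) -> int:
    if bd < 4:
        return 0
    if bd <= 10:
        return 1
    if bd <= 16:
        return 2
    return 3


def score_metabolic_acidosis(ph: float, bd_magnitude: float) -> int:
    """Metabolic acidosis: max of the pH ladder and the base-deficit ladder.

    pH: >7.35 → 0; 7.25–7.35 → 1; 7.10–<7.25 → 2; <7.10 → 3.
    BD magnitude: <4 → 0; 4–10 → 1; >10–16 → 2; >16 → 3.
    The item takes the worse (higher) of the two.
    """
    _finite(ph, "ph")
    _require(6.5 < ph < 8.0, f"ph out of physiologic range (6.5, 8.0): {ph}")
    _finite(bd_magnitude, "base deficit")
    _require(bd_magnitude >= 0, f"base deficit magnitude must be >= 0, got {bd_magnitude}")
    return max(_metabolic_ph_points(ph), _metabolic_bd_points(bd_magnitude))


def score_respiratory_acidosis(pco2: float) -> int:
    """Respiratory acidosis (PCO2, mmHg): ≤45 → 0; >45–55 → 1; >55–65 → 2; >65 → 3.

    PCO2 below 35 falls outside every printed bin; hypocapnia is not
    respiratory acidosis, so it scores 0.
    """
    _finite(pco2, "pco2")
    _require(pco2 > 0, f"pco2 must be positive, got {pco2}")
    if pco2 <= 45:
        return 0
    if pco2 <= 55:
        return 1
    if pco2 <= 65:
        return 2
    return 3


def score_ventilation(mode: VentMode) -> int:
    """Invasive MV: none → 0; conventional → 1; HFOV → 3 (2 is unattainable)."""
    if not isinstance(mode, VentMode):
        try:
            mode = VentMode(mode)
        except ValueError as exc:
            raise ScoreInputError(f"unknown ventilation mode: {mode!r}") from exc
    return {VentMode.NONE: 0, VentMode.CONVENTIONAL: 1, VentMode.HFOV: 3}[mode]


def score_tachycardia(hr: float) -> int:
    """Heart rate (bpm): <160 → 0; 160–180 → 1; >180 → 2."""
    _finite(hr, "heart_rate")
    _require(hr > 0, f"heart_rate must be positive, got {hr}")
    if hr < 160:
        return 0
    if hr <= 180:
        return 1
    return 2


def score_max_pip(pip: Optional[float]) -> int:
    """Maximum PIP (cmH2O): absent or <18 → 0; 18–23 → 1; >23 → 2."""
    if pip is None:
        return 0
    _finite(pip, "pip")
    _require(pip >= 0, f"pip must be non-negative, got {pip}")
    if pip < 18:
        return 0
    if pip <= 23:
        return 1
    return 2


def score_reduction(prior: float, current: float) -> int:
    """Percent reduction vs prior assessment: >20% → 0; 10–20% → 1; <10% → 2.

    Any increase counts as a reduction below 10% and scores 2.
    """
    _finite(prior, "prior")
    _finite(current, "current")
    _require(prior > 0, f"prior value must be positive, got {prior}")
    _require(current > 0, f"current value must be positive, got {current}")
    reduction = 100.0 * (prior - current) / prior
    if reduction > 20:
        return 0
    if reduction >= 10:
        return 1
    return 2


def score_fio2_admission(fio2: float) -> int:
    """FiO2 at admission (%): <40 → 0; 40–60 → 1; >60 → 2."""
    _finite(fio2, "fio2_admission")
    _require(21 <= fio2 <= 100, f"fio2 must be in [21, 100] percent, got {fio2}")
    if fio2 < 40:
        return 0
    if fio2 <= 60:
        return 1
    return 2


def score_surfactant(doses: int) -> int:
    """Cumulative surfactant doses: 0 → 0; 1 → 1; more than one → 2."""
    _require(
        doses is not None and float(doses).is_integer() and doses >= 0,
        f"surfactant dose count must be a non-negative integer, got {doses!r}",
    )
    doses = int(doses)
    if doses == 0:
        return 0
    if doses == 1:
        return 1
    return 2


# ---------------------------------------------------------------------------
# Full-score assembly
# ---------------------------------------------------------------------------

def compute_simple(
    record: InfantRecord,
    obs: TimepointObservation,
    prior_obs: "TimepointObservation | AdmissionBaseline",
) -> ScoreBreakdown:
    """Score all 14 items for one infant at one assessment hour.

    ``prior_obs`` is the chronologically preceding scheduled observation, or
    an :class:`AdmissionBaseline` for the 6 h assessment. Items that cannot
    be scored because a value is missing or inapplicable (e.g. PIP while not
    ventilated) take the least-severity score 0 and are flagged.
    """
    _require(record.infant_id == obs.infant_id,
             f"observation infant {obs.infant_id!r} does not match record {record.infant_id!r}")
    if isinstance(prior_obs, TimepointObservation):
        _require(prior_obs.infant_id == record.infant_id,
                 f"prior observation infant {prior_obs.infant_id!r} does not match record")
        _require(prior_obs.hour < obs.hour,
                 f"prior observation hour {prior_obs.hour} not before {obs.hour}")
        prior_fio2, prior_pip = prior_obs.fio2, prior_obs.pip
    else:
        prior_fio2, prior_pip = prior_obs.fio2, prior_obs.pip

    flags: list[str] = []
    pts: dict[str, int] = {}

    pts["chorioamnionitis"] = 1 if record.chorioamnionitis else 0
    pts["antenatal_steroid"] = 0 if record.antenatal_steroid_complete else 1
    pts["birth_weight"] = score_birth_weight(record.birth_weight)
    pts["cord_base_deficit"] = score_cord_gas(record.cord_base_deficit)
    pts["fio2_admission"] = score_fio2_admission(record.fio2_admission)

    if obs.hypotension_inotropes is None:
        pts["hypotension"] = 0
        flags.append("hypotension:missing")
    else:
        pts["hypotension"] = 1 if obs.hypotension_inotropes else 0

    if obs.heart_rate is None:
        pts["tachycardia"] = 0
        flags.append("tachycardia:missing")
    else:
        pts["tachycardia"] = score_tachycardia(obs.heart_rate)

    pts["invasive_mv"] = score_ventilation(obs.vent_mode)

    if obs.ph is None or obs.base_deficit is None:
        if obs.ph is not None:
            pts["metabolic_acidosis"] = _metabolic_ph_points(obs.ph)
            flags.append("metabolic_acidosis:bd_missing")
        elif obs.base_deficit is not None:
            pts["metabolic_acidosis"] = _metabolic_bd_points(obs.base_deficit)
            flags.append("metabolic_acidosis:ph_missing")
        else:
            pts["metabolic_acidosis"] = 0
            flags.append("metabolic_acidosis:missing")
    else:
        pts["metabolic_acidosis"] = score_metabolic_acidosis(obs.ph, obs.base_deficit)

    if obs.pco2 is None:
        pts["respiratory_acidosis"] = 0
        flags.append("respiratory_acidosis:missing")
    else:
        pts["respiratory_acidosis"] = score_respiratory_acidosis(obs.pco2)

    ventilated = obs.vent_mode is not VentMode.NONE
    if not ventilated:
        pts["max_pip"] = 0
        pts["pip_reduction"] = 0
        flags.append("max_pip:not_ventilated")
        flags.append("pip_reduction:not_ventilated")
    else:
        if obs.pip is None:
            pts["max_pip"] = 0
            pts["pip_reduction"] = 0
            flags.append("max_pip:missing")
            flags.append("pip_reduction:missing")
        else:
            pts["max_pip"] = score_max_pip(obs.pip)
            if prior_pip is None:
                pts["pip_reduction"] = 0
                flags.append("pip_reduction:no_prior")
            else:
                pts["pip_reduction"] = score_reduction(prior_pip, obs.pip)

    if obs.fio2 is None:
        pts["fio2_reduction"] = 0
        flags.append("fio2_reduction:missing")
    elif obs.fio2 <= 21:
        # no supplemental oxygen: the reduction item is inapplicable and takes
        # the least-severity score (a well infant on room air must not accrue
        # the "<10% reduction" penalty indefinitely)
        pts["fio2_reduction"] = 0
        flags.append("fio2_reduction:room_air")
    elif prior_fio2 is None:
        pts["fio2_reduction"] = 0
        flags.append("fio2_reduction:no_prior")
    else:
        pts["fio2_reduction"] = score_reduction(prior_fio2, obs.fio2)

    if obs.surfactant_doses is None:
        pts["surfactant"] = 0
        flags.append("surfactant:missing")
    else:
        pts["surfactant"] = score_surfactant(obs.surfactant_doses)

    ordered = {name: pts[name] for name in ITEM_NAMES}
    return ScoreBreakdown(
        infant_id=record.infant_id,
        hour=obs.hour,
        item_points=ordered,
        total=sum(ordered.values()),
        flags=flags,
    )


_CARRY_FIELDS = (
    "heart_rate",
    "hypotension_inotropes",
    "fio2",
    "ph",
    "base_deficit",
    "pco2",
    "surfactant_doses",
)


def score_trajectory(
    record: InfantRecord,
    observations: Sequence[TimepointObservation],
    admission_pip: Optional[float] = None,
) -> list[ScoreBreakdown]:
    """Score an infant's full observation trajectory.

    Observations must be sorted by hour with unique hours from the schedule.
    Reduction items at the first observation use the admission baseline
    (admission FiO2 from the record, plus ``admission_pip`` if supplied).
    Missing dynamic values are carried forward from the most recent earlier
    observation and flagged.
    """
    _require(len(observations) > 0, "at least one observation is required")
    hours = [o.hour for o in observations]
    _require(len(set(hours)) == len(hours), f"duplicate assessment hours: {sorted(hours)}")
    _require(hours == sorted(hours), "observations must be sorted by hour")
    for o in observations:
        _require(o.infant_id == record.infant_id,
                 f"observation infant {o.infant_id!r} does not match record {record.infant_id!r}")
    doses = [o.surfactant_doses for o in observations if o.surfactant_doses is not None]
    _require(all(a <= b for a, b in zip(doses, doses[1:])),
             "cumulative surfactant_doses must be non-decreasing over hours")

    baseline = AdmissionBaseline(fio2=record.fio2_admission, pip=admission_pip)
    out: list[ScoreBreakdown] = []
    prior: TimepointObservation | AdmissionBaseline = baseline
    last_seen: dict[str, object] = {}
    for obs in observations:
        carried: list[str] = []
        filled = {}
        for name in _CARRY_FIELDS:
            val = getattr(obs, name)
            if val is None and name in last_seen:
                filled[name] = last_seen[name]
                carried.append(f"{name}:carried_forward")
            elif val is not None:
                last_seen[name] = val
        if filled:
            obs_eff = TimepointObservation(
                infant_id=obs.infant_id, hour=obs.hour,
                vent_mode=obs.vent_mode, pip=obs.pip,
                **{n: filled.get(n, getattr(obs, n)) for n in _CARRY_FIELDS},
            )
        else:
            obs_eff = obs
        bd = compute_simple(record, obs_eff, prior)
        bd.flags.extend(carried)
        out.append(bd)
        prior = obs_eff
    return out
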