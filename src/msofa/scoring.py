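"""Organ-dysfunction scoring for the modified SOFA (mSOFA) severity score.

The SOFA score grades six organ systems — respiratory, coagulation, liver,
cardiovascular, central nervous system and renal — each on an integer scale
from 0 (normal function) to 4 (worst dysfunction); the total is the sum,
0–24.  The modification implemented here replaces the respiratory
criterion's PaO2/FiO2 ratio (which requires arterial blood gas analysis)
with the pulse-oximetry surrogate SpO2/FiO2, so the score can be computed
in settings where blood gases are rarely available.  Both respiratory modes
are provided: ``spo2`` (the modified score, the default) and ``pao2`` (the
original SOFA respiratory criterion, for comparison when PaO2 exists).

All cut-points live in the declarative band tables ``SUBSCORE_BANDS`` and
``VASOPRESSOR_CATEGORIES`` below, which are the single source of truth for
the banding convention.  Published band edges are ambiguous at exact
boundary values; this module resolves every boundary with half-open
intervals, closed on the side nearer normality being exited (e.g. an
SpO2/FiO2 ratio of exactly 67 scores 3, not 4; platelets of exactly 150
score 1).  The convention is documented in docs/methods.md.

This module is pure and in-memory: no file I/O, no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class OxygenDevice(str, Enum):
    """How supplemental oxygen (if any) is being delivered."""

    ROOM_AIR = "room_air"
    NASAL_CANNULA = "nasal_cannula"
    FACE_MASK = "face_mask"
    VENTILATOR = "ventilator"


class RespiratoryMode(str, Enum):
    """Which oxygenation ratio drives the respiratory subscore."""

    SPO2 = "spo2"
    PAO2 = "pao2"


class VasopressorDrug(str, Enum):
    """Vasoactive agents recognised by the cardiovascular criterion."""

    DOPAMINE = "dopamine"
    DOBUTAMINE = "dobutamine"
    NOREPINEPHRINE = "norepinephrine"


class IncompleteObservationError(ValueError):
    """An observation lacks a field its oxygen-delivery device requires."""


class MissingMeasurementError(ValueError):
    """The requested respiratory mode needs a measurement that is absent."""


class UnscorableComponentError(ValueError):
    """No admissible input is available for an organ component."""


@dataclass(frozen=True)
class OxygenDelivery:
    """Oxygen-delivery state at one observation.

    ``flow`` (L/min) is meaningful for nasal cannulae only; ``fio2`` must
    be supplied directly for face masks and ventilators.  Room air is
    always FiO2 0.21.
    """

    device: OxygenDevice
    flow: Optional[float] = None
    fio2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.flow is not None and self.flow < 0:
            raise ValueError(f"oxygen flow must be non-negative, got {self.flow}")
        if self.fio2 is not None and not (0.21 <= self.fio2 <= 1.0):
            raise ValueError(f"fio2 must lie in [0.21, 1.0], got {self.fio2}")


@dataclass(frozen=True)
class VasopressorDose:
    """One vasopressor administration, dosed in µg/kg/min."""

    drug: VasopressorDrug
    dose: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", VasopressorDrug(self.drug))
        if self.dose < 0:
            raise ValueError(f"vasopressor dose must be non-negative, got {self.dose}")


#: Declarative band tables.  Each entry is an ordered tuple of
#: ``(operator, threshold, points)`` rules evaluated first-match-wins; the
#: final rule ``("else", None, points)`` is the default.  Operators compare
#: the measured value against the threshold.
SUBSCORE_BANDS: dict[str, tuple[tuple[str, Optional[float], int], ...]] = {
    "respiratory_spo2": (
        (">", 301, 0),
        (">=", 221, 1),
        (">=", 142, 2),
        (">=", 67, 3),
        ("else", None, 4),
    ),
    "respiratory_pao2": (
        (">", 400, 0),
        (">=", 300, 1),
        (">=", 200, 2),
        (">=", 100, 3),
        ("else", None, 4),
    ),
    "platelets": (
        (">", 150, 0),
        (">=", 100, 1),
        (">=", 50, 2),
        (">=", 20, 3),
        ("else", None, 4),
    ),
    "bilirubin": (
        ("<", 1.2, 0),
        ("<", 2.0, 1),
        ("<", 6.0, 2),
        ("<", 12.0, 3),
        ("else", None, 4),
    ),
    "gcs": (
        (">=", 15, 0),
        (">=", 13, 1),
        (">=", 10, 2),
        (">=", 6, 3),
        ("else", None, 4),
    ),
    "creatinine": (
        ("<", 1.2, 0),
        ("<", 2.0, 1),
        ("<", 3.5, 2),
        ("<", 5.0, 3),
        ("else", None, 4),
    ),
    "urine_output": (
        ("<", 200, 4),
        ("<", 500, 3),
        ("else", None, 0),
    ),
}

#: Cardiovascular drug/dose categories: ``(drug, low_exclusive, high_inclusive,
#: points)`` — a dose d qualifies when low < d <= high (None = unbounded).
#: Dobutamine maps to category 2 at any dose and never higher on its own.
VASOPRESSOR_CATEGORIES: tuple[tuple[VasopressorDrug, Optional[float], Optional[float], int], ...] = (
    (VasopressorDrug.DOPAMINE, None, 5.0, 2),
    (VasopressorDrug.DOPAMINE, 5.0, 15.0, 3),
    (VasopressorDrug.DOPAMINE, 15.0, None, 4),
    (VasopressorDrug.DOBUTAMINE, None, None, 2),
    (VasopressorDrug.NOREPINEPHRINE, None, 0.1, 3),
    (VasopressorDrug.NOREPINEPHRINE, 0.1, None, 4),
)

_OPS = {
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
}


def _scan_bands(table: str, value: float) -> int:
    for op, threshold, points in SUBSCORE_BANDS[table]:
        if op == "else" or _OPS[op](value, threshold):
            return points
    raise AssertionError(f"band table {table!r} has no default rule")


@dataclass(frozen=True)
class OrganSubscores:
    """The six organ components of one mSOFA evaluation at one timepoint."""

    respiratory: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int
    respiratory_mode: RespiratoryMode = RespiratoryMode.SPO2

    _COMPONENTS = ("respiratory", "coagulation", "liver", "cardiovascular", "cns", "renal")

    def __post_init__(self) -> None:
        object.__setattr__(self, "respiratory_mode", RespiratoryMode(self.respiratory_mode))
        for name in self._COMPONENTS:
            value = getattr(self, name)
            if not (isinstance(value, int) and 0 <= value <= 4):
                raise ValueError(f"{name} subscore must be an integer in [0, 4], got {value!r}")

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in self._COMPONENTS)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in self._COMPONENTS}


def estimate_fio2(delivery: OxygenDelivery) -> float:
    """Return the inspired-oxygen fraction for an oxygen-delivery state.

    Room air is 0.21.  For nasal cannulae the fraction is estimated from
    the flow rate as 0.21 + 0.03 per L/min, clipped to the physical range
    [0.21, 1.0].  Face masks and ventilators must carry a measured or set
    FiO2, which is returned unchanged.
    """
    device = OxygenDevice(delivery.device)
    if device is OxygenDevice.ROOM_AIR:
        return 0.21
    if device is OxygenDevice.NASAL_CANNULA:
        if delivery.flow is None:
            raise IncompleteObservationError("nasal cannula requires a flow rate (L/min)")
        return min(max(0.21 + 0.03 * delivery.flow, 0.21), 1.0)
    # face mask or ventilator: FiO2 must be known
    if delivery.fio2 is None:
        raise IncompleteObservationError(f"{device.value} requires a known FiO2")
    return delivery.fio2


def oxygenation_ratio(
    spo2: Optional[float],
    pao2: Optional[float],
    fio2: float,
    mode: RespiratoryMode | str = RespiratoryMode.SPO2,
) -> float:
    """SpO2/FiO2 or PaO2/FiO2 ratio, per the requested respiratory mode.

    SpO2 enters as a percentage (0–100) and FiO2 as a fraction, so SpO2
    90% on FiO2 1.0 gives a ratio of 90; PaO2 enters in mmHg, so PaO2
    60 mmHg on FiO2 1.0 gives 60.  These units are what make the
    respiratory band cut-points correct.
    """
    mode = RespiratoryMode(mode)
    if not (0.21 <= fio2 <= 1.0):
        raise ValueError(f"fio2 must lie in [0.21, 1.0], got {fio2}")
    if mode is RespiratoryMode.SPO2:
        if spo2 is None:
            raise MissingMeasurementError("spo2 mode requires an SpO2 measurement")
        if not (0 <= spo2 <= 100):
            raise ValueError(f"spo2 must lie in [0, 100] percent, got {spo2}")
        return spo2 / fio2
    if pao2 is None:
        raise MissingMeasurementError("pao2 mode requires a PaO2 measurement")
    if pao2 < 0:
        raise ValueError(f"pao2 must be non-negative, got {pao2}")
    return pao2 / fio2


def respiratory_subscore(ratio: float, mode: RespiratoryMode | str = RespiratoryMode.SPO2) -> int:
    """Respiratory points from an oxygenation ratio (5 bands, 0–4)."""
    mode = RespiratoryMode(mode)
    if ratio < 0 or math.isnan(ratio):
        raise ValueError(f"oxygenation ratio must be non-negative, got {ratio}")
    table = "respiratory_spo2" if mode is RespiratoryMode.SPO2 else "respiratory_pao2"
    return _scan_bands(table, ratio)


def coagulation_subscore(platelets: float) -> int:
    """Coagulation points from the platelet count (10^3/mm^3)."""
    if platelets < 0 or math.isnan(platelets):
        raise ValueError(f"platelet count must be non-negative, got {platelets}")
    return _scan_bands("platelets", platelets)


def liver_subscore(bilirubin: float) -> int:
    """Liver points from total bilirubin (mg/dL)."""
    if bilirubin < 0 or math.isnan(bilirubin):
        raise ValueError(f"bilirubin must be non-negative, got {bilirubin}")
    return _scan_bands("bilirubin", bilirubin)


def _vasopressor_category(dose: VasopressorDose) -> int:
    drug = VasopressorDrug(dose.drug)
    for table_drug, low, high, points in VASOPRESSOR_CATEGORIES:
        if drug is not table_drug:
            continue
        if low is not None and not dose.dose > low:
            continue
        if high is not None and not dose.dose <= high:
            continue
        return points
    raise ValueError(f"no cardiovascular category for {drug.value} at dose {dose.dose}")


def cardiovascular_subscore(
    map_mmhg: Optional[float],
    vasopressors: Sequence[VasopressorDose] = (),
) -> int:
    """Cardiovascular points from mean arterial pressure and vasopressors.

    Without vasopressors: MAP >= 70 mmHg scores 0, MAP < 70 scores 1.
    Each administered drug maps to a category (dopamine <=5 or any
    dobutamine -> 2; dopamine >5 or norepinephrine <=0.1 -> 3; dopamine
    >15 or norepinephrine >0.1 -> 4); with several qualifying categories
    the maximum — the worst — is returned.
    """
    vasopressors = tuple(vasopressors)
    if not vasopressors:
        if map_mmhg is None:
            raise UnscorableComponentError("cardiovascular component needs MAP or vasopressor data")
        if map_mmhg <= 0:
            raise ValueError(f"MAP must be positive, got {map_mmhg}")
        return 0 if map_mmhg >= 70 else 1
    if map_mmhg is not None and map_mmhg <= 0:
        raise ValueError(f"MAP must be positive, got {map_mmhg}")
    categories = [_vasopressor_category(v) for v in vasopressors]
    if map_mmhg is not None and map_mmhg < 70:
        categories.append(1)
    return max(categories)


def cns_subscore(gcs: float) -> int:
    """Central-nervous-system points from the Glasgow Coma Scale (3–15)."""
    if not (3 <= gcs <= 15):
        raise ValueError(f"GCS must lie in [3, 15], got {gcs}")
    return _scan_bands("gcs", gcs)


def renal_subscore(creatinine: Optional[float], urine_output: Optional[float] = None) -> int:
    """Renal points from creatinine (mg/dL) and/or urine output (mL/day).

    The creatinine band and the urine-output band are combined by maximum
    (the worst applies); an absent urine output contributes nothing.
    """
    if creatinine is None and urine_output is None:
        raise UnscorableComponentError("renal component needs creatinine or urine output")
    points = 0
    if creatinine is not None:
        if creatinine < 0 or math.isnan(creatinine):
            raise ValueError(f"creatinine must be non-negative, got {creatinine}")
        points = max(points, _scan_bands("creatinine", creatinine))
    if urine_output is not None:
        if urine_output < 0 or math.isnan(urine_output):
            raise ValueError(f"urine output must be non-negative, got {urine_output}")
        points = max(points, _scan_bands("urine_output", urine_output))
    return points


def total_msofa(subscores: OrganSubscores) -> int:
    """Total mSOFA: the sum of the six organ components, 0–24."""
    return subscores.total
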