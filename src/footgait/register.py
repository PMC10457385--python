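"""The subject-level database register: one row per volunteer walking test.

The register CSV has three header rows — section names, parameter names and
one-line explanations — followed by one data row per volunteer. It joins the
test metadata, socio-demographics, anthropometrics, the clinical instrument
outcomes and the aggregated gait summary of the instrumented walking test.

Two missing-value states are encoded and kept distinct in memory and on
disk: ``incapable`` (the subject could not perform a test) and ``-`` (datum
not collected). They are never conflated with numeric zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .clinical import Missing
from .metrics import FIELD_LABELS, GaitSummary

Cell = float | int | str | bool | Missing

#: metric (field, label) pairs aggregated in the register (all but the index)
_METRIC_FIELDS = [(name, label) for name, label in FIELD_LABELS if name != "n"]


@dataclass
class RegisterRow:
    """One volunteer's row of the database register."""

    volunteer_id: int
    device_type: str = "CSIC"  # CSIC or Gaitup
    device_id: str = "-"
    location: Cell = Missing.ABSENT  # Nursing home / Consultation / Familiar
    surface: Cell = Missing.ABSENT
    faller: Cell = Missing.ABSENT  # 1 if a fall in the previous year
    age: Cell = Missing.ABSENT
    sex: Cell = Missing.ABSENT  # M / F
    nursing_home: Cell = Missing.ABSENT
    weight_kg: Cell = Missing.ABSENT
    height_cm: Cell = Missing.ABSENT
    bmi: Cell = Missing.ABSENT
    gds: Cell = Missing.ABSENT
    four_m_time: Cell = Missing.ABSENT
    four_m_speed: Cell = Missing.ABSENT
    fried_weight_loss: Cell = Missing.ABSENT
    fried_exhaustion: Cell = Missing.ABSENT
    fried_low_activity: Cell = Missing.ABSENT
    fried_slowness: Cell = Missing.ABSENT
    fried_weakness: Cell = Missing.ABSENT
    fried_index: Cell = Missing.ABSENT
    sppb_balance: Cell = Missing.ABSENT
    sppb_gait: Cell = Missing.ABSENT
    sppb_chair: Cell = Missing.ABSENT
    sppb_total: Cell = Missing.ABSENT
    tug_time: Cell = Missing.ABSENT
    fes_i_total: Cell = Missing.ABSENT
    total_distance: Cell = Missing.ABSENT
    walking_time: Cell = Missing.ABSENT
    n_strides: Cell = Missing.ABSENT
    avg: dict[str, Cell] = field(default_factory=dict)  # keyed by metric field
    std: dict[str, Cell] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.bmi is Missing.ABSENT
            and not isinstance(self.weight_kg, Missing)
            and not isinstance(self.height_cm, Missing)
        ):
            self.bmi = float(self.weight_kg) / (float(self.height_cm) / 100.0) ** 2

    def attach_summary(self, summary: GaitSummary) -> None:
        """Fill the gait-summary cells from an aggregated walking test."""
        self.total_distance = summary.total_distance
        self.walking_time = summary.walking_time
        self.n_strides = summary.n_strides
        self.avg = dict(summary.avg)
        self.std = dict(summary.std)


# (key, section, parameter, explanation); keys match RegisterRow attributes
_SCHEMA: list[tuple[str, str, str, str]] = [
    ("volunteer_id", "Test data", "Volunteer", "Volunteer identification number"),
    ("device_type", "Test data", "Device", "IMU family used (CSIC or Gaitup)"),
    ("device_id", "Test data", "Device ID", "Identifier of the IMU"),
    ("location", "Test data", "Location", "Nursing home / Consultation / Familiar"),
    ("surface", "Test data", "Surface", "Walking surface of the test"),
    ("faller", "Test data", "Faller", "1 if the volunteer fell during the last year"),
    ("age", "Socio-demographic data", "Age", "Age in years"),
    ("sex", "Socio-demographic data", "Sex", "M male, F female"),
    ("nursing_home", "Socio-demographic data", "Nursing home", "1 if resident"),
    ("weight_kg", "Anatomical, functional and cognitive variables", "Weight", "kg"),
    ("height_cm", "Anatomical, functional and cognitive variables", "Height", "cm"),
    ("bmi", "Anatomical, functional and cognitive variables", "BMI", "kg/m^2"),
    ("gds", "Anatomical, functional and cognitive variables", "GDS", "Stage 1-7"),
    ("four_m_time", "Gait test of 4-meter walk", "Time", "Seconds to walk 4 m"),
    ("four_m_speed", "Gait test of 4-meter walk", "Gait Speed", "4 m / time, m/s"),
    ("fried_weight_loss", "Frailty criteria", "Weight loss", "1 if > 4.5 kg lost"),
    ("fried_exhaustion", "Frailty criteria", "Exhaustion", "1 if >= 2 days/week"),
    ("fried_low_activity", "Frailty criteria", "Low activity", "1 if below sex cut-off"),
    ("fried_slowness", "Frailty criteria", "Slowness", "1 if speed below cut-off"),
    ("fried_weakness", "Frailty criteria", "Weakness", "1 if force below cut-off"),
    ("fried_index", "Frailty criteria", "Frailty index", "Sum of criteria, 0-5"),
    ("sppb_balance", "Short Physical Performance Battery (SPPB) test", "Balance", "0-4"),
    ("sppb_gait", "Short Physical Performance Battery (SPPB) test", "Gait speed", "0-4"),
    ("sppb_chair", "Short Physical Performance Battery (SPPB) test", "Chair stand", "0-4"),
    ("sppb_total", "Short Physical Performance Battery (SPPB) test", "SPPB total", "0-12"),
    ("tug_time", "Timed up and go (TUG) test", "Time", "Seconds"),
    ("fes_i_total", "Short FES-I test", "FES-I total", "Sum of 7 items, 7-28"),
    ("total_distance", "Gait data from the IMU recordings", "Total distance", "m walked"),
    ("walking_time", "Gait data from the IMU recordings", "Walking time", "s, still intervals excluded"),
    ("n_strides", "Gait data from the IMU recordings", "Num. strides", "Strides kept after filtering"),
]
for _name, _label in _METRIC_FIELDS:
    _SCHEMA.append(
        ("avg:" + _name, "Gait data from the IMU recordings", f"Avg {_label}",
         f"Average of {_label} over kept strides")
    )
for _name, _label in _METRIC_FIELDS:
    _SCHEMA.append(
        ("std:" + _name, "Gait data from the IMU recordings", f"STD {_label}",
         f"Standard deviation of {_label} over kept strides")
    )


def register_schema() -> list[tuple[str, str, str, str]]:
    """The register column schema: (key, section, parameter, explanation)."""
    return list(_SCHEMA)


def _encode(value: Cell) -> str:
    if isinstance(value, Missing):
        return value.value
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _decode(text: str) -> Cell:
    text = text.strip()
    if text.lower() == Missing.INCAPABLE.value:
        return Missing.INCAPABLE
    if text == Missing.ABSENT.value or text == "":
        return Missing.ABSENT
    try:
        f = float(text)
    except ValueError:
        return text
    return int(f) if f.is_integer() and "." not in text and "e" not in text.lower() else f


def _get(row: RegisterRow, key: str) -> Cell:
    if key.startswith("avg:"):
        return row.avg.get(key[4:], Missing.ABSENT)
    if key.startswith("std:"):
        return row.std.get(key[4:], Missing.ABSENT)
    return getattr(row, key)


def _set(row: RegisterRow, key: str, value: Cell) -> None:
    if key.startswith("avg:"):
        row.avg[key[4:]] = value
    elif key.startswith("std:"):
        row.std[key[4:]] = value
    else:
        setattr(row, key, value)


def write_register(rows: Sequence[RegisterRow], path: str | Path) -> None:
    """Write the register CSV: three header rows, then one row per volunteer."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([s for _, s, _, _ in _SCHEMA])
        w.writerow([p for _, _, p, _ in _SCHEMA])
        w.writerow([e for _, _, _, e in _SCHEMA])
        for row in rows:
            w.writerow([_encode(_get(row, key)) for key, _, _, _ in _SCHEMA])


def read_register(path: str | Path) -> list[RegisterRow]:
    """Read a register CSV written by :func:`write_register`.

    Parameter-name matching is case-insensitive; the section and explanation
    header rows are not interpreted.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        sections = [s.strip().lower() for s in next(reader)]
        params = [p.strip().lower() for p in next(reader)]
        _explanations = next(reader)
        # parameter names repeat across sections ("Time"), so match on both
        key_by_col = {(s.lower(), p.lower()): k for k, s, p, _ in _SCHEMA}
        keys = [key_by_col.get(sp) for sp in zip(sections, params)]
        rows = []
        for cells in reader:
            if not any(c.strip() for c in cells):
                continue
            row = RegisterRow(volunteer_id=0)
            for key, cell in zip(keys, cells):
                if key is not None:
                    _set(row, key, _decode(cell))
            rows.append(row)
    return rows
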