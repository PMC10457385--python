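"""Readers and writers for the database file dialects.

Four plain-text dialects are handled here:

* raw recordings        — TXT, columns ``accX[a.u.] .. gyrZ[a.u.]`` (+ optional time)
* calibrated recordings — TXT, columns ``accX[m/s^2] .. gyrZ[rad/s]``
* calibration parameters — TXT, 3 rows x 15 columns (bias vectors, misalignment
  and scaling matrices split column-wise, clock factor followed by two zeros)
* per-stride metrics    — CSV with the 14 canonical gait-parameter labels

The subject-level register CSV lives in :mod:`footgait.register`.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .datatypes import CalibrationParams, Device, ImuRecording, UnitsState

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import StrideMetrics


class DialectError(ValueError):
    """File does not follow the expected column dialect."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


#: Canonical metrics-CSV column labels, in file order.
METRICS_COLUMNS = (
    "Num. Steps",
    "Stride time",
    "Swing",
    "Load",
    "Foot Flat",
    "Push",
    "Toe Off angle",
    "Heel Strike angle",
    "Cadence",
    "Speed",
    "Stride Length",
    "3D Length Path",
    "2D Length Path",
    "Clearance",
)

_AXES = ("X", "Y", "Z")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-, tab- or comma-delimited numeric table with header."""
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & ~df[col].astype(str).str.strip().str.lower().isin(
            ("nan", "")
        )
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        out[col] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _find_channel(columns: Sequence[str], sensor: str, axis: str) -> str:
    """Locate e.g. 'accX[a.u.]' case-insensitively, tolerant of unit suffix."""
    pat = re.compile(rf"^{sensor}{axis}\b.*", re.IGNORECASE)
    for c in columns:
        if pat.match(c.replace(" ", "")):
            return c
    raise DialectError(f"missing channel column {sensor}{axis!s} (have {list(columns)})")


def _find_time(columns: Sequence[str]) -> str | None:
    for c in columns:
        if re.match(r"^(time|t)\b", c, re.IGNORECASE):
            return c
    return None


def _read_recording(
    path: str | Path,
    units_state: UnitsState,
    rate_hz: float,
    device: Device,
) -> ImuRecording:
    df = _numeric(_read_table(path), path)
    cols = list(df.columns)
    acc = np.column_stack([df[_find_channel(cols, "acc", ax)] for ax in _AXES])
    gyr = np.column_stack([df[_find_channel(cols, "gyr", ax)] for ax in _AXES])
    tcol = _find_time(cols)
    if tcol is not None:
        time = df[tcol].to_numpy(dtype=float)
    else:
        time = np.arange(len(df)) / rate_hz
    return ImuRecording(
        time=time, acc=acc, gyr=gyr, rate_hz=rate_hz,
        device=device, units_state=units_state,
    )


def read_raw_recording(
    path: str | Path, rate_hz: float = 104.0, device: Device = Device.CSIC
) -> ImuRecording:
    """Read a raw (arbitrary-unit) recording TXT.

    Channels are mapped to canonical (X, Y, Z) = (lateral, frontal, vertical)
    order by column name, regardless of the order in the file. If no time
    column is present, ``time = n / rate_hz`` is synthesised (the clock factor
    is applied later during calibration).
    """
    return _read_recording(path, UnitsState.RAW, rate_hz, device)


def read_calibrated_recording(
    path: str | Path, rate_hz: float = 104.0, device: Device = Device.CSIC
) -> ImuRecording:
    """Read a calibrated recording TXT (acc in m/s^2, gyr in rad/s)."""
    return _read_recording(path, UnitsState.CALIBRATED, rate_hz, device)


def _write_recording(rec: ImuRecording, path: str | Path, unit_acc: str, unit_gyr: str) -> None:
    cols = {"time[s]": rec.time}
    for i, ax in enumerate(_AXES):
        cols[f"acc{ax}[{unit_acc}]"] = rec.acc[:, i]
    for i, ax in enumerate(_AXES):
        cols[f"gyr{ax}[{unit_gyr}]"] = rec.gyr[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_raw_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a raw recording in the tab-separated TXT dialect."""
    if rec.units_state is not UnitsState.RAW:
        raise ValueError("recording is not in raw units")
    _write_recording(rec, path, "a.u.", "a.u.")


def write_calibrated_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a calibrated recording (SI units) in the TXT dialect."""
    if rec.units_state is not UnitsState.CALIBRATED:
        raise ValueError("recording is not calibrated")
    _write_recording(rec, path, "m/s^2", "rad/s")


# --- calibration-parameter files -------------------------------------------

_CAL_COLUMNS = (
    ["ACC_biasVector"]
    + [f"ACC_misalignmentM_col{n}" for n in (1, 2, 3)]
    + [f"ACC_scalingM_col{n}" for n in (1, 2, 3)]
    + ["GYR_biasVector"]
    + [f"GYR_misalignmentM_col{n}" for n in (1, 2, 3)]
    + [f"GYR_scalingM_col{n}" for n in (1, 2, 3)]
    + ["clockError"]
)


def read_calibration_params(path: str | Path) -> CalibrationParams:
    """Read a calibration-parameter TXT file.

    The file holds 3 rows; each matrix is stored as three columns named
    ``*_colN`` re-assembled column-by-column in N order. The ``clockError``
    column contains the time-scale factor followed by two zeros.
    """
    df = _numeric(_read_table(path), path)
    lower = {c.lower(): c for c in df.columns}

    def col(name: str) -> np.ndarray:
        try:
            return df[lower[name.lower()]].to_numpy(dtype=float)
        except KeyError:
            raise DialectError(f"{path}: missing column {name!r}") from None

    def matrix(prefix: str) -> np.ndarray:
        return np.column_stack([col(f"{prefix}_col{n}") for n in (1, 2, 3)])

    return CalibrationParams(
        acc_bias=col("ACC_biasVector"),
        acc_misalignment=matrix("ACC_misalignmentM"),
        acc_scaling=matrix("ACC_scalingM"),
        gyr_bias=col("GYR_biasVector"),
        gyr_misalignment=matrix("GYR_misalignmentM"),
        gyr_scaling=matrix("GYR_scalingM"),
        clock_error=float(col("clockError")[0]),
    )


def write_calibration_params(params: CalibrationParams, path: str | Path) -> None:
    """Write calibration parameters in the 3-row, 15-column TXT dialect."""
    cols: list[np.ndarray] = [params.acc_bias]
    cols += [params.acc_misalignment[:, n] for n in range(3)]
    cols += [params.acc_scaling[:, n] for n in range(3)]
    cols.append(params.gyr_bias)
    cols += [params.gyr_misalignment[:, n] for n in range(3)]
    cols += [params.gyr_scaling[:, n] for n in range(3)]
    cols.append(np.array([params.clock_error, 0.0, 0.0]))
    df = pd.DataFrame(np.column_stack(cols), columns=_CAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# --- per-stride metrics CSV -------------------------------------------------


def write_stride_metrics(strides: "Sequence[StrideMetrics]", path: str | Path) -> None:
    """Write per-stride metrics as a CSV with the canonical 14 column labels.

    Stride numbering is n = 0..N-1 in the ``Num. Steps`` column.
    """
    if len(strides) == 0:
        raise ValueError("cannot write an empty stride list")
    rows = [s.as_row() for s in strides]
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_stride_metrics(path: str | Path) -> "list[StrideMetrics]":
    """Read a per-stride metrics CSV back into StrideMetrics objects."""
    from .metrics import StrideMetrics

    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing metric columns {missing}")
    return [StrideMetrics.from_row(row) for _, row in df.iterrows()]
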