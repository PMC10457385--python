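"""Write and read every file dialect: raw TXT, calibration TXT, metrics CSV,
database register.

Generates one synthetic volunteer in the database's folder naming scheme,
re-reads the raw counts, applies the calibration parameters, analyzes the
bout and writes the per-stride metrics CSV plus a one-row register.
"""

import tempfile
import warnings
from pathlib import Path

from footgait import GaitSimParams, PipelineConfig, apply_calibration
from footgait.io import (
    read_calibration_params,
    read_raw_recording,
    read_stride_metrics,
    write_stride_metrics,
)
from footgait.pipeline import analyze
from footgait.register import RegisterRow, write_register
from footgait.synthetic import write_fixture_set

workdir = Path(tempfile.mkdtemp(prefix="footgait_demo_"))
[files] = write_fixture_set(
    [GaitSimParams(n_strides=12, initial_still_s=8.0, seed=21)], workdir
)
print("fixture files:", ", ".join(p.name for p in files.values()))

raw = read_raw_recording(files["raw"])
cal = read_calibration_params(files["calibration"])
print(f"raw recording: {len(raw)} samples, units={raw.units_state.value}, "
      f"clock factor {cal.clock_error:.6f}")

rec = apply_calibration(raw, cal)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = analyze(rec, config=PipelineConfig(static_window_s=8.0))

metrics_path = workdir / "V001_metrics.csv"
write_stride_metrics(result.strides, metrics_path)
back = read_stride_metrics(metrics_path)
print(f"metrics CSV: {len(back)} strides, columns numbered n=0..{back[-1].n}")

row = RegisterRow(volunteer_id=1, device_id="45CA", sex="F", age=83,
                  weight_kg=59.0, height_cm=152.0)
row.attach_summary(result.summary)
register_path = workdir / "Database_register.csv"
write_register([row], register_path)
import csv

with open(register_path, newline="") as fh:
    sections = next(csv.reader(fh))
n_lines = len(register_path.read_text().splitlines())
print(f"register: {n_lines} lines (3 header rows + 1 volunteer), "
      f"{len(sections)} columns")
print("sections:", "; ".join(dict.fromkeys(sections)))
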