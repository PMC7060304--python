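"""On-disk formats: frame-series CSV + metadata sidecar, step annotations,
blood-gas tables and the JSON titration report.

All tables are plain comma-separated text with a header row and ``.``
decimals; pressures are cmH2O, gas tensions mmHg, times seconds. The frame
CSV carries a ``t_s`` column followed by 1024 pixel columns ``px_0001`` ..
``px_1024`` in row-major order with row 1 most ventral (the convention is
restated in the sidecar and never inferred). The vendor's proprietary
binary stream is out of scope; converters can target this CSV instead.
"""

from __future__ import annotations

import json
import math
import os
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    GRID_COLS,
    GRID_ROWS,
    N_PIXELS,
    PIXEL_ORDER,
    FrameSeries,
    TitrationResult,
    ValidationError,
)

REPORT_SCHEMA = "hfoveit-titration-report/1"

PIXEL_COLUMNS = [f"px_{i + 1:04d}" for i in range(N_PIXELS)]

ANNOTATION_COLUMNS = ["step_index", "mpaw_cmh2o", "t_start_s", "t_end_s"]
BLOOD_GAS_COLUMNS = ["step_index", "pao2_mmhg", "paco2_mmhg", "fio2"]


def sidecar_path(csv_path: str) -> str:
    base, _ = os.path.splitext(str(csv_path))
    return base + ".meta.yaml"


# ---------------------------------------------------------------------------
# frame series
# ---------------------------------------------------------------------------

def write_frame_series(series: FrameSeries, path) -> None:
    """Write a frame series as CSV plus a ``.meta.yaml`` sidecar."""
    path = str(path)
    df = pd.DataFrame(series.pixel_signals, columns=PIXEL_COLUMNS)
    df.insert(0, "t_s", series.times)
    # %.17g guarantees bit-exact float64 round trips
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "grid_rows": GRID_ROWS,
        "grid_cols": GRID_COLS,
        "frame_rate_hz": float(series.frame_rate),
        "pixel_order": PIXEL_ORDER,
        "oscillation_hz": float(series.oscillation_hz),
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_frame_series(path) -> FrameSeries:
    """Read a frame-series CSV and its metadata sidecar.

    Raises
    ------
    ValidationError
        Missing sidecar, wrong pixel-column count, non-monotone time stamps
        or any other violated invariant; the message names the offending
        record or rule.
    """
    path = str(path)
    meta_path = sidecar_path(path)
    if not os.path.exists(path):
        raise ValidationError(f"frame series file not found: {path}")
    if not os.path.exists(meta_path):
        raise ValidationError(
            f"missing metadata sidecar {meta_path} for frame series {path}"
        )
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("grid_rows", "grid_cols", "frame_rate_hz", "oscillation_hz"):
        if key not in meta:
            raise ValidationError(f"sidecar {meta_path}: missing key '{key}'")
    rows, cols = int(meta["grid_rows"]), int(meta["grid_cols"])
    if (rows, cols) != (GRID_ROWS, GRID_COLS):
        raise ValidationError(
            f"sidecar {meta_path}: grid {rows}x{cols} unsupported, "
            f"expected {GRID_ROWS}x{GRID_COLS}"
        )
    frame_rate = float(meta["frame_rate_hz"])
    f0 = float(meta["oscillation_hz"])
    if frame_rate <= 2.0 * f0:
        raise ValidationError(
            f"sidecar {meta_path}: frame_rate_hz={frame_rate} does not "
            f"resolve oscillation_hz={f0} (need frame_rate > 2*oscillation)"
        )

    df = pd.read_csv(path, float_precision="round_trip")
    if "t_s" not in df.columns:
        raise ValidationError(f"{path}: missing required column 't_s'")
    pix_cols = [c for c in df.columns if c != "t_s"]
    if len(pix_cols) != rows * cols:
        raise ValidationError(
            f"{path}: expected {rows * cols} pixel columns, found "
            f"{len(pix_cols)}"
        )
    if pix_cols != PIXEL_COLUMNS:
        raise ValidationError(
            f"{path}: pixel columns must be px_0001..px_{N_PIXELS:04d} "
            "in order"
        )
    times = df["t_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if len(bad):
        raise ValidationError(
            f"{path}: t_s not strictly increasing at data row {bad[0] + 2} "
            f"(t_s={times[bad[0] + 1]!r})"
        )
    frames = df[PIXEL_COLUMNS].to_numpy(dtype=float).reshape(-1, rows, cols)
    return FrameSeries(
        times=times, frames=frames, frame_rate=frame_rate, oscillation_hz=f0
    )


# ---------------------------------------------------------------------------
# step annotations
# ---------------------------------------------------------------------------

def validate_step_annotations(df: pd.DataFrame, source: str = "annotations") -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df = df.sort_values("step_index").reset_index(drop=True)
    if df["step_index"].duplicated().any():
        dup = int(df.loc[df["step_index"].duplicated(), "step_index"].iloc[0])
        raise ValidationError(f"{source}: duplicate step_index {dup}")
    mpaw = df["mpaw_cmh2o"].to_numpy(dtype=float)
    if np.any(np.diff(mpaw) >= 0):
        k = int(np.argmax(np.diff(mpaw) >= 0))
        raise ValidationError(
            f"{source}: mpaw_cmh2o must be strictly decreasing with "
            f"step_index (trial is decremental); violated between steps "
            f"{df['step_index'][k]} and {df['step_index'][k + 1]} "
            f"({mpaw[k]} -> {mpaw[k + 1]} cmH2O)"
        )
    t0 = df["t_start_s"].to_numpy(dtype=float)
    t1 = df["t_end_s"].to_numpy(dtype=float)
    if np.any(t1 <= t0):
        k = int(np.argmax(t1 <= t0))
        raise ValidationError(
            f"{source}: empty or negative window at step {df['step_index'][k]}"
        )
    if np.any(t0[1:] < t1[:-1] - 1e-9):
        k = int(np.argmax(t0[1:] < t1[:-1] - 1e-9))
        raise ValidationError(
            f"{source}: windows overlap between steps "
            f"{df['step_index'][k]} and {df['step_index'][k + 1]}"
        )
    return df


def read_step_annotations(path) -> pd.DataFrame:
    """Read and validate a step-annotation CSV, sorted by ``step_index``."""
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_step_annotations(df, source=str(path))


def write_step_annotations(df: pd.DataFrame, path) -> None:
    validate_step_annotations(df).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# blood gas
# ---------------------------------------------------------------------------

def validate_blood_gas(
    df: pd.DataFrame,
    annotations: Optional[pd.DataFrame] = None,
    source: str = "blood gas",
) -> pd.DataFrame:
    missing = [c for c in BLOOD_GAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing columns {missing}")
    df = df[BLOOD_GAS_COLUMNS].copy().sort_values("step_index")
    df = df.reset_index(drop=True)
    if (df["pao2_mmhg"] <= 0).any():
        k = int(df.index[df["pao2_mmhg"] <= 0][0])
        raise ValidationError(
            f"{source}: PaO2 must be > 0 mmHg (step {df['step_index'][k]})"
        )
    bad = (df["fio2"] <= 0) | (df["fio2"] > 1)
    if bad.any():
        k = int(df.index[bad][0])
        raise ValidationError(
            f"{source}: FiO2 must lie in (0, 1] (step {df['step_index'][k]}, "
            f"fio2={df['fio2'][k]})"
        )
    if annotations is not None:
        want = set(int(s) for s in annotations["step_index"])
        have = set(int(s) for s in df["step_index"])
        lacking = sorted(want - have)
        if lacking:
            raise ValidationError(
                f"{source}: missing blood-gas rows for step_index {lacking}"
            )
    return df


def read_blood_gas(path, annotations: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_blood_gas(df, annotations=annotations, source=str(path))


def write_blood_gas(df: pd.DataFrame, path) -> None:
    validate_blood_gas(df).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# per-step maps table (preprocess output / regional+titration input)
# ---------------------------------------------------------------------------

AER_COLUMNS = [f"aer_{i + 1:04d}" for i in range(N_PIXELS)]
VENT_COLUMNS = [f"vent_{i + 1:04d}" for i in range(N_PIXELS)]


def write_step_maps(steps, path) -> None:
    """Write per-step aeration/ventilation maps as one wide CSV row per step."""
    rows = []
    for s in steps:
        row = {"step_index": s.step_index, "mpaw_cmh2o": s.mpaw}
        row.update(zip(AER_COLUMNS, s.aeration.values.ravel()))
        row.update(zip(VENT_COLUMNS, s.ventilation.values.ravel()))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_step_maps(path):
    """Read the per-step maps CSV back into a list of :class:`StepMaps`."""
    from .core import AerationMap, StepMaps, VentilationMap

    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["step_index", "mpaw_cmh2o"] + AER_COLUMNS + VENT_COLUMNS
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: step-maps CSV missing {len(missing)} columns "
            f"(first: {missing[0]})"
        )
    steps = []
    for _, row in df.sort_values("step_index").iterrows():
        mpaw = float(row["mpaw_cmh2o"])
        aer = row[AER_COLUMNS].to_numpy(dtype=float).reshape(GRID_ROWS, GRID_COLS)
        vent = row[VENT_COLUMNS].to_numpy(dtype=float).reshape(GRID_ROWS, GRID_COLS)
        steps.append(
            StepMaps(
                step_index=int(row["step_index"]),
                mpaw=mpaw,
                aeration=AerationMap(aer, mpaw=mpaw),
                ventilation=VentilationMap(vent, mpaw=mpaw),
            )
        )
    mpaws = [s.mpaw for s in steps]
    if any(b >= a for a, b in zip(mpaws, mpaws[1:])):
        raise ValidationError(f"{path}: mpaw_cmh2o must be strictly decreasing")
    return steps


# ---------------------------------------------------------------------------
# titration report (JSON)
# ---------------------------------------------------------------------------

def _jsonable(x):
    if x is None or isinstance(x, (str, bool)):
        return x
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        return None if math.isnan(float(x)) else float(x)
    raise TypeError(f"cannot serialize {type(x)!r}")


def report_dict(result: TitrationResult, config: Optional[dict] = None) -> dict:
    """Assemble the JSON-serializable report for a :class:`TitrationResult`."""
    sel = {}
    for s in (result.by_oxygenation, result.by_cov, result.by_regions):
        sel[s.method] = {
            "mpaw_cmh2o": _jsonable(s.mpaw),
            "note": s.note,
        }
    curves = [
        {k: _jsonable(v) for k, v in rec.items()}
        for rec in result.curves.to_dict(orient="records")
    ]
    return {
        "schema": REPORT_SCHEMA,
        "optimal_mpaw": sel,
        "disagreements_cmh2o": {
            k: _jsonable(v) for k, v in result.disagreements.items()
        },
        "per_step": curves,
        "config": config or {},
    }


def validate_report(report: dict) -> dict:
    if report.get("schema") != REPORT_SCHEMA:
        raise ValidationError(
            f"report schema {report.get('schema')!r} != {REPORT_SCHEMA!r}"
        )
    for key in ("optimal_mpaw", "disagreements_cmh2o", "per_step"):
        if key not in report:
            raise ValidationError(f"report: missing key '{key}'")
    for method in ("oxygenation", "cov", "regions"):
        if method not in report["optimal_mpaw"]:
            raise ValidationError(f"report: missing method '{method}'")
    return report


def write_result_report(result: TitrationResult, path, config: Optional[dict] = None) -> dict:
    rep = report_dict(result, config=config)
    with open(path, "w") as fh:
        json.dump(rep, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return rep


def read_result_report(path) -> dict:
    with open(path) as fh:
        return validate_report(json.load(fh))
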