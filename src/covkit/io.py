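"""CSV readers for the domain objects and deterministic TSV/JSON reporting.

All inputs are UTF-8, comma-separated, header-required CSV; concentrations
are always uM in files. Validation errors carry row context. Outputs are
deterministic: fixed field order, floats to 4 significant decimals in TSV
and full precision in JSON, so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import pandas as pd

from .kinetics import InactivationObservation, ProgressCurve
from .screening import PlateLayout, ScreenResult, WellSpec

__all__ = [
    "read_observations",
    "read_response",
    "read_counts",
    "read_plates",
    "write_report",
]

OBS_COLUMNS = ["id", "I_uM", "E0", "Et", "t_min"]
RESPONSE_COLUMNS = ["I_uM", "pct_inhibition"]
READINGS_COLUMNS = ["plate_id", "well", "time_min", "A340"]
LAYOUT_COLUMNS = ["plate_id", "well", "role", "compound_id", "conc_uM"]


def _require_columns(frame: pd.DataFrame, columns: list[str], path: Path | str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(frame: pd.DataFrame, columns: list[str], path: Path | str) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[converted.isna() & out[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2} "
                f"(value {out.loc[bad[0], col]!r})"
            )
        if converted.isna().any():
            raise ValueError(f"{path}: empty cell in column {col!r}")
        out[col] = converted
    return out


def read_observations(path: str | Path) -> list[InactivationObservation]:
    """Read an inactivation-observation CSV (id, I_uM, E0, Et, t_min)."""
    frame = pd.read_csv(path)
    _require_columns(frame, OBS_COLUMNS, path)
    frame = _numeric(frame, ["I_uM", "E0", "Et", "t_min"], path)
    observations = []
    for idx, row in frame.iterrows():
        try:
            observations.append(
                InactivationObservation(
                    I=row["I_uM"], E0=row["E0"], Et=row["Et"], t=row["t_min"]
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: row {idx + 2} (id={row['id']}): {err}") from err
    return observations


def read_response(path: str | Path) -> list[tuple[float, float]]:
    """Read a concentration-response CSV (I_uM, pct_inhibition)."""
    frame = pd.read_csv(path)
    _require_columns(frame, RESPONSE_COLUMNS, path)
    frame = _numeric(frame, RESPONSE_COLUMNS, path)
    return [(float(r["I_uM"]), float(r["pct_inhibition"])) for _, r in frame.iterrows()]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a spectral-count CSV (protein_id, description, t_rep*, c_rep*)."""
    frame = pd.read_csv(path)
    for col in ("protein_id", "description"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dupes = frame["protein_id"][frame["protein_id"].duplicated()]
    if not dupes.empty:
        first = dupes.iloc[0]
        row = frame.index[frame["protein_id"] == first][1] + 2
        raise ValueError(f"{path}: duplicate protein id {first!r} at row {row}")
    rep_cols = [c for c in frame.columns if c.startswith(("t_rep", "c_rep"))]
    if not rep_cols:
        raise ValueError(f"{path}: no replicate count columns (t_rep*/c_rep*)")
    return _numeric(frame, rep_cols, path)


def read_plates(
    readings_path: str | Path, layout_path: str | Path
) -> list[tuple[dict[str, ProgressCurve], PlateLayout]]:
    """Read plate readings and layout CSVs into (readings, layout) pairs."""
    readings = pd.read_csv(readings_path)
    _require_columns(readings, READINGS_COLUMNS, readings_path)
    readings = _numeric(readings, ["time_min", "A340"], readings_path)
    layout = pd.read_csv(layout_path)
    _require_columns(layout, LAYOUT_COLUMNS, layout_path)

    plates = []
    for plate_id, plate_layout in layout.groupby("plate_id", sort=True):
        wells: dict[str, WellSpec] = {}
        for idx, row in plate_layout.iterrows():
            well = str(row["well"])
            if well in wells:
                raise ValueError(f"{layout_path}: duplicate well {well!r} on plate {plate_id}")
            role = str(row["role"])
            if role == "compound":
                wells[well] = WellSpec(
                    role="compound",
                    compound_id=str(row["compound_id"]),
                    conc_uM=float(row["conc_uM"]),
                )
            elif role in ("control", "blank"):
                wells[well] = WellSpec(role=role)  # type: ignore[arg-type]
            else:
                raise ValueError(f"{layout_path}: row {idx + 2}: unknown role {role!r}")
        plate_reads = readings[readings["plate_id"] == plate_id]
        curves: dict[str, ProgressCurve] = {}
        for well, group in plate_reads.groupby("well"):
            group = group.sort_values("time_min")
            curves[str(well)] = ProgressCurve(
                tuple(group["time_min"]), tuple(group["A340"])
            )
        plates.append((curves, PlateLayout(plate_id=str(plate_id), wells=wells)))
    if not plates:
        raise ValueError(f"{layout_path}: no plates found")
    return plates


def _sig4(value: float) -> str:
    if isinstance(value, float):
        if math.isnan(value):
            return "nan"
        return f"{value:.4g}"
    return str(value)


def write_report(result: Any, path: str | Path, fmt: str = "json") -> None:
    """Write a stage result deterministically as JSON or TSV.

    Dataclasses and ScreenResult/DataFrame results are supported; TSV
    rounds floats to 4 significant decimals, JSON keeps full precision.
    """
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        frame = result
    elif isinstance(result, ScreenResult):
        rows = []
        for cid in sorted(result.inhibition, key=lambda c: result.ranks.get(c, 0)):
            row: dict[str, Any] = {"compound_id": cid}
            for conc in sorted(result.inhibition[cid]):
                row[f"pct_inh_{conc:g}"] = result.inhibition[cid][conc]
            if result.ranks:
                row["rank"] = result.ranks[cid]
                row["hit"] = result.hits[cid]
            rows.append(row)
        frame = pd.DataFrame(rows)
    elif dataclasses.is_dataclass(result) and not isinstance(result, type):
        record = dataclasses.asdict(result)
        flat: dict[str, Any] = {}
        for key, value in record.items():
            if isinstance(value, dict):
                for k2, v2 in value.items():
                    flat[f"{key}.{k2}"] = v2
            else:
                flat[key] = value
        frame = pd.DataFrame([flat])
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")

    if fmt == "json":
        records = frame.to_dict(orient="records")
        payload = records[0] if len(records) == 1 else records
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    elif fmt == "tsv":
        formatted = frame.map(lambda v: _sig4(v) if isinstance(v, float) else v)
        formatted.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
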