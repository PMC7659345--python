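"""Delimited-text and structured-config I/O for every data modality.

All tabular interchange is comma-separated UTF-8 with '.' decimals and '#'
comment lines; numeric output uses 17 significant digits so that
write → read round-trips are exact to floating-point resolution.

Formats
-------
ΔA matrix        first row ``time_s`` + wavelengths (nm); one row per delay
                 time: time (s) followed by ΔA values.
I–V table        columns ``voltage_mV, current_pA[, sem_pA], condition_id``.
conditions file  YAML mapping condition_id → ions (per-ion in/out mM, charge,
                 rel_permeability) and temperature_K.
trace table      two columns with '#key: value' metadata header lines.
reports          YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .ephys import (
    DecayTrace,
    DoseResponseCurve,
    IonSpecies,
    IVCurve,
    RecordingConditions,
)
from .photocycle import TransientDataset

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_iv_tables",
    "write_iv_tables",
    "read_conditions",
    "write_conditions",
    "read_trace",
    "write_trace",
    "read_report",
    "write_report",
]

_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed delimited file; the message names the offending line."""


def _data_lines(path: Path) -> list[tuple[int, str]]:
    lines = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        lines.append((lineno, stripped))
    return lines


def read_matrix(path: str | Path) -> TransientDataset:
    """Read a ΔA(λ, t) matrix (first row wavelengths, first column time)."""
    path = Path(path)
    lines = _data_lines(path)
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    header_no, header = lines[0]
    tokens = header.split(",")
    try:
        wavelengths = np.array([float(tok) for tok in tokens[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}:{header_no}: non-numeric wavelength header: {exc}") from None
    n_wl = wavelengths.size
    times, rows = [], []
    for lineno, line in lines[1:]:
        cells = line.split(",")
        if len(cells) != n_wl + 1:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {n_wl + 1})"
            )
        try:
            values = [float(c) for c in cells]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell: {exc}") from None
        times.append(values[0])
        rows.append(values[1:])
    # file rows are time-indexed; the in-memory matrix is (wavelength, time)
    return TransientDataset(np.array(times), wavelengths, np.array(rows).T)


def write_matrix(path: str | Path, data: TransientDataset) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# transient absorption matrix: rows = time (s), columns = wavelength (nm)\n")
        fh.write("time_s," + ",".join(_FMT % w for w in data.wavelengths) + "\n")
        for i, t in enumerate(data.times):
            fh.write(_FMT % t + "," + ",".join(_FMT % v for v in data.delta_a[:, i]) + "\n")


# ---------------------------------------------------------------------------
# I–V tables and conditions


def read_conditions(path: str | Path) -> dict[str, RecordingConditions]:
    """YAML conditions file → condition_id → RecordingConditions."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    out = {}
    for cid, block in raw.items():
        ions = [
            IonSpecies(
                name=str(name),
                z=int(spec["z"]),
                conc_in=float(spec["conc_in_mM"]),
                conc_out=float(spec["conc_out_mM"]),
                rel_permeability=float(spec.get("rel_permeability", 0.0)),
            )
            for name, spec in block["ions"].items()
        ]
        out[str(cid)] = RecordingConditions(
            ions=ions, temperature=float(block.get("temperature_K", 295.0))
        )
    return out


def write_conditions(path: str | Path, conditions: dict[str, RecordingConditions]) -> None:
    doc = {}
    for cid, cond in conditions.items():
        doc[cid] = {
            "temperature_K": cond.temperature,
            "ions": {
                ion.name: {
                    "z": ion.z,
                    "conc_in_mM": ion.conc_in,
                    "conc_out_mM": ion.conc_out,
                    "rel_permeability": ion.rel_permeability,
                }
                for ion in cond.ions
            },
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_iv_tables(
    table_path: str | Path, conditions_path: str | Path
) -> list[IVCurve]:
    """I–V table + conditions file → one IVCurve per condition_id."""
    df = pd.read_csv(table_path, comment="#")
    required = {"voltage_mV", "current_pA", "condition_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{table_path}: missing columns {sorted(missing)}")
    conditions = read_conditions(conditions_path)
    curves = []
    for cid, group in df.groupby("condition_id", sort=False):
        if str(cid) not in conditions:
            raise ParseError(f"{table_path}: condition_id {cid!r} not in conditions file")
        group = group.sort_values("voltage_mV")
        sem = group["sem_pA"].to_numpy() if "sem_pA" in group.columns else None
        curves.append(
            IVCurve(
                group["voltage_mV"].to_numpy(),
                group["current_pA"].to_numpy(),
                conditions=conditions[str(cid)],
                sem=sem,
            )
        )
    return curves


def write_iv_tables(
    table_path: str | Path,
    conditions_path: str | Path,
    curves: Iterable[IVCurve],
    condition_ids: Iterable[str] | None = None,
) -> None:
    curves = list(curves)
    ids = list(condition_ids) if condition_ids else [f"cond{i}" for i in range(len(curves))]
    frames = []
    for cid, curve in zip(ids, curves):
        frame = pd.DataFrame(
            {"voltage_mV": curve.voltages, "current_pA": curve.currents}
        )
        if curve.sem is not None:
            frame["sem_pA"] = curve.sem
        frame["condition_id"] = cid
        frames.append(frame)
    pd.concat(frames).to_csv(table_path, index=False, float_format=_FMT)
    write_conditions(conditions_path, {cid: c.conditions for cid, c in zip(ids, curves)})


# ---------------------------------------------------------------------------
# two-column traces with metadata


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
    """Two-column delimited file with '#key: value' metadata headers."""
    path = Path(path)
    meta: dict[str, str] = {}
    xs, ys = [], []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        cells = stripped.split(",")
        if len(cells) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
        try:
            xs.append(float(cells[0]))
            ys.append(float(cells[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell: {exc}") from None
    return np.array(xs), np.array(ys), meta


def write_trace(
    path: str | Path,
    x: np.ndarray,
    y: np.ndarray,
    meta: dict[str, object] | None = None,
    columns: tuple[str, str] = ("x", "y"),
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"#{key}: {value}\n")
        fh.write(f"#columns: {columns[0]},{columns[1]}\n")
        for xi, yi in zip(x, y):
            fh.write(_FMT % xi + "," + _FMT % yi + "\n")


def read_dose_response(path: str | Path) -> DoseResponseCurve:
    c, i, meta = read_trace(path)
    order = np.argsort(c)
    return DoseResponseCurve(c[order], i[order], voltage=float(meta.get("voltage_mV", 80.0)))


def read_decay_trace(path: str | Path) -> DecayTrace:
    t, i, _ = read_trace(path)
    return DecayTrace(t, i)


# ---------------------------------------------------------------------------
# reports


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(yaml.safe_dump(report, sort_keys=False), encoding="utf-8")


def read_report(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))
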