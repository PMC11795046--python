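"""Durable, replayable run provenance on plain text.

A run store is a directory of diff-friendly text files:

* ``config.json``        — canonical config snapshot
* ``doses.csv``          — one row per induced well (plate, well, dose, readout, objective)
* ``measurements.csv``   — every plate-reader reading, long format
* ``decisions.jsonl``    — one optimizer decision per line

Floats are serialized with shortest round-trip repr, so
``read_run(write_run(s)) == s`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .dose import Dose
from .errors import StoreFormatError
from .loop import RunStore
from .twin import WellMeasurement, CONTROL_ROWS, CULTURE_ROWS, N_COLUMNS

__all__ = ["write_run", "read_run", "PlateMap", "export_plate_map"]

_MEAS_COLUMNS = [
    "plate", "row", "column", "time_h", "od600", "fluorescence", "role", "inducer", "enzyme",
]
_DOSE_COLUMNS = ["plate", "row", "column", "inducer", "enzyme", "fluorescence", "objective"]


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):  # incl. np.float64; repr of builtin float round-trips
        return repr(float(v))
    return str(v)


def _write_csv(path: Path, columns: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def write_run(store: RunStore, path: str | Path) -> Path:
    """Persist a run store into directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.json", "w", encoding="utf-8") as fh:
        json.dump(store.config, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_csv(
        path / "doses.csv",
        _DOSE_COLUMNS,
        [[r[c] for c in _DOSE_COLUMNS] for r in store.dose_records],
    )
    _write_csv(
        path / "measurements.csv",
        _MEAS_COLUMNS,
        [
            [
                m.plate_index, m.row, m.column, m.time_h, m.od600, m.fluorescence, m.role,
                None if m.dose is None else m.dose.inducer,
                None if m.dose is None or m.dose.enzyme is None else m.dose.enzyme,
            ]
            for m in store.measurements
        ],
    )
    with open(path / "decisions.jsonl", "w", encoding="utf-8") as fh:
        for d in store.decisions:
            fh.write(json.dumps(d, sort_keys=True) + "\n")
    return path


def _opt_float(v) -> float | None:
    return None if v == "" or v is None else float(v)


def read_run(path: str | Path) -> RunStore:
    """Load a run store written by :func:`write_run`; exact numeric round-trip."""
    path = Path(path)
    if not path.is_dir():
        raise StoreFormatError(f"run store directory not found: {path}")
    for name in ("config.json", "doses.csv", "measurements.csv", "decisions.jsonl"):
        if not (path / name).is_file():
            raise StoreFormatError(f"run store is missing {name}")
    with open(path / "config.json", encoding="utf-8") as fh:
        config = json.load(fh)

    dose_records = []
    for rec in _read_csv_rows(path / "doses.csv", _DOSE_COLUMNS):
        dose_records.append(
            {
                "plate": int(rec["plate"]),
                "row": rec["row"],
                "column": int(rec["column"]),
                "inducer": float(rec["inducer"]),
                "enzyme": _opt_float(rec["enzyme"]),
                "fluorescence": float(rec["fluorescence"]),
                "objective": float(rec["objective"]),
            }
        )

    measurements = []
    for rec in _read_csv_rows(path / "measurements.csv", _MEAS_COLUMNS):
        inducer = _opt_float(rec["inducer"])
        enzyme = _opt_float(rec["enzyme"])
        dose = None if inducer is None else Dose(inducer, enzyme)
        measurements.append(
            WellMeasurement(
                plate_index=int(rec["plate"]),
                row=rec["row"],
                column=int(rec["column"]),
                time_h=float(rec["time_h"]),
                od600=float(rec["od600"]),
                fluorescence=float(rec["fluorescence"]),
                role=rec["role"],
                dose=dose,
            )
        )

    decisions = []
    with open(path / "decisions.jsonl", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                decisions.append(json.loads(line))
            except json.JSONDecodeError as err:
                raise StoreFormatError(
                    f"decisions.jsonl line {i}: invalid JSON ({err.msg})"
                ) from None
    return RunStore(
        config=config,
        dose_records=dose_records,
        measurements=measurements,
        decisions=decisions,
    )


def _read_csv_rows(path: Path, columns: list[str]):
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header != columns:
            raise StoreFormatError(f"{path.name}: unexpected header {header}")
        for i, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(columns):
                raise StoreFormatError(f"{path.name} line {i}: expected {len(columns)} fields")
            yield dict(zip(columns, parts))


@dataclass(frozen=True)
class PlateMap:
    """8×12 grid of well roles/doses for one plate, with its barcode."""

    plate_index: int
    barcode: str
    grid: pd.DataFrame  # index A..H, columns 1..12

    def to_csv(self, path: str | Path) -> None:
        self.grid.to_csv(path, index_label="row")


def export_plate_map(store: RunStore, plate_index: int) -> PlateMap:
    """Render one plate of a run as a 96-cell grid.

    Culture cells show the dose fraction(s) ("x=8.0" or "x=8.0;e=42.0");
    rows A and H show their control role.  Deterministic and idempotent.
    """
    rows = list(CONTROL_ROWS[:1]) + list(CULTURE_ROWS) + list(CONTROL_ROWS[1:])
    grid = pd.DataFrame("", index=rows, columns=range(1, N_COLUMNS + 1), dtype=object)
    seen_roles: dict[tuple[str, int], str] = {}
    for m in store.measurements:
        if m.plate_index != plate_index:
            continue
        key = (m.row, m.column)
        if key in seen_roles:
            continue
        if m.role == "culture":
            label = f"x={m.dose.inducer:g}"
            if m.dose.enzyme is not None:
                label += f";e={m.dose.enzyme:g}"
        else:
            label = m.role
        seen_roles[key] = label
        grid.loc[m.row, m.column] = label
    if not seen_roles:
        for r in rows:
            for c in range(1, N_COLUMNS + 1):
                grid.loc[r, c] = "control" if r in CONTROL_ROWS else ""
    seed = store.config.get("seed", 0)
    return PlateMap(
        plate_index=plate_index,
        barcode=f"RUN{seed:06d}-P{plate_index:02d}",
        grid=grid,
    )
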