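"""Data model and I/O for 96-well plate layouts and plate-reader exports.

Conventions used throughout the package, enforced here at parse time:

* wells are addressed ``A1``..``H12`` externally and by 0-based row-major
  ``(row, column)`` indices internally;
* times are minutes, volumes are microlitres, concentrations are mM,
  optical densities are dimensionless.

Two reader-export dialects are supported: a *wide* dialect (8x12 grids,
kinetic reads stacked as blocks each preceded by a ``time,<minutes>``
line) and a tidy *long* dialect (``well,time,value`` rows).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ValidationError

ROWS = "ABCDEFGH"
N_ROWS = 8
N_COLS = 12

ROLES = frozenset({"sample", "standard", "blank", "control"})

ALL_WELLS = tuple(f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1))


def well_to_index(address: str) -> tuple[int, int]:
    """Return 0-based (row, column) indices for an ``A1``-style address."""
    addr = str(address).strip().upper()
    if len(addr) < 2 or addr[0] not in ROWS:
        raise FormatError(f"malformed well address {address!r}")
    try:
        col = int(addr[1:])
    except ValueError:
        raise FormatError(f"malformed well address {address!r}") from None
    if not 1 <= col <= N_COLS:
        raise FormatError(f"well address {address!r} outside the 8x12 plate")
    return ROWS.index(addr[0]), col - 1


def index_to_well(row: int, col: int) -> str:
    """Inverse of :func:`well_to_index`."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise FormatError(f"plate index ({row}, {col}) outside the 8x12 plate")
    return f"{ROWS[row]}{col + 1}"


@dataclass(frozen=True)
class WellSpec:
    """Role and contents of one well in a plate layout."""

    role: str
    content: str = ""
    tip_id: int | None = None
    programmed_volume: float | None = None  # uL
    standard_concentration: float | None = None  # mM
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown well role {self.role!r}; expected one of {sorted(ROLES)}")
        if self.tip_id is not None and self.tip_id < 1:
            raise ValidationError(f"tip_id must be >= 1, got {self.tip_id}")


@dataclass
class PlateLayout:
    """Plate map: well address -> :class:`WellSpec`."""

    plate_id: str
    wells: dict[str, WellSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for addr in self.wells:
            well_to_index(addr)

    def wells_with_role(self, role: str) -> dict[str, WellSpec]:
        return {a: s for a, s in self.wells.items() if s.role == role}


_LAYOUT_COLUMNS = [
    "well", "role", "content", "tip_id", "programmed_volume",
    "standard_concentration", "replicate",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    return float(s)


def _opt_int(value) -> int | None:
    f = _opt_float(value)
    return None if f is None else int(f)


def parse_layout(source: str | Path, plate_id: str = "plate") -> PlateLayout:
    """Parse a plate-map CSV into a validated :class:`PlateLayout`.

    ``source`` may be a path or the CSV text itself.  Required columns:
    well, role; the rest may be blank where the role permits.  Standard
    wells must carry a concentration.
    """
    text = _read_text(source)
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    missing = {"well", "role"} - set(df.columns)
    if missing:
        raise FormatError(f"layout is missing required columns: {sorted(missing)}")
    wells: dict[str, WellSpec] = {}
    for i, row in df.iterrows():
        addr_raw = row["well"].strip()
        r, c = well_to_index(addr_raw)
        addr = index_to_well(r, c)
        if addr in wells:
            raise FormatError(f"duplicate well {addr} in layout (row {i + 2})")
        try:
            spec = WellSpec(
                role=row["role"].strip(),
                content=row.get("content", "").strip(),
                tip_id=_opt_int(row.get("tip_id", "")),
                programmed_volume=_opt_float(row.get("programmed_volume", "")),
                standard_concentration=_opt_float(row.get("standard_concentration", "")),
                replicate_id=(row.get("replicate", "").strip() or None),
            )
        except ValueError as exc:
            raise FormatError(f"well {addr}: {exc}") from exc
        if spec.role == "standard" and spec.standard_concentration is None:
            raise ValidationError(f"standard well {addr} has no standard_concentration")
        wells[addr] = spec
    return PlateLayout(plate_id=plate_id, wells=wells)


def serialize_layout(layout: PlateLayout) -> str:
    """Write a :class:`PlateLayout` back to CSV text (round-trips with parse)."""
    rows = []
    for addr in sorted(layout.wells, key=well_to_index):
        s = layout.wells[addr]
        rows.append({
            "well": addr,
            "role": s.role,
            "content": s.content,
            "tip_id": "" if s.tip_id is None else s.tip_id,
            "programmed_volume": "" if s.programmed_volume is None else repr(s.programmed_volume),
            "standard_concentration": ""
            if s.standard_concentration is None else repr(s.standard_concentration),
            "replicate": s.replicate_id or "",
        })
    df = pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)
    return df.to_csv(index=False)


@dataclass
class ReaderData:
    """Per-well absorbance values, endpoint or kinetic.

    For kinetic data all wells share the ``times`` axis (minutes) and each
    value is a 1-D array; for endpoint data ``times`` is None and each value
    is a scalar.
    """

    plate_id: str
    wavelength: float
    mode: str  # "endpoint" | "kinetic"
    values: dict[str, float | np.ndarray]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("endpoint", "kinetic"):
            raise ValidationError(f"unknown reader mode {self.mode!r}")
        for addr in self.values:
            well_to_index(addr)
        if self.mode == "kinetic":
            if self.times is None or len(self.times) < 2:
                raise ValidationError("kinetic data needs a shared time axis of length >= 2")
            self.times = np.asarray(self.times, dtype=float)
            n = len(self.times)
            for addr, v in self.values.items():
                arr = np.asarray(v, dtype=float)
                if arr.shape != (n,):
                    raise ValidationError(
                        f"well {addr}: series length {arr.size} != time axis length {n}")
                if not np.all(np.isfinite(arr)):
                    raise ValidationError(f"well {addr}: non-finite absorbance")
                self.values[addr] = arr
        else:
            for addr, v in self.values.items():
                if not np.isfinite(float(v)):
                    raise ValidationError(f"well {addr}: non-finite absorbance")
                self.values[addr] = float(v)

    def grid(self, read_index: int | None = None) -> np.ndarray:
        """Return an 8x12 array (NaN where a well is absent)."""
        g = np.full((N_ROWS, N_COLS), np.nan)
        for addr, v in self.values.items():
            r, c = well_to_index(addr)
            g[r, c] = float(v) if self.mode == "endpoint" else float(np.asarray(v)[read_index or 0])
        return g


def _read_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    s = str(source)
    if "\n" not in s and "," not in s and Path(s).exists():
        return Path(s).read_text(encoding="utf-8")
    return s


def _parse_grid_block(lines: list[str], start_line: int) -> np.ndarray:
    if len(lines) != N_ROWS:
        raise FormatError(f"wide block starting at line {start_line} has {len(lines)} rows, expected {N_ROWS}")
    grid = np.empty((N_ROWS, N_COLS))
    for r, line in enumerate(lines):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != N_COLS:
            raise FormatError(
                f"row {ROWS[r]} (line {start_line + r}) has {len(cells)} columns, expected {N_COLS}")
        for c, cell in enumerate(cells):
            try:
                grid[r, c] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric cell {cell!r} at well {index_to_well(r, c)}") from None
    return grid


def parse_reader_export(source: str | Path, dialect: str,
                        plate_id: str = "plate", wavelength: float = 350.0) -> ReaderData:
    """Parse a plate-reader export in the ``wide`` or ``long`` dialect.

    Wide: one or more 8x12 comma-separated grids; each kinetic read is
    preceded by a ``time,<minutes>`` line, endpoint exports have a single
    bare grid.  Long: CSV with columns ``well,time,value`` (``time`` blank
    for endpoint reads).
    """
    text = _read_text(source)
    if dialect == "wide":
        return _parse_wide(text, plate_id, wavelength)
    if dialect == "long":
        return _parse_long(text, plate_id, wavelength)
    raise ConfigError(f"unknown reader dialect {dialect!r}; expected 'wide' or 'long'")


def _parse_wide(text: str, plate_id: str, wavelength: float) -> ReaderData:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty reader export")
    blocks: list[tuple[float | None, np.ndarray]] = []
    i = 0
    while i < len(lines):
        t: float | None = None
        if lines[i].lower().startswith("time"):
            parts = lines[i].split(",")
            try:
                t = float(parts[1])
            except (IndexError, ValueError):
                raise FormatError(f"malformed time header {lines[i]!r}") from None
            i += 1
        blocks.append((t, _parse_grid_block(lines[i:i + N_ROWS], i + 1)))
        i += N_ROWS
    if len(blocks) == 1 and blocks[0][0] is None:
        values = {index_to_well(r, c): blocks[0][1][r, c]
                  for r in range(N_ROWS) for c in range(N_COLS)}
        return ReaderData(plate_id, wavelength, "endpoint", values)
    if any(t is None for t, _ in blocks):
        raise FormatError("kinetic wide export: every block needs a 'time,<minutes>' header")
    times = np.array([t for t, _ in blocks], dtype=float)
    stack = np.stack([g for _, g in blocks])  # (n_times, 8, 12)
    values = {index_to_well(r, c): stack[:, r, c]
              for r in range(N_ROWS) for c in range(N_COLS)}
    return ReaderData(plate_id, wavelength, "kinetic", values, times=times)


def _parse_long(text: str, plate_id: str, wavelength: float) -> ReaderData:
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    missing = {"well", "value"} - set(df.columns)
    if missing:
        raise FormatError(f"long export missing columns: {sorted(missing)}")
    has_time = "time" in df.columns and df["time"].str.strip().ne("").any()
    vals: dict[str, float] | dict[str, dict[float, float]] = {}
    for i, row in df.iterrows():
        addr = index_to_well(*well_to_index(row["well"]))
        try:
            v = float(row["value"])
        except ValueError:
            raise FormatError(f"non-numeric value {row['value']!r} at well {addr}") from None
        if has_time:
            t = float(row["time"])
            vals.setdefault(addr, {})[t] = v
        else:
            if addr in vals:
                raise FormatError(f"duplicate endpoint value for well {addr}")
            vals[addr] = v
    if not has_time:
        return ReaderData(plate_id, wavelength, "endpoint", dict(vals))
    times = np.array(sorted({t for series in vals.values() for t in series}))
    values: dict[str, np.ndarray] = {}
    for addr, series in vals.items():
        if set(series) != set(times.tolist()):
            raise ValidationError(f"well {addr} does not share the common time axis")
        values[addr] = np.array([series[t] for t in times])
    return ReaderData(plate_id, wavelength, "kinetic", values, times=times)


def serialize_reader_export(reader: ReaderData, dialect: str) -> str:
    """Inverse of :func:`parse_reader_export` for fully populated plates."""
    if dialect == "long":
        rows = []
        for addr in sorted(reader.values, key=well_to_index):
            if reader.mode == "endpoint":
                rows.append({"well": addr, "time": "", "value": repr(reader.values[addr])})
            else:
                for t, v in zip(reader.times, reader.values[addr]):
                    rows.append({"well": addr, "time": repr(float(t)), "value": repr(float(v))})
        return pd.DataFrame(rows, columns=["well", "time", "value"]).to_csv(index=False)
    if dialect == "wide":
        def fmt(grid: np.ndarray) -> str:
            return "\n".join(",".join(repr(float(x)) for x in row) for row in grid)
        if reader.mode == "endpoint":
            return fmt(reader.grid()) + "\n"
        out = []
        for i, t in enumerate(reader.times):
            out.append(f"time,{float(t)!r}")
            out.append(fmt(reader.grid(read_index=i)))
        return "\n".join(out) + "\n"
    raise ConfigError(f"unknown reader dialect {dialect!r}; expected 'wide' or 'long'")
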