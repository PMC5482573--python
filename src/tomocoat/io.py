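"""MRC2014 volume I/O, particle tables (TSV and STAR dialects), run configs.

Axis convention: in-memory density arrays are ``[z, y, x]`` with x the
fastest axis on disk (MAPC/MAPR/MAPS = 1/2/3), so maps open correctly in
standard viewers.  Coordinates in tables are 0-based voxel-center values;
this convention is written into every table header comment.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .core import DensityMap

#: mandatory particle-table columns; everything else rides along verbatim
PARTICLE_COLUMNS = ["particle_id", "vesicle_id", "x", "y", "z", "rot", "tilt", "psi"]
OPTIONAL_COLUMNS = ["shift_x", "shift_y", "shift_z", "cc", "half_set", "class"]

_TABLE_HEADER = (
    "# tomocoat particle table; coordinates are 0-based voxel-center; "
    "Euler angles rot/tilt/psi are ZXZ intrinsic, degrees"
)


# ---------------------------------------------------------------------------
# MRC


def write_mrc(density: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014 mode 2 (32-bit float) with voxel size and origin."""
    path = Path(path)
    g = gemmi.Ccp4Map()
    g.grid = gemmi.FloatGrid(np.ascontiguousarray(density.data.T, dtype=np.float32))
    nz, ny, nx = density.data.shape
    vs = float(density.voxel_size)
    g.grid.unit_cell = gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90.0, 90.0, 90.0)
    g.update_ccp4_header()
    for word, value in zip((50, 51, 52), density.origin):
        g.set_header_float(word, float(value))
    g.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> DensityMap:
    """Read an MRC2014 mode-2 map; error on any other data mode."""
    m = gemmi.read_ccp4_map(str(path))
    mode = m.header_i32(4)
    if mode != 2:
        raise ValueError(f"unsupported MRC data mode {mode}; only mode 2 (float32) is handled")
    data = np.array(m.grid, copy=True).T.astype(np.float32)
    nz, ny, nx = data.shape
    cell = m.grid.unit_cell
    vs = cell.a / nx
    origin = tuple(m.header_float(w) for w in (50, 51, 52))
    return DensityMap(data=data, voxel_size=float(vs), origin=origin)


# ---------------------------------------------------------------------------
# Particle tables


def validate_particle_table(table: pd.DataFrame) -> None:
    missing = [c for c in PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"particle table missing mandatory columns: {missing}")


def write_particles_tsv(table: pd.DataFrame, path: str | Path) -> None:
    validate_particle_table(table)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_particles_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    validate_particle_table(table)
    return table


def write_particles_star(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table as a single STAR data block with one loop."""
    validate_particle_table(table)
    lines = [_TABLE_HEADER, "", "data_particles", "", "loop_"]
    cols = list(table.columns)
    for i, col in enumerate(cols, start=1):
        lines.append(f"_{col} #{i}")
    for _, row in table.iterrows():
        lines.append("\t".join(_star_format(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def _star_format(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.6f}"
    return str(value)


def read_particles_star(path: str | Path) -> pd.DataFrame:
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            cols, rows = [], []
            continue
        if in_loop and line.startswith("_"):
            cols.append(line.split()[0].lstrip("_"))
            continue
        if in_loop:
            fields = line.split()
            if len(fields) != len(cols):
                raise ValueError(f"STAR row has {len(fields)} fields, expected {len(cols)}")
            rows.append(fields)
    if not cols:
        raise ValueError(f"no STAR loop found in {path}")
    table = pd.DataFrame(rows, columns=cols)
    for col in table.columns:
        raw_values = table[col]
        try:
            converted = pd.to_numeric(raw_values)
        except (ValueError, TypeError):
            continue
        if converted.dtype.kind == "f" and not raw_values.str.contains(r"[.eE]").any():
            converted = converted.astype(np.int64)
        table[col] = converted
    validate_particle_table(table)
    return table


def write_tilt_sidecar(path: str | Path, angles, order, doses, defoci) -> None:
    pd.DataFrame(
        {"tilt_angle": angles, "acquisition_order": order, "accumulated_dose": doses,
         "defocus_um": defoci}
    ).to_csv(path, sep="\t", index=False)


def read_tilt_sidecar(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run metadata


def write_run_log(path: str | Path, payload: dict) -> None:
    from . import __version__

    payload = dict(payload)
    payload.setdefault("tomocoat_version", __version__)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
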