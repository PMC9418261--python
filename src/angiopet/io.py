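"""Readers and writers: network CSV/VTK, field CSV/PNG/VTK, curve CSV.

All CSV output is written at 15 significant digits so that write -> read
round-trips reproduce values to double precision.  VTK files use the plain
ASCII legacy format (polydata for networks, structured points for fields).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import ScalarField, VectorField
from .network import VesselNetwork

__all__ = [
    "write_network", "read_network", "write_network_vtk",
    "write_field", "read_field", "write_field_png", "write_field_vtk",
    "write_curve", "read_curve",
]

_FFMT = "%.15g"


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

def network_frame(net: VesselNetwork, state=None) -> pd.DataFrame:
    """Tabulate a network (one row per segment) with optional flow state."""
    a, b, d = net.segment_arrays()
    n = len(a)
    ia, ja = np.divmod(a, net.n_side)
    ib, jb = np.divmod(b, net.n_side)
    h = net.grid_spacing_m
    df = pd.DataFrame({
        "segment_id": np.arange(n, dtype=int),
        "node_a": a, "node_b": b,
        "x_a_m": ja * h, "y_a_m": ia * h,
        "x_b_m": jb * h, "y_b_m": ib * h,
        "diameter_um": d,
        "length_um": np.full(n, net.length_um),
        "hematocrit": state.H if state is not None else np.zeros(n),
        "flow_m3_s": state.Q_b if state is not None else np.zeros(n),
        "viscosity_pa_s": state.mu_blood if state is not None else np.zeros(n),
    })
    return df


def write_network(net: VesselNetwork, path: str | Path, state=None) -> Path:
    """Write the CSV edge list.  A commented header line carries the lattice
    metadata needed for an exact round trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = (f"# n_side={net.n_side} grid_spacing_m={net.grid_spacing_m!r} "
            f"parent_nodes={','.join(map(str, net.parent_nodes)) or '-'}\n")
    buf = _io.StringIO()
    network_frame(net, state).to_csv(buf, index=False, float_format=_FFMT)
    path.write_text(meta + buf.getvalue())
    return path


def read_network(path: str | Path) -> tuple[VesselNetwork, pd.DataFrame]:
    """Read a network CSV back into a :class:`VesselNetwork` plus the full
    segment table (including any stored flow state columns)."""
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: missing network metadata header")
        kv = dict(item.split("=", 1) for item in meta[1:].split())
        df = pd.read_csv(fh)
    net = VesselNetwork(int(kv["n_side"]), float(kv["grid_spacing_m"]))
    for _, row in df.iterrows():
        net.add_segment(int(row["node_a"]), int(row["node_b"]), row["diameter_um"])
    if kv["parent_nodes"] != "-":
        net.parent_nodes = [int(x) for x in kv["parent_nodes"].split(",")]
    return net, df


def write_network_vtk(net: VesselNetwork, path: str | Path, state=None) -> Path:
    """Legacy ASCII VTK polydata: one line cell per segment, diameter (and
    flow state, if given) as cell data."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nodes = net.node_list()
    index = {nd: k for k, nd in enumerate(nodes)}
    a, b, d = net.segment_arrays()
    lines = [
        "# vtk DataFile Version 3.0",
        "angiopet vessel network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(nodes)} double",
    ]
    for nd in nodes:
        x, y = net.xy_m(int(nd))
        lines.append(f"{x:.15g} {y:.15g} 0")
    lines.append(f"LINES {len(a)} {3 * len(a)}")
    for ka, kb in zip(a, b):
        lines.append(f"2 {index[int(ka)]} {index[int(kb)]}")
    lines.append(f"CELL_DATA {len(a)}")
    lines.append("SCALARS diameter_um double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{x:.15g}" for x in d)
    if state is not None:
        for name, arr in (("flow_m3_s", state.Q_b), ("hematocrit", state.H)):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.15g}" for x in arr)
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# fields
# --------------------------------------------------------------------------

def write_field(fieldobj: ScalarField | VectorField, path: str | Path) -> Path:
    """CSV grid dump (row i = lattice row i).  Vector fields write two
    stacked blocks separated by a comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(fieldobj, ScalarField):
        header = (f"# scalar name={fieldobj.name or '-'} units={fieldobj.units or '-'} "
                  f"grid_spacing_m={fieldobj.grid_spacing!r}\n")
        body = "\n".join(",".join(_FFMT % v for v in row) for row in fieldobj.values)
        path.write_text(header + body + "\n")
    else:
        header = (f"# vector name={fieldobj.name or '-'} units={fieldobj.units or '-'} "
                  f"grid_spacing_m={fieldobj.grid_spacing!r}\n")
        bx = "\n".join(",".join(_FFMT % v for v in row) for row in fieldobj.vx)
        by = "\n".join(",".join(_FFMT % v for v in row) for row in fieldobj.vy)
        path.write_text(header + bx + "\n# component vy\n" + by + "\n")
    return path


def read_field(path: str | Path) -> ScalarField | VectorField:
    path = Path(path)
    text = path.read_text().strip().splitlines()
    meta = text[0]
    if not meta.startswith("#"):
        raise ValueError(f"{path}: missing field metadata header")
    parts = dict(item.split("=", 1) for item in meta[1:].split() if "=" in item)
    kind = meta[1:].split()[0]
    name = "" if parts.get("name") == "-" else parts.get("name", "")
    units = "" if parts.get("units") == "-" else parts.get("units", "")
    h = float(parts["grid_spacing_m"])
    rows = text[1:]
    if kind == "scalar":
        vals = np.array([[float(x) for x in r.split(",")] for r in rows])
        return ScalarField(vals, h, units, name)
    isep = rows.index("# component vy")
    vx = np.array([[float(x) for x in r.split(",")] for r in rows[:isep]])
    vy = np.array([[float(x) for x in r.split(",")] for r in rows[isep + 1:]])
    return VectorField(vx, vy, h, units, name)


def write_field_png(fieldobj: ScalarField, path: str | Path, cmap: str = "viridis",
                    title: str | None = None, annotate: str | None = None) -> Path:
    """Render a scalar field to PNG with a colorbar annotated with the value
    range; colormap fixed to viridis unless overridden."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    ext = fieldobj.grid_spacing * (fieldobj.shape[1] - 1)
    im = ax.imshow(fieldobj.values, origin="lower", cmap=cmap,
                   extent=(0, ext, 0, ext))
    cb = fig.colorbar(im, ax=ax)
    cb.set_label(fieldobj.units or "")
    vmin, vmax = float(np.min(fieldobj.values)), float(np.max(fieldobj.values))
    ax.set_title(title or f"{fieldobj.name} [{vmin:.3g}, {vmax:.3g}] {fieldobj.units}")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if annotate:
        ax.text(0.02, 0.02, annotate, transform=ax.transAxes, fontsize=6,
                color="white", alpha=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def write_field_vtk(fieldobj: ScalarField, path: str | Path) -> Path:
    """Legacy ASCII VTK structured points file for a scalar field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ny, nx = fieldobj.shape
    lines = [
        "# vtk DataFile Version 3.0",
        f"angiopet field {fieldobj.name}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {fieldobj.grid_spacing:.15g} {fieldobj.grid_spacing:.15g} 1",
        f"POINT_DATA {nx * ny}",
        f"SCALARS {fieldobj.name or 'value'} double 1",
        "LOOKUP_TABLE default",
    ]
    lines.extend(f"{v:.15g}" for v in fieldobj.values.ravel())
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# curves
# --------------------------------------------------------------------------

def write_curve(times_s, values, path: str | Path, value_name: str = "value") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": times_s, value_name: values}).to_csv(
        path, index=False, float_format=_FFMT)
    return path


def read_curve(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
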