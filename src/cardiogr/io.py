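"""Result output: ASCII VTU snapshots and CSV/JSON summaries.

The VTU writer emits plain-text XML unstructured grids (linear or quadratic
tetrahedra, VTK cell types 10 and 24) with point and cell data arrays, which
ParaView and VTK-based tools read directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import TetMesh

__all__ = ["write_vtu", "write_state_vtu"]

_VTK_TET = {4: 10, 10: 24}


def write_vtu(
    mesh: TetMesh,
    path: str | Path,
    *,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    nodes: np.ndarray | None = None,
) -> None:
    """Write the mesh (optionally with deformed ``nodes``) and data arrays."""
    nodes = mesh.nodes if nodes is None else nodes
    elems = mesh.elems
    nen = elems.shape[1]
    ctype = _VTK_TET[nen]

    def arr(a: np.ndarray) -> str:
        return " ".join(f"{v:.9g}" for v in np.asarray(a, dtype=float).ravel())

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{len(elems)}">',
        "<Points>",
        f'<DataArray type="Float64" NumberOfComponents="3" format="ascii">{arr(nodes)}</DataArray>',
        "</Points>",
        "<Cells>",
        f'<DataArray type="Int64" Name="connectivity" format="ascii">{" ".join(map(str, elems.ravel()))}</DataArray>',
        f'<DataArray type="Int64" Name="offsets" format="ascii">{" ".join(str(nen * (i + 1)) for i in range(len(elems)))}</DataArray>',
        f'<DataArray type="UInt8" Name="types" format="ascii">{" ".join(str(ctype) for _ in range(len(elems)))}</DataArray>',
        "</Cells>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, data in point_data.items():
            data = np.asarray(data, dtype=float)
            nc = 1 if data.ndim == 1 else data.shape[1]
            lines.append(
                f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{nc}" '
                f'format="ascii">{arr(data)}</DataArray>'
            )
        lines.append("</PointData>")
    if cell_data:
        lines.append("<CellData>")
        for name, data in cell_data.items():
            data = np.asarray(data, dtype=float)
            nc = 1 if data.ndim == 1 else data.shape[1]
            lines.append(
                f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{nc}" '
                f'format="ascii">{arr(data)}</DataArray>'
            )
        lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_state_vtu(model, u: np.ndarray, path: str | Path) -> None:
    """Snapshot of a G&R state: displacement, per-constituent density,
    remodeling stretch, fiber stress and local mass change (cell averages)."""
    disc = model.disc
    nq = disc.w.shape[1]

    def cell_avg(gp_field: np.ndarray) -> np.ndarray:
        return gp_field.reshape(-1, nq, *gp_field.shape[1:]).mean(axis=1)

    sig, _, _ = model.constituent_stresses(u)
    cd = {
        "mass_change": cell_avg(model.fields.mass_ratio(model.mix) - 1.0),
        "sigma_myocyte": cell_avg(sig[:, 0]),
        "sigma_collagen_mean": cell_avg(sig[:, 1:].mean(axis=1)),
        "rho0_myocyte": cell_avg(model.fields.rho0[:, 0]),
        "lambda_r_myocyte": cell_avg(model.fields.lambda_r[:, 0]),
    }
    write_vtu(
        model.mesh,
        path,
        point_data={"displacement": u.reshape(-1, 3)},
        cell_data=cd,
    )
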