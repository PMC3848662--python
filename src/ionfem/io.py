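"""Output writers: probe CSV, legacy VTK snapshots, study tables, MTX dumps.

Snapshots use the legacy VTK ASCII UNSTRUCTURED_GRID format (readable by
ParaView and pyvista); potential is stored in mV under point-data field
"phi", concentrations in uM under their species names.  Probe CSV keeps full
double precision (17 significant digits) so repeated runs are bit-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import TriMesh

__all__ = [
    "write_vtk",
    "write_snapshot_series",
    "write_probe_csv",
    "write_convergence_csv",
    "write_stability_report",
    "write_mtx",
]


def write_vtk(mesh: TriMesh, point_data: dict[str, np.ndarray], path) -> None:
    """Write a legacy VTK ASCII unstructured grid with scalar point data."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nionfem snapshot\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{float(x)!r} {float(y)!r} 0.0\n")
        nel = mesh.n_elements
        fh.write(f"CELLS {nel} {4 * nel}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_TYPES {nel}\n")
        fh.write("\n".join(["5"] * nel) + "\n")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, values in point_data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(repr(float(v)) for v in values) + "\n")


def write_snapshot_series(mesh: TriMesh, trajectory, directory, stem="snapshot") -> list[Path]:
    """One VTK file per stored snapshot plus a plain-text series index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    index_lines = []
    for i, (t, conc, phi) in enumerate(trajectory.snapshots):
        data = {name: conc[j] for j, name in enumerate(trajectory.species_names)}
        data["phi"] = phi
        p = directory / f"{stem}_{i:05d}.vtk"
        write_vtk(mesh, data, p)
        paths.append(p)
        index_lines.append(f"{p.name}\t{t!r}")
    (directory / f"{stem}.series").write_text("\n".join(index_lines) + "\n")
    return paths


def write_probe_csv(trajectory, path, probe: int = 0) -> None:
    """Probe time series: time, one column per species (uM), phi (mV), iters."""
    df = trajectory.to_dataframe(probe)
    df.to_csv(path, index=False, float_format="%.17g")


def write_convergence_csv(records, path) -> None:
    """Mesh-refinement table as CSV (model, h, dt, nel, E_h, mean_picard)."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "model": r.model,
                "h": r.h,
                "dt": r.dt,
                "nel": r.n_elements,
                "E_h": r.error,
                "mean_picard": r.mean_picard,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_stability_report(result, path) -> None:
    """Human-readable summary of a time-step robustness study."""
    lines = [f"stability study: model {result.model}", f"time steps: {result.dts}"]
    for (d1, d2), disc in zip(zip(result.dts, result.dts[1:]), result.discrepancies):
        lines.append(
            f"final product field, dt={d1:g} vs dt={d2:g}: "
            f"relative L2 discrepancy {disc:.6e}"
        )
    lines.append(f"max pairwise discrepancy: {result.max_discrepancy:.6e}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mtx(matrix, path) -> None:
    """Debug dump of an assembled sparse matrix in MatrixMarket format."""
    from scipy.io import mmwrite

    mmwrite(str(path), matrix)
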