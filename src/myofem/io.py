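"""Export helpers: legacy-ASCII VTK unstructured grids and CSV dumps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import MuscleMesh

__all__ = ["write_vtk", "export_mesh_csv", "write_manifest"]

_FAMILY_CODE = {"ecm": 0, "myofiber": 1, "aponeurosis": 2}


def write_vtk(
    path: str | Path,
    mesh: MuscleMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    displacement: np.ndarray | None = None,
) -> Path:
    """Write the mesh (optionally deformed) as a legacy VTK file.

    Cells carry the element family code and the local fiber direction;
    extra per-point / per-cell arrays may be supplied.  Node ordering of
    each hexahedron follows the standard trilinear convention
    (counter-clockwise bottom face, then top face), which is also VTK's.
    """
    path = Path(path)
    nodes = mesh.nodes if displacement is None else mesh.nodes + displacement
    blocks = [
        ("ecm", mesh.ecm_elements),
        ("myofiber", mesh.myofiber_elements),
        ("aponeurosis", mesh.apo_elements),
    ]
    cells = [conn for _, conn in blocks if len(conn)]
    families = np.concatenate(
        [np.full(len(conn), _FAMILY_CODE[name]) for name, conn in blocks if len(conn)]
    )
    fibers = np.concatenate(
        [
            mesh.ecm_frames[:, :, 1],
            mesh.myofiber_frames[:, :, 1],
            np.zeros((len(mesh.apo_elements), 3)),
        ]
    )
    all_cells = np.vstack(cells)
    n_cells = len(all_cells)

    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmyofem mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        np.savetxt(fh, nodes, fmt="%.9g")
        fh.write(f"CELLS {n_cells} {n_cells * 9}\n")
        np.savetxt(
            fh,
            np.hstack([np.full((n_cells, 1), 8), all_cells]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {n_cells}\n")
        np.savetxt(fh, np.full(n_cells, 12), fmt="%d")

        fh.write(f"CELL_DATA {n_cells}\n")
        fh.write("SCALARS family int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, families, fmt="%d")
        fh.write("VECTORS fiber_direction double\n")
        np.savetxt(fh, fibers, fmt="%.9g")
        for name, arr in (cell_data or {}).items():
            arr = np.asarray(arr, dtype=float)
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9g")

        pd_items = dict(point_data or {})
        if displacement is not None:
            pd_items.setdefault("displacement", displacement)
        if pd_items:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in pd_items.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.9g")
    return path


def export_mesh_csv(mesh: MuscleMesh, out_dir: str | Path) -> None:
    """Plain node / element dumps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(mesh.nodes, columns=["x_mm", "y_mm", "z_mm"]).rename_axis(
        "node"
    ).to_csv(out / "nodes.csv")
    rows = []
    for name, conn in (
        ("ecm", mesh.ecm_elements),
        ("myofiber", mesh.myofiber_elements),
        ("aponeurosis", mesh.apo_elements),
    ):
        for el in conn:
            rows.append({"family": name, **{f"n{i}": int(v) for i, v in enumerate(el)}})
    pd.DataFrame(rows).rename_axis("element").to_csv(out / "elements.csv")


def write_manifest(out_dir: str | Path, config_dict: dict, extra: dict | None = None) -> Path:
    """JSON run manifest: resolved config, versions, convergence info."""
    import hashlib

    import numpy
    import scipy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {"numpy": numpy.__version__, "scipy": scipy.__version__},
    }
    manifest.update(extra or {})
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
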