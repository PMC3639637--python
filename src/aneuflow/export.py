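"""Run-artifact writers: CSV profiles, legacy-ASCII VTK fields, JSON summaries.

VTK output uses the legacy STRUCTURED_POINTS text format, readable by
ParaView/VisIt without any VTK library dependency.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .analysis import CutlineProfile


def profiles_to_dataframe(profiles: Iterable[CutlineProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            pd.DataFrame(
                {
                    "position_mm": p.positions * 1e3,
                    "velocity_mm_s": p.velocity_mm_s,
                    "solver": p.solver,
                    "cutline": p.name,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def profiles_to_csv(profiles: Iterable[CutlineProfile], path) -> None:
    df = profiles_to_dataframe(profiles)
    df.to_csv(path, index=False, float_format="%.9g")


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def save_fields_npz(path, **arrays) -> None:
    """Checkpoint fields as a compressed array archive."""
    np.savez_compressed(path, **arrays)


def write_vtk_structured_points(path, origin, spacing, fields: dict) -> None:
    """Write scalar/vector point fields on a uniform grid to legacy VTK.

    ``fields`` maps names to arrays of shape (nx, ny[, nz]) for scalars or
    (d, nx, ny[, nz]) for vectors.
    """
    first = next(iter(fields.values()))
    grid_shape = first.shape[1:] if first.ndim > len(origin) else first.shape
    dims = tuple(grid_shape) + (1,) * (3 - len(grid_shape))
    org = tuple(origin) + (0.0,) * (3 - len(origin))
    n_points = int(np.prod(dims))
    lines = [
        "# vtk DataFile Version 3.0",
        "aneuflow fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        f"ORIGIN {org[0]:.9g} {org[1]:.9g} {org[2]:.9g}",
        f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}",
        f"POINT_DATA {n_points}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape == tuple(grid_shape):  # scalar
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.reshape(grid_shape).ravel(order="F")
            lines.extend(f"{v:.9g}" for v in flat)
        else:  # vector: pad to 3 components
            d = arr.shape[0]
            comps = [arr[k].ravel(order="F") for k in range(d)]
            comps += [np.zeros(n_points)] * (3 - d)
            lines.append(f"VECTORS {name} double")
            lines.extend(
                f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in zip(*comps)
            )
    Path(path).write_text("\n".join(lines) + "\n")
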