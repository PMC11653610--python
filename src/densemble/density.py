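"""Mixing of tabulated electron densities and the relative L2 error.

Densities are exchanged as tabulations on a shared quadrature grid
(points, positive quadrature weights, one value array per source).  The
ensemble density is the pointwise sum of per-functional densities with
the ensemble's normalized weights; the error against a reference density
is the quadrature-weighted relative L2 norm

    drho = ||rho_ref - rho|| / ||rho_ref||,   ||f||^2 = sum_k w_k f_k^2
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from densemble.benchmark import MissingSpeciesError
from densemble.ensemble import EnsembleModel

NEGATIVE_DENSITY_TOLERANCE = -1e-10

__all__ = [
    "DensityGrid",
    "mix_density",
    "density_error",
    "load_grid",
    "save_grid",
]


@dataclass
class DensityGrid:
    """Densities from several sources tabulated on one quadrature grid.

    Parameters
    ----------
    points : (n, 3) array
        Grid coordinates, in the unit named by ``unit`` (no conversion is
        ever applied; the unit is carried through I/O verbatim).
    quad_weights : (n,) array of positive volume elements.
    values : mapping source id -> (n,) density array.
    reference_id : str, optional
        Which source is the reference for :func:`density_error`.
    """

    points: np.ndarray
    quad_weights: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)
    reference_id: str | None = None
    unit: str = "bohr"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.quad_weights = np.asarray(self.quad_weights, dtype=float)
        n = self.points.shape[0]
        if self.points.shape != (n, 3):
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if self.quad_weights.shape != (n,):
            raise ValueError("quad_weights length must match point count")
        if not (self.quad_weights > 0).all():
            raise ValueError("quadrature weights must be positive")
        clean = {}
        for src, vals in self.values.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n,):
                raise ValueError(
                    f"density {src!r} has {vals.shape[0]} values for {n} points"
                )
            low = vals.min() if vals.size else 0.0
            if low < NEGATIVE_DENSITY_TOLERANCE:
                raise ValueError(
                    f"density {src!r} has negative values (min {low:.3e})"
                )
            if low < 0.0:
                warnings.warn(
                    f"density {src!r} has tiny negative values (min {low:.3e}); "
                    "keeping them",
                    stacklevel=2,
                )
            clean[src] = vals
        self.values = clean
        if self.reference_id is not None and self.reference_id not in self.values:
            raise ValueError(f"reference id {self.reference_id!r} has no values")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def source_ids(self) -> tuple[str, ...]:
        return tuple(self.values)

    def integrate(self, source_or_values: str | np.ndarray) -> float:
        """Quadrature integral (electron count) of one density."""
        if isinstance(source_or_values, str):
            vals = self.values[source_or_values]
        else:
            vals = np.asarray(source_or_values, dtype=float)
        return float(np.sum(self.quad_weights * vals))

    def reference(self) -> np.ndarray:
        if self.reference_id is None:
            raise ValueError("grid has no reference density")
        return self.values[self.reference_id]


def mix_density(grid: DensityGrid, model: EnsembleModel) -> np.ndarray:
    """Pointwise weighted sum of per-functional densities, normalized weights.

    When every constituent density integrates to the common electron
    count, so does the mixture (the normalized weights sum to one).
    """
    if not np.isfinite(model.normalized_weights).all():
        raise ValueError("model has no valid normalized weights")
    out = np.zeros(grid.n_points)
    for func, w in zip(model.functionals, model.normalized_weights):
        if func not in grid.values:
            raise MissingSpeciesError(f"grid has no density for source {func!r}")
        out += w * grid.values[func]
    return out


def density_error(
    grid: DensityGrid,
    mixed: np.ndarray,
    reference: np.ndarray | None = None,
) -> float:
    """Relative L2 error of a density against the grid's reference."""
    ref = grid.reference() if reference is None else np.asarray(reference, float)
    mixed = np.asarray(mixed, dtype=float)
    if mixed.shape != ref.shape:
        raise ValueError("density arrays must match the grid length")
    w = grid.quad_weights
    ref_norm = np.sqrt(np.sum(w * ref**2))
    if ref_norm == 0.0:
        raise ValueError("reference density has zero norm")
    return float(np.sqrt(np.sum(w * (ref - mixed) ** 2)) / ref_norm)


def save_grid(grid: DensityGrid, path: str | Path) -> None:
    """Write a grid file (text or HDF5, chosen by extension).

    Text layout: comment header declaring the coordinate unit, reference
    id and column names, then whitespace-delimited rows
    ``x y z w rho_1 rho_2 ...``.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _save_grid_hdf5(grid, path)
        return
    sources = list(grid.values)
    with open(path, "w") as fh:
        fh.write(f"# unit: {grid.unit}\n")
        if grid.reference_id is not None:
            fh.write(f"# reference: {grid.reference_id}\n")
        fh.write("# columns: x y z w " + " ".join(sources) + "\n")
        data = np.column_stack(
            [grid.points, grid.quad_weights]
            + [grid.values[s] for s in sources]
        )
        np.savetxt(fh, data, fmt="%.17g")


def load_grid(path: str | Path) -> DensityGrid:
    """Read a grid file written by :func:`save_grid`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_grid_hdf5(path)
    unit = None
    reference_id = None
    columns: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.lower().startswith("unit:"):
                unit = body.split(":", 1)[1].strip()
            elif body.lower().startswith("reference:"):
                reference_id = body.split(":", 1)[1].strip()
            elif body.lower().startswith("columns:"):
                columns = body.split(":", 1)[1].split()
    if unit is None:
        raise ValueError(f"{path}: grid file must declare its coordinate unit")
    if columns is None or columns[:4] != ["x", "y", "z", "w"]:
        raise ValueError(f"{path}: missing or malformed columns header")
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != len(columns):
        raise ValueError(
            f"{path}: {data.shape[1]} data columns for {len(columns)} names"
        )
    sources = columns[4:]
    return DensityGrid(
        points=data[:, :3],
        quad_weights=data[:, 3],
        values={s: data[:, 4 + i] for i, s in enumerate(sources)},
        reference_id=reference_id,
        unit=unit,
    )


def _save_grid_hdf5(grid: DensityGrid, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("grid")
        g.attrs["unit"] = grid.unit
        if grid.reference_id is not None:
            g.attrs["reference"] = grid.reference_id
        g.create_dataset("points", data=grid.points)
        g.create_dataset("quad_weights", data=grid.quad_weights)
        vals = g.create_group("values")
        for src, arr in grid.values.items():
            vals.create_dataset(src, data=arr)


def _load_grid_hdf5(path: Path) -> DensityGrid:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["grid"]
        return DensityGrid(
            points=np.asarray(g["points"]),
            quad_weights=np.asarray(g["quad_weights"]),
            values={k: np.asarray(v) for k, v in g["values"].items()},
            reference_id=g.attrs.get("reference"),
            unit=str(g.attrs["unit"]),
        )
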