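"""Read and write voxel-wise current-density fields and regional result tables.

A current-density field is a voxel grid carrying either a scalar magnitude
or a 3-component vector per voxel, in mA/m², produced by an external FEM
simulator (or by the built-in spherical phantom) at a stated injected dose
in mA.  Fields travel as NIfTI-1 volumes or as plain coordinate tables
(``x,y,z,density`` CSV, one row per sampled location in world mm), and
regional summaries travel as ``region,mean_density_mA_per_m2,voxel_count``
CSV.

Conventions: voxel indices are 0-based; the affine maps voxel indices to
world millimetres in RAS+ orientation, as in the NIfTI standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FieldFormatError",
    "FieldShapeError",
    "TableRowError",
    "VoxelGrid",
    "CurrentDensityField",
    "read_field_nifti",
    "write_field_nifti",
    "read_field_table",
    "write_field_table",
    "magnitude",
    "region_table",
    "write_region_table",
    "read_region_table",
]

REGION_TABLE_COLUMNS = ("region", "mean_density_mA_per_m2", "voxel_count")


class FieldFormatError(ValueError):
    """The input file is not a readable field in a supported format."""


class FieldShapeError(FieldFormatError):
    """The volume has a shape that cannot represent a scalar or vector field."""


class TableRowError(ValueError):
    """One or more coordinate-table rows fall outside the target grid."""

    def __init__(self, rows: list[int], message: str):
        self.rows = rows
        super().__init__(message)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (np.round rounds to even)."""
    return np.trunc(x + np.copysign(0.5, x))


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice with a voxel→world-mm affine (RAS+)."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 homogeneous, voxel index -> world mm

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid extents must be three positive integers, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine linear part is singular")
        aff = aff.copy()
        aff[3] = (0.0, 0.0, 0.0, 1.0)
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        return (xyz - self.affine[:3, 3]) @ inv.T

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Snap world coordinates to the nearest voxel index (halves away from zero)."""
        return _round_half_away(self.world_to_voxel(xyz)).astype(np.int64)

    def contains_index(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        ok = np.ones(len(ijk), dtype=bool)
        for axis in range(3):
            ok &= (ijk[:, axis] >= 0) & (ijk[:, axis] < self.shape[axis])
        return ok

    def all_voxel_centres(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1).reshape(-1, 3)
        return self.voxel_to_world(ijk).reshape(*self.shape, 3)


@dataclass(frozen=True)
class CurrentDensityField:
    """A per-voxel current density (mA/m²) at one injected dose (mA).

    ``values`` is either a 3-D scalar-magnitude array or a 4-D array whose
    last axis holds the x/y/z vector components.  ``mask`` marks in-head
    voxels; values outside the mask carry no meaning.
    """

    grid: VoxelGrid
    values: np.ndarray
    dose: float
    mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape[:3] != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape[:3]} does not match grid {self.grid.shape}"
            )
        if values.ndim == 4 and values.shape[3] != 3:
            raise FieldShapeError(
                f"vector field must have 3 components, got {values.shape[3]}"
            )
        if values.ndim not in (3, 4):
            raise FieldShapeError(f"field must be 3-D or 4-D, got {values.ndim}-D")
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        mask = self.mask
        if mask is None:
            mask = np.ones(self.grid.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        finite = np.isfinite(values).all(axis=3) if values.ndim == 4 else np.isfinite(values)
        mask = mask & finite
        if values.ndim == 3 and (values[mask] < 0).any():
            raise ValueError("scalar magnitudes must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 4

    def magnitudes(self) -> np.ndarray:
        """Per-voxel Euclidean magnitude as a 3-D array."""
        if self.is_vector:
            return np.linalg.norm(self.values, axis=3)
        return self.values

    def with_dose(self, dose: float) -> "CurrentDensityField":
        """Relabel the dose metadata without touching voxel values."""
        return replace(self, dose=dose)


def magnitude(field: CurrentDensityField) -> CurrentDensityField:
    """Reduce a vector field to its per-voxel Euclidean norm; scalar fields pass through."""
    if not field.is_vector:
        return field
    return CurrentDensityField(
        grid=field.grid, values=field.magnitudes(), dose=field.dose, mask=field.mask
    )


def read_field_nifti(path, dose: float) -> CurrentDensityField:
    """Load a scalar (3-D) or vector (4-D, last extent 3) density volume.

    Voxels that are non-finite or exactly zero are excluded from the in-head
    mask: FEM exports carry zeros outside the head.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = np.asarray(img.affine, dtype=float)
    except FieldFormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FieldFormatError(f"cannot read NIfTI field {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] != 3:
        raise FieldShapeError(
            f"{path}: 4-D field must have 3 components on the last axis, "
            f"got {data.shape[3]}"
        )
    if data.ndim not in (3, 4):
        raise FieldShapeError(f"{path}: expected 3-D or 4-D volume, got {data.ndim}-D")
    grid = VoxelGrid(shape=data.shape[:3], affine=affine)
    if data.ndim == 4:
        finite = np.isfinite(data).all(axis=3)
        nonzero = np.abs(np.where(np.isfinite(data), data, 0.0)).sum(axis=3) > 0
    else:
        finite = np.isfinite(data)
        nonzero = np.where(finite, data, 0.0) != 0
    data = np.where(finite[..., None] if data.ndim == 4 else finite, data, 0.0)
    if data.ndim == 3:
        data = np.abs(data)  # magnitudes are non-negative by definition
    return CurrentDensityField(grid=grid, values=data, dose=dose, mask=finite & nonzero)


def write_field_nifti(field: CurrentDensityField, path) -> None:
    """Write a field as NIfTI, zero-filled outside the mask."""
    data = np.where(
        field.mask[..., None] if field.is_vector else field.mask, field.values, 0.0
    )
    nib.save(nib.Nifti1Image(data, field.grid.affine), str(path))


def read_field_table(path, grid: VoxelGrid, dose: float) -> CurrentDensityField:
    """Load a coordinate table (``x,y,z,density`` in mm and mA/m²) onto a grid.

    Each row is snapped to the nearest voxel centre; rows sharing a voxel are
    averaged; voxels no row visits stay outside the mask.  Rows outside the
    grid raise :class:`TableRowError` listing the offending 0-based row
    indices.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("x", "y", "z", "density") if c not in df.columns]
    if missing:
        raise FieldFormatError(f"{path}: missing column(s) {missing}")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    dens = df["density"].to_numpy(dtype=float)
    ijk = grid.world_to_index(xyz)
    inside = grid.contains_index(ijk)
    if not inside.all():
        bad = np.flatnonzero(~inside).tolist()
        raise TableRowError(
            bad, f"{path}: {len(bad)} row(s) outside grid bounds (rows {bad[:10]}...)"
        )
    flat = np.ravel_multi_index(tuple(ijk.T), grid.shape)
    n = int(np.prod(grid.shape))
    sums = np.bincount(flat, weights=dens, minlength=n)
    counts = np.bincount(flat, minlength=n)
    mask = counts > 0
    values = np.zeros(n)
    values[mask] = sums[mask] / counts[mask]
    return CurrentDensityField(
        grid=grid,
        values=values.reshape(grid.shape),
        dose=dose,
        mask=mask.reshape(grid.shape),
    )


def write_field_table(field: CurrentDensityField, path) -> None:
    """Export masked voxels as an ``x,y,z,density`` table (magnitudes)."""
    mags = field.magnitudes()
    ijk = np.argwhere(field.mask)
    xyz = field.grid.voxel_to_world(ijk)
    pd.DataFrame(
        {
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "density": mags[field.mask],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def region_table(
    names,
    means,
    counts,
    dose: float | None = None,
    source: str | None = None,
) -> pd.DataFrame:
    """Assemble a regional summary table with fixed column order.

    Region names must be unique, voxel counts at least 1 and means
    non-negative; provenance (dose, source) is stored in ``DataFrame.attrs``.
    """
    names = list(names)
    means = np.asarray(means, dtype=float)
    counts = np.asarray(counts, dtype=np.int64)
    if len(names) != len(means) or len(names) != len(counts):
        raise ValueError("names, means and counts must have equal length")
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    if (counts < 1).any():
        raise ValueError("voxel counts must be >= 1")
    if (means < 0).any():
        raise ValueError("mean densities must be >= 0")
    df = pd.DataFrame(
        {
            "region": names,
            "mean_density_mA_per_m2": means,
            "voxel_count": counts,
        }
    )
    df.attrs["dose"] = dose
    df.attrs["source"] = source
    return df


def write_region_table(table: pd.DataFrame, path) -> None:
    """Write a regional table as CSV at full precision; errors on empty tables."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty region table")
    missing = [c for c in REGION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"region table missing column(s) {missing}")
    table.loc[:, REGION_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_region_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    return region_table(
        df["region"],
        df["mean_density_mA_per_m2"],
        df["voxel_count"],
        source=str(path),
    )
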