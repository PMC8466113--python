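"""Landmark-based mapping from native space to a reference atlas space.

Registration uses the three classical midline landmarks — anterior
commissure (AC), posterior commissure (PC) and a mid-sagittal point — and
fits the 7-parameter similarity transform (proper rotation, isotropic
scale, translation) that maps native landmark positions onto their
reference counterparts in the least-squares sense (the Umeyama/Kabsch
construction).  Three point pairs cannot identify shear, so similarity is
the richest transform class these landmarks support; reflections are
never admitted.

Atlas labels are categorical, so voxels are assigned by nearest-neighbour
lookup in the parcellation grid, never interpolated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .field_io import CurrentDensityField, VoxelGrid
from .region_stats import RegionAssignment

__all__ = [
    "CollinearLandmarksError",
    "LandmarkSet",
    "SimilarityTransform",
    "LandmarkFit",
    "fit_landmark_transform",
    "apply_transform",
    "Parcellation",
    "label_voxels",
    "read_landmarks",
    "write_landmarks",
    "read_parcellation",
    "write_parcellation",
]

_LANDMARK_KEYS = ("ac", "pc", "midsagittal")


class CollinearLandmarksError(ValueError):
    """The three landmarks do not span a plane; the transform is unidentifiable."""


@dataclass(frozen=True)
class LandmarkSet:
    """AC, PC and mid-sagittal point in world mm for one space."""

    ac: np.ndarray
    pc: np.ndarray
    midsagittal: np.ndarray

    def __post_init__(self):
        for key in _LANDMARK_KEYS:
            p = np.asarray(getattr(self, key), dtype=float).reshape(3)
            p.flags.writeable = False
            object.__setattr__(self, key, p)
        pts = self.as_array()
        d01 = np.linalg.norm(pts[0] - pts[1])
        d02 = np.linalg.norm(pts[0] - pts[2])
        d12 = np.linalg.norm(pts[1] - pts[2])
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if min(d01, d02, d12) <= 1.0 or area <= 1.0:
            raise CollinearLandmarksError(
                f"landmarks are (near-)collinear: pairwise distances "
                f"({d01:.3f}, {d02:.3f}, {d12:.3f}) mm, triangle area {area:.3f} mm²"
            )

    def as_array(self) -> np.ndarray:
        """Landmarks stacked as a 3×3 array (rows: ac, pc, midsagittal)."""
        return np.stack([self.ac, self.pc, self.midsagittal])


@dataclass(frozen=True)
class SimilarityTransform:
    """p ↦ scale · rotation · p + translation (proper rotation, no reflection)."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3).copy()
        t = np.asarray(self.translation, dtype=float).reshape(3).copy()
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation is not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection not allowed)")
        R.flags.writeable = False
        t.flags.writeable = False
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=np.eye(3), scale=1.0, translation=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * (pts @ self.rotation.T) + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        sinv = 1.0 / self.scale
        return SimilarityTransform(
            rotation=Rinv, scale=sinv, translation=-sinv * (Rinv @ self.translation)
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            scale=self.scale * other.scale,
            translation=self.scale * (self.rotation @ other.translation)
            + self.translation,
        )

    def matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class LandmarkFit:
    """A fitted similarity transform with its landmark residual."""

    transform: SimilarityTransform
    residual_rms: float
    reflection_corrected: bool


def fit_landmark_transform(native: LandmarkSet, reference: LandmarkSet) -> LandmarkFit:
    """Least-squares similarity transform taking native landmarks to reference.

    Umeyama's closed form: centre both triplets, take the SVD of the
    cross-covariance, and force a proper rotation.  If the unconstrained
    optimum is a reflection, the nearest proper rotation is used instead
    and flagged via ``reflection_corrected``.
    """
    src = native.as_array()
    dst = reference.as_array()
    mu_src = src.mean(axis=0)
    mu_dst = dst.mean(axis=0)
    x = src - mu_src
    y = dst - mu_dst
    cov = y.T @ x / len(src)
    var_src = (x**2).sum() / len(src)
    U, s, Vt = np.linalg.svd(cov)
    d = np.ones(3)
    flipped = np.linalg.det(U) * np.linalg.det(Vt) < 0
    if flipped:
        d[-1] = -1.0
    R = U @ np.diag(d) @ Vt
    scale = float((s * d).sum() / var_src)
    if not scale > 0:
        raise CollinearLandmarksError("degenerate landmark configuration: non-positive scale")
    t = mu_dst - scale * (R @ mu_src)
    transform = SimilarityTransform(rotation=R, scale=scale, translation=t)
    resid = transform.apply(src) - dst
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return LandmarkFit(transform=transform, residual_rms=rms, reflection_corrected=bool(flipped))


def apply_transform(t: SimilarityTransform, points) -> np.ndarray:
    """Transform an array (or list) of world-mm points; returns an (n, 3) array."""
    return t.apply(np.asarray(points, dtype=float))


@dataclass(frozen=True)
class Parcellation:
    """Integer label volume in reference space plus a label→region-name table."""

    grid: VoxelGrid
    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if labels.shape != self.grid.shape:
            raise ValueError("label volume shape does not match grid")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        names = {int(k): str(v) for k, v in dict(self.names).items()}
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)[:10]}")
        if len(set(names.values())) != len(names):
            raise ValueError("region names must be unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", names)

    @property
    def region_labels(self) -> list[int]:
        """Nonzero labels actually present in the volume, ascending."""
        u = np.unique(self.labels)
        return [int(v) for v in u if v != 0]


def label_voxels(
    field: CurrentDensityField,
    parcellation: Parcellation,
    t: SimilarityTransform,
) -> RegionAssignment:
    """Assign each masked field voxel the atlas label at its transformed position.

    Each masked voxel's world centre is pushed through ``t`` (native →
    reference), snapped to the nearest parcellation voxel, and given that
    voxel's label.  Voxels landing outside the parcellation grid or on
    background keep label 0 (unassigned); a warning is emitted if more than
    half of the masked voxels end up unassigned.
    """
    out = np.zeros(field.grid.shape, dtype=np.int64)
    ijk = np.argwhere(field.mask)
    n_masked = len(ijk)
    if n_masked:
        world = field.grid.voxel_to_world(ijk)
        ref_world = t.apply(world)
        ref_ijk = parcellation.grid.world_to_index(ref_world)
        inside = parcellation.grid.contains_index(ref_ijk)
        labels = np.zeros(n_masked, dtype=np.int64)
        if inside.any():
            sel = ref_ijk[inside]
            labels[inside] = parcellation.labels[sel[:, 0], sel[:, 1], sel[:, 2]]
        out[tuple(ijk.T)] = labels
        unassigned = float((labels == 0).sum()) / n_masked
    else:
        unassigned = 1.0
    if unassigned > 0.5:
        warnings.warn(
            f"{unassigned:.0%} of masked voxels could not be assigned an atlas label",
            stacklevel=2,
        )
    return RegionAssignment(
        labels=out, mask=field.mask, names=parcellation.names, unassigned_fraction=unassigned
    )


# ---------------------------------------------------------------------------
# on-disk formats


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(getattr(landmarks, k)) for k in _LANDMARK_KEYS}, fh, indent=1)


def read_landmarks(path) -> LandmarkSet:
    with open(path) as fh:
        data = json.load(fh)
    missing = [k for k in _LANDMARK_KEYS if k not in data]
    if missing:
        raise ValueError(f"{path}: missing landmark key(s) {missing}")
    return LandmarkSet(**{k: np.asarray(data[k], dtype=float) for k in _LANDMARK_KEYS})


def write_parcellation(parcellation: Parcellation, volume_path, names_path) -> None:
    nib.save(
        nib.Nifti1Image(parcellation.labels.astype(np.int32), parcellation.grid.affine),
        str(volume_path),
    )
    pd.DataFrame(
        {
            "label": sorted(parcellation.names),
            "region_name": [parcellation.names[k] for k in sorted(parcellation.names)],
        }
    ).to_csv(names_path, index=False)


def read_parcellation(volume_path, names_path) -> Parcellation:
    img = nib.load(str(volume_path))
    labels = np.asarray(img.dataobj)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if np.abs(labels - rounded).max() > 1e-6:
            raise ValueError(f"{volume_path}: label volume is not integer-valued")
        labels = rounded.astype(np.int64)
    names_df = pd.read_csv(names_path)
    names = dict(zip(names_df["label"].astype(int), names_df["region_name"].astype(str)))
    grid = VoxelGrid(shape=labels.shape, affine=np.asarray(img.affine, dtype=float))
    return Parcellation(grid=grid, labels=labels.astype(np.int64), names=names)
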