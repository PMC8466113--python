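"""Closed-form spherical head phantom: fields, parcellations, cohorts.

The phantom replaces an FEM head model with the exact current-density
field of a point-source electrode pair in an infinite homogeneous medium,
masked to a sphere:

    J(r) = (I / 4π) · [ (r − r₊)/|r − r₊|³ − (r − r₋)/|r − r₋|³ ]

with r₊, r₋ the anode/cathode points on the sphere surface and I the
injected dose.  Distances are in metres, so with I in mA the field is in
mA/m².  The field is exactly linear in I — the idealised behaviour a
standard head shows — which makes the phantom a sharp oracle for
dose-invariance of the focality index.  The no-flux scalp boundary
condition of a real (bounded) head is knowingly violated: the phantom
exists to exercise the dosimetry pipeline, not to model a head accurately.

Voxels within one voxel spacing of an electrode are cut from the in-head
mask, since the point-source field diverges there.

Dose–response archetypes perturb the otherwise-linear fields to emulate
the three qualitative individual profiles seen in practice: ``linear``
(no perturbation, constant DTDI), ``target_gain`` (target region gains
density super-linearly with dose, DTDI rises) and ``hotspot_emerge`` (a
non-target region surges above a dose threshold and steals the peak,
DTDI falls).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .atlas import LandmarkSet, Parcellation, SimilarityTransform
from .field_io import CurrentDensityField, VoxelGrid

__all__ = [
    "ARCHETYPES",
    "PhantomSpec",
    "ArchetypeParams",
    "SyntheticSubject",
    "phantom_grid",
    "potential",
    "current_density_at",
    "simulate_field",
    "make_parcellation",
    "inject_dose_response",
    "generate_subject",
    "generate_cohort",
    "REFERENCE_LANDMARKS",
]

ARCHETYPES = ("linear", "target_gain", "hotspot_emerge")

# AC/PC/mid-sagittal in the phantom's reference frame (sphere centred at 0, mm).
REFERENCE_LANDMARKS = LandmarkSet(
    ac=np.array([0.0, 10.0, 0.0]),
    pc=np.array([0.0, -18.0, 0.0]),
    midsagittal=np.array([0.0, -4.0, 44.0]),
)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, conductivity and montage of the spherical phantom.

    Defaults: an 80 mm head sphere sampled at 4 mm, grey-matter
    conductivity 0.276 S/m, electrodes 60° apart near the top of the
    sphere, and 116 parcels mirroring a whole-brain anatomical atlas.
    """

    radius: float = 80.0          # mm
    spacing: float = 4.0          # mm
    conductivity: float = 0.276   # S/m (grey matter)
    anode: tuple[float, float, float] = (0.5, 0.0, 0.8660254037844387)
    cathode: tuple[float, float, float] = (-0.5, 0.0, 0.8660254037844387)
    n_regions: int = 116
    seed: int = 0

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.n_regions < 2:
            raise ValueError("at least two regions are required")
        a = _unit(self.anode)
        c = _unit(self.cathode)
        if np.allclose(a, c):
            raise ValueError("anode and cathode directions must differ")
        object.__setattr__(self, "anode", tuple(a))
        object.__setattr__(self, "cathode", tuple(c))

    @property
    def anode_mm(self) -> np.ndarray:
        return self.radius * np.asarray(self.anode)

    @property
    def cathode_mm(self) -> np.ndarray:
        return self.radius * np.asarray(self.cathode)


@dataclass(frozen=True)
class ArchetypeParams:
    """Dose–response perturbation parameters.

    target_gain multiplies target-region voxels by 1 + beta·(dose − d0);
    hotspot_emerge multiplies hotspot-region voxels by
    1 + gamma·max(0, dose − d_thr), so the hotspot is silent at the
    threshold dose and surges above it.
    """

    beta: float = 0.3    # /mA, target gain slope
    d0: float = 1.0      # mA, target-gain reference dose
    gamma: float = 1.0   # /mA, hotspot growth rate
    d_thr: float = 1.0   # mA, hotspot onset dose


def phantom_grid(spec: PhantomSpec) -> VoxelGrid:
    """Isotropic grid centred on the sphere, one voxel margin beyond the radius."""
    half = int(np.ceil(spec.radius / spec.spacing))
    n = 2 * half + 1
    affine = np.eye(4)
    affine[:3, :3] *= spec.spacing
    affine[:3, 3] = -half * spec.spacing
    return VoxelGrid(shape=(n, n, n), affine=affine)


def potential(spec: PhantomSpec, dose: float, points_mm: np.ndarray) -> np.ndarray:
    """Scalar potential V(r) = (I/4πσ)[1/|r−r₊| − 1/|r−r₋|] at world points (mm)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) / 1000.0
    rp = spec.anode_mm / 1000.0
    rm = spec.cathode_mm / 1000.0
    dp = np.linalg.norm(pts - rp, axis=-1)
    dm = np.linalg.norm(pts - rm, axis=-1)
    with np.errstate(divide="ignore"):
        return dose / (4.0 * np.pi * spec.conductivity) * (1.0 / dp - 1.0 / dm)


def current_density_at(spec: PhantomSpec, dose: float, points_mm: np.ndarray) -> np.ndarray:
    """Analytic vector current density (mA/m²) at world points given in mm."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) / 1000.0
    rp = spec.anode_mm / 1000.0
    rm = spec.cathode_mm / 1000.0
    dvp = pts - rp
    dvm = pts - rm
    dp = np.linalg.norm(dvp, axis=-1, keepdims=True)
    dm = np.linalg.norm(dvm, axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = dose / (4.0 * np.pi) * (dvp / dp**3 - dvm / dm**3)
    return out


def simulate_field(spec: PhantomSpec, dose: float) -> CurrentDensityField:
    """Monopole-pair vector field on the phantom grid, masked to the sphere.

    The mask drops voxels outside the sphere and voxels within one voxel
    spacing of either electrode (the point-source singularity guard).
    """
    if not dose > 0:
        raise ValueError("dose must be positive")
    grid = phantom_grid(spec)
    centres = grid.all_voxel_centres()            # (*shape, 3), mm
    flat = centres.reshape(-1, 3)
    values = current_density_at(spec, dose, flat).reshape(*grid.shape, 3)
    r = np.linalg.norm(flat, axis=1)
    dp = np.linalg.norm(flat - spec.anode_mm, axis=1)
    dm = np.linalg.norm(flat - spec.cathode_mm, axis=1)
    mask = (r <= spec.radius) & (dp > spec.spacing) & (dm > spec.spacing)
    values = np.where(mask.reshape(*grid.shape, 1), values, 0.0)
    return CurrentDensityField(
        grid=grid, values=values, dose=dose, mask=mask.reshape(grid.shape)
    )


def make_parcellation(spec: PhantomSpec) -> Parcellation:
    """Partition in-sphere voxels into contiguous parcels, named R001, R002, …

    Seeds are placed by farthest-point sampling (first seed drawn from the
    spec's RNG seed), then every in-sphere voxel joins its nearest seed —
    a deterministic Voronoi-style parcellation of the phantom volume.
    """
    grid = phantom_grid(spec)
    centres = grid.all_voxel_centres().reshape(-1, 3)
    inside = np.linalg.norm(centres, axis=1) <= spec.radius
    pts = centres[inside]
    if len(pts) < spec.n_regions:
        raise ValueError(
            f"only {len(pts)} in-sphere voxels for {spec.n_regions} regions"
        )
    rng = np.random.default_rng(spec.seed)
    seeds = np.empty(spec.n_regions, dtype=np.int64)
    seeds[0] = rng.integers(len(pts))
    mindist = np.linalg.norm(pts - pts[seeds[0]], axis=1)
    for k in range(1, spec.n_regions):
        seeds[k] = int(np.argmax(mindist))
        mindist = np.minimum(mindist, np.linalg.norm(pts - pts[seeds[k]], axis=1))
    _, nearest = cKDTree(pts[seeds]).query(pts)
    labels = np.zeros(len(centres), dtype=np.int64)
    labels[inside] = nearest + 1
    names = {k + 1: f"R{k + 1:03d}" for k in range(spec.n_regions)}
    return Parcellation(grid=grid, labels=labels.reshape(grid.shape), names=names)


def inject_dose_response(
    field: CurrentDensityField,
    parcellation: Parcellation,
    archetype: str,
    dose: float,
    params: ArchetypeParams = ArchetypeParams(),
    target_label: int | None = None,
    hotspot_label: int | None = None,
) -> CurrentDensityField:
    """Apply a dose-dependent regional perturbation to a phantom field.

    ``linear`` returns the field unchanged.  ``target_gain`` scales the
    target region by 1 + beta·(dose − d0); ``hotspot_emerge`` scales the
    hotspot region by 1 + gamma·max(0, dose − d_thr).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")
    if archetype == "linear":
        return field
    if archetype == "target_gain":
        label, factor = target_label, 1.0 + params.beta * (dose - params.d0)
    else:
        label, factor = hotspot_label, 1.0 + params.gamma * max(0.0, dose - params.d_thr)
    if label is None:
        raise ValueError(f"archetype {archetype!r} requires its region label")
    if factor == 1.0:
        return field
    sel = parcellation.labels == label
    scale = np.where(sel, factor, 1.0)
    values = field.values * (scale[..., None] if field.is_vector else scale)
    return CurrentDensityField(grid=field.grid, values=values, dose=field.dose, mask=field.mask)


@dataclass(frozen=True)
class SyntheticSubject:
    """One phantom subject: per-dose fields plus everything needed to analyse them."""

    fields: Mapping[float, CurrentDensityField]   # native space
    parcellation: Parcellation                    # reference space
    native_landmarks: LandmarkSet
    reference_landmarks: LandmarkSet
    true_transform: SimilarityTransform           # native -> reference, ground truth
    archetype: str
    target_region: str
    hotspot_region: str
    target_label: int
    hotspot_label: int
    seed: int


def _nearest_label(parcellation: Parcellation, point_mm: np.ndarray) -> int:
    """Label of the nearest labelled voxel to a world point."""
    ijk = parcellation.grid.world_to_index(point_mm)[0]
    ijk = np.clip(ijk, 0, np.asarray(parcellation.grid.shape) - 1)
    label = int(parcellation.labels[tuple(ijk)])
    if label:
        return label
    lab_idx = np.argwhere(parcellation.labels > 0)
    world = parcellation.grid.voxel_to_world(lab_idx)
    j = int(np.argmin(np.linalg.norm(world - np.asarray(point_mm).reshape(3), axis=1)))
    return int(parcellation.labels[tuple(lab_idx[j])])


def _random_similarity(rng: np.random.Generator) -> SimilarityTransform:
    """Small random similarity: rotation ≤ 10°, scale in [0.9, 1.1], shift ≤ 10 mm."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, 10.0))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    scale = rng.uniform(0.9, 1.1)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = rng.uniform(0.0, 10.0) * direction
    return SimilarityTransform(rotation=R, scale=scale, translation=translation)


def generate_subject(
    spec: PhantomSpec,
    archetype: str,
    doses: Sequence[float],
    seed: int,
    params: ArchetypeParams = ArchetypeParams(),
) -> SyntheticSubject:
    """Build one phantom subject with fields at each candidate dose.

    The subject's native space differs from the phantom reference space by
    a seeded random similarity transform; native fields carry the warped
    affine while the parcellation stays in reference space, so recovering
    regional statistics requires the landmark registration step, exactly as
    for real data.  The ground-truth native→reference transform is retained
    for validation.

    The target region is the parcel under the sphere-surface point midway
    between the electrodes (on their side of the head); the hotspot region
    used by ``hotspot_emerge`` is the non-target parcel with the highest
    baseline regional mean.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")
    if len(doses) < 2:
        raise ValueError("at least two candidate doses are required")
    doses = tuple(float(d) for d in doses)
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("doses must be strictly increasing")
    rng = np.random.default_rng(seed)
    spec = replace(spec, seed=int(rng.integers(2**31)))
    parcellation = make_parcellation(spec)

    a = np.asarray(spec.anode)
    c = np.asarray(spec.cathode)
    target_point = spec.radius * _unit(a + c)
    target_label = _nearest_label(parcellation, target_point)
    # The emergent hotspot is seeded in the non-target parcel that already
    # receives the most current (a near-electrode parcel), so its surge
    # reliably steals the regional peak at supra-threshold doses.
    base = simulate_field(spec, doses[0])
    mags = np.linalg.norm(base.values, axis=3)
    sel = base.mask & (parcellation.labels > 0)
    sums = np.bincount(parcellation.labels[sel], weights=mags[sel],
                       minlength=spec.n_regions + 1)
    counts = np.bincount(parcellation.labels[sel], minlength=spec.n_regions + 1)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    means[target_label] = -1.0
    hotspot_label = int(np.argmax(means))

    ref_to_native = _random_similarity(rng)
    true_transform = ref_to_native.inverse()
    native_landmarks = LandmarkSet(
        ac=ref_to_native.apply(REFERENCE_LANDMARKS.ac)[0],
        pc=ref_to_native.apply(REFERENCE_LANDMARKS.pc)[0],
        midsagittal=ref_to_native.apply(REFERENCE_LANDMARKS.midsagittal)[0],
    )

    native_affine = ref_to_native.matrix() @ phantom_grid(spec).affine
    fields = {}
    for dose in doses:
        field = simulate_field(spec, dose)
        field = inject_dose_response(
            field, parcellation, archetype, dose, params,
            target_label=target_label, hotspot_label=hotspot_label,
        )
        native_grid = VoxelGrid(shape=field.grid.shape, affine=native_affine)
        fields[dose] = CurrentDensityField(
            grid=native_grid, values=field.values, dose=dose, mask=field.mask
        )
    return SyntheticSubject(
        fields=fields,
        parcellation=parcellation,
        native_landmarks=native_landmarks,
        reference_landmarks=REFERENCE_LANDMARKS,
        true_transform=true_transform,
        archetype=archetype,
        target_region=parcellation.names[target_label],
        hotspot_region=parcellation.names[hotspot_label],
        target_label=target_label,
        hotspot_label=hotspot_label,
        seed=seed,
    )


def generate_cohort(
    spec: PhantomSpec,
    archetypes: Sequence[str],
    doses: Sequence[float],
    n_per_archetype: int,
    master_seed: int,
    params: ArchetypeParams = ArchetypeParams(),
) -> list[SyntheticSubject]:
    """A cohort of phantom subjects, ``n_per_archetype`` per archetype.

    Subject seeds are drawn from one master seed, so the whole cohort is
    reproducible from a single integer.
    """
    rng = np.random.default_rng(master_seed)
    cohort = []
    for archetype in archetypes:
        for _ in range(n_per_archetype):
            cohort.append(
                generate_subject(spec, archetype, doses, int(rng.integers(2**31)), params)
            )
    return cohort
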