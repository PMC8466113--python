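"""End-to-end per-subject analysis: fields → registration → regional stats → DTDI."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .atlas import LandmarkSet, Parcellation, fit_landmark_transform, label_voxels
from .dtdi import DoseProfile, DoseRecommendation, compute_dtdi, recommend_dose, titrate
from .field_io import CurrentDensityField
from .region_stats import RegionStats, region_means


@dataclass(frozen=True)
class SubjectReport:
    """Everything the pipeline derives for one subject."""

    stats_by_dose: Mapping[float, RegionStats]
    profile: DoseProfile | None
    recommendation: DoseRecommendation | None
    residual_rms: float
    unassigned_fraction: float


def analyze_subject(
    fields_by_dose: Mapping[float, CurrentDensityField],
    parcellation: Parcellation,
    native_landmarks: LandmarkSet,
    reference_landmarks: LandmarkSet,
    target: str,
    min_voxels: int = 1,
    epsilon: float = 0.05,
    threshold: float = 0.75,
) -> SubjectReport:
    """Register, label and summarise one subject's fields; titrate if ≥ 2 doses.

    The native→reference transform is fitted once from the landmark pair
    and reused for every dose (all fields share the subject's anatomy).
    """
    if not fields_by_dose:
        raise ValueError("no fields supplied")
    fit = fit_landmark_transform(native_landmarks, reference_landmarks)
    stats_by_dose: dict[float, RegionStats] = {}
    unassigned = 0.0
    for dose in sorted(fields_by_dose):
        field = fields_by_dose[dose]
        assignment = label_voxels(field, parcellation, fit.transform)
        unassigned = max(unassigned, assignment.unassigned_fraction)
        stats_by_dose[dose] = region_means(field, assignment, min_voxels=min_voxels)
    profile = recommendation = None
    if len(stats_by_dose) >= 2:
        profile = titrate(stats_by_dose, target, epsilon=epsilon)
        recommendation = recommend_dose(profile, threshold=threshold)
    else:
        # single dose: still validate the target exists
        (only,) = stats_by_dose.values()
        compute_dtdi(only, target)
    return SubjectReport(
        stats_by_dose=stats_by_dose,
        profile=profile,
        recommendation=recommendation,
        residual_rms=fit.residual_rms,
        unassigned_fraction=unassigned,
    )
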