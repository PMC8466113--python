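"""Dose–target determination index (DTDI) and focality-based dose titration.

DTDI is the ratio of the mean current density in the target region to the
maximum regional mean anywhere in the parcellation:

    DTDI = mean density at target ROI / max regional mean density

Because the peak search includes the target itself, DTDI lies in [0, 1]:
1 means the target receives more current than any other region (perfectly
focal stimulation); 0 means the target receives none.  For an exactly
linear head model the whole field scales with the injected current, so
DTDI is dose-invariant; departures from constancy across doses reveal
dose-dependent hotspots or target gains, and the dose with the highest
DTDI is the preferred one.

The reverse-dose rule assumes that same linearity: to reach a desired
target density, scale a reference dose by desired/actual density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .region_stats import RegionStats, peak_region

__all__ = [
    "DegenerateFieldError",
    "TargetNotFoundError",
    "DTDIResult",
    "DoseProfile",
    "DoseRecommendation",
    "ReverseDoseResult",
    "compute_dtdi",
    "averaged_dtdi",
    "reverse_dose",
    "titrate",
    "classify_trend",
    "linearity_index",
    "recommend_dose",
]

TRENDS = ("constant", "increasing", "decreasing", "mixed")


class DegenerateFieldError(ValueError):
    """All regional means are zero; DTDI is undefined."""


class TargetNotFoundError(KeyError):
    """The requested target region is absent from the statistics."""


@dataclass(frozen=True)
class DTDIResult:
    """DTDI for one field: target and peak regions with their mean densities."""

    targets: tuple[str, ...]
    target_mean: float
    peak_regions: tuple[str, ...]
    peak_mean: float
    dtdi: float
    dose: float

    def __post_init__(self):
        if not 0.0 <= self.dtdi <= 1.0:
            raise ValueError(f"DTDI out of range [0, 1]: {self.dtdi}")


@dataclass(frozen=True)
class DoseProfile:
    """DTDI and target density across candidate doses, with trend classification."""

    doses: tuple[float, ...]
    results: tuple[DTDIResult, ...]
    trend: str
    linearity: float
    epsilon: float

    def __post_init__(self):
        if len(self.doses) != len(self.results):
            raise ValueError("one result per dose required")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.trend not in TRENDS:
            raise ValueError(f"unknown trend {self.trend!r}")

    @property
    def dtdis(self) -> tuple[float, ...]:
        return tuple(r.dtdi for r in self.results)

    @property
    def target_densities(self) -> tuple[float, ...]:
        return tuple(r.target_mean for r in self.results)


@dataclass(frozen=True)
class DoseRecommendation:
    dose: float
    dtdi: float
    passes_threshold: bool
    threshold: float


@dataclass(frozen=True)
class ReverseDoseResult:
    """An individualized dose, possibly clipped to the safety cap."""

    dose: float
    clipped: bool
    uncapped_dose: float
    cap: float | None


def compute_dtdi(stats: RegionStats, target: str) -> DTDIResult:
    """DTDI = target regional mean / maximum regional mean.

    The peak search includes the target, so the result is bounded by 1 and
    equals 1 exactly when the target is (one of) the peak region(s).
    """
    target_mean = stats.mean_of(target) if target in stats.names else _missing(target, stats)
    peaks, peak_mean = peak_region(stats)
    if peak_mean == 0.0:
        raise DegenerateFieldError("all regional means are zero; DTDI undefined")
    return DTDIResult(
        targets=(target,),
        target_mean=target_mean,
        peak_regions=peaks,
        peak_mean=peak_mean,
        dtdi=target_mean / peak_mean,
        dose=stats.dose,
    )


def _missing(target: str, stats: RegionStats):
    raise TargetNotFoundError(
        f"target region {target!r} not among {len(stats)} regions with statistics"
    )


def averaged_dtdi(stats: RegionStats, targets: Sequence[str]) -> DTDIResult:
    """Arithmetic mean of per-target DTDIs for a multi-target montage.

    The average of ratios each in [0, 1] stays in [0, 1].  The reported
    target mean is the average of the per-target regional means.
    """
    if len(targets) == 0:
        raise ValueError("at least one target region is required")
    parts = [compute_dtdi(stats, t) for t in targets]
    return DTDIResult(
        targets=tuple(targets),
        target_mean=float(np.mean([p.target_mean for p in parts])),
        peak_regions=parts[0].peak_regions,
        peak_mean=parts[0].peak_mean,
        dtdi=float(np.mean([p.dtdi for p in parts])),
        dose=stats.dose,
    )


def reverse_dose(
    actual_density: float,
    desired_density: float,
    fixed_dose: float,
    cap: float | None = 4.0,
) -> ReverseDoseResult:
    """Individualized dose = (desired density / actual density) × reference dose.

    Valid under the linear dose–field relationship.  Doses above the safety
    cap (default 4 mA, the upper end of tolerated tDCS currents) are clipped
    and flagged; pass ``cap=None`` to disable.
    """
    if not (actual_density > 0 and desired_density > 0 and fixed_dose > 0):
        raise ValueError(
            "actual density, desired density and reference dose must all be positive"
        )
    dose = (desired_density / actual_density) * fixed_dose
    clipped = cap is not None and dose > cap
    return ReverseDoseResult(
        dose=cap if clipped else dose, clipped=clipped, uncapped_dose=dose, cap=cap
    )


def classify_trend(dtdi_by_dose: Sequence[float], epsilon: float = 0.05) -> str:
    """Label a DTDI sequence constant / increasing / decreasing / mixed.

    Constant means the total swing (max − min) is within ``epsilon``;
    otherwise a non-decreasing sequence is increasing, a non-increasing one
    decreasing, and anything else mixed.
    """
    values = [float(v) for v in dtdi_by_dose]
    if len(values) < 2:
        raise ValueError("at least two values are required to classify a trend")
    if max(values) - min(values) <= epsilon:
        return "constant"
    diffs = np.diff(values)
    if (diffs >= 0).all():
        return "increasing"
    if (diffs <= 0).all():
        return "decreasing"
    return "mixed"


def linearity_index(target_density_by_dose: Mapping[float, float]) -> float:
    """Worst relative departure of target density from proportionality to dose.

    With the smallest dose d₀ as reference, the index is
    max over d of |(ρ(d)/ρ(d₀)) · (d₀/d) − 1|; 0 means the density scales
    exactly linearly with the injected current.
    """
    if len(target_density_by_dose) < 2:
        raise ValueError("at least two doses are required")
    doses = sorted(target_density_by_dose)
    rho = {d: float(target_density_by_dose[d]) for d in doses}
    if any(v <= 0 for v in rho.values()):
        raise ValueError("target densities must be positive")
    d0 = doses[0]
    return max(abs((rho[d] / rho[d0]) * (d0 / d) - 1.0) for d in doses)


def titrate(
    stats_by_dose: Mapping[float, RegionStats],
    target: str,
    epsilon: float = 0.05,
) -> DoseProfile:
    """DTDI across candidate doses, with trend class and linearity index."""
    if len(stats_by_dose) < 2:
        raise ValueError("titration requires statistics at two or more doses")
    doses = tuple(sorted(float(d) for d in stats_by_dose))
    results = tuple(compute_dtdi(stats_by_dose[d], target) for d in doses)
    trend = classify_trend([r.dtdi for r in results], epsilon=epsilon)
    lin = linearity_index({d: r.target_mean for d, r in zip(doses, results)})
    return DoseProfile(doses=doses, results=results, trend=trend, linearity=lin, epsilon=epsilon)


def recommend_dose(profile: DoseProfile, threshold: float = 0.75) -> DoseRecommendation:
    """Pick the dose with the highest DTDI; ties go to the lowest dose (safety).

    ``passes_threshold`` records whether the chosen DTDI clears the focality
    screening threshold (default 0.75).
    """
    best_dose, best = profile.doses[0], profile.results[0].dtdi
    for d, r in zip(profile.doses[1:], profile.results[1:]):
        if r.dtdi > best:
            best_dose, best = d, r.dtdi
    assert best == max(profile.dtdis)
    return DoseRecommendation(
        dose=best_dose,
        dtdi=best,
        passes_threshold=best >= threshold,
        threshold=threshold,
    )
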