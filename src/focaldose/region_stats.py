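"""Per-region current-density statistics: the regional dosimetry core.

Given a field and a voxel→region assignment, compute the arithmetic mean of
per-voxel current-density magnitudes within each atlas region, find the
peak region (the region with the highest mean — a candidate hotspot), and
rank the top fraction of regions by mean density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .field_io import CurrentDensityField, magnitude, region_table

__all__ = [
    "EmptyResultError",
    "RegionAssignment",
    "RegionStats",
    "region_means",
    "peak_region",
    "hotspot_table",
]


class EmptyResultError(ValueError):
    """No region satisfied the statistics contract (e.g. all below min_voxels)."""


@dataclass(frozen=True)
class RegionAssignment:
    """Per-voxel atlas label for one field; 0 marks unassigned voxels."""

    labels: np.ndarray
    mask: np.ndarray
    names: Mapping[int, str]
    unassigned_fraction: float = 0.0

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        mask = np.asarray(self.mask, dtype=bool)
        if labels.shape != mask.shape:
            raise ValueError("labels and mask shapes differ")
        present = set(np.unique(labels[mask]).tolist()) - {0}
        unknown = present - {int(k) for k in self.names}
        if unknown:
            raise ValueError(f"assigned labels missing from name table: {sorted(unknown)[:10]}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class RegionStats:
    """Mean density (mA/m²) and voxel count per region for one field."""

    names: tuple[str, ...]
    means: np.ndarray
    counts: np.ndarray
    dose: float
    dropped: tuple[str, ...] = ()

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if not (len(self.names) == len(means) == len(counts)):
            raise ValueError("names, means and counts must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("region names must be unique")
        if len(means) and (means < 0).any():
            raise ValueError("means must be non-negative")
        if len(counts) and (counts < 1).any():
            raise ValueError("counts must be >= 1")
        means.flags.writeable = False
        counts.flags.writeable = False
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "dropped", tuple(self.dropped))

    def __len__(self) -> int:
        return len(self.names)

    def mean_of(self, region: str) -> float:
        try:
            return float(self.means[self.names.index(region)])
        except ValueError:
            raise KeyError(f"region {region!r} not present in statistics") from None

    def as_table(self, source: str | None = None) -> pd.DataFrame:
        return region_table(self.names, self.means, self.counts, dose=self.dose, source=source)


def region_means(
    field: CurrentDensityField,
    assignment: RegionAssignment,
    min_voxels: int = 1,
) -> RegionStats:
    """Arithmetic mean of per-voxel density magnitude within each region.

    Regions with fewer than ``min_voxels`` assigned voxels are dropped from
    the statistics and listed in ``RegionStats.dropped``.  Unassigned voxels
    (label 0) never contribute.
    """
    if assignment.labels.shape != field.grid.shape:
        raise ValueError("assignment does not match the field grid")
    if min_voxels < 1:
        raise ValueError("min_voxels must be a positive integer")
    mags = magnitude(field).values
    sel = field.mask & assignment.mask & (assignment.labels > 0)
    lab = assignment.labels[sel]
    val = mags[sel]
    nbins = int(lab.max()) + 1 if lab.size else 1
    counts = np.bincount(lab, minlength=nbins)
    sums = np.bincount(lab, weights=val, minlength=nbins)
    present = np.flatnonzero(counts)
    keep = present[counts[present] >= min_voxels]
    dropped = [assignment.names[int(l)] for l in present if counts[l] < min_voxels]
    if keep.size == 0:
        raise EmptyResultError(
            f"no region has at least {min_voxels} assigned voxel(s)"
        )
    return RegionStats(
        names=tuple(assignment.names[int(l)] for l in keep),
        means=sums[keep] / counts[keep],
        counts=counts[keep],
        dose=field.dose,
        dropped=tuple(dropped),
    )


def peak_region(stats: RegionStats) -> tuple[tuple[str, ...], float]:
    """All regions attaining the maximum mean density, and that maximum.

    Ties are reported together, sorted lexicographically.
    """
    if len(stats) == 0:
        raise EmptyResultError("no regions in statistics")
    peak = float(stats.means.max())
    winners = tuple(sorted(n for n, m in zip(stats.names, stats.means) if m == peak))
    assert all(peak >= m for m in stats.means)
    return winners, peak


def hotspot_table(stats: RegionStats, fraction: float = 0.1) -> pd.DataFrame:
    """The top ``ceil(fraction × n_regions)`` regions by mean density.

    Sorted descending by mean (name as tie-break for a stable order); ties
    with the region at the cut are included, so the table may exceed the
    nominal size.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(stats) == 0:
        raise EmptyResultError("no regions in statistics")
    n = math.ceil(fraction * len(stats))
    order = sorted(range(len(stats)), key=lambda i: (-stats.means[i], stats.names[i]))
    cut_mean = stats.means[order[n - 1]]
    chosen = [i for rank, i in enumerate(order) if rank < n or stats.means[i] == cut_mean]
    return region_table(
        [stats.names[i] for i in chosen],
        stats.means[chosen],
        stats.counts[chosen],
        dose=stats.dose,
    )
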