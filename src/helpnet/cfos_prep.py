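"""Prepare raw c-Fos region counts for multivariate analysis.

Counts are normalized to cells per 250 um^2 so that differently sized
sampled areas are comparable across rats. Regions observed in fewer than
three subjects of any condition are excluded, and remaining missing cells
are interpolated by the mean of the observed values for that region within
the same condition. The pipeline order is fixed: exclusion first, then
interpolation — reversing it would let interpolated values rescue sparse
regions.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from helpnet.data_model import (
    ActivityMatrix,
    RegionActivityRecord,
    ValidationError,
    cfos_density,
    pivot_to_matrix,
)

__all__ = [
    "PrepReport",
    "compute_density",
    "exclude_sparse_regions",
    "interpolate_missing",
    "prepare",
]


@dataclass
class PrepReport:
    """Audit record of exclusions and interpolation for one prep run."""

    regions_in: int
    regions_excluded: list[tuple[str, str]] = field(default_factory=list)
    cells_interpolated: int = 0
    interpolation_mode: str = "condition_mean"

    @property
    def regions_out(self) -> int:
        return self.regions_in - len(self.regions_excluded)


def compute_density(
    records: Sequence[RegionActivityRecord],
    conditions: Mapping[str, str],
) -> ActivityMatrix:
    """Convert counts/areas to a density matrix (cells per 250 um^2)."""
    return pivot_to_matrix(records, conditions)


density = cfos_density  # scalar convention, re-exported for callers


def exclude_sparse_regions(
    m: ActivityMatrix, min_per_condition: int = 3
) -> tuple[ActivityMatrix, PrepReport]:
    """Drop regions with fewer than ``min_per_condition`` observed values
    in any condition."""
    if min_per_condition < 1:
        raise ValueError("min_per_condition must be >= 1")
    report = PrepReport(regions_in=m.n_regions)
    observed = ~np.isnan(m.values)
    keep = np.ones(m.n_regions, dtype=bool)
    for level in m.conditions:
        counts = observed[m.condition_mask(level)].sum(axis=0)
        for j in np.nonzero(counts < min_per_condition)[0]:
            if keep[j]:
                keep[j] = False
                report.regions_excluded.append(
                    (
                        m.region_ids[j],
                        f"only {int(counts[j])} value(s) in condition {level} "
                        f"(min {min_per_condition})",
                    )
                )
    if not keep.any():
        raise ValidationError("all regions excluded by the sparsity rule")
    out = ActivityMatrix(
        values=m.values[:, keep],
        subject_ids=list(m.subject_ids),
        region_ids=[r for r, k in zip(m.region_ids, keep) if k],
        condition=m.condition.copy(),
    )
    return out, report


def interpolate_missing(
    m: ActivityMatrix, mode: str = "condition_mean"
) -> tuple[ActivityMatrix, PrepReport]:
    """Fill missing cells with the per-(condition, region) observed mean."""
    if mode != "condition_mean":
        raise ValueError(f"unknown interpolation mode {mode!r}")
    values = m.values.copy()
    n_filled = 0
    for level in m.conditions:
        rows = m.condition_mask(level)
        block = values[rows]
        missing = np.isnan(block)
        if not missing.any():
            continue
        counts = (~missing).sum(axis=0)
        empty = np.nonzero((counts == 0) & missing.any(axis=0))[0]
        if empty.size:
            raise ValidationError(
                f"condition {level} has no observed values for region(s) "
                f"{[m.region_ids[j] for j in empty[:5]]}; exclude them first"
            )
        with np.errstate(invalid="ignore"):
            means = np.nanmean(block, axis=0)
        block[missing] = np.broadcast_to(means, block.shape)[missing]
        values[rows] = block
        n_filled += int(missing.sum())
    out = ActivityMatrix(
        values=values,
        subject_ids=list(m.subject_ids),
        region_ids=list(m.region_ids),
        condition=m.condition.copy(),
    )
    report = PrepReport(
        regions_in=m.n_regions, cells_interpolated=n_filled, interpolation_mode=mode
    )
    return out, report


def prepare(
    records: Sequence[RegionActivityRecord],
    conditions: Mapping[str, str],
    min_per_condition: int = 3,
) -> tuple[ActivityMatrix, PrepReport]:
    """Full prep: density pivot, sparsity exclusion, then interpolation."""
    m = compute_density(records, conditions)
    m, report = exclude_sparse_regions(m, min_per_condition)
    m, interp_report = interpolate_missing(m)
    report.cells_interpolated = interp_report.cells_interpolated
    report.interpolation_mode = interp_report.interpolation_mode
    return m, report
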