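"""Summary statistics and cohort comparisons.

Per mechanical environment the headline statistic is the median effective
strain; cohorts are summarised as mean ± SD (sample SD, n−1) of per-animal
medians for each (group, week) cell. Histograms use a fixed grid of 250
bins over 0–15,000 µε with an explicit overflow bucket so counts always
conserve the sample size. Bone volume is reported normalised to the week 0
value (BV/BV0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .adapt import ks_statistic  # re-exported convenience for group KS curves
from .errors import InvalidInputError, ScenarioAlignmentError
from .microfe import StrainDistribution

__all__ = [
    "HistogramSpec",
    "CohortRecord",
    "median_strain",
    "strain_histogram",
    "group_summary",
    "normalized_bone_volume",
    "compare_scenarios",
    "ks_statistic",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Fixed histogram grid: left-closed right-open bins over [low, high)."""

    low_ue: float = 0.0
    high_ue: float = 15_000.0
    bins: int = 250

    def __post_init__(self) -> None:
        if not self.high_ue > self.low_ue:
            raise InvalidInputError("histogram range must have high > low")
        if self.bins < 1:
            raise InvalidInputError("histogram needs at least one bin")

    @property
    def bin_width_ue(self) -> float:
        return (self.high_ue - self.low_ue) / self.bins

    def edges(self) -> np.ndarray:
        return np.linspace(self.low_ue, self.high_ue, self.bins + 1)


@dataclass
class CohortRecord:
    """One animal × time-point row of a cohort table."""

    animal_id: str
    group: str  # "loaded" | "control"
    week: int
    median_strain_ue: float
    applied_force_n: float
    bone_volume_mm3: float
    bv_ratio: float  # BV / BV(week 0)

    def __post_init__(self) -> None:
        if self.bv_ratio <= 0:
            raise InvalidInputError("BV/BV0 must be > 0")


def median_strain(dist: StrainDistribution | np.ndarray | Sequence[float]) -> float:
    """Sample median in µε (mean of the middle two values for even sizes)."""
    values = dist.strains_ue if isinstance(dist, StrainDistribution) else np.asarray(dist)
    if np.size(values) == 0:
        raise InvalidInputError("median of an empty distribution is undefined")
    return float(np.median(values))


def strain_histogram(
    dist: StrainDistribution | np.ndarray | Sequence[float],
    spec: HistogramSpec | None = None,
) -> tuple[np.ndarray, int]:
    """Counts per bin plus an explicit overflow count for values ≥ high.

    Counts + overflow always equal the sample size; out-of-range values are
    never dropped or clipped.
    """
    spec = spec or HistogramSpec()
    values = dist.strains_ue if isinstance(dist, StrainDistribution) else np.asarray(dist, float)
    values = np.ravel(values)
    overflow = int(np.count_nonzero(values >= spec.high_ue))
    in_range = values[(values >= spec.low_ue) & (values < spec.high_ue)]
    # np.histogram closes the last bin on the right; half-open semantics are
    # preserved because values >= high were already diverted to overflow
    counts, _ = np.histogram(in_range, bins=spec.bins, range=(spec.low_ue, spec.high_ue))
    return counts.astype(np.int64), overflow


def group_summary(records: Sequence[CohortRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of per-animal median strains for every (group, week) cell.

    SD uses the n−1 denominator and is NaN (an explicit undefined marker)
    for single-animal cells; the row also carries the animal count.
    """
    df = _records_frame(records)
    if df.empty:
        raise InvalidInputError("no records to summarise")
    out = (
        df.groupby(["group", "week"], sort=True)["median_strain_ue"]
        .agg(mean_ue="mean", sd_ue=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def normalized_bone_volume(
    series_masks: Sequence[np.ndarray], voxel_size: float
) -> np.ndarray:
    """BV/BV0 per time point from a series of bone masks (week 0 first)."""
    if len(series_masks) == 0:
        raise InvalidInputError("empty mask series")
    counts = np.array([int(np.count_nonzero(m)) for m in series_masks], dtype=float)
    if counts[0] == 0:
        raise InvalidInputError("week 0 bone mask is empty; BV/BV0 undefined")
    bv = counts * voxel_size**3
    return bv / bv[0]


def _records_frame(records: Sequence[CohortRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


def compare_scenarios(
    constant: Sequence[CohortRecord] | pd.DataFrame,
    adaptive: Sequence[CohortRecord] | pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Contrast constant loading with per-session adaptive loading.

    Both tables must cover identical (animal, week) pairs. Returns
    ``summary``: per-(group, week) mean ± SD of medians under both
    scenarios and the adaptive/constant SD ratio (NaN marks undefined
    cells), and ``loads``: per-animal recommended-load trajectories.
    """
    dc = _records_frame(constant)
    da = _records_frame(adaptive)
    key = ["animal_id", "week"]
    if sorted(map(tuple, dc[key].values.tolist())) != sorted(
        map(tuple, da[key].values.tolist())
    ):
        raise ScenarioAlignmentError(
            "constant and adaptive scenarios cover different animal/week pairs"
        )
    sc = group_summary(dc).rename(
        columns={"mean_ue": "constant_mean_ue", "sd_ue": "constant_sd_ue"}
    )
    sa = group_summary(da).rename(
        columns={"mean_ue": "adaptive_mean_ue", "sd_ue": "adaptive_sd_ue"}
    )
    summary = sc.merge(sa.drop(columns="n"), on=["group", "week"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = summary["adaptive_sd_ue"] / summary["constant_sd_ue"]
    summary["sd_ratio"] = ratio.where(summary["constant_sd_ue"] > 0)
    loads = da.pivot_table(
        index="animal_id", columns="week", values="applied_force_n", aggfunc="first"
    )
    return {"summary": summary, "loads": loads}
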