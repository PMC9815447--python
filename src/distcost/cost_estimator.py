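"""Privacy-preserving distance-cost estimation (the index-development arm).

Patient counts are never observed: the expected case count of a basic
statistical area is its resident population times the regional disease
prevalence, n' = round(pop x prevalence).  Each unit contributes
n' x D'c to the total distance cost, where D'c is the road-network distance
from the unit's population center to the facility, and the regional cost is

    D = sum_units n' * D'c

with the case-weighted average D / sum n' as the headline "average distance
to care".  No address-level data enters anywhere in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError
from .region_model import Region
from .road_network import ODMatrix

#: below this insured/resident ratio the resident-population proxy is weak
COVERAGE_THRESHOLD = 0.95


@dataclass
class PrevalenceRecord:
    """One row of a public prevalence table (stored as a fraction in [0,1])."""

    region_id: str
    year: int
    disease: str
    prevalence: float
    resident_population: int = 0
    insured_population: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(
                f"prevalence must be in [0, 1], got {self.prevalence} "
                f"({self.region_id}/{self.year}/{self.disease})"
            )
        if self.resident_population < 0 or (
            self.insured_population is not None and self.insured_population < 0
        ):
            raise ValidationError("populations must be >= 0")


def coverage_check(insured_population: int, resident_population: int) -> float:
    """Insured / resident ratio.

    The resident population stands in for the insured one when estimating
    patient counts; a ratio below ~0.95 means that proxy is weaker and
    callers should warn.
    """
    if resident_population <= 0:
        raise ValidationError("resident_population must be > 0")
    return insured_population / resident_population


def estimate_patient_count(population: int, prevalence: float) -> int:
    """Expected patient count n' = round(population x prevalence).

    Rounding is half-away-from-zero (so 0.5 rounds up for the non-negative
    quantities here), which reproduces the published worked estimates up to
    the +/-1 slack inherent in a prevalence printed to 2 decimals.
    """
    if population < 0:
        raise ValidationError(f"population must be >= 0, got {population}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValidationError(f"prevalence must be in [0, 1], got {prevalence}")
    return int(math.floor(population * prevalence + 0.5))


@dataclass
class UnitEstimate:
    """Estimated burden of one unit: n' cases at network distance D'c."""

    unit_id: str
    expected_cases: float
    estimated_cases: int
    network_distance: float | None = None

    @property
    def contribution(self) -> float:
        """Distance contribution n' x D'c in meter-persons."""
        if self.network_distance is None:
            raise ValidationError(f"unit {self.unit_id!r} has no network distance")
        return self.estimated_cases * self.network_distance


@dataclass
class AllocationResult:
    """Per-unit case allocation plus the region-level rounding audit.

    ``region_total`` is round(region population x prevalence) — computed
    from the region total, not by summing per-unit roundings — and
    ``rounding_discrepancy`` is (sum of per-unit roundings) - region_total.
    """

    estimates: list[UnitEstimate]
    region_total: int
    rounding_discrepancy: int

    @property
    def expected_total(self) -> float:
        return sum(e.expected_cases for e in self.estimates)


def allocate_unit_cases(
    region: Region,
    prevalence: float | dict[str, float],
) -> AllocationResult:
    """Allocate expected cases to every unit of ``region``.

    ``prevalence`` is either a single region-wide fraction applied
    uniformly, or a per-unit mapping unit_id -> fraction (which overrides
    the region rate where present; missing units get 0 only if no region
    rate can be formed, so pass a plain float for the uniform case).
    """
    if isinstance(prevalence, dict):
        rates = {u.unit_id: prevalence[u.unit_id] for u in region.units}
        region_rate = None
    else:
        rates = {u.unit_id: float(prevalence) for u in region.units}
        region_rate = float(prevalence)
    estimates = [
        UnitEstimate(
            unit_id=u.unit_id,
            expected_cases=u.population * rates[u.unit_id],
            estimated_cases=estimate_patient_count(u.population, rates[u.unit_id]),
        )
        for u in region.units
    ]
    if region_rate is not None:
        region_total = estimate_patient_count(region.population, region_rate)
    else:
        region_total = int(
            math.floor(sum(e.expected_cases for e in estimates) + 0.5)
        )
    discrepancy = sum(e.estimated_cases for e in estimates) - region_total
    return AllocationResult(estimates, region_total, discrepancy)


@dataclass
class CostSummary:
    """Aggregated distance cost at one level (unit, community, or region).

    ``rows`` carries one record per group: group id, how many member units
    exist and how many entered the average (they differ when a patient mask
    restricts to inhabited areas), case count, case-weighted average
    distance, and total distance.  Conservation holds by construction:
    ``total_distance`` equals the sum of member contributions.
    """

    level: str
    total_cases: int
    total_distance: float
    average_distance: float
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class CostReport:
    """Cost summaries at all three aggregation levels."""

    unit: CostSummary
    community: CostSummary
    region: CostSummary


def _summarize(level: str, groups: dict[str, dict]) -> CostSummary:
    rows = []
    for gid in sorted(groups):
        g = groups[gid]
        cases = g["cases"]
        total = g["total"]
        rows.append(
            {
                "group_id": gid,
                "n_units_total": g["n_total"],
                "n_units_used": g["n_used"],
                "estimated_cases": cases,
                "average_distance_m": total / cases if cases > 0 else float("nan"),
                "total_distance_m": total,
            }
        )
    df = pd.DataFrame(rows)
    total_cases = int(sum(g["cases"] for g in groups.values()))
    total_distance = float(sum(g["total"] for g in groups.values()))
    return CostSummary(
        level=level,
        total_cases=total_cases,
        total_distance=total_distance,
        average_distance=total_distance / total_cases if total_cases else float("nan"),
        rows=df,
    )


def estimated_cost(
    estimates: list[UnitEstimate],
    od: ODMatrix,
    region: Region,
    facility_id: str,
    unit_mask: set[str] | None = None,
) -> CostReport:
    """Aggregate per-unit contributions n' x D'c to all levels.

    ``unit_mask``, when given, restricts case counts and averages to the
    listed units — used to mirror a validation cohort that inhabits only a
    subset of areas, so the two arms average over the same geography.
    Distances are taken from ``od``; a unit missing there is an error.
    """
    missing = [
        e.unit_id for e in estimates if (e.unit_id, facility_id) not in od.entries
    ]
    if missing:
        raise ValidationError(f"no OD entry for unit(s): {missing[:10]}")

    unit_groups: dict[str, dict] = {}
    comm_groups: dict[str, dict] = {}
    region_group = {"cases": 0, "total": 0.0, "n_total": 0, "n_used": 0}
    for e in estimates:
        e.network_distance = od.distance(e.unit_id, facility_id)
        used = unit_mask is None or e.unit_id in unit_mask
        cid = region.community_of(e.unit_id)
        cg = comm_groups.setdefault(
            cid, {"cases": 0, "total": 0.0, "n_total": 0, "n_used": 0}
        )
        cg["n_total"] += 1
        region_group["n_total"] += 1
        if not used:
            continue
        contrib = e.contribution
        unit_groups[e.unit_id] = {
            "cases": e.estimated_cases,
            "total": contrib,
            "n_total": 1,
            "n_used": 1,
        }
        cg["cases"] += e.estimated_cases
        cg["total"] += contrib
        cg["n_used"] += 1
        region_group["cases"] += e.estimated_cases
        region_group["total"] += contrib
        region_group["n_used"] += 1

    return CostReport(
        unit=_summarize("unit", unit_groups),
        community=_summarize("community", comm_groups),
        region=_summarize("region", {region.name or "region": region_group}),
    )


def share_of_areas(n_used: int, n_total: int) -> float:
    """Percentage of areas in use, rounded to 1 decimal as printed in reports."""
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    return round(100.0 * n_used / n_total, 1)
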