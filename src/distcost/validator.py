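"""Validation arm: individual distances, agreement (ICC), adjusted regression.

The validation cohort has real residential locations, so the actual
distance d_ij of each patient can be measured on the road network.  The
claim under test is the identity D = sum d_ij = sum n' * D'c: averaging per
area, the estimated distance of an area should be interchangeable with the
observed mean distance of its residents.  Agreement is quantified by the
intraclass correlation coefficient computed from two-way ANOVA mean
squares (absolute-agreement, single-measures form by default), and by an
OLS regression of estimated on actual distance adjusted for patient age
and gender.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cost_estimator import (
    AllocationResult,
    CostReport,
    CostSummary,
    allocate_unit_cases,
    estimated_cost,
)
from .exceptions import DegenerateInputError, ValidationError
from .region_model import Coord, Facility, Region
from .road_network import ODMatrix, RoadGraph, od_matrix, snap
import networkx as nx

logger = logging.getLogger(__name__)

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass
class PatientRecord:
    """One validation-group outpatient with a known residence."""

    patient_id: str
    location: Coord
    unit_id: str
    age: float
    gender: int  # male = 1, female = 0
    disease: str = ""
    year: int = 0

    def __post_init__(self):
        if self.gender not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: gender must be 0 or 1, got {self.gender}"
            )
        if not self.age > 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: age must be > 0, got {self.age}"
            )


@dataclass
class IndividualDistanceSet:
    """Per-patient network distances d_ij with drop accounting."""

    records: list[tuple[str, str, float]]  # (patient_id, unit_id, d_ij)
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def total(self) -> float:
        return float(sum(d for _, _, d in self.records))

    def unit_means(self) -> dict[str, float]:
        sums: dict[str, list[float]] = {}
        for _, uid, d in self.records:
            sums.setdefault(uid, []).append(d)
        return {uid: float(np.mean(v)) for uid, v in sums.items()}


def individual_distances(
    patients: list[PatientRecord],
    facility: Facility,
    graph: RoadGraph,
    include_connectors: bool = True,
) -> IndividualDistanceSet:
    """Network distance from each patient's residence to the facility.

    Residences and the facility are snapped to their nearest nodes; with
    connectors on, the snap gaps are added as straight-line segments.
    Patients on a component disconnected from the facility are dropped with
    a warning, never silently given distance 0.
    """
    fac_node, fac_gap = snap(facility.location, graph)
    dist = nx.single_source_dijkstra_path_length(graph.graph, fac_node, weight="length")
    records: list[tuple[str, str, float]] = []
    dropped: list[str] = []
    for p in patients:
        node, gap = snap(p.location, graph)
        base = dist.get(node)
        if base is None:
            dropped.append(p.patient_id)
            continue
        d = base + (gap + fac_gap if include_connectors else 0.0)
        records.append((p.patient_id, p.unit_id, d))
    if dropped:
        logger.warning(
            "%d patient(s) unreachable from facility, excluded: %s",
            len(dropped), dropped[:10],
        )
    return IndividualDistanceSet(records=records, dropped=dropped)


def paired_area_distances(
    actual: IndividualDistanceSet,
    estimated: CostSummary,
    level: str,
    region: Region | None = None,
) -> list[tuple[str, float, float]]:
    """Pair actual and estimated mean distances per area.

    One pair per group with at least one validation patient; uninhabited
    groups are dropped, mirroring a cohort that occupies only a subset of
    the region's areas.  ``level`` is "unit" or "community"; community
    pairing needs ``region`` to map unit ids to communities.
    """
    if level not in ("unit", "community"):
        raise ValidationError(f"level must be 'unit' or 'community', got {level!r}")
    groups: dict[str, list[float]] = {}
    for _, uid, d in actual.records:
        gid = uid if level == "unit" else region.community_of(uid)  # type: ignore[union-attr]
        groups.setdefault(gid, []).append(d)
    est = estimated.rows.set_index("group_id")["average_distance_m"]
    pairs = [
        (gid, float(np.mean(ds)), float(est[gid]))
        for gid, ds in sorted(groups.items())
        if gid in est.index and np.isfinite(est[gid])
    ]
    if not pairs:
        raise DegenerateInputError("no overlapping groups between the two arms")
    return pairs


@dataclass
class AgreementResult:
    """ICC with its 95% CI and F-test p-value at one pairing level."""

    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    pairing_level: str
    n_pairs: int
    form: str = "agreement"
    degenerate_ci: bool = False


def _anova_mean_squares(x: np.ndarray, y: np.ndarray):
    """Two-way ANOVA mean squares for an n x 2 rating table."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(
    pairs: list[tuple[float, float]],
    form: str = "agreement",
    pairing_level: str = "unit",
    alpha: float = ALPHA,
) -> AgreementResult:
    """Intraclass correlation between two measurement columns.

    Default is the two-way random-effects, absolute-agreement,
    single-measures form,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),  k = 2,

    the conservative choice when the claim is that the two measurements are
    interchangeable (a systematic offset lowers it).  ``form="consistency"``
    drops the column-variance penalty.  The 95% CI follows the standard
    F-based construction; the p-value tests ICC = 0 via F = MSR/MSE on
    (n-1, (n-1)(k-1)) degrees of freedom.
    """
    if form not in ("agreement", "consistency"):
        raise ValidationError(f"unknown ICC form {form!r}")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateInputError("need at least 3 (x, y) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite values in pairs")
    x, y = arr[:, 0], arr[:, 1]
    msr, msc, mse, n, k = _anova_mean_squares(x, y)

    # all measurements identical: perfect, but no variance to form a CI from
    if msr <= 0 and mse <= 0:
        return AgreementResult(1.0, 1.0, 1.0, 0.0, pairing_level, n, form, True)

    if form == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        val = (msr - mse) / denom if denom > 0 else 1.0
    else:
        denom = msr + (k - 1) * mse
        val = (msr - mse) / denom if denom > 0 else 1.0

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse > 0:
        f_obs = msr / mse
        p = float(stats.f.sf(f_obs, df1, df2))
    else:
        p = 0.0

    degenerate = mse <= 0 or not np.isfinite(val) or abs(1.0 - val) < 1e-15
    if degenerate:
        return AgreementResult(float(val), float(val), float(val), p,
                               pairing_level, n, form, True)

    if form == "agreement":
        a = (k * val) / (n * (1.0 - val))
        b = 1.0 + (k * val * (n - 1)) / (n * (1.0 - val))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, df1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, df1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        f_obs = msr / mse
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    return AgreementResult(
        float(val), float(lo), float(hi), p, pairing_level, n, form, False
    )


@dataclass
class RegressionResult:
    """OLS of estimated distance on actual distance, gender, age."""

    coefficients: dict[str, float]
    standardized_betas: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    adjusted_r2: float
    r2: float
    n: int


_PREDICTORS = ("actual_distance", "gender", "age")


def adjusted_regression(
    patients: list[PatientRecord],
    actual_d: np.ndarray,
    estimated_d: np.ndarray,
) -> RegressionResult:
    """Regress each patient's estimated (area-level) distance on their
    actual distance, adjusting for gender (male = 1) and age.

    Standardized betas are b_j * sd(x_j) / sd(y); adjusted R-squared is
    1 - (1 - R^2)(n - 1)/(n - p - 1).  A collinear or constant predictor
    column is an error naming the column, not a silent drop.
    """
    y = np.asarray(estimated_d, dtype=float)
    xd = np.asarray(actual_d, dtype=float)
    if len(patients) != len(y) or len(xd) != len(y):
        raise ValidationError("patients, actual_d and estimated_d lengths differ")
    n = len(y)
    if n <= 4:
        raise DegenerateInputError(f"need n > 4 patients, got {n}")
    X = np.column_stack(
        [xd, [p.gender for p in patients], [p.age for p in patients]]
    )
    for j, name in enumerate(_PREDICTORS):
        if np.std(X[:, j]) == 0:
            raise ValidationError(f"predictor {name!r} is constant (rank deficient)")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    names = ("intercept",) + _PREDICTORS
    coefs = dict(zip(names, map(float, fit.params)))
    ci_arr = fit.conf_int(alpha=ALPHA)
    cis = {nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci_arr)}
    pvals = dict(zip(names, map(float, fit.pvalues)))
    sy = np.std(y, ddof=1)
    betas = {
        nm: float(coefs[nm] * np.std(X[:, j], ddof=1) / sy)
        for j, nm in enumerate(_PREDICTORS)
    }
    return RegressionResult(
        coefficients=coefs,
        standardized_betas=betas,
        conf_int=cis,
        p_values=pvals,
        adjusted_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        n=n,
    )


@dataclass
class ValidationReport:
    """End-to-end comparison of the two arms for one disease-year."""

    od: ODMatrix
    allocation: AllocationResult
    cost: CostReport                      # masked to inhabited units
    cost_all: CostReport                  # full region, no mask
    distances: IndividualDistanceSet | None = None
    pairs_unit: list[tuple[str, float, float]] | None = None
    pairs_community: list[tuple[str, float, float]] | None = None
    icc_unit: AgreementResult | None = None
    icc_community: AgreementResult | None = None
    regression: RegressionResult | None = None

    @property
    def estimation_only(self) -> bool:
        return self.distances is None


def agreement_report(
    region: Region,
    patients: list[PatientRecord],
    facility: Facility,
    graph: RoadGraph,
    prevalence: float,
    include_connectors: bool = True,
    icc_form: str = "agreement",
) -> ValidationReport:
    """Run both arms end to end and compare them.

    Estimation arm: OD matrix, per-unit n' = pop x prevalence, cost
    aggregation.  Validation arm (skipped when ``patients`` is empty):
    per-patient d_ij, area-level pairing at unit and community level, ICC at
    both levels, and the age/gender-adjusted regression with per-patient
    outcome = the estimated distance D'c of the patient's area.
    """
    od = od_matrix(region, facility, graph, include_connectors=include_connectors)
    allocation = allocate_unit_cases(region, prevalence)
    facility_id = facility.facility_id
    cost_all = estimated_cost(allocation.estimates, od, region, facility_id)
    if not patients:
        return ValidationReport(od=od, allocation=allocation,
                                cost=cost_all, cost_all=cost_all)

    dist = individual_distances(patients, facility, graph,
                                include_connectors=include_connectors)
    inhabited = {uid for _, uid, _ in dist.records}
    cost = estimated_cost(allocation.estimates, od, region, facility_id,
                          unit_mask=inhabited)
    pairs_u = paired_area_distances(dist, cost.unit, "unit")
    pairs_c = paired_area_distances(dist, cost.community, "community", region)
    icc_u = icc([(a, e) for _, a, e in pairs_u], form=icc_form, pairing_level="unit")
    icc_c = icc([(a, e) for _, a, e in pairs_c], form=icc_form,
                pairing_level="community")

    kept = {pid for pid, _, _ in dist.records}
    pat_kept = [p for p in patients if p.patient_id in kept]
    d_by_pid = {pid: d for pid, _, d in dist.records}
    unit_d = od.unit_distances(facility_id)
    actual = np.array([d_by_pid[p.patient_id] for p in pat_kept])
    estimated = np.array([unit_d[p.unit_id] for p in pat_kept])
    reg = adjusted_regression(pat_kept, actual, estimated)
    return ValidationReport(
        od=od, allocation=allocation, cost=cost, cost_all=cost_all,
        distances=dist, pairs_unit=pairs_u, pairs_community=pairs_c,
        icc_unit=icc_u, icc_community=icc_c, regression=reg,
    )


def report_tables(report: ValidationReport) -> dict[str, pd.DataFrame]:
    """Flatten a :class:`ValidationReport` into CSV-ready tables."""
    tables = {
        "estimates_unit": report.cost.unit.rows,
        "estimates_community": report.cost.community.rows,
        "estimates_region": report.cost.region.rows,
    }
    if report.estimation_only:
        return tables
    tables["pairs_unit"] = pd.DataFrame(
        report.pairs_unit, columns=["group_id", "actual_mean_m", "estimated_mean_m"]
    )
    tables["pairs_community"] = pd.DataFrame(
        report.pairs_community, columns=["group_id", "actual_mean_m", "estimated_mean_m"]
    )
    icc_rows = [
        {
            "pairing_level": r.pairing_level, "n_pairs": r.n_pairs, "form": r.form,
            "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value,
        }
        for r in (report.icc_unit, report.icc_community)
    ]
    tables["icc"] = pd.DataFrame(icc_rows)
    reg = report.regression
    reg_rows = [
        {
            "variable": nm,
            "coefficient": reg.coefficients[nm],
            "standardized_beta": reg.standardized_betas.get(nm, float("nan")),
            "ci_low": reg.conf_int[nm][0],
            "ci_high": reg.conf_int[nm][1],
            "p_value": reg.p_values[nm],
        }
        for nm in ("intercept",) + _PREDICTORS
    ]
    tables["regression"] = pd.DataFrame(reg_rows)
    return tables
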