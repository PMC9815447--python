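import numpy as np
import pandas as pd
import pytest

from distcost.cost_estimator import allocate_unit_cases, estimated_cost
from distcost.exceptions import DegenerateInputError, ValidationError
from distcost.region_model import Facility
from distcost.road_network import RoadGraph, network_distance, od_matrix, snap
from distcost.validator import (
    PatientRecord,
    adjusted_regression,
    agreement_report,
    icc,
    individual_distances,
    paired_area_distances,
    report_tables,
)

# 6 hand-sized pairs; expected values frozen from an independent two-way
# ANOVA mean-squares computation (verified against pingouin.intraclass_corr)
HAND_PAIRS = [(70.1, 71.0), (82.5, 81.9), (90.0, 90.4),
              (68.3, 69.9), (85.2, 84.8), (77.7, 78.5)]
HAND_ICC_AGREEMENT = 0.9942988566107747
HAND_ICC_CONSISTENCY = 0.9949277601134637
HAND_P = 1.7548588415644564e-06


def pg_icc(pairs, kind):
    """Independent oracle: pingouin's ICC on the long-format table."""
    import pingouin as pg

    arr = np.asarray(pairs, float)
    n = len(arr)
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), 2),
            "raters": np.tile(["a", "b"], n),
            "score": arr.ravel(),
        }
    )
    t = pg.intraclass_corr(df, targets="targets", raters="raters",
                           ratings="score").set_index("Type")
    return t.loc[kind]


class TestPatientRecord:
    def test_gender_domain(self):
        with pytest.raises(ValidationError, match="gender"):
            PatientRecord("p", (0, 0), "u", 50, 2)

    def test_positive_age(self):
        with pytest.raises(ValidationError, match="age"):
            PatientRecord("p", (0, 0), "u", 0, 1)


class TestIndividualDistances:
    def test_patient_at_facility_node(self, path_region):
        _, graph, facility = path_region
        pats = [PatientRecord("p1", (0.0, 0.0), "u1", 50, 1)]
        res = individual_distances(pats, facility, graph)
        assert res.records[0][2] == 0.0

    def test_three_patients_same_node(self, path_region):
        _, graph, _ = path_region
        fac = Facility("f0", (2000.0, 0.0))  # snaps to b at 2500 with 500 m gap
        pats = [PatientRecord(f"p{i}", (2500.0, 0.0), "u2", 50, i % 2)
                for i in range(3)]
        res = individual_distances(pats, fac, graph, include_connectors=True)
        assert res.total == pytest.approx(1500.0)
        assert res.total / res.n == pytest.approx(500.0)

    def test_matches_per_pair_oracle(self, default_scenario):
        sc = default_scenario
        pats = sc.patients[:40]
        res = individual_distances(pats, sc.facility, sc.graph,
                                   include_connectors=False)
        fac_node, _ = snap(sc.facility.location, sc.graph)
        for (pid, _, d), p in zip(res.records, pats):
            node, _ = snap(p.location, sc.graph)
            assert d == pytest.approx(
                network_distance(fac_node, node, sc.graph), rel=1e-12
            )

    def test_unreachable_patient_dropped_with_count(self):
        g = RoadGraph({"a": (0, 0), "b": (10, 0), "c": (999, 999), "d": (999, 1000)},
                      [("a", "b", 10.0), ("c", "d", 1.0)])
        pats = [
            PatientRecord("ok", (10.0, 0.0), "u1", 40, 1),
            PatientRecord("lost", (999.0, 999.0), "u2", 40, 0),
        ]
        res = individual_distances(pats, Facility("f", (0.0, 0.0)), g)
        assert res.n == 1 and res.dropped == ["lost"]

    def test_unit_means_bounded_by_member_distances(self, default_scenario):
        sc = default_scenario
        res = individual_distances(sc.patients, sc.facility, sc.graph)
        per_unit: dict[str, list[float]] = {}
        for _, uid, d in res.records:
            per_unit.setdefault(uid, []).append(d)
        means = res.unit_means()
        for uid, ds in per_unit.items():
            assert min(ds) - 1e-9 <= means[uid] <= max(ds) + 1e-9


class TestPairedAreaDistances:
    def _cost(self, scenario, inhabited):
        od = od_matrix(scenario.region, scenario.facility, scenario.graph)
        alloc = allocate_unit_cases(scenario.region, scenario.config.prevalence)
        return estimated_cost(alloc.estimates, od, scenario.region, "hospital",
                              unit_mask=inhabited)

    def test_identity_inputs_give_equal_means(self, identity_scenario):
        sc = identity_scenario
        dist = individual_distances(sc.patients, sc.facility, sc.graph)
        inhabited = {uid for _, uid, _ in dist.records}
        cost = self._cost(sc, inhabited)
        pairs = paired_area_distances(dist, cost.unit, "unit")
        for _, actual, estimated in pairs:
            assert actual == pytest.approx(estimated, rel=1e-12)

    def test_pair_count_equals_inhabited_units(self, default_scenario):
        sc = default_scenario
        dist = individual_distances(sc.patients, sc.facility, sc.graph)
        inhabited = {uid for _, uid, _ in dist.records}
        cost = self._cost(sc, inhabited)
        pairs = paired_area_distances(dist, cost.unit, "unit")
        assert len(pairs) == len(inhabited)

    def test_community_level_pairs(self, default_scenario):
        sc = default_scenario
        dist = individual_distances(sc.patients, sc.facility, sc.graph)
        inhabited = {uid for _, uid, _ in dist.records}
        cost = self._cost(sc, inhabited)
        pairs = paired_area_distances(dist, cost.community, "community", sc.region)
        lived_comms = {sc.region.community_of(uid) for uid in inhabited}
        assert {g for g, _, _ in pairs} == lived_comms


class TestICC:
    def test_perfect_agreement(self):
        pairs = [(x, x) for x in (1.0, 5.0, 9.0, 13.0)]
        res = icc(pairs)
        assert res.icc == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_anticorrelated_is_negative(self):
        x = np.linspace(-50, 50, 12)
        res = icc(list(zip(x, -x)))
        assert res.icc < 0

    def test_hand_pairs_match_frozen_anova_oracle(self):
        res = icc(HAND_PAIRS)
        assert res.icc == pytest.approx(HAND_ICC_AGREEMENT, rel=1e-10)
        assert res.p_value == pytest.approx(HAND_P, rel=1e-6)
        assert res.ci_low <= res.icc <= res.ci_high
        cons = icc(HAND_PAIRS, form="consistency")
        assert cons.icc == pytest.approx(HAND_ICC_CONSISTENCY, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pingouin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        x = rng.normal(100, 20, n)
        y = x + rng.normal(0, 5, n) + 3.0
        pairs = list(zip(x, y))
        mine = icc(pairs)
        ref = pg_icc(pairs, "ICC(A,1)")
        assert mine.icc == pytest.approx(float(ref.ICC), rel=1e-9)
        assert mine.p_value == pytest.approx(float(ref.pval), rel=1e-6)
        lo, hi = ref["CI95"]
        assert mine.ci_low == pytest.approx(lo, abs=0.01)
        assert mine.ci_high == pytest.approx(hi, abs=0.01)

    def test_symmetric_in_columns(self):
        res_xy = icc(HAND_PAIRS)
        res_yx = icc([(y, x) for x, y in HAND_PAIRS])
        assert res_xy.icc == pytest.approx(res_yx.icc, rel=1e-12)

    def test_invariant_to_common_affine_rescaling(self):
        scaled = [(3.0 * x - 7.0, 3.0 * y - 7.0) for x, y in HAND_PAIRS]
        assert icc(scaled).icc == pytest.approx(icc(HAND_PAIRS).icc, rel=1e-10)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            icc([(1.0, 1.0), (2.0, 2.0)])

    def test_constant_identical_columns_degenerate_one(self):
        res = icc([(5.0, 5.0)] * 4)
        assert res.icc == 1.0 and res.degenerate_ci


def make_patients(rng, n):
    return [
        PatientRecord(f"p{i}", (0.0, 0.0), f"u{i}",
                      age=float(rng.uniform(30, 90)),
                      gender=int(rng.integers(0, 2)))
        for i in range(n)
    ]


class TestAdjustedRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(1)
        pats = make_patients(rng, 30)
        x = rng.uniform(60_000, 95_000, 30)
        y = 2.0 * x
        res = adjusted_regression(pats, x, y)
        assert res.coefficients["actual_distance"] == pytest.approx(2.0)
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert abs(res.coefficients["gender"]) < 1e-6
        assert abs(res.coefficients["age"]) < 1e-6

    def test_adjusted_r2_closed_form(self):
        rng = np.random.default_rng(2)
        pats = make_patients(rng, 40)
        x = rng.uniform(0, 100, 40)
        y = x + rng.normal(0, 20, 40)
        res = adjusted_regression(pats, x, y)
        n, p = res.n, 3
        assert res.adjusted_r2 == pytest.approx(
            1 - (1 - res.r2) * (n - 1) / (n - p - 1), rel=1e-12
        )
        assert res.adjusted_r2 <= res.r2

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        pats = make_patients(rng, 20)
        x = rng.uniform(0, 100, 20)
        y = 1.5 * x + 4.0 + rng.normal(0, 5, 20)
        res = adjusted_regression(pats, x, y)
        X = np.column_stack(
            [np.ones(20), x, [p.gender for p in pats], [p.age for p in pats]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        for b, name in zip(beta, ("intercept", "actual_distance", "gender", "age")):
            assert res.coefficients[name] == pytest.approx(b, rel=1e-9)

    def test_standardized_beta_definition(self):
        rng = np.random.default_rng(4)
        pats = make_patients(rng, 25)
        x = rng.uniform(0, 100, 25)
        y = x + rng.normal(0, 10, 25)
        res = adjusted_regression(pats, x, y)
        expected = res.coefficients["actual_distance"] * np.std(x, ddof=1) / np.std(y, ddof=1)
        assert res.standardized_betas["actual_distance"] == pytest.approx(expected)

    def test_single_gender_cohort_names_column(self):
        rng = np.random.default_rng(5)
        pats = [
            PatientRecord(f"p{i}", (0, 0), "u", age=float(40 + i), gender=1)
            for i in range(10)
        ]
        x = rng.uniform(0, 100, 10)
        with pytest.raises(ValidationError, match="gender"):
            adjusted_regression(pats, x, x)

    def test_too_few_patients(self):
        rng = np.random.default_rng(6)
        pats = make_patients(rng, 4)
        with pytest.raises(DegenerateInputError):
            adjusted_regression(pats, np.arange(4.0), np.arange(4.0))


class TestAgreementReport:
    def test_identity_scenario_perfect_agreement(self, identity_scenario):
        sc = identity_scenario
        rep = agreement_report(sc.region, sc.patients, sc.facility, sc.graph,
                               sc.config.prevalence)
        assert rep.icc_unit.icc == pytest.approx(1.0)
        assert rep.regression.coefficients["actual_distance"] == pytest.approx(1.0)
        assert rep.regression.adjusted_r2 == pytest.approx(1.0)
        assert rep.cost.region.total_distance == pytest.approx(
            rep.distances.total, rel=1e-9
        )

    def test_empty_patient_table_estimation_only(self, default_scenario):
        sc = default_scenario
        rep = agreement_report(sc.region, [], sc.facility, sc.graph,
                               sc.config.prevalence)
        assert rep.estimation_only
        assert rep.icc_unit is None and rep.regression is None
        tables = report_tables(rep)
        assert set(tables) == {"estimates_unit", "estimates_community",
                               "estimates_region"}

    def test_deterministic_across_reruns(self, default_scenario):
        sc = default_scenario
        r1 = agreement_report(sc.region, sc.patients, sc.facility, sc.graph,
                              sc.config.prevalence)
        r2 = agreement_report(sc.region, sc.patients, sc.facility, sc.graph,
                              sc.config.prevalence)
        assert r1.icc_unit.icc == r2.icc_unit.icc
        assert r1.regression.coefficients == r2.regression.coefficients
        assert r1.cost.region.total_distance == r2.cost.region.total_distance

    def test_report_tables_shapes(self, default_scenario):
        sc = default_scenario
        rep = agreement_report(sc.region, sc.patients, sc.facility, sc.graph,
                               sc.config.prevalence)
        tables = report_tables(rep)
        assert len(tables["icc"]) == 2
        assert list(tables["regression"]["variable"]) == [
            "intercept", "actual_distance", "gender", "age"
        ]
        assert len(tables["pairs_community"]) <= len(sc.region.communities)
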