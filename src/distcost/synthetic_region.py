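"""Seeded generator of synthetic rural regions for end-to-end testing.

Emulates a remote-township setting: ~512 basic statistical areas of
150-450 residents nested in 15 communities strung along a valley corridor,
with a single referral hospital roughly 70-92 km away along the one road
that serves the corridor.  True disease cases are drawn per unit from the
resident population at a fixed prevalence; a validation cohort is a random
sample of those cases whose "residences" scatter around the unit center
with Gaussian jitter.  Everything is reproducible from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import Point

from .cost_estimator import estimate_patient_count
from .exceptions import DistcostError, ValidationError
from .region_model import Facility, Region, SpatialUnit
from .road_network import RoadGraph, build_graph, snap
from .validator import PatientRecord

SPINE_SPACING = 2000.0       # meters between corridor spine nodes
COMMUNITY_SCATTER = 1500.0   # SD of unit-center scatter around its community
CORRIDOR_SPAN = (0.88, 1.05)  # community anchors at these fractions of offset


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study region (defaults mirror the target setting).

    ``sampling_fraction`` is the share of true cases observed as validation
    patients (~7%, a few hundred outpatients of ~2,300 estimated cases);
    ``jitter_sd`` is the residential scatter around the unit center in
    meters.  ``case_model`` draws per-unit true cases either from
    Binomial(population, prevalence) ("binomial", realistic sampling noise)
    or as the deterministic rounding n' = round(pop x prevalence)
    ("expected", used for exact-identity checks).
    """

    seed: int = 0
    n_units: int = 512
    n_communities: int = 15
    unit_population_range: tuple[int, int] = (150, 450)
    prevalence: float = 0.0965
    disease: str = "diabetes"
    year: int = 2017
    facility_offset: float = 80_000.0
    jitter_sd: float = 300.0
    sampling_fraction: float = 0.07
    age_mean: float = 65.0
    age_sd: float = 13.0
    male_fraction: float = 0.5
    case_model: str = "binomial"  # or "expected"
    layout: str = "corridor"      # or "blob"

    def __post_init__(self):
        lo, hi = self.unit_population_range
        if lo <= 0 or hi < lo:
            raise ValidationError("unit_population_range must be positive and ordered")
        for name in ("prevalence", "sampling_fraction", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.jitter_sd < 0 or self.facility_offset <= 0:
            raise ValidationError("jitter_sd must be >= 0 and facility_offset > 0")
        if self.case_model not in ("binomial", "expected"):
            raise ValidationError(f"unknown case_model {self.case_model!r}")
        if self.layout not in ("corridor", "blob"):
            raise ValidationError(f"unknown layout {self.layout!r}")


@dataclass
class SyntheticScenario:
    """A fully materialized scenario plus its generating truth."""

    region: Region
    graph: RoadGraph
    facility: Facility
    patients: list[PatientRecord]
    truth: dict = field(default_factory=dict)
    config: ScenarioConfig = field(default_factory=ScenarioConfig)


def _community_sizes(n_units: int, n_communities: int) -> list[int]:
    base, extra = divmod(n_units, n_communities)
    return [base + (1 if i < extra else 0) for i in range(n_communities)]


def generate(config: ScenarioConfig) -> SyntheticScenario:
    """Materialize a scenario from a config; identical seeds give identical output.

    The road network is a spine of nodes every 2 km from the facility along
    the corridor, plus one straight branch from every unit center to the
    spine (blob layout routes units through their community anchor), so the
    graph is connected by construction and every unit center is itself a
    node.  True cases per unit follow ``config.case_model``; the observed
    cohort thins them binomially at ``sampling_fraction`` and jitters each
    address by a Gaussian clipped at 3 SD per coordinate.
    """
    rng = np.random.default_rng(config.seed)
    off = config.facility_offset
    nc = config.n_communities

    lo_f, hi_f = CORRIDOR_SPAN
    anchor_x = np.linspace(lo_f * off, hi_f * off, nc)
    anchor_y = rng.uniform(-800.0, 800.0, size=nc)
    if config.layout == "blob":
        theta = rng.uniform(0, 2 * math.pi, size=nc)
        r = rng.uniform(0, 0.12 * off, size=nc)
        anchor_x = off + r * np.cos(theta)
        anchor_y = r * np.sin(theta)

    sizes = _community_sizes(config.n_units, nc)
    plo, phi = config.unit_population_range
    units: list[SpatialUnit] = []
    centers: list[tuple[float, float]] = []
    idx = 0
    for ci, size in enumerate(sizes):
        scatter = rng.normal(0.0, COMMUNITY_SCATTER, size=(size, 2))
        pops = rng.integers(plo, phi + 1, size=size)
        for j in range(size):
            cx = float(anchor_x[ci] + scatter[j, 0])
            cy = float(anchor_y[ci] + scatter[j, 1])
            units.append(
                SpatialUnit(
                    unit_id=f"u{idx:04d}",
                    community_id=f"c{ci:02d}",
                    township_id="t00",
                    geometry=Point(cx, cy),
                    population=int(pops[j]),
                )
            )
            centers.append((cx, cy))
            idx += 1
    region = Region(units, name="synthetic", crs_note="synthetic planar meters")

    # roads: corridor spine from the facility past the farthest community
    x_max = float(anchor_x.max() + 4 * COMMUNITY_SCATTER)
    n_spine = int(math.ceil(x_max / SPINE_SPACING)) + 1
    spine = [(i * SPINE_SPACING, 0.0) for i in range(n_spine)]
    lines: list[list[tuple[float, float]]] = [spine]

    def nearest_spine(p: tuple[float, float]) -> tuple[float, float]:
        i = int(np.clip(round(p[0] / SPINE_SPACING), 0, n_spine - 1))
        return spine[i]

    if config.layout == "blob":
        for ci in range(nc):
            a = (float(anchor_x[ci]), float(anchor_y[ci]))
            lines.append([a, nearest_spine(a)])
        anchor_of = {f"c{ci:02d}": (float(anchor_x[ci]), float(anchor_y[ci]))
                     for ci in range(nc)}
        for u, c in zip(units, centers):
            lines.append([c, anchor_of[u.community_id]])
    else:
        for c in centers:
            lines.append([c, nearest_spine(c)])

    graph = build_graph(lines)
    if not graph.is_connected():
        comps = nx.number_connected_components(graph.graph)
        raise DistcostError(
            f"generated road graph is disconnected ({comps} components); "
            "this indicates a construction bug, not a valid scenario"
        )
    facility = Facility(facility_id="hospital", location=(0.0, 0.0))

    # truth distances: network distance of every unit center to the facility
    fac_node, _ = snap(facility.location, graph)
    dist = nx.single_source_dijkstra_path_length(graph.graph, fac_node,
                                                 weight="length")
    unit_truth_d: dict[str, float] = {}
    for u, c in zip(units, centers):
        node, gap = graph.nearest_node(c)
        unit_truth_d[u.unit_id] = dist[node] + gap

    # cases and the observed validation cohort
    true_cases: dict[str, int] = {}
    patients: list[PatientRecord] = []
    pid = 0
    for u, c in zip(units, centers):
        if config.case_model == "binomial":
            k = int(rng.binomial(u.population, config.prevalence))
        else:
            k = estimate_patient_count(u.population, config.prevalence)
        true_cases[u.unit_id] = k
        n_obs = (
            k if config.sampling_fraction >= 1.0
            else int(rng.binomial(k, config.sampling_fraction))
        )
        if n_obs == 0:
            continue
        jit = rng.normal(0.0, 1.0, size=(n_obs, 2))
        np.clip(jit, -3.0, 3.0, out=jit)
        jit *= config.jitter_sd
        ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n_obs),
                       18.0, 100.0)
        genders = rng.binomial(1, config.male_fraction, size=n_obs)
        for j in range(n_obs):
            patients.append(
                PatientRecord(
                    patient_id=f"p{pid:05d}",
                    location=(c[0] + float(jit[j, 0]), c[1] + float(jit[j, 1])),
                    unit_id=u.unit_id,
                    age=float(ages[j]),
                    gender=int(genders[j]),
                    disease=config.disease,
                    year=config.year,
                )
            )
            pid += 1

    truth = {
        "true_cases": true_cases,
        "unit_distance": unit_truth_d,
        "n_patients": len(patients),
    }
    return SyntheticScenario(
        region=region, graph=graph, facility=facility,
        patients=patients, truth=truth, config=config,
    )
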