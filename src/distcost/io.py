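"""Readers and writers for the interchange formats (GeoJSON + CSV + YAML).

All geometry I/O is plain GeoJSON handled with ``json`` + shapely; tables
are CSV via pandas.  Coordinates must already be in a planar projected
system in meters — inputs whose coordinates all fit in lon/lat ranges are
rejected with an explicit error rather than silently measured in degrees.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .cost_estimator import COVERAGE_THRESHOLD, CostSummary, PrevalenceRecord
from .exceptions import SchemaError, ValidationError
from .region_model import Facility, Region, SpatialUnit
from .road_network import ODMatrix, RoadGraph
from .synthetic_region import ScenarioConfig, SyntheticScenario
from .validator import PatientRecord


def _looks_geographic(coords: list[tuple[float, float]]) -> bool:
    return bool(coords) and all(
        abs(x) <= 180.0 and abs(y) <= 90.0 for x, y in coords
    )


def _require_projected(coords, path):
    if _looks_geographic(list(coords)):
        raise SchemaError(
            f"{path}: coordinates look geographic (lon/lat); inputs must be "
            "in a planar projected CRS in meters — reproject before loading"
        )


# ---------------------------------------------------------------- units
UNIT_PROPS = ("unit_id", "community_id", "population")


def read_units(path: str | Path, attrs_csv: str | Path | None = None) -> Region:
    """Read a Region from a GeoJSON FeatureCollection.

    Feature properties must carry unit_id, community_id and population
    (township_id optional); alternatively an attribute CSV joinable on
    unit_id supplies them.  Row-level problems are collected and reported
    together with feature numbers.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    attrs = None
    if attrs_csv is not None:
        attrs = pd.read_csv(attrs_csv, dtype={"unit_id": str}).set_index("unit_id")
    units: list[SpatialUnit] = []
    problems: list[tuple[int, str]] = []
    sample_coords: list[tuple[float, float]] = []
    for i, feat in enumerate(gj.get("features", []), start=1):
        props = dict(feat.get("properties") or {})
        uid = props.get("unit_id")
        if attrs is not None and uid in attrs.index:
            row = attrs.loc[uid]
            for k in ("community_id", "township_id", "population"):
                if k in row.index and not pd.isna(row[k]):
                    props.setdefault(k, row[k])
        missing = [k for k in UNIT_PROPS if props.get(k) is None]
        if missing:
            problems.append((i, f"missing properties {missing}"))
            continue
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # noqa: BLE001 - report, don't crash the loop
            problems.append((i, f"bad geometry: {exc}"))
            continue
        c = geom.centroid
        sample_coords.append((c.x, c.y))
        try:
            units.append(
                SpatialUnit(
                    unit_id=str(props["unit_id"]),
                    community_id=str(props["community_id"]),
                    township_id=str(props.get("township_id", "")),
                    population=int(props["population"]),
                    geometry=geom,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append((i, str(exc)))
    if problems:
        lines = "; ".join(f"feature {i}: {m}" for i, m in problems[:20])
        raise SchemaError(f"{path}: {lines}", rows=problems)
    _require_projected(sample_coords, path)
    crs = (gj.get("crs") or {}).get("properties", {}).get("name", "")
    return Region(units, name=path.stem, crs_note=crs or "assumed projected meters")


def write_units(region: Region, path: str | Path) -> None:
    feats = []
    for u in region.units:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(u.geometry),
                "properties": {
                    "unit_id": u.unit_id,
                    "community_id": u.community_id,
                    "township_id": u.township_id,
                    "population": u.population,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------- roads
ROAD_CSV_COLS = ("node_a_x", "node_a_y", "node_b_x", "node_b_y")


def read_roads(path: str | Path, merge_tol: float = 0.5) -> RoadGraph:
    """Read a road network from GeoJSON (LineString/MultiLineString
    features) or a CSV edge list with endpoint coordinates and an optional
    precomputed ``length`` column."""
    from .road_network import build_graph  # local import avoids cycle at module load

    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = [c for c in ROAD_CSV_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        pts = list(zip(df["node_a_x"], df["node_a_y"])) + list(
            zip(df["node_b_x"], df["node_b_y"])
        )
        _require_projected(pts, path)
        import math

        def nid(x, y):
            return f"n{round(x / merge_tol)}:{round(y / merge_tol)}"

        nodes: dict[str, tuple[float, float]] = {}
        edges = []
        for _, r in df.iterrows():
            a = (float(r["node_a_x"]), float(r["node_a_y"]))
            b = (float(r["node_b_x"]), float(r["node_b_y"]))
            ia, ib = nid(*a), nid(*b)
            nodes.setdefault(ia, a)
            nodes.setdefault(ib, b)
            if ia == ib:
                continue
            length = (
                float(r["length"])
                if "length" in df.columns and not pd.isna(r.get("length"))
                else math.hypot(b[0] - a[0], b[1] - a[1])
            )
            edges.append((ia, ib, length))
        return RoadGraph(nodes, edges)

    with open(path) as fh:
        gj = json.load(fh)
    lines: list[list[tuple[float, float]]] = []
    feats = gj.get("features", []) if gj.get("type") == "FeatureCollection" else [gj]
    for feat in feats:
        geom = feat.get("geometry", feat)
        gtype = geom.get("type")
        if gtype == "LineString":
            lines.append([tuple(c[:2]) for c in geom["coordinates"]])
        elif gtype == "MultiLineString":
            lines.extend([tuple(c[:2]) for c in part] for part in geom["coordinates"])
        else:
            raise SchemaError(f"{path}: unsupported geometry type {gtype!r}")
    _require_projected([p for ln in lines for p in ln], path)
    return build_graph(lines, merge_tol=merge_tol)


def write_roads(graph: RoadGraph, path: str | Path) -> None:
    nodes = graph.nodes
    feats = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [list(nodes[a]), list(nodes[b])],
            },
            "properties": {"length_m": length},
        }
        for a, b, length in graph.edges
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ----------------------------------------------------------- prevalence
def read_prevalence(
    path: str | Path, default_unit: str = "fraction"
) -> list[PrevalenceRecord]:
    """Read a prevalence table; a ``prevalence_unit`` column ({percent|
    fraction}, default from config) fixes the scale, stored internally as a
    fraction."""
    if default_unit not in ("percent", "fraction"):
        raise ValidationError(f"default_unit must be percent|fraction, got {default_unit!r}")
    df = pd.read_csv(path)
    required = ("region_id", "year", "disease", "prevalence")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records = []
    problems = []
    for i, r in df.iterrows():
        unit = str(r.get("prevalence_unit", default_unit) or default_unit)
        p = float(r["prevalence"])
        if unit == "percent":
            p /= 100.0
        elif unit != "fraction":
            problems.append((i + 2, f"unknown prevalence_unit {unit!r}"))
            continue
        try:
            records.append(
                PrevalenceRecord(
                    region_id=str(r["region_id"]),
                    year=int(r["year"]),
                    disease=str(r["disease"]),
                    prevalence=p,
                    resident_population=int(r.get("resident_population", 0) or 0),
                    insured_population=(
                        int(r["insured_population"])
                        if "insured_population" in df.columns
                        and not pd.isna(r["insured_population"])
                        else None
                    ),
                )
            )
        except ValidationError as exc:
            problems.append((i + 2, str(exc)))
    if problems:
        lines = "; ".join(f"row {i}: {m}" for i, m in problems[:20])
        raise SchemaError(f"{path}: {lines}", rows=problems)
    return records


def write_prevalence(records: list[PrevalenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "year": r.year,
                "disease": r.disease,
                "prevalence": r.prevalence,
                "prevalence_unit": "fraction",
                "insured_population": r.insured_population,
                "resident_population": r.resident_population,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# -------------------------------------------------------------- patients
PATIENT_COLS = ("patient_id", "x", "y", "unit_id", "age", "gender")


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read the validation cohort; row-level violations (gender outside
    {0,1}, non-positive age) are reported with their CSV row numbers."""
    df = pd.read_csv(path, dtype={"patient_id": str, "unit_id": str})
    missing = [c for c in PATIENT_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    patients = []
    problems = []
    for i, r in df.iterrows():
        try:
            patients.append(
                PatientRecord(
                    patient_id=str(r["patient_id"]),
                    location=(float(r["x"]), float(r["y"])),
                    unit_id=str(r["unit_id"]),
                    age=float(r["age"]),
                    gender=int(r["gender"]),
                    disease=str(r.get("disease", "")),
                    year=int(r.get("year", 0) or 0),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append((i + 2, str(exc)))  # +2: header is row 1
    if problems:
        lines = "; ".join(f"row {i}: {m}" for i, m in problems[:20])
        raise SchemaError(f"{path}: {lines}", rows=problems)
    return patients


def write_patients(patients: list[PatientRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "x": p.location[0],
                "y": p.location[1],
                "unit_id": p.unit_id,
                "age": p.age,
                "gender": p.gender,
                "disease": p.disease,
                "year": p.year,
            }
            for p in patients
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- outputs
def write_od(od: ODMatrix, path: str | Path) -> None:
    rows = [
        {
            "unit_id": uid,
            "facility_id": fid,
            "distance_m": round(d, 2),
            "snap_m": round(od.snap_report.get(uid, 0.0), 2),
        }
        for (uid, fid), d in sorted(od.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cost_summary(summary: CostSummary, path: str | Path) -> None:
    df = summary.rows.copy()
    for col in ("average_distance_m", "total_distance_m"):
        df[col] = df[col].round(2)
    df.to_csv(path, index=False)


def coverage_warnings(records: list[PrevalenceRecord]) -> list[str]:
    """Human-readable warnings for rows whose insured/resident ratio falls
    below the proxy threshold."""
    out = []
    for r in records:
        if r.insured_population is None or r.resident_population <= 0:
            continue
        ratio = r.insured_population / r.resident_population
        if ratio < COVERAGE_THRESHOLD:
            out.append(
                f"{r.region_id}/{r.year}/{r.disease}: insurance coverage "
                f"{ratio:.3f} below {COVERAGE_THRESHOLD:.2f}; resident-population "
                "proxy is weaker"
            )
    return out


# -------------------------------------------------------------- scenario
def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> None:
    """Write a synthetic scenario in exactly the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_units(scenario.region, outdir / "units.geojson")
    write_roads(scenario.graph, outdir / "roads.geojson")
    write_patients(scenario.patients, outdir / "patients.csv")
    cfg = scenario.config
    write_prevalence(
        [
            PrevalenceRecord(
                region_id=scenario.region.name,
                year=cfg.year,
                disease=cfg.disease,
                prevalence=cfg.prevalence,
                resident_population=scenario.region.population,
            )
        ],
        outdir / "prevalence.csv",
    )
    with open(outdir / "facility.json", "w") as fh:
        json.dump(
            {
                "facility_id": scenario.facility.facility_id,
                "x": scenario.facility.location[0],
                "y": scenario.facility.location[1],
            },
            fh,
        )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(scenario.truth, fh)
    with open(outdir / "scenario_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)


def read_facility(path: str | Path) -> Facility:
    with open(path) as fh:
        d = json.load(fh)
    return Facility(facility_id=str(d["facility_id"]), location=(float(d["x"]), float(d["y"])))


# ---------------------------------------------------------------- config
@dataclass
class RunConfig:
    """Merged file + command-line configuration for one run."""

    units: str = ""
    roads: str = ""
    prevalence: str = ""
    patients: str = ""
    facility_x: float = 0.0
    facility_y: float = 0.0
    facility_id: str = "facility"
    connectors: bool = True
    engine: str = "network"           # or "euclidean"
    icc_form: str = "agreement"       # or "consistency"
    prevalence_unit: str = "fraction"
    outdir: str = "out"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> dict:
    """Load a YAML key/value config file; returns {} when no path given."""
    if not path:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return data
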