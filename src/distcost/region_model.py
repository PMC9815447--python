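"""Spatial hierarchy: basic statistical areas nested in communities.

The basic statistical area is Taiwan's smallest census dissemination unit
(roughly 150-450 residents, much finer than a township).  A region is a set
of such units, each belonging to exactly one community; communities nest in
a township.  Every unit carries a representative *center* — the origin used
for all distance measurement — and aggregates of units use the
population-weighted mean of member centers.

All coordinates must be in a planar projected system in meters (e.g. a
national transverse-Mercator grid).  Geographic lon/lat input is rejected
at load time (see :mod:`distcost.io`): every distance this package reports
is a length in meters, which a geographic CRS cannot provide directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .exceptions import DegenerateInputError, GeometryError, ValidationError

Coord = tuple[float, float]


@dataclass
class SpatialUnit:
    """One basic statistical area.

    Parameters
    ----------
    unit_id, community_id, township_id
        Identifiers; ``unit_id`` must be unique within a region.
    geometry
        Shapely Point or Polygon in projected meters.
    population
        Resident head count (persons), non-negative.
    center
        Representative point in meters; derived from ``geometry`` by
        :func:`unit_center` when not supplied.
    """

    unit_id: str
    community_id: str
    population: int
    geometry: BaseGeometry | None = None
    township_id: str = ""
    center: Coord | None = None

    def __post_init__(self):
        if self.population < 0:
            raise ValidationError(
                f"unit {self.unit_id!r}: population must be >= 0, "
                f"got {self.population}"
            )
        if self.center is None and self.geometry is not None:
            self.center = unit_center(self)


def unit_center(unit: SpatialUnit) -> Coord:
    """Representative center of a single unit.

    A point geometry is its own center; a polygon contributes its area
    centroid.  Population weighting enters only when *aggregating* units
    (no sub-unit population surface is available), see
    :func:`weighted_population_center`.
    """
    geom = unit.geometry
    if geom is None or geom.is_empty:
        raise GeometryError(f"unit {unit.unit_id!r} has empty or missing geometry")
    if isinstance(geom, Point):
        return (geom.x, geom.y)
    c = geom.centroid
    if c.is_empty:
        raise GeometryError(f"unit {unit.unit_id!r}: centroid undefined")
    return (c.x, c.y)


def weighted_population_center(units: list[SpatialUnit]) -> Coord:
    """Population-weighted mean of member-unit centers.

    Returns sum(pop_u * center_u) / sum(pop_u) component-wise.  This is the
    origin used when a whole community (or any aggregate) is collapsed to a
    single point.
    """
    if not units:
        raise DegenerateInputError("no units given")
    total = 0.0
    sx = sy = 0.0
    for u in units:
        cx, cy = u.center if u.center is not None else unit_center(u)
        sx += u.population * cx
        sy += u.population * cy
        total += u.population
    if total == 0:
        raise DegenerateInputError("all unit populations are zero")
    return (sx / total, sy / total)


@dataclass
class Community:
    """A community: an ordered list of member units and their total population."""

    community_id: str
    member_unit_ids: list[str] = field(default_factory=list)
    population: int = 0


@dataclass
class Facility:
    """A care facility (here, the single medical center) at a projected point."""

    facility_id: str
    location: Coord


class Region:
    """A named collection of units with communities derived from membership.

    Validates that unit ids are unique and derives the community roster
    (member lists and populations) from the units themselves, so community
    populations are always consistent with their members.
    """

    def __init__(self, units: list[SpatialUnit], name: str = "", crs_note: str = ""):
        seen: set[str] = set()
        for u in units:
            if u.unit_id in seen:
                raise ValidationError(f"duplicate unit_id {u.unit_id!r}")
            seen.add(u.unit_id)
        self.units: list[SpatialUnit] = list(units)
        self.name = name
        self.crs_note = crs_note
        self._by_id = {u.unit_id: u for u in self.units}
        comms: dict[str, Community] = {}
        for u in self.units:
            c = comms.setdefault(u.community_id, Community(u.community_id))
            c.member_unit_ids.append(u.unit_id)
            c.population += u.population
        self.communities: dict[str, Community] = comms

    def __len__(self) -> int:
        return len(self.units)

    def unit(self, unit_id: str) -> SpatialUnit:
        return self._by_id[unit_id]

    @property
    def population(self) -> int:
        return sum(u.population for u in self.units)

    def community_of(self, unit_id: str) -> str:
        return self._by_id[unit_id].community_id

    def community_center(self, community_id: str) -> Coord:
        """Population-weighted center of a community's member units."""
        comm = self.communities[community_id]
        return weighted_population_center(
            [self._by_id[uid] for uid in comm.member_unit_ids]
        )
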