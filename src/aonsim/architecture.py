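"""Discrete-time architectural growth engine.

Simulates the organ-scale development of a soybean seedling from sowing to
day 16: hypocotyl with two cotyledons and a primary root at germination,
shoot phytomers (epicotyl, unifoliate leaves, then internode + petiole +
trifoliate leaf) appearing at a fixed plastochron, lateral roots initiating
acropetally along the primary root, and — after rhizobial inoculation —
nodule primordia placed stochastically in the infection-susceptible zone
behind each growing root tip.  Primordia mature into nodules after a fixed
age unless they were arrested by the signalling layer.

The engine is deliberately coarse on the shoot (organ counts and lengths
only) and detailed on the root, because the root reports the nodulation
phenotype.  Architecture never depends on signalling state, so runs of the
two near-isogenic genotypes with the same seed produce identical topologies
and identical random-number streams.

All ops mutate the plant in place and return it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterator

import numpy as np

from .errors import ConfigurationError, UnknownOrganError
from .params import GenotypeParameters, ROOT_SIDE_KINDS

ACTIVE = "active"
ARRESTED = "arrested"
SENESCED = "senesced"
ABSCISED = "abscised"

# Shoot axis kinds whose apical children track the parent tip as it grows.
_EPS = 1e-9


@dataclass
class Organ:
    """One plant organ: a 1-D segment attached to its parent axis.

    ``attach_pos`` is the position (mm from the parent's base) at which this
    organ joins its parent; positions within an organ run from 0 (base,
    attachment end) to ``length`` (distal tip).  ``apical`` marks organs
    attached at the parent's tip, which ride along as the parent elongates.
    """

    id: str
    kind: str
    parent_id: str | None
    attach_pos: float
    length: float
    diameter: float
    birth_day: float
    status: str = ACTIVE
    biomass_fraction: float = 1.0
    genotype: str = ""
    apical: bool = False


@dataclass
class PlantTopology:
    """Rooted tree of organs plus simulation clock.

    The tree is rooted at the hypocotyl base, which coincides with the
    root-system base (the hypocotyl/root junction): the primary root is a
    child of the hypocotyl at attachment position 0.
    """

    organs: dict[str, Organ] = dc_field(default_factory=dict)
    day: float = 0.0
    genotype_name: str = ""
    registry: dict[str, GenotypeParameters] = dc_field(default_factory=dict)
    # genotype identity of each graft part; intact plants use one name
    part_genotypes: dict[str, str] = dc_field(default_factory=dict)
    cotyledon_capacity: float = 1.0
    _children: dict[str, list[str]] = dc_field(default_factory=dict)
    _counter: int = 0
    _last_initiation_day: float | None = None

    # -- structural helpers -------------------------------------------------
    def organ(self, organ_id: str) -> Organ:
        try:
            return self.organs[organ_id]
        except KeyError:
            raise UnknownOrganError(f"unknown organ id {organ_id!r}") from None

    def children(self, organ_id: str) -> list[Organ]:
        return [self.organs[c] for c in self._children.get(organ_id, ())]

    def params_for(self, organ: Organ) -> GenotypeParameters:
        return self.registry[organ.genotype or self.genotype_name]

    @property
    def params(self) -> GenotypeParameters:
        return self.registry[self.genotype_name]

    @property
    def base_id(self) -> str:
        return "o0000"  # the hypocotyl, by construction

    def new_id(self) -> str:
        oid = f"o{self._counter:04d}"
        self._counter += 1
        return oid

    def add_organ(
        self,
        kind: str,
        parent_id: str | None,
        attach_pos: float,
        birth_day: float,
        genotype: str,
        *,
        apical: bool = False,
        status: str = ACTIVE,
    ) -> Organ:
        p = self.registry[genotype]
        organ = Organ(
            id=self.new_id(),
            kind=kind,
            parent_id=parent_id,
            attach_pos=attach_pos,
            length=p.initial_length.get(kind, 0.0),
            diameter=p.diameter.get(kind, 1.0),
            birth_day=birth_day,
            status=status,
            genotype=genotype,
            apical=apical,
        )
        self.organs[organ.id] = organ
        if parent_id is not None:
            self._children.setdefault(parent_id, []).append(organ.id)
        return organ

    def iter_kind(self, *kinds: str) -> Iterator[Organ]:
        want = set(kinds)
        for oid in sorted(self.organs):
            o = self.organs[oid]
            if o.kind in want:
                yield o

    def genotype_of_part(self, part: str) -> str:
        return self.part_genotypes.get(part, self.genotype_name)


def _part_for_kind(kind: str) -> str:
    if kind in ROOT_SIDE_KINDS:
        return "root"
    if kind == "cotyledon":
        return "cotyledon"
    if kind == "hypocotyl":
        return "hypocotyl"
    return "shoot"


def init_plant(
    params: GenotypeParameters | dict[str, GenotypeParameters],
    seed: int,
    *,
    genotype_name: str | None = None,
    part_genotypes: dict[str, str] | None = None,
) -> PlantTopology:
    """Create a day-0 seedling: hypocotyl, primary root, two cotyledons.

    ``params`` may be a single genotype (intact plant) or a registry of
    genotypes combined with ``part_genotypes`` mapping the graft parts
    ``shoot`` / ``cotyledon`` / ``hypocotyl`` / ``root`` to genotype names
    (a ``cotyledon`` part of ``None``/missing entry mapped to the empty
    string yields a cotyledon-free plant).  Deterministic given
    (params, seed); the seed is consumed later by the growth loop.
    """
    if isinstance(params, GenotypeParameters):
        params.validate()
        registry = {params.name: params}
        name = params.name
        parts = {p: name for p in ("shoot", "cotyledon", "hypocotyl", "root")}
    else:
        registry = dict(params)
        for g in registry.values():
            g.validate()
        if part_genotypes is None or genotype_name is None:
            raise ConfigurationError(
                "init_plant with a registry requires genotype_name and part_genotypes"
            )
        name = genotype_name
        parts = dict(part_genotypes)
        for part, gname in parts.items():
            if gname and gname not in registry:
                raise ConfigurationError(
                    f"part {part!r} names unregistered genotype {gname!r}"
                )

    plant = PlantTopology(
        genotype_name=name, registry=registry, part_genotypes=parts
    )
    hypo_geno = parts.get("hypocotyl") or name
    hypo = plant.add_organ("hypocotyl", None, 0.0, 0.0, hypo_geno)
    plant.add_organ("primary_root", hypo.id, 0.0, 0.0, parts.get("root") or name)
    cot_geno = parts.get("cotyledon", "")
    if cot_geno:
        for _ in range(2):
            plant.add_organ(
                "cotyledon", hypo.id, hypo.length, 0.0, cot_geno, apical=True
            )
    # epicotyl and all later shoot organs use the shoot genotype
    return plant


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _apex_organ(plant: PlantTopology) -> Organ:
    """Topmost shoot axis segment (most recent internode/epicotyl/hypocotyl)."""
    apex = plant.organs[plant.base_id]
    for o in plant.iter_kind("epicotyl", "internode"):
        if o.birth_day >= apex.birth_day:
            apex = o
    return apex


def _emit_phytomers(plant: PlantTopology, new_day: float) -> None:
    params = plant.params
    interval = params.phytomer_interval
    if interval <= 0:
        return
    shoot_geno = plant.genotype_of_part("shoot")
    n_events = sum(1 for _ in plant.iter_kind("epicotyl", "internode"))
    while (n_events + 1) * interval <= new_day + _EPS:
        n_events += 1
        t = n_events * interval
        apex = _apex_organ(plant)
        if n_events == 1:
            # epicotyl emerges at the cotyledon node with the unifoliate pair
            epi = plant.add_organ(
                "epicotyl", apex.id, apex.length, t, shoot_geno, apical=True
            )
            for _ in range(2):
                plant.add_organ(
                    "unifoliate_leaf", epi.id, epi.length, t, shoot_geno, apical=True
                )
        else:
            node = plant.add_organ(
                "internode", apex.id, apex.length, t, shoot_geno, apical=True
            )
            pet = plant.add_organ(
                "petiole", node.id, node.length, t, shoot_geno, apical=True
            )
            plant.add_organ("leaf", pet.id, pet.length, t, shoot_geno, apical=True)


def _emit_laterals(plant: PlantTopology, new_day: float) -> None:
    primary = next(plant.iter_kind("primary_root"))
    params = plant.params_for(primary)
    spacing = params.lateral_spacing
    if spacing <= 0:
        return
    n = sum(1 for _ in plant.iter_kind("lateral_root"))
    root_geno = plant.genotype_of_part("root")
    # a lateral emerges once the tip has advanced past its initiation site by
    # the susceptible-zone offset (laterals arise in the mature zone)
    while (n + 1) * spacing + params.susceptible_offset <= primary.length:
        n += 1
        plant.add_organ("lateral_root", primary.id, n * spacing, new_day, root_geno)


def grow(plant: PlantTopology, dt: float, rng: np.random.Generator) -> PlantTopology:
    """Advance architecture by ``dt`` days.

    Axes elongate linearly (capped at their mature length), apical
    attachments ride the parent tip, new phytomers and lateral roots appear
    on schedule, and cotyledons pass active -> senesced -> abscised with a
    linearly declining biomass fraction in between.
    """
    if not dt > 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    new_day = plant.day + dt

    for oid in sorted(plant.organs):
        o = plant.organs[oid]
        if o.status != ACTIVE:
            continue
        p = plant.params_for(o)
        rate = p.elongation_rate.get(o.kind, 0.0)
        if rate > 0:
            o.length = min(o.length + rate * dt, p.max_length.get(o.kind, math.inf))
    # apical children track the parent tip
    for oid in sorted(plant.organs):
        o = plant.organs[oid]
        if o.apical and o.parent_id is not None:
            o.attach_pos = plant.organs[o.parent_id].length

    _emit_phytomers(plant, new_day)
    _emit_laterals(plant, new_day)

    for cot in plant.iter_kind("cotyledon"):
        p = plant.params_for(cot)
        s, a = p.cotyledon_senescence_day, p.cotyledon_abscission_day
        if cot.status == ABSCISED:
            continue
        if new_day >= a:
            cot.status = ABSCISED
            cot.biomass_fraction = 0.0
        elif new_day >= s:
            cot.status = SENESCED
            cot.biomass_fraction = (a - new_day) / (a - s) if a > s else 0.0

    plant.day = new_day
    return plant


# ---------------------------------------------------------------------------
# nodulation
# ---------------------------------------------------------------------------

def initiate_primordia(
    plant: PlantTopology, inoculation_day: float, rng: np.random.Generator
) -> PlantTopology:
    """Place new nodule primordia and mature old ones.

    New primordia appear as a Poisson process (rate = density x susceptible
    zone length x elapsed days) in the zone ``[tip - susceptible_offset,
    tip]`` of every root still elongating, once the plant has been
    inoculated.  Active primordia older than the maturation age become
    nodules.  Roots are visited in sorted-id order so the random stream is
    reproducible and identical across near-isogenic genotypes.
    """
    since = plant._last_initiation_day
    start = inoculation_day if since is None else max(since, inoculation_day)
    dt = plant.day - start
    plant._last_initiation_day = max(plant.day, inoculation_day)

    if dt > 0:
        for root in plant.iter_kind("primary_root", "lateral_root"):
            p = plant.params_for(root)
            if root.status != ACTIVE:
                continue
            if root.length >= p.max_length.get(root.kind, math.inf) - _EPS:
                continue  # tip matured, no longer susceptible
            if plant.day - root.birth_day < p.susceptibility_age:
                continue  # root hairs not yet infectable
            zone_lo = max(0.0, root.length - p.susceptible_offset)
            zone_len = root.length - zone_lo
            lam = p.primordium_density * zone_len * dt
            if lam <= 0:
                continue
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            positions = zone_lo + rng.random(n) * zone_len
            geno = root.genotype or plant.genotype_name
            for pos in positions:
                plant.add_organ(
                    "nodule_primordium", root.id, float(pos), plant.day, geno
                )

    for pr in plant.iter_kind("nodule_primordium"):
        p = plant.params_for(pr)
        if pr.status == ACTIVE and plant.day - pr.birth_day >= p.primordium_maturation_age:
            pr.kind = "nodule"
            pr.length = p.initial_length.get("nodule", pr.length)
            pr.diameter = p.diameter.get("nodule", pr.diameter)
    return plant


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _chain(plant: PlantTopology, organ: Organ, pos: float) -> list[tuple[str, float]]:
    """Path from a point (organ, pos) down to the plant base, as
    (organ_id, position-within-organ) entries starting at the point."""
    out = [(organ.id, pos)]
    o = organ
    while o.parent_id is not None:
        pos = o.attach_pos
        o = plant.organs[o.parent_id]
        out.append((o.id, pos))
    return out


def path_distance_points(
    plant: PlantTopology, a: tuple[str, float], b: tuple[str, float]
) -> float:
    """Distance in mm along the organ tree between two axis points."""
    ca = _chain(plant, plant.organ(a[0]), a[1])[::-1]  # base first
    cb = _chain(plant, plant.organ(b[0]), b[1])[::-1]
    k = 0
    while k < len(ca) and k < len(cb) and ca[k][0] == cb[k][0]:
        k += 1
    # ca[k-1] / cb[k-1] are on the last common organ
    qa, qb = ca[k - 1][1], cb[k - 1][1]
    rest_a = sum(p for _, p in ca[k:])
    rest_b = sum(p for _, p in cb[k:])
    return abs(qa - qb) + rest_a + rest_b


def anchor(plant: PlantTopology, organ_id: str) -> tuple[str, float]:
    """The attachment point of an organ, as a point on its parent axis."""
    o = plant.organ(organ_id)
    if o.parent_id is None:
        return (o.id, 0.0)
    return (o.parent_id, o.attach_pos)


def path_distance(plant: PlantTopology, a: str, b: str) -> float:
    """Tree-path length in mm between the attachment points of two organs."""
    return path_distance_points(plant, anchor(plant, a), anchor(plant, b))


def nodule_depth(plant: PlantTopology, organ_id: str) -> float:
    """Path distance (mm) from the root-system base to a nodule/primordium."""
    o = plant.organ(organ_id)
    d = o.attach_pos
    o = plant.organs[o.parent_id] if o.parent_id else o
    while o.kind == "lateral_root":
        d += o.attach_pos
        o = plant.organs[o.parent_id]
    return d


@dataclass
class Census:
    """Snapshot of the nodulation phenotype at one day."""

    day: float
    genotype: str
    nodule_count: int
    arrested_count: int
    primordium_count: int
    depths_mm: tuple[float, ...]  # depths of emerged nodules, sorted

    @property
    def mean_depth_mm(self) -> float:
        return float(np.mean(self.depths_mm)) if self.depths_mm else 0.0

    @property
    def depth_iqr_mm(self) -> float:
        """Interquartile range of nodule depths — the 'nodulation interval'."""
        if len(self.depths_mm) < 2:
            return 0.0
        q1, q3 = np.percentile(self.depths_mm, [25, 75])
        return float(q3 - q1)

    def rows(self) -> list[dict]:
        return [
            {
                "day": self.day,
                "genotype": self.genotype,
                "kind": "nodule",
                "depth_mm": d,
                "status": ACTIVE,
            }
            for d in self.depths_mm
        ]


def census(plant: PlantTopology) -> Census:
    """Count nodules, arrested primordia and active (immature) primordia,
    with per-nodule depths from the root-system base."""
    depths = []
    arrested = 0
    active_pr = 0
    for o in plant.iter_kind("nodule", "nodule_primordium"):
        if o.kind == "nodule":
            depths.append(nodule_depth(plant, o.id))
        elif o.status == ARRESTED:
            arrested += 1
        else:
            active_pr += 1
    return Census(
        day=plant.day,
        genotype=plant.genotype_name,
        nodule_count=len(depths),
        arrested_count=arrested,
        primordium_count=active_pr,
        depths_mm=tuple(sorted(depths)),
    )
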