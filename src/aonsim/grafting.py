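"""Graft chimeras: reciprocal epicotyl-and-hypocotyl graft simulation.

A graft label such as ``Ns+Bc+Br`` names the genotype of the three plant
parts: shoot (epicotyl and above), cotyledons (with the hypocotyl they sit
on), and root.  The reciprocal design between a mutant and its wild type
joins the shoot of one genotype — with or without its cotyledons — onto the
root of the other, giving four combinations (e.g. Ns+Nc+Br, Ns+Bc+Br,
Bs+Bc+Nr, Bs+Nc+Nr for nts1116 x Bragg).

The graft junction is transport-transparent: signals cross it at the plain
advection rate.  Cotyledon retention states (0_C, 1_YC, 2_YC, 2_GC) are
imposed as schedules at the graft day — cotyledon removal and/or a reduced
SDI production capacity — mirroring how retention classes are observed on
real grafted seedlings rather than emerging from senescence dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .architecture import ABSCISED, Census, PlantTopology, init_plant
from .errors import ConfigurationError
from .params import GenotypeParameters, SignallingParameters
from .simulate import Schedule, SimulationResult, run_simulation

RETENTION_STATES = ("0_C", "1_YC", "2_YC", "2_GC")
# Per-cotyledon SDI capacity after the graft day; 0_C / 1_YC also remove
# both / one cotyledon(s).  Declared stand-ins: the retained capacity of a
# yellowing cotyledon is not quantified empirically.
DEFAULT_RETENTION_CAPACITY = {"0_C": 0.0, "1_YC": 0.4, "2_YC": 0.4, "2_GC": 1.0}
DEFAULT_GRAFT_DAY = 4.0


@dataclass(frozen=True)
class GraftSpec:
    """A chimeric assembly of genotype parts."""

    shoot_genotype: str
    cotyledon_genotype: str | None
    root_genotype: str
    retention: str = "2_GC"

    def __post_init__(self) -> None:
        if self.retention not in RETENTION_STATES:
            raise ConfigurationError(
                f"unknown retention state {self.retention!r}; "
                f"expected one of {RETENTION_STATES}"
            )


@dataclass
class GraftResult:
    spec: GraftSpec
    nodule_count_day16: int
    census: Census
    result: SimulationResult


def render_graft_label(
    spec: GraftSpec, initials: dict[str, str] | None = None
) -> str:
    """Label like 'Ns+Bc+Br' from part genotypes (default initials: the
    upper-cased first letter of each genotype name)."""
    def ini(name: str | None) -> str:
        if name is None:
            return "x"
        if initials and name in initials:
            return initials[name]
        return name[0].upper()

    return f"{ini(spec.shoot_genotype)}s+{ini(spec.cotyledon_genotype)}c+{ini(spec.root_genotype)}r"


def parse_graft_label(
    label: str, genotypes: dict[str, str], retention: str = "2_GC"
) -> GraftSpec:
    """Parse 'Ns+Bc+Br' given a mapping of initials to genotype names
    (e.g. ``{"N": "nts1116", "B": "bragg"}``; 'x' marks absent cotyledons)."""
    parts = label.split("+")
    if len(parts) != 3 or [p[-1:] for p in parts] != ["s", "c", "r"]:
        raise ConfigurationError(
            f"malformed graft label {label!r}; expected e.g. 'Ns+Bc+Br'"
        )
    def geno(tok: str) -> str | None:
        ini = tok[:-1]
        if ini.lower() == "x":
            return None
        if ini not in genotypes:
            raise ConfigurationError(
                f"graft label {label!r}: unknown genotype initial {ini!r}"
            )
        return genotypes[ini]

    cot = geno(parts[1])
    return GraftSpec(
        shoot_genotype=geno(parts[0]),
        cotyledon_genotype=cot,
        root_genotype=geno(parts[2]),
        retention=retention,
    )


def enumerate_reciprocal_grafts(
    genotype_a: str, genotype_b: str, retention: str = "2_GC"
) -> list[GraftSpec]:
    """The four reciprocal epicotyl-and-hypocotyl graft combinations between
    two genotypes: each shoot over the other root, with the cotyledons kept
    either on the shoot side or on the root side."""
    if genotype_a == genotype_b:
        warnings.warn(
            f"identical genotypes {genotype_a!r}: degenerate self-graft",
            stacklevel=2,
        )
        return [GraftSpec(genotype_a, genotype_a, genotype_a, retention)]
    a, b = genotype_a, genotype_b
    return [
        GraftSpec(a, a, b, retention),  # As+Ac+Br: shoot keeps its cotyledons
        GraftSpec(a, b, b, retention),  # As+Bc+Br: cotyledons stay on the root
        GraftSpec(b, b, a, retention),
        GraftSpec(b, a, a, retention),
    ]


def assemble_graft(
    spec: GraftSpec, registry: dict[str, GenotypeParameters]
) -> PlantTopology:
    """Day-0 chimeric seedling with per-part genotype identity.

    Shoot organs carry the shoot genotype's NARK flags, cotyledons (and the
    hypocotyl below them) the cotyledon genotype's, root organs the root
    genotype's; growth parameters come from each part's genotype (which are
    identical across near-isogenic genotypes anyway).
    """
    for part, name in (
        ("shoot", spec.shoot_genotype),
        ("cotyledon", spec.cotyledon_genotype),
        ("root", spec.root_genotype),
    ):
        if name is not None and name not in registry:
            raise ConfigurationError(f"graft {part} genotype {name!r} not registered")
    parts = {
        "shoot": spec.shoot_genotype,
        "root": spec.root_genotype,
        "hypocotyl": spec.cotyledon_genotype or spec.root_genotype,
    }
    if spec.cotyledon_genotype is not None:
        parts["cotyledon"] = spec.cotyledon_genotype
    return init_plant(
        registry, 0, genotype_name=spec.root_genotype, part_genotypes=parts
    )


def _retention_event(spec: GraftSpec, capacity: dict[str, float]):
    per_cot = capacity[spec.retention]
    remove = {"0_C": 2, "1_YC": 1}.get(spec.retention, 0)

    def apply(plant: PlantTopology) -> None:
        plant.cotyledon_capacity = per_cot
        cots = sorted(
            (o for o in plant.organs.values() if o.kind == "cotyledon"),
            key=lambda o: o.id,
        )
        for o in cots[:remove]:
            o.status = ABSCISED
            o.biomass_fraction = 0.0

    return apply


def simulate_graft(
    spec: GraftSpec,
    registry: dict[str, GenotypeParameters],
    aon_params: SignallingParameters | None,
    schedule: Schedule | None = None,
    seed: int = 0,
    *,
    graft_day: float = DEFAULT_GRAFT_DAY,
    retention_capacity: dict[str, float] | None = None,
    hypothesis: str = "cotyledon_shoot",
) -> GraftResult:
    """Full day-0 -> end run of an assembled chimera.

    Perception follows each organ's own genotype NARK flags (no
    complementation override): e.g. in Ns+Bc+Br only the Bragg cotyledons
    can produce SDI.  The retention state is imposed at ``graft_day``.
    """
    sched = schedule or Schedule()
    parts = {
        "shoot": spec.shoot_genotype,
        "root": spec.root_genotype,
        "hypocotyl": spec.cotyledon_genotype or spec.root_genotype,
    }
    if spec.cotyledon_genotype is not None:
        parts["cotyledon"] = spec.cotyledon_genotype
    assemble_graft(spec, registry)  # validates genotype names
    capacity = retention_capacity or DEFAULT_RETENTION_CAPACITY
    events = [(graft_day, _retention_event(spec, capacity))]
    res = run_simulation(
        spec.root_genotype,
        aon_params,
        hypothesis=hypothesis,
        schedule=sched,
        seed=seed,
        registry=registry,
        part_genotypes=parts,
        events=events,
    )
    final_day = sched.snapshot_days[-1]
    c = res.census_at(final_day)
    return GraftResult(
        spec=spec, nodule_count_day16=c.nodule_count, census=c, result=res
    )
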