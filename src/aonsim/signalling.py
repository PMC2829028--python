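"""Hypothetical AON signalling: Q emission, transport, perception, inhibition.

The two mobile signals are modelled as discrete mass parcels advected by
plug flow along the organ tree at a fixed speed (mm/day):

* **Q** is emitted as a single pulse when a nodule primordium is induced and
  travels *shootward* — down a root toward its base, across the
  hypocotyl/root junction, then up the shoot axis toward the leaves.
* **SDI** is produced in NARK-functional aerial organs in proportion to the
  local Q they perceive and travels *rootward*, back down to the root
  system, where a sufficient local concentration arrests uncommitted
  nodule primordia.

Flux moving toward the distal ends of the tree (shootward in the shoot,
rootward in the root) splits at every branch junction, by default in
proportion to the cross-sectional area (diameter squared) of the receiving
axes; flux converging toward the base never splits.  Transport conserves
mass exactly; only explicit decay, perception (stoichiometric conversion of
Q into SDI) and organ abscission remove it.

Parcels within an organ are periodically merged on a fixed spatial grid to
bound their number; merging conserves mass and its first moment, so a lone
pulse keeps its exact front position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np

from .architecture import ACTIVE, ARRESTED, ABSCISED, Organ, PlantTopology, grow, initiate_primordia
from .errors import ConfigurationError, UnknownOrganError
from .params import AXIS_KINDS, PERCEIVING_KINDS, ROOT_SIDE_KINDS, SignallingParameters

_EPS = 1e-9

SHOOTWARD = "shootward"
ROOTWARD = "rootward"


@dataclass
class SignalField:
    """Per-organ amounts of the two mobile signals, resolved as parcels.

    ``parcels[signal]`` maps organ id -> list of (position mm, mass units).
    Amount maps and concentrations (units per mm of organ length) are
    derived views.
    """

    parcels: dict[str, dict[str, list[list[float]]]] = dc_field(
        default_factory=lambda: {"q": {}, "sdi": {}}
    )

    def add(self, signal: str, organ_id: str, pos: float, mass: float) -> None:
        if mass <= 0:
            return
        self.parcels[signal].setdefault(organ_id, []).append([pos, mass])

    def amounts(self, signal: str) -> dict[str, float]:
        return {
            oid: sum(m for _, m in ps)
            for oid, ps in self.parcels[signal].items()
            if ps
        }

    def amount(self, signal: str, organ_id: str) -> float:
        return sum(m for _, m in self.parcels[signal].get(organ_id, ()))

    def total(self, signal: str) -> float:
        return sum(m for ps in self.parcels[signal].values() for _, m in ps)

    def concentration(self, signal: str, organ: Organ) -> float:
        if organ.length <= 0:
            return 0.0
        return self.amount(signal, organ.id) / organ.length

    def local_concentration(
        self, signal: str, organ: Organ, pos: float, window_mm: float
    ) -> float:
        """Mean concentration in a window of the organ axis centred at pos."""
        lo = max(0.0, pos - window_mm / 2)
        hi = min(max(organ.length, _EPS), pos + window_mm / 2)
        if hi <= lo:
            return 0.0
        mass = sum(
            m
            for p, m in self.parcels[signal].get(organ.id, ())
            if lo - _EPS <= p <= hi + _EPS
        )
        return mass / (hi - lo)

    def scale(self, signal: str, factor: float) -> None:
        for ps in self.parcels[signal].values():
            for parcel in ps:
                parcel[1] *= factor

    def prune(self, plant: PlantTopology) -> float:
        """Drop parcels held in abscised organs; returns the mass removed."""
        removed = 0.0
        for signal in self.parcels:
            for oid in list(self.parcels[signal]):
                o = plant.organs.get(oid)
                if o is None or o.status == ABSCISED:
                    removed += sum(m for _, m in self.parcels[signal][oid])
                    del self.parcels[signal][oid]
        return removed

    def merge_bins(self, signal: str, bin_mm: float) -> None:
        for oid, ps in self.parcels[signal].items():
            if len(ps) <= 1:
                continue
            bins: dict[int, list[float]] = {}
            for pos, mass in ps:
                b = int(pos // bin_mm)
                acc = bins.setdefault(b, [0.0, 0.0])  # [mass, mass*pos]
                acc[0] += mass
                acc[1] += mass * pos
            self.parcels[signal][oid] = [
                [acc[1] / acc[0], acc[0]] for _, acc in sorted(bins.items())
            ]


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def emit_q(
    field: SignalField,
    plant: PlantTopology,
    new_primordia: Iterable[str],
    params: SignallingParameters,
) -> SignalField:
    """Release one pulse of Q per newly induced primordium, placed on the
    parent root at the primordium's attachment position."""
    if params.q_per_primordium <= 0:
        for oid in new_primordia:
            plant.organ(oid)
        return field
    for oid in new_primordia:
        pr = plant.organ(oid)
        if pr.parent_id is None:
            raise UnknownOrganError(f"primordium {oid!r} has no parent root")
        field.add("q", pr.parent_id, pr.attach_pos, params.q_per_primordium)
    return field


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

def _is_root_side(kind: str) -> bool:
    return kind in ROOT_SIDE_KINDS


def _local_distal(kind: str, direction: str) -> bool:
    """Whether global movement corresponds to increasing position (toward
    the distal tip) within an organ of this kind."""
    if direction == SHOOTWARD:
        return not _is_root_side(kind)
    return _is_root_side(kind)


def _flow_children(plant: PlantTopology, organ: Organ) -> list[Organ]:
    """Axis children that can receive distally moving flux."""
    return [
        c
        for c in plant.children(organ.id)
        if c.kind in AXIS_KINDS and c.status != ABSCISED
    ]


def _flow_map(plant: PlantTopology) -> dict[str, list[tuple[float, Organ]]]:
    """Per-organ sorted (attach_pos, child) list of flux-receiving children."""
    out: dict[str, list[tuple[float, Organ]]] = {}
    for oid in plant.organs:
        cs = _flow_children(plant, plant.organs[oid])
        if cs:
            out[oid] = sorted(((c.attach_pos, c) for c in cs), key=lambda t: t[0])
    return out


def _tip_sink(plant: PlantTopology, organ: Organ) -> float:
    """Phloem sink strength of this organ's tip: elongation rate times
    cross-section for an actively growing root tip, else 0."""
    if organ.kind not in ("primary_root", "lateral_root") or organ.status != ACTIVE:
        return 0.0
    p = plant.params_for(organ)
    if organ.length >= p.max_length.get(organ.kind, math.inf) - _EPS:
        return 0.0
    return p.elongation_rate.get(organ.kind, 0.0) * organ.diameter**2


def _sink_map(plant: PlantTopology) -> dict[str, float]:
    """Total sink strength of each organ's subtree (self included)."""
    sinks: dict[str, float] = {}

    def visit(oid: str) -> float:
        if oid in sinks:
            return sinks[oid]
        o = plant.organs[oid]
        total = _tip_sink(plant, o) + sum(
            visit(c.id) for c in plant.children(oid)
        )
        sinks[oid] = total
        return total

    visit(plant.base_id)
    for oid in plant.organs:  # disconnected safety
        visit(oid)
    return sinks


def _split_weights(
    organs: list[Organ | None],
    parent: Organ,
    rule: str,
    *,
    sinks: dict[str, float] | None = None,
    cont_sinks: float = 0.0,
) -> list[float]:
    """Weights for flux splitting among receivers; ``None`` entries stand for
    the continuing parent axis.

    ``equal`` splits uniformly; ``cross_section`` in proportion to diameter
    squared (xylem-like conductance); ``sink`` in proportion to the number
    of actively growing root tips downstream of each receiver (phloem-like
    mass flow toward sinks), falling back to cross-section where no
    receiver subtends a growing tip.
    """
    if rule == "equal":
        w = [1.0] * len(organs)
    elif rule == "sink" and sinks is not None:
        w = [
            float(cont_sinks if o is None else sinks.get(o.id, 0)) for o in organs
        ]
        if sum(w) <= 0:
            w = [(parent.diameter if o is None else o.diameter) ** 2 for o in organs]
    else:  # cross_section
        w = [
            (parent.diameter if o is None else o.diameter) ** 2 for o in organs
        ]
    s = sum(w)
    return [x / s for x in w]


def advect(
    field: SignalField,
    plant: PlantTopology,
    rate: float,
    direction: str,
    dt: float,
    decay: float = 0.0,
    *,
    signal: str = "q",
    split_rule: str = "cross_section",
    bin_mm: float | None = None,
) -> SignalField:
    """Move all parcels of one signal a path distance ``rate * dt``.

    Shootward flux converges toward the root base and then diverges up the
    shoot; rootward flux converges down the shoot and diverges into the root
    system.  Divergent flux splits at branch junctions.  Parcels reaching a
    terminal tip (leaf or root apex) rest there.  With ``decay == 0`` total
    mass is conserved exactly.
    """
    if direction not in (SHOOTWARD, ROOTWARD):
        raise ConfigurationError(f"direction must be shootward/rootward, got {direction!r}")
    if rate < 0:
        raise ConfigurationError(f"rate must be >= 0, got {rate}")
    if not dt > 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")

    if rate > 0:
        flow = _flow_map(plant)
        sinks = _sink_map(plant) if split_rule == "sink" else None
        out = SignalField()
        # stack of (organ, pos, mass, remaining distance)
        for oid in sorted(field.parcels[signal]):
            for pos, mass in field.parcels[signal][oid]:
                stack = [(plant.organs.get(oid), pos, mass, rate * dt)]
                while stack:
                    organ, p, m, rem = stack.pop()
                    if organ is None or m <= 0:
                        continue
                    if _local_distal(organ.kind, direction):
                        # move toward increasing position, splitting at junctions
                        juncs = flow.get(organ.id, ())
                        while True:
                            length = max(organ.length, 0.0)
                            nxt = math.inf
                            for jp, _ in juncs:
                                if jp > p + _EPS:
                                    nxt = jp
                                    break
                            stop = min(p + rem, nxt, length)
                            rem -= stop - p
                            p = stop
                            if rem <= _EPS:
                                out.add(signal, organ.id, p, m)
                                break
                            at_tip = p >= length - _EPS
                            here = [c for jp, c in juncs if abs(jp - p) < 1e-6]
                            cont = not at_tip  # axis continues beyond p
                            if not here:
                                if cont:
                                    continue
                                out.add(signal, organ.id, length, m)  # rest at tip
                                break
                            receivers: list[Organ | None] = list(here)
                            if cont:
                                receivers.append(None)
                            cont_sinks = 0
                            if sinks is not None and cont:
                                cont_sinks = _tip_sink(plant, organ) + sum(
                                    sinks.get(c.id, 0)
                                    for jp, c in juncs
                                    if jp > p + _EPS
                                )
                            ws = _split_weights(
                                receivers,
                                organ,
                                split_rule,
                                sinks=sinks,
                                cont_sinks=cont_sinks,
                            )
                            for r, w in zip(receivers, ws):
                                if r is not None:
                                    stack.append((r, 0.0, m * w, rem))
                            if cont:
                                m = m * ws[-1]
                                continue
                            break
                    else:
                        # move toward position 0 (convergent, no splitting)
                        travel = min(rem, p)
                        p -= travel
                        rem -= travel
                        if rem <= _EPS:
                            out.add(signal, organ.id, p, m)
                            continue
                        if organ.parent_id is not None:
                            parent = plant.organs[organ.parent_id]
                            stack.append((parent, organ.attach_pos, m, rem))
                        else:
                            # plant base: rootward flux crosses into the root
                            if direction == ROOTWARD:
                                roots = [
                                    c
                                    for jp, c in flow.get(organ.id, ())
                                    if _is_root_side(c.kind) and abs(jp) < 1e-6
                                ]
                                if roots:
                                    ws = _split_weights(
                                        list(roots), organ, split_rule, sinks=sinks
                                    )
                                    for r, w in zip(roots, ws):
                                        stack.append((r, 0.0, m * w, rem))
                                else:
                                    out.add(signal, organ.id, 0.0, m)
                            else:
                                out.add(signal, organ.id, 0.0, m)
        field.parcels[signal] = out.parcels[signal]

    if decay > 0:
        field.scale(signal, math.exp(-decay * dt))
    if bin_mm:
        field.merge_bins(signal, bin_mm)
    return field


# ---------------------------------------------------------------------------
# perception / production
# ---------------------------------------------------------------------------

def _nark_activity(
    plant: PlantTopology,
    organ: Organ,
    params: SignallingParameters,
    hypothesis: str,
) -> float:
    """Effective NARK perception capacity of an organ in [0, 1].

    Leaves perceive when their genotype carries functional GmNARK (or in a
    complementation run, where the hypothetical receptor is imposed).
    Cotyledons additionally require the cotyledon-shoot hypothesis, must not
    be abscised, and are scaled by their declining biomass and by any graft
    retention capacity.
    """
    if organ.kind not in PERCEIVING_KINDS:
        return 0.0
    if organ.status == ABSCISED:
        return 0.0
    functional = (
        True if params.override_nark else plant.params_for(organ).nark(organ.kind)
    )
    if not functional:
        return 0.0
    if organ.kind == "cotyledon":
        if hypothesis != "cotyledon_shoot":
            return 0.0
        return organ.biomass_fraction * plant.cotyledon_capacity
    return 1.0


def perceive_and_produce_sdi(
    field: SignalField,
    plant: PlantTopology,
    params: SignallingParameters,
    hypothesis: str,
    dt: float | None = None,
) -> SignalField:
    """Convert perceived Q into SDI in NARK-functional aerial organs.

    Production follows first-order kinetics: over a sub-step the fraction
    ``1 - exp(-sdi_gain * activity * dt)`` of the organ's Q is converted
    into SDI at the same positions.  Unless ``catalytic``, perception
    consumes the Q it converts, keeping mass accounting closed.
    """
    if hypothesis not in ("cotyledon_root", "cotyledon_shoot"):
        raise ConfigurationError(f"unknown hypothesis {hypothesis!r}")
    dt = params.dt_signal if dt is None else dt
    if params.sdi_gain <= 0:
        return field
    for oid in sorted(field.parcels["q"]):
        organ = plant.organs.get(oid)
        if organ is None:
            continue
        act = _nark_activity(plant, organ, params, hypothesis)
        if act <= 0:
            continue
        frac = 1.0 - math.exp(-params.sdi_gain * act * dt)
        for parcel in field.parcels["q"][oid]:
            produced = parcel[1] * frac
            if produced <= 0:
                continue
            field.add("sdi", oid, parcel[0], produced)
            if not params.catalytic:
                parcel[1] -= produced
    return field


# ---------------------------------------------------------------------------
# inhibition
# ---------------------------------------------------------------------------

def inhibit(
    plant: PlantTopology,
    field: SignalField,
    params: SignallingParameters,
    concentrations: dict[str, float] | None = None,
) -> PlantTopology:
    """Arrest uncommitted nodule primordia where local SDI is at threshold.

    A primordium older than ``commitment_age`` is committed and can no
    longer be arrested; emerged nodules are never arrested.  Arrest is
    permanent.  ``concentrations`` may supply a precomputed per-primordium
    concentration (e.g. a time average over a growth step, as the
    synchronisation loop does); otherwise the instantaneous local
    concentration is used.
    """
    if not math.isfinite(params.t_inh) or params.t_inh <= 0:
        return plant
    sdi = field.parcels["sdi"]
    for pr in plant.iter_kind("nodule_primordium"):
        if pr.status != ACTIVE:
            continue
        if plant.day - pr.birth_day > params.commitment_age:
            continue
        if concentrations is not None:
            conc = concentrations.get(pr.id, 0.0)
        else:
            parent = plant.organs[pr.parent_id]
            if parent.id not in sdi:
                continue
            conc = field.local_concentration(
                "sdi", parent, pr.attach_pos, params.conc_window_mm
            )
        if conc >= params.t_inh:
            pr.status = ARRESTED
    return plant


# ---------------------------------------------------------------------------
# multi-rate synchronisation
# ---------------------------------------------------------------------------

def synchronize(
    plant: PlantTopology,
    field: SignalField,
    growth_dt: float,
    params: SignallingParameters | None,
    hypothesis: str,
    rng: np.random.Generator,
    *,
    inoculation_day: float = 2.0,
) -> tuple[PlantTopology, SignalField]:
    """Advance one growth step with interleaved signalling sub-steps.

    One architectural step (growth + primordium initiation) is followed by
    ``ceil(growth_dt / dt_signal)`` signalling sub-steps, each applying the
    fixed sequence emit -> advect Q -> perceive/produce -> advect SDI.
    The Q pulses of primordia initiated in this growth step are released in
    the first sub-step.  Inhibition is evaluated once per growth step on the
    *time-averaged* local SDI concentration accumulated over the sub-steps —
    averaging (rather than sampling instantaneous concentrations) makes the
    arrest decision numerically stable under sub-step refinement, since a
    moving parcel's transient spike contributes in proportion to its
    residence time.  Signalling never draws from ``rng``, so a run's
    architecture — and its random stream — is independent of the signalling
    parameterisation.
    """
    grow(plant, growth_dt, rng)
    initiate_primordia(plant, inoculation_day, rng)
    field.prune(plant)

    if params is None:
        return plant, field

    new_primordia = [
        o.id
        for o in plant.iter_kind("nodule_primordium", "nodule")
        if abs(o.birth_day - plant.day) < _EPS
    ]
    n_sub = max(1, math.ceil(growth_dt / params.dt_signal - _EPS))
    dt_s = growth_dt / n_sub
    watch = [
        pr
        for pr in plant.iter_kind("nodule_primordium")
        if pr.status == ACTIVE
        and plant.day - pr.birth_day <= params.commitment_age
    ]
    exposure: dict[str, float] = {pr.id: 0.0 for pr in watch}
    for i in range(n_sub):
        if i == 0:
            emit_q(field, plant, new_primordia, params)
        advect(
            field, plant, params.r_q, SHOOTWARD, dt_s, params.decay_q,
            signal="q", split_rule=params.split_rule,
        )
        perceive_and_produce_sdi(field, plant, params, hypothesis, dt_s)
        advect(
            field, plant, params.r_sdi, ROOTWARD, dt_s, params.decay_sdi,
            signal="sdi", split_rule=params.split_rule_sdi,
        )
        for pr in watch:
            parent = plant.organs[pr.parent_id]
            exposure[pr.id] += dt_s * field.local_concentration(
                "sdi", parent, pr.attach_pos, params.conc_window_mm
            )
    # merge once per growth step (not per sub-step) so the numerical
    # diffusion introduced by binning is independent of dt_signal
    field.merge_bins("q", params.bin_mm)
    field.merge_bins("sdi", params.bin_mm)
    mean_conc = {pid: e / growth_dt for pid, e in exposure.items()}
    inhibit(plant, field, params, concentrations=mean_conc)
    return plant, field
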