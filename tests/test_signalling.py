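"""Signal transport, perception, inhibition and the multi-rate loop."""

import dataclasses
import math

import numpy as np
import pytest

from aonsim import (
    Schedule,
    SignalField,
    UnknownOrganError,
    advect,
    default_signalling,
    emit_q,
    inhibit,
    init_plant,
    perceive_and_produce_sdi,
    run_simulation,
    synchronize,
)
from aonsim.architecture import ARRESTED, ACTIVE, grow


def _plant_with_root(registry, length=100.0):
    plant = init_plant(registry["bragg"], seed=1)
    primary = next(plant.iter_kind("primary_root"))
    primary.length = length
    return plant, primary


class TestEmission:
    def test_pulse_per_primordium(self, registry, signalling):
        plant, primary = _plant_with_root(registry)
        p1 = plant.add_organ("nodule_primordium", primary.id, 10.0, 0.0, "bragg")
        p2 = plant.add_organ("nodule_primordium", primary.id, 20.0, 0.0, "bragg")
        field = SignalField()
        emit_q(field, plant, [p1.id, p2.id], signalling)
        assert field.total("q") == pytest.approx(2 * signalling.q_per_primordium)
        assert field.total("sdi") == 0.0

    def test_no_primordia_no_change(self, registry, signalling):
        plant, _ = _plant_with_root(registry)
        field = SignalField()
        emit_q(field, plant, [], signalling)
        assert field.total("q") == 0.0

    def test_zero_pulse_size(self, registry, signalling):
        plant, primary = _plant_with_root(registry)
        p1 = plant.add_organ("nodule_primordium", primary.id, 10.0, 0.0, "bragg")
        sig = dataclasses.replace(signalling, q_per_primordium=0.0)
        field = SignalField()
        emit_q(field, plant, [p1.id], sig)
        assert field.total("q") == 0.0

    def test_unknown_primordium(self, registry, signalling):
        plant, _ = _plant_with_root(registry)
        with pytest.raises(UnknownOrganError):
            emit_q(SignalField(), plant, ["zzz"], signalling)


class TestAdvection:
    def test_zero_rate_leaves_field_unchanged(self, registry):
        plant, primary = _plant_with_root(registry)
        field = SignalField()
        field.add("q", primary.id, 42.0, 1.5)
        advect(field, plant, rate=0.0, direction="shootward", dt=1.0)
        assert field.parcels["q"][primary.id] == [[42.0, 1.5]]

    def test_pulse_front_position(self, registry):
        """A pulse at the base of an unbranched root moves rate*dt."""
        plant, primary = _plant_with_root(registry, length=100.0)
        field = SignalField()
        field.add("sdi", primary.id, 0.0, 1.0)
        advect(field, plant, rate=50.0, direction="rootward", dt=0.1, signal="sdi")
        (pos, mass), = field.parcels["sdi"][primary.id]
        assert pos == pytest.approx(5.0)
        assert mass == pytest.approx(1.0)

    def test_conservation_on_branched_tree(self, registry, rng):
        """Zero decay conserves total mass to 1e-9 relative on a grown,
        branched architecture over many steps in both directions."""
        plant = init_plant(registry["bragg"], seed=1)
        while plant.day < 12.0:
            grow(plant, 0.25, rng)
        field = SignalField()
        for i, root in enumerate(plant.iter_kind("primary_root", "lateral_root")):
            field.add("q", root.id, min(1.0 * i, root.length), 1.0 + 0.1 * i)
        total = field.total("q")
        for _ in range(40):
            advect(field, plant, rate=30.0, direction="shootward", dt=0.05)
        assert field.total("q") == pytest.approx(total, rel=1e-9)
        field2 = SignalField()
        for leaf in plant.iter_kind("leaf", "unifoliate_leaf", "cotyledon"):
            field2.add("sdi", leaf.id, 0.0, 2.0)
        total2 = field2.total("sdi")
        for _ in range(40):
            advect(
                field2, plant, rate=40.0, direction="rootward", dt=0.05,
                signal="sdi", split_rule="sink",
            )
        assert field2.total("sdi") == pytest.approx(total2, rel=1e-9)

    def test_decay_is_exponential(self, registry):
        plant, primary = _plant_with_root(registry)
        field = SignalField()
        field.add("q", primary.id, 50.0, 2.0)
        advect(field, plant, rate=1.0, direction="shootward", dt=0.5, decay=0.3)
        assert field.total("q") == pytest.approx(2.0 * math.exp(-0.3 * 0.5))

    def test_root_to_shoot_transition(self, registry):
        """Shootward flux crosses the root/hypocotyl junction and climbs."""
        plant, primary = _plant_with_root(registry, length=10.0)
        field = SignalField()
        field.add("q", primary.id, 5.0, 1.0)
        advect(field, plant, rate=20.0, direction="shootward", dt=1.0)
        assert field.amount("q", primary.id) == 0.0
        # 15 mm past the junction: hypocotyl (35 mm long) or beyond
        assert field.total("q") == pytest.approx(1.0)
        hypo = plant.organs[plant.base_id]
        in_hypo = field.amount("q", hypo.id)
        in_cots = sum(
            field.amount("q", c.id) for c in plant.iter_kind("cotyledon")
        )
        assert in_hypo + in_cots == pytest.approx(1.0)


class TestPerception:
    def _charge_leaves(self, plant, amount=1.0):
        field = SignalField()
        for leaf in plant.iter_kind("leaf", "unifoliate_leaf", "cotyledon"):
            field.add("q", leaf.id, 0.0, amount)
        return field

    def _grown(self, registry, genotype, day=8.0):
        res = run_simulation(
            genotype, None, registry=registry, seed=1,
            schedule=Schedule(end_day=day, snapshot_days=(day,)),
        )
        return res.plant

    def test_mutant_produces_no_sdi(self, registry, signalling):
        plant = self._grown(registry, "nts1116")
        field = self._charge_leaves(plant)
        perceive_and_produce_sdi(field, plant, signalling, "cotyledon_shoot", 0.5)
        assert field.total("sdi") == 0.0

    def test_cotyledon_root_hypothesis_silences_cotyledons(self, registry, signalling):
        plant = self._grown(registry, "bragg")
        field = SignalField()
        for cot in plant.iter_kind("cotyledon"):
            field.add("q", cot.id, 0.0, 1.0)
        perceive_and_produce_sdi(field, plant, signalling, "cotyledon_root", 0.5)
        assert field.total("sdi") == 0.0
        perceive_and_produce_sdi(field, plant, signalling, "cotyledon_shoot", 0.5)
        assert field.total("sdi") > 0.0

    def test_zero_gain_produces_nothing(self, registry, signalling):
        plant = self._grown(registry, "bragg")
        field = self._charge_leaves(plant)
        sig = dataclasses.replace(signalling, sdi_gain=0.0)
        perceive_and_produce_sdi(field, plant, sig, "cotyledon_shoot", 0.5)
        assert field.total("sdi") == 0.0

    def test_stoichiometric_conversion(self, registry, signalling):
        """Q consumed equals SDI produced: total signal mass is conserved."""
        plant = self._grown(registry, "bragg")
        field = self._charge_leaves(plant, amount=3.0)
        q0 = field.total("q")
        perceive_and_produce_sdi(field, plant, signalling, "cotyledon_shoot", 0.5)
        assert field.total("q") + field.total("sdi") == pytest.approx(q0)
        assert field.total("sdi") > 0.0


class TestInhibition:
    def _primed(self, registry, conc):
        plant, primary = _plant_with_root(registry, length=50.0)
        plant.day = 3.0
        pr = plant.add_organ("nodule_primordium", primary.id, 25.0, 2.5, "bragg")
        field = SignalField()
        # deposit mass giving the requested window concentration
        field.add("sdi", primary.id, 25.0, conc * 10.0)
        return plant, field, pr

    def test_below_threshold_no_arrest(self, registry, signalling):
        plant, field, pr = self._primed(registry, conc=signalling.t_inh / 2)
        inhibit(plant, field, signalling)
        assert pr.status == ACTIVE

    def test_at_threshold_arrests(self, registry, signalling):
        plant, field, pr = self._primed(registry, conc=signalling.t_inh * 2)
        inhibit(plant, field, signalling)
        assert pr.status == ARRESTED

    def test_infinite_threshold_never_arrests(self, registry, signalling):
        sig = dataclasses.replace(signalling, t_inh=math.inf)
        plant, field, pr = self._primed(registry, conc=1e9)
        inhibit(plant, field, sig)
        assert pr.status == ACTIVE

    def test_committed_primordium_immune(self, registry, signalling):
        plant, field, pr = self._primed(registry, conc=1e6)
        plant.day = pr.birth_day + signalling.commitment_age + 1.0
        inhibit(plant, field, signalling)
        assert pr.status == ACTIVE


class TestSynchronize:
    def test_null_signalling_equals_architectural_run(self, registry, signalling):
        zero = dataclasses.replace(
            signalling, q_per_primordium=0.0, sdi_gain=0.0, t_inh=0.0,
            override_nark=True,
        )
        a = run_simulation("nts1116", None, seed=4, registry=registry)
        b = run_simulation("nts1116", zero, seed=4, registry=registry)
        assert a.census_at(16.0) == b.census_at(16.0)

    def test_override_makes_genotypes_equivalent(self, registry, signalling):
        """With the hypothetical receptor imposed everywhere, the Bragg and
        nts1116 runs coincide (they differ only in NARK flags)."""
        sig = dataclasses.replace(signalling, override_nark=True)
        a = run_simulation("bragg", sig, seed=4, registry=registry)
        b = run_simulation("nts1116", sig, seed=4, registry=registry)
        ca, cb = a.census_at(16.0), b.census_at(16.0)
        assert ca.nodule_count == cb.nodule_count
        assert ca.depths_mm == cb.depths_mm

    def test_regulation_monotone_in_gain_and_threshold(self, registry, signalling):
        counts_gain = []
        for gain in (0.5, 2.0, 8.0):
            sig = dataclasses.replace(signalling, sdi_gain=gain)
            res = run_simulation("bragg", sig, seed=2, registry=registry)
            counts_gain.append(res.census_at(16.0).nodule_count)
        assert counts_gain == sorted(counts_gain, reverse=True)
        counts_t = []
        for t in (0.003, 0.006, 0.012):
            sig = dataclasses.replace(signalling, t_inh=t)
            res = run_simulation("bragg", sig, seed=2, registry=registry)
            counts_t.append(res.census_at(16.0).nodule_count)
        assert counts_t == sorted(counts_t)

    def test_supernodulation_recovered_without_gain(self, registry, signalling):
        sig = dataclasses.replace(signalling, sdi_gain=0.0)
        unregulated = run_simulation("nts1116", None, seed=6, registry=registry)
        complemented = run_simulation(
            "nts1116", dataclasses.replace(sig, override_nark=True),
            seed=6, registry=registry,
        )
        assert (
            complemented.census_at(16.0).nodule_count
            == unregulated.census_at(16.0).nodule_count
        )
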