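"""Parameter sets for genotypes and AON signalling.

The two soybean genotypes modelled here — the wild-type cultivar Bragg and
its near-isogenic supernodulating mutant nts1116 — share every growth
parameter and differ *only* in which organ kinds carry a functional GmNARK
receptor (``nark_functional``).  That near-isogenicity is enforced at load
time, because the whole complementation methodology rests on it: with
signalling disabled the two genotypes must be architecturally
indistinguishable.

All defaults live in ``data/defaults.yaml``; this module only defines the
containers, validation, and loading.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

# Organ kinds (string enum kept as plain constants for YAML friendliness).
ORGAN_KINDS = (
    "hypocotyl",
    "epicotyl",
    "internode",
    "petiole",
    "leaf",
    "unifoliate_leaf",
    "cotyledon",
    "primary_root",
    "lateral_root",
    "nodule_primordium",
    "nodule",
)

ROOT_SIDE_KINDS = frozenset(
    {"primary_root", "lateral_root", "nodule_primordium", "nodule"}
)
# Organ kinds that can perceive Q and produce SDI (given functional NARK).
PERCEIVING_KINDS = frozenset({"leaf", "unifoliate_leaf", "cotyledon"})
# Axis kinds through which signal parcels travel.
AXIS_KINDS = frozenset(ORGAN_KINDS) - {"nodule_primordium", "nodule"}


def _check_nonneg(name: str, mapping: Mapping[str, float]) -> None:
    for k, v in mapping.items():
        if k not in ORGAN_KINDS:
            raise ConfigurationError(f"{name}: unknown organ kind {k!r}")
        if not (v >= 0):
            raise ConfigurationError(f"{name}[{k}] must be >= 0, got {v}")


@dataclass
class GenotypeParameters:
    """Growth and NARK-functionality parameters of one genotype.

    Lengths in mm, rates in mm/day, times in days post-sowing.
    """

    name: str
    elongation_rate: dict[str, float]
    max_length: dict[str, float]
    initial_length: dict[str, float]
    diameter: dict[str, float]
    phytomer_interval: float
    lateral_spacing: float
    susceptible_offset: float
    susceptibility_age: float
    primordium_density: float
    primordium_maturation_age: float
    cotyledon_senescence_day: float
    cotyledon_abscission_day: float
    nark_functional: dict[str, bool] = field(default_factory=dict)

    def validate(self) -> "GenotypeParameters":
        _check_nonneg("elongation_rate", self.elongation_rate)
        _check_nonneg("max_length", self.max_length)
        _check_nonneg("initial_length", self.initial_length)
        _check_nonneg("diameter", self.diameter)
        for fname in (
            "phytomer_interval",
            "lateral_spacing",
            "susceptible_offset",
            "susceptibility_age",
            "primordium_density",
            "primordium_maturation_age",
            "cotyledon_senescence_day",
            "cotyledon_abscission_day",
        ):
            v = getattr(self, fname)
            if not (v >= 0):
                raise ConfigurationError(f"{fname} must be >= 0, got {v}")
        if self.cotyledon_abscission_day < self.cotyledon_senescence_day:
            raise ConfigurationError(
                "cotyledon_abscission_day must be >= cotyledon_senescence_day"
            )
        for k in self.nark_functional:
            if k not in ORGAN_KINDS:
                raise ConfigurationError(f"nark_functional: unknown kind {k!r}")
        return self

    def nark(self, kind: str) -> bool:
        return bool(self.nark_functional.get(kind, False))

    def growth_fields_equal(self, other: "GenotypeParameters") -> bool:
        """True if the two parameter sets differ at most in name/NARK flags."""
        for f in fields(self):
            if f.name in ("name", "nark_functional"):
                continue
            if getattr(self, f.name) != getattr(other, f.name):
                return False
        return True

    def to_dict(self) -> dict[str, Any]:
        return {f.name: copy.deepcopy(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GenotypeParameters":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"genotype parameters: unknown key(s) {sorted(unknown)}"
            )
        missing = known - set(d) - {"nark_functional"}
        if missing:
            raise ConfigurationError(
                f"genotype parameters: missing key(s) {sorted(missing)}"
            )
        return cls(**{k: copy.deepcopy(v) for k, v in d.items()}).validate()


@dataclass
class SignallingParameters:
    """Parameters of the hypothetical AON signalling machinery.

    ``r_q``/``r_sdi`` are plug-flow transport rates (mm/day), ``t_inh`` the
    local SDI concentration (units/mm) at or above which an uncommitted
    nodule primordium is arrested, and ``sdi_gain`` the first-order rate
    (per day) at which perceived Q is converted into SDI in NARK-functional
    organs.
    """

    r_q: float = 50.0
    r_sdi: float = 50.0
    q_per_primordium: float = 1.0
    sdi_gain: float = 2.0
    t_inh: float = 0.006
    decay_q: float = 0.0
    decay_sdi: float = 0.0
    commitment_age: float = 1.5
    dt_signal: float = 0.025
    bin_mm: float = 5.0
    conc_window_mm: float = 10.0
    split_rule: str = "cross_section"
    split_rule_sdi: str = "sink"
    catalytic: bool = False
    override_nark: bool = False

    def validate(self) -> "SignallingParameters":
        for fname in (
            "r_q",
            "r_sdi",
            "q_per_primordium",
            "sdi_gain",
            "t_inh",
            "decay_q",
            "decay_sdi",
            "commitment_age",
        ):
            v = getattr(self, fname)
            if not (v >= 0):
                raise ConfigurationError(f"{fname} must be >= 0, got {v}")
        if not (self.dt_signal > 0):
            raise ConfigurationError(f"dt_signal must be > 0, got {self.dt_signal}")
        if not (self.bin_mm > 0):
            raise ConfigurationError(f"bin_mm must be > 0, got {self.bin_mm}")
        if not (self.conc_window_mm > 0):
            raise ConfigurationError(
                f"conc_window_mm must be > 0, got {self.conc_window_mm}"
            )
        for fname in ("split_rule", "split_rule_sdi"):
            v = getattr(self, fname)
            if v not in ("cross_section", "equal", "sink"):
                raise ConfigurationError(
                    f"{fname} must be 'cross_section', 'equal' or 'sink', got {v!r}"
                )
        return self

    @property
    def inactive(self) -> bool:
        """True when the parameterisation cannot regulate anything."""
        return self.sdi_gain == 0 and self.q_per_primordium == 0

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SignallingParameters":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"signalling parameters: unknown key(s) {sorted(unknown)}"
            )
        return cls(**dict(d)).validate()

    def with_levels(self, r_q: float, r_sdi: float, t_inh: float) -> "SignallingParameters":
        return replace(self, r_q=r_q, r_sdi=r_sdi, t_inh=t_inh)


def load_defaults() -> dict[str, Any]:
    """Load the packaged default study conditions (deep copy, safe to edit)."""
    text = resources.files("aonsim.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_genotypes(defaults: Mapping[str, Any] | None = None) -> dict[str, GenotypeParameters]:
    """Build the Bragg and nts1116 parameter sets from the shared defaults.

    The returned registry is guaranteed near-isogenic: any pair of genotypes
    shares every growth field.
    """
    d = defaults if defaults is not None else load_defaults()
    growth = d["growth"]
    registry: dict[str, GenotypeParameters] = {}
    for name, geno in d["genotypes"].items():
        params = dict(copy.deepcopy(growth))
        params["name"] = name
        params["nark_functional"] = dict(geno.get("nark_functional") or {})
        registry[name] = GenotypeParameters.from_dict(params)
    names = list(registry)
    for other in names[1:]:
        if not registry[names[0]].growth_fields_equal(registry[other]):
            raise ConfigurationError(
                f"genotypes {names[0]!r} and {other!r} are not near-isogenic: "
                "growth parameters differ"
            )
    return registry


def default_signalling(defaults: Mapping[str, Any] | None = None) -> SignallingParameters:
    d = defaults if defaults is not None else load_defaults()
    return SignallingParameters.from_dict(d["signalling"])


def default_grid_levels(defaults: Mapping[str, Any] | None = None) -> dict[str, list[float]]:
    d = defaults if defaults is not None else load_defaults()
    return {k: list(v) for k, v in d["grid"].items()}
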