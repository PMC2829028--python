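"""Run configuration files and fixture generation.

Configurations are a small YAML dialect with a versioned ``schema`` header.
A run config resolves to genotype parameter sets, a signalling parameter
set and/or a grid of factor levels, a schedule, a seed and an output
directory.  Unknown or missing keys raise named configuration errors.
"""

from __future__ import annotations

import hashlib

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .params import (
    GenotypeParameters,
    SignallingParameters,
    default_genotypes,
    default_grid_levels,
    default_signalling,
    load_defaults,
)
from .simulate import Schedule

SCHEMA = "aonsim-run/1"

_TOP_KEYS = {
    "schema",
    "genotypes",
    "signalling",
    "grid",
    "schedule",
    "seed",
    "output_dir",
}
_SCHEDULE_KEYS = {"end_day", "growth_dt", "inoculation_day", "snapshot_days"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one reproducible run."""

    genotypes: dict[str, GenotypeParameters]
    signalling: SignallingParameters
    grid_levels: dict[str, list[float]]
    schedule: Schedule
    seed: int = 1
    output_dir: str = "."

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema": SCHEMA,
            "genotypes": {n: g.to_dict() for n, g in sorted(self.genotypes.items())},
            "signalling": self.signalling.to_dict(),
            "grid": {k: list(v) for k, v in self.grid_levels.items()},
            "schedule": {
                "end_day": self.schedule.end_day,
                "growth_dt": self.schedule.growth_dt,
                "inoculation_day": self.schedule.inoculation_day,
                "snapshot_days": list(self.schedule.snapshot_days),
            },
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def render(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.render().encode()).hexdigest()[:12]


def default_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        genotypes=default_genotypes(),
        signalling=default_signalling(),
        grid_levels=default_grid_levels(),
        schedule=_schedule_from(load_defaults()["schedule"]),
        seed=seed,
    )


def _schedule_from(d: Mapping[str, Any]) -> Schedule:
    unknown = set(d) - _SCHEDULE_KEYS
    if unknown:
        raise ConfigurationError(f"schedule: unknown key(s) {sorted(unknown)}")
    sched = Schedule(
        end_day=float(d.get("end_day", 16.0)),
        growth_dt=float(d.get("growth_dt", 0.25)),
        inoculation_day=float(d.get("inoculation_day", 2.0)),
        snapshot_days=tuple(float(x) for x in d.get("snapshot_days", (10.0, 16.0))),
    )
    return sched.validate()


def parse_config(data: Mapping[str, Any]) -> RunConfig:
    if not isinstance(data, Mapping):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"config: unknown key(s) {sorted(unknown)}")
    schema = data.get("schema", SCHEMA)
    if schema != SCHEMA:
        raise ConfigurationError(f"unsupported config schema {schema!r}")

    if "genotypes" in data:
        genotypes = {
            name: GenotypeParameters.from_dict({**g, "name": name})
            for name, g in data["genotypes"].items()
        }
    else:
        genotypes = default_genotypes()
    signalling = (
        SignallingParameters.from_dict(data["signalling"])
        if "signalling" in data
        else default_signalling()
    )
    grid_levels = (
        {k: [float(x) for x in v] for k, v in data["grid"].items()}
        if "grid" in data
        else default_grid_levels()
    )
    schedule = _schedule_from(data.get("schedule", {}))
    seed = int(data.get("seed", 1))
    return RunConfig(
        genotypes=genotypes,
        signalling=signalling,
        grid_levels=grid_levels,
        schedule=schedule,
        seed=seed,
        output_dir=str(data.get("output_dir", ".")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ConfigurationError(f"config file {p} does not parse: {e}") from e
    try:
        return parse_config(data or {})
    except ConfigurationError as e:
        raise ConfigurationError(f"{p}: {e}") from e


def generate_fixtures(seed: int, outdir: str | Path) -> list[Path]:
    """Write the default genotype, signalling and grid parameter files.

    Stands in for empirical growth tables: the emitted Bragg and nts1116
    parameter sets are plausible organ-scale defaults whose single defining
    difference is NARK functionality.  Byte-identical for equal seeds.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    defaults = load_defaults()
    written = []

    for name, geno in default_genotypes(defaults).items():
        path = out / f"{name}.yaml"
        path.write_text(
            yaml.safe_dump(
                {"schema": "aonsim-genotype/1", "seed": seed, **geno.to_dict()},
                sort_keys=True,
            )
        )
        written.append(path)

    sig_path = out / "signalling.yaml"
    sig_path.write_text(
        yaml.safe_dump(
            {
                "schema": "aonsim-signalling/1",
                "seed": seed,
                **default_signalling(defaults).to_dict(),
            },
            sort_keys=True,
        )
    )
    written.append(sig_path)

    grid_path = out / "grid.yaml"
    grid_path.write_text(
        yaml.safe_dump(
            {
                "schema": "aonsim-grid/1",
                "seed": seed,
                **default_grid_levels(defaults),
            },
            sort_keys=True,
        )
    )
    written.append(grid_path)

    run_path = out / "run.yaml"
    run_path.write_text(default_config(seed=seed).render())
    written.append(run_path)
    return written


def load_genotype_file(path: str | Path) -> GenotypeParameters:
    data = yaml.safe_load(Path(path).read_text())
    data.pop("schema", None)
    data.pop("seed", None)
    return GenotypeParameters.from_dict(data)
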