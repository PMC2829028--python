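"""Computational complementation: virtual-experiment grids and S_cp scoring.

The core statistic is the similarity degree

    S_cp = 100 * (N_nt - N_cp) / (N_nt - N_br)   [percent]

comparing the nodule count ``N_cp`` of the mutant model complemented with
hypothetical AON signalling against the supernodulating mutant baseline
``N_nt`` and the wild-type baseline ``N_br``: the fraction of the nodules
that the wild type suppresses which the complemented model also suppresses.
100% is perfect complementation, 0% none, and values above 100% indicate
over-regulation.  A result is classified "good" when S_cp lies in
[80%, 120%] (bounds inclusive).

Virtual experiments form a full-factorial grid over three 3-level factors —
the Q and SDI transport rates and the inhibition threshold — run once under
each cotyledon hypothesis: CRH_i (cotyledon-root, cotyledons signalling-
inert) and CSH_i (cotyledon-shoot, cotyledons produce SDI).  CRH_i and
CSH_i share levels and seed, so each pair differs only in the cotyledon's
role.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import pandas as pd

from .architecture import Census
from .errors import ConfigurationError, DegenerateBaselineError
from .params import GenotypeParameters, SignallingParameters
from .simulate import Schedule, SimulationResult, run_simulation

GOOD = "good"
NOT_GOOD = "not_good"

FACTORS = ("r_q", "r_sdi", "t_inh")
HYPOTHESIS_PREFIX = {"cotyledon_root": "CRH", "cotyledon_shoot": "CSH"}


@dataclass(frozen=True)
class SimilarityInputs:
    """Nodule counts of the three models at one measurement day."""

    n_nt: int  # mutant architectural model
    n_br: int  # wild-type architectural model
    n_cp: int  # complemented (mutant + AON) model


def similarity_degree(inputs: SimilarityInputs) -> float:
    """Similarity degree S_cp in percent; requires n_nt > n_br."""
    if inputs.n_nt <= inputs.n_br:
        raise DegenerateBaselineError(
            f"similarity degree undefined: mutant baseline n_nt={inputs.n_nt} "
            f"does not exceed wild-type baseline n_br={inputs.n_br}"
        )
    return 100.0 * (inputs.n_nt - inputs.n_cp) / (inputs.n_nt - inputs.n_br)


def classify(s_cp: float) -> str:
    """'good' iff 80 <= S_cp <= 120 (inclusive); s_cp must be finite."""
    if not math.isfinite(s_cp):
        raise ConfigurationError(f"S_cp must be finite, got {s_cp}")
    return GOOD if 80.0 <= s_cp <= 120.0 else NOT_GOOD


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of a virtual-experiment grid."""

    hypothesis: str
    index: int  # 1-based within the hypothesis
    levels: tuple[int, int, int]  # 1-based level index per factor
    values: tuple[float, float, float]  # (r_q, r_sdi, t_inh)
    seed: int

    @property
    def label(self) -> str:
        return f"{HYPOTHESIS_PREFIX[self.hypothesis]}_{self.index}"


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    n_nt_day10: int
    n_br_day10: int
    n_cp_day10: int
    n_nt_day16: int
    n_br_day16: int
    n_cp_day16: int
    s_cp_day10: float
    s_cp_day16: float
    classification_day10: str
    classification_day16: str
    nodule_depth_summary: tuple[int, float, float]  # count, mean mm, IQR mm


def build_grid(
    levels_per_factor: dict[str, list[float]],
    seed: int,
    hypotheses: tuple[str, ...] = ("cotyledon_root", "cotyledon_shoot"),
) -> list[ExperimentSpec]:
    """Full-factorial grid, one spec per cell and hypothesis.

    Labels are assigned in lexicographic order of the (r_q, r_sdi, t_inh)
    level indices, so e.g. three levels per factor yield CRH_1..CRH_27 and
    CSH_1..CSH_27 with CRH_i and CSH_i sharing levels and seed.
    """
    if set(levels_per_factor) != set(FACTORS):
        raise ConfigurationError(
            f"grid must define exactly the factors {FACTORS}, "
            f"got {sorted(levels_per_factor)}"
        )
    for f in FACTORS:
        if not levels_per_factor[f]:
            raise ConfigurationError(f"factor {f!r} has no levels")
    specs = []
    for hyp in hypotheses:
        if hyp not in HYPOTHESIS_PREFIX:
            raise ConfigurationError(f"unknown hypothesis {hyp!r}")
        combos = itertools.product(
            *(list(enumerate(levels_per_factor[f], start=1)) for f in FACTORS)
        )
        for i, combo in enumerate(combos, start=1):
            levels = tuple(ix for ix, _ in combo)
            values = tuple(v for _, v in combo)
            specs.append(
                ExperimentSpec(
                    hypothesis=hyp, index=i, levels=levels, values=values, seed=seed
                )
            )
    _assert_paired(specs)
    return specs


def _assert_paired(specs: list[ExperimentSpec]) -> None:
    by_hyp: dict[str, dict[int, ExperimentSpec]] = {}
    for s in specs:
        by_hyp.setdefault(s.hypothesis, {})[s.index] = s
    hyps = list(by_hyp)
    for a, b in itertools.combinations(hyps, 2):
        for i in set(by_hyp[a]) & set(by_hyp[b]):
            sa, sb = by_hyp[a][i], by_hyp[b][i]
            if sa.levels != sb.levels or sa.seed != sb.seed:
                raise ConfigurationError(
                    f"paired-design violation: {sa.label} and {sb.label} "
                    "differ in levels or seed"
                )


def reference_signalling(
    base: SignallingParameters, levels_per_factor: dict[str, list[float]]
) -> SignallingParameters:
    """The wild-type reference parameterisation: the mid level of each grid
    factor (the 'confirmed mechanisms' baseline)."""
    mids = {f: levels_per_factor[f][len(levels_per_factor[f]) // 2] for f in FACTORS}
    return base.with_levels(mids["r_q"], mids["r_sdi"], mids["t_inh"])


def run_baselines(
    registry: dict[str, GenotypeParameters],
    reference: SignallingParameters,
    schedule: Schedule,
    seed: int,
    *,
    mutant: str = "nts1116",
    wild_type: str = "bragg",
) -> tuple[SimulationResult, SimulationResult]:
    """The two baseline runs sharing the grid's seed and schedule:
    the unregulated mutant architectural model, and the wild-type reference
    (wild-type genotype with the reference AON parameterisation)."""
    nt = run_simulation(
        mutant, None, schedule=schedule, seed=seed, registry=registry
    )
    br = run_simulation(
        wild_type,
        reference,
        hypothesis="cotyledon_shoot",
        schedule=schedule,
        seed=seed,
        registry=registry,
    )
    return nt, br


def run_experiment(
    spec: ExperimentSpec,
    registry: dict[str, GenotypeParameters],
    base_signalling: SignallingParameters,
    schedule: Schedule,
    *,
    mutant: str = "nts1116",
) -> SimulationResult:
    """One complementation run: mutant growth + imposed AON signalling."""
    r_q, r_sdi, t_inh = spec.values
    sig = replace(
        base_signalling.with_levels(r_q, r_sdi, t_inh), override_nark=True
    )
    return run_simulation(
        mutant,
        sig,
        hypothesis=spec.hypothesis,
        schedule=schedule,
        seed=spec.seed,
        registry=registry,
    )


def run_grid(
    grid: list[ExperimentSpec],
    registry: dict[str, GenotypeParameters],
    base_signalling: SignallingParameters,
    levels_per_factor: dict[str, list[float]],
    schedule: Schedule | None = None,
    *,
    mutant: str = "nts1116",
    wild_type: str = "bragg",
    day_early: float = 10.0,
    day_late: float = 16.0,
    reference: SignallingParameters | None = None,
) -> list[ExperimentResult]:
    """Run every grid cell against shared baselines.

    Baselines are computed once with the grid's seed; the wild-type
    reference run uses ``reference`` (by default the mid grid levels).  A
    mutant baseline that fails to out-nodulate the wild-type reference at
    either measurement day aborts with :class:`DegenerateBaselineError`.
    Results are sorted CRH first, then CSH, by index.
    """
    if not grid:
        return []
    sched = schedule or Schedule(snapshot_days=(day_early, day_late))
    seeds = {s.seed for s in grid}
    if len(seeds) != 1:
        raise ConfigurationError("all grid cells must share one seed")
    if reference is None:
        reference = reference_signalling(base_signalling, levels_per_factor)
    nt, br = run_baselines(
        registry, reference, sched, seeds.pop(), mutant=mutant, wild_type=wild_type
    )
    counts = {}
    for day in (day_early, day_late):
        n_nt = nt.census_at(day).nodule_count
        n_br = br.census_at(day).nodule_count
        if n_nt <= n_br:
            raise DegenerateBaselineError(
                f"day {day}: mutant baseline ({n_nt} nodules) does not exceed "
                f"wild-type reference ({n_br}); similarity degree undefined"
            )
        counts[day] = (n_nt, n_br)
    results = []
    for spec in sorted(grid, key=lambda s: (s.hypothesis == "cotyledon_shoot", s.index)):
        res = run_experiment(
            spec, registry, base_signalling, sched, mutant=mutant
        )
        n10 = res.census_at(day_early).nodule_count
        n16 = res.census_at(day_late).nodule_count
        s10 = similarity_degree(SimilarityInputs(*counts[day_early], n10))
        s16 = similarity_degree(SimilarityInputs(*counts[day_late], n16))
        c16 = res.census_at(day_late)
        results.append(
            ExperimentResult(
                spec=spec,
                n_nt_day10=counts[day_early][0],
                n_br_day10=counts[day_early][1],
                n_cp_day10=n10,
                n_nt_day16=counts[day_late][0],
                n_br_day16=counts[day_late][1],
                n_cp_day16=n16,
                s_cp_day10=s10,
                s_cp_day16=s16,
                classification_day10=classify(s10),
                classification_day16=classify(s16),
                nodule_depth_summary=(
                    c16.nodule_count,
                    c16.mean_depth_mm,
                    c16.depth_iqr_mm,
                ),
            )
        )
    return results


def results_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """Grid results as a DataFrame with unit-carrying column names."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.spec.label,
                "hypothesis": r.spec.hypothesis,
                "r_q_mm_per_day": r.spec.values[0],
                "r_sdi_mm_per_day": r.spec.values[1],
                "t_inh_units_per_mm": r.spec.values[2],
                "n_nt_day10": r.n_nt_day10,
                "n_br_day10": r.n_br_day10,
                "n_cp_day10": r.n_cp_day10,
                "n_nt_day16": r.n_nt_day16,
                "n_br_day16": r.n_br_day16,
                "n_cp_day16": r.n_cp_day16,
                "s_cp_day10_percent": r.s_cp_day10,
                "s_cp_day16_percent": r.s_cp_day16,
                "class_day10": r.classification_day10,
                "class_day16": r.classification_day16,
                "nodule_count_day16": r.nodule_depth_summary[0],
                "mean_depth_day16_mm": r.nodule_depth_summary[1],
                "depth_iqr_day16_mm": r.nodule_depth_summary[2],
            }
        )
    return pd.DataFrame(rows)


def aggregate_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average grid result tables from replicate seeds.

    Numeric columns are averaged per label; classifications are re-derived
    from the mean similarity degrees.
    """
    if len(tables) == 1:
        return tables[0]
    cat = pd.concat(tables, ignore_index=True)
    num = cat.groupby("label", sort=False).mean(numeric_only=True).reset_index()
    meta = tables[0][["label", "hypothesis"]]
    out = meta.merge(num, on="label")
    out["class_day10"] = out.s_cp_day10_percent.map(classify)
    out["class_day16"] = out.s_cp_day16_percent.map(classify)
    return out


@dataclass(frozen=True)
class DistributionComparison:
    """Differences (a - b) between two nodulation censuses."""

    count_diff: int
    mean_depth_diff_mm: float
    depth_iqr_diff_mm: float


def compare_distributions(census_a: Census, census_b: Census) -> DistributionComparison:
    """Compare nodule number, mean depth, and nodulation interval (depth
    interquartile range) between two censuses taken at the same day."""
    if abs(census_a.day - census_b.day) > 1e-6:
        raise ConfigurationError(
            f"censuses taken at different days: {census_a.day} vs {census_b.day}"
        )
    return DistributionComparison(
        count_diff=census_a.nodule_count - census_b.nodule_count,
        mean_depth_diff_mm=census_a.mean_depth_mm - census_b.mean_depth_mm,
        depth_iqr_diff_mm=census_a.depth_iqr_mm - census_b.depth_iqr_mm,
    )
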