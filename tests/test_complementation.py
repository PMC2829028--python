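"""Similarity degree, classification, grid design, distribution comparison."""

import dataclasses

import pytest

from aonsim import (
    Census,
    ConfigurationError,
    DegenerateBaselineError,
    Schedule,
    SimilarityInputs,
    build_grid,
    classify,
    compare_distributions,
    reference_signalling,
    results_table,
    run_grid,
    similarity_degree,
)


class TestSimilarityDegree:
    @pytest.mark.parametrize(
        "n_nt,n_br,n_cp,expected",
        [
            (100, 40, 40, 100.0),  # complemented count equals wild type
            (100, 40, 100, 0.0),  # complementation did nothing
            (100, 40, 28, 120.0),  # over-regulation beyond the wild type
            (100, 40, 70, 50.0),
        ],
    )
    def test_values(self, n_nt, n_br, n_cp, expected):
        s = similarity_degree(SimilarityInputs(n_nt, n_br, n_cp))
        assert s == pytest.approx(expected)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(DegenerateBaselineError):
            similarity_degree(SimilarityInputs(40, 40, 10))
        with pytest.raises(DegenerateBaselineError):
            similarity_degree(SimilarityInputs(30, 40, 10))

    def test_strictly_decreasing_in_complemented_count(self):
        values = [
            similarity_degree(SimilarityInputs(100, 40, n)) for n in range(0, 120)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestClassification:
    @pytest.mark.parametrize(
        "s,expected",
        [
            (100.0, "good"),
            (80.0, "good"),
            (120.0, "good"),
            (79.9, "not_good"),
            (120.1, "not_good"),
            (0.0, "not_good"),
            (-10.0, "not_good"),
            (250.0, "not_good"),
        ],
    )
    def test_interval(self, s, expected):
        assert classify(s) == expected

    def test_rejects_nonfinite(self):
        with pytest.raises(ConfigurationError):
            classify(float("nan"))


class TestGridDesign:
    def test_full_factorial_three_levels(self, grid_levels):
        specs = build_grid(grid_levels, seed=1)
        assert len(specs) == 54
        crh = [s for s in specs if s.hypothesis == "cotyledon_root"]
        csh = [s for s in specs if s.hypothesis == "cotyledon_shoot"]
        assert len(crh) == len(csh) == 27
        assert [s.label for s in crh] == [f"CRH_{i}" for i in range(1, 28)]
        # paired design: same index -> same levels and seed
        for a, b in zip(crh, csh):
            assert a.levels == b.levels
            assert a.values == b.values
            assert a.seed == b.seed
        # lexicographic level order
        assert crh[0].levels == (1, 1, 1)
        assert crh[1].levels == (1, 1, 2)
        assert crh[26].levels == (3, 3, 3)

    @pytest.mark.parametrize("n_levels,expected", [(1, 1), (2, 8), (3, 27)])
    def test_cell_count_scales(self, grid_levels, n_levels, expected):
        levels = {k: v[:n_levels] for k, v in grid_levels.items()}
        specs = build_grid(levels, seed=1, hypotheses=("cotyledon_shoot",))
        assert len(specs) == expected

    def test_wrong_factors_rejected(self, grid_levels):
        bad = dict(grid_levels)
        del bad["t_inh"]
        with pytest.raises(ConfigurationError):
            build_grid(bad, seed=1)
        bad = {**grid_levels, "extra": [1.0]}
        with pytest.raises(ConfigurationError):
            build_grid(bad, seed=1)

    def test_rebuild_is_identical(self, grid_levels):
        assert build_grid(grid_levels, seed=3) == build_grid(grid_levels, seed=3)


class TestRunGrid:
    def test_single_cell_grid_and_null_signal_pairing(
        self, registry, signalling, grid_levels
    ):
        """With sdi_gain=0 the cotyledon hypothesis is irrelevant: CRH_i and
        CSH_i produce identical results."""
        levels = {k: [v[1]] for k, v in grid_levels.items()}
        specs = build_grid(levels, seed=1)
        assert len(specs) == 2
        base = dataclasses.replace(signalling, sdi_gain=0.0)
        reference = reference_signalling(signalling, grid_levels)
        results = run_grid(
            specs, registry, base, levels, Schedule(), reference=reference
        )
        assert len(results) == 2
        crh, csh = results
        assert crh.spec.hypothesis == "cotyledon_root"
        assert (crh.n_cp_day10, crh.n_cp_day16) == (csh.n_cp_day10, csh.n_cp_day16)
        assert crh.s_cp_day10 == csh.s_cp_day10
        # no SDI, no arrest: the complemented run equals the mutant baseline
        assert crh.n_cp_day16 == crh.n_nt_day16
        assert crh.s_cp_day16 == pytest.approx(0.0)

    def test_results_table_columns(self, registry, signalling, grid_levels):
        levels = {k: [v[1]] for k, v in grid_levels.items()}
        specs = build_grid(levels, seed=1)
        results = run_grid(specs, registry, signalling, levels, Schedule())
        table = results_table(results)
        assert list(table.columns[:5]) == [
            "label",
            "hypothesis",
            "r_q_mm_per_day",
            "r_sdi_mm_per_day",
            "t_inh_units_per_mm",
        ]
        assert table.shape[0] == 2
        assert set(table.class_day16) <= {"good", "not_good"}
        # the mid-level cotyledon-shoot cell IS the wild-type reference
        csh = table[table.hypothesis == "cotyledon_shoot"].iloc[0]
        assert csh.s_cp_day10_percent == pytest.approx(100.0)
        assert csh.s_cp_day16_percent == pytest.approx(100.0)


def _census(day, depths):
    return Census(
        day=day,
        genotype="x",
        nodule_count=len(depths),
        arrested_count=0,
        primordium_count=0,
        depths_mm=tuple(sorted(depths)),
    )


class TestCompareDistributions:
    def test_self_comparison_is_zero(self):
        c = _census(16.0, [5.0, 10.0, 20.0])
        d = compare_distributions(c, c)
        assert (d.count_diff, d.mean_depth_diff_mm, d.depth_iqr_diff_mm) == (0, 0.0, 0.0)

    def test_crown_vs_uniform_pattern(self):
        """Equal counts, but crown depths cluster shallow: the crown census
        shows a smaller nodulation interval (negative IQR difference)."""
        crown = _census(16.0, [5.0, 7.0, 8.0, 9.0, 11.0])
        uniform = _census(16.0, [10.0, 45.0, 80.0, 115.0, 150.0])
        d = compare_distributions(crown, uniform)
        assert d.count_diff == 0
        assert d.depth_iqr_diff_mm < 0
        assert d.mean_depth_diff_mm < 0

    def test_empty_vs_empty(self):
        d = compare_distributions(_census(10.0, []), _census(10.0, []))
        assert (d.count_diff, d.mean_depth_diff_mm, d.depth_iqr_diff_mm) == (0, 0.0, 0.0)

    def test_day_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_distributions(_census(10.0, []), _census(16.0, []))
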