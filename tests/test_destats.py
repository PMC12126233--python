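import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traplate import (
    DEThresholds,
    GeneGroupSummary,
    ValidationError,
    bhattacharyya_modified,
    call_de,
    log2_fold_change,
    run_de_analysis,
    ssmd,
    translational_efficiency,
)
from traplate.destats import _classify, de_results_frame

groups = st.lists(st.floats(0.0, 1e3, allow_nan=False), min_size=2, max_size=5)


def brute_ssmd(a, b):
    ma = sum(b) / len(b) - sum(a) / len(a)
    va = sum((x - sum(a) / len(a)) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - sum(b) / len(b)) ** 2 for x in b) / (len(b) - 1)
    return ma / math.sqrt(va + vb)


def brute_bc(a, b, sign_source):
    mean = lambda xs: sum(xs) / len(xs)
    var = lambda xs: max(sum((x - mean(xs)) ** 2 for x in xs) / (len(xs) - 1), 1e-8)
    sa, sb = var(a), var(b)
    db = 0.25 * math.log(0.25 * (sa / sb + sb / sa + 2)) + 0.25 * (mean(a) - mean(b)) ** 2 / (
        sa + sb
    )
    if sign_source == 0:
        return 0.0
    return math.copysign(1 - math.exp(-db), sign_source)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "control, condition, pc, expected",
        [
            ((2, 2, 2), (8, 8, 8), 0.0, 2.0),
            ((3, 1, 2), (3, 1, 2), 0.0, 0.0),
            ((1, 2, 3), (2, 4, 6), 0.0, 1.0),
        ],
    )
    def test_known_values(self, control, condition, pc, expected):
        assert log2_fold_change(control, condition, pc) == pytest.approx(expected, abs=1e-12)

    def test_zero_median_zero_pseudocount_is_an_error(self):
        with pytest.raises(ValidationError):
            log2_fold_change((0, 0, 0), (1, 1, 1), 0.0)

    def test_even_length_uses_midpoint_median(self):
        assert log2_fold_change((1, 3), (4, 12), 0.0) == pytest.approx(2.0)


class TestSSMD:
    def test_identical_groups_are_zero(self):
        assert ssmd((1, 2, 3), (1, 2, 3)) == 0.0

    def test_textbook_value(self):
        assert ssmd((1, 2, 3), (4, 5, 6)) == pytest.approx(3 / math.sqrt(2), abs=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            assert ssmd(a, b) == pytest.approx(-ssmd(b, a), abs=1e-12)

    def test_degenerate_variances_use_sentinel(self):
        assert ssmd((1, 1), (2, 2)) == 1e9
        assert ssmd((2, 2), (1, 1)) == -1e9
        assert ssmd((1, 1), (1, 1)) == 0.0

    def test_invariant_under_shift_and_positive_scale(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        base = ssmd(a, b)
        assert ssmd([x + 7 for x in a], [x + 7 for x in b]) == pytest.approx(base, abs=1e-12)
        assert ssmd([3 * x for x in a], [3 * x for x in b]) == pytest.approx(base, abs=1e-12)

    def test_short_group_is_an_error(self):
        with pytest.raises(ValidationError):
            ssmd((1,), (2, 3))


class TestBhattacharyyaModified:
    def test_identical_distributions_give_zero(self):
        assert bhattacharyya_modified((1, 2, 3), (1, 2, 3), sign_source=1.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_far_separated_gaussians(self):
        # mu 0 vs 10, sigma 1 each: D_B = 12.5, 1 - exp(-12.5) ~ 0.9999963
        a = (-1.0, 0.0, 1.0)  # mean 0, var 1
        b = (9.0, 10.0, 11.0)  # mean 10, var 1
        got = bhattacharyya_modified(a, b, sign_source=1.0)
        assert got == pytest.approx(1 - math.exp(-12.5), abs=1e-9)

    def test_zero_sign_source_returns_zero(self):
        assert bhattacharyya_modified((1, 2), (5, 6), sign_source=0.0) == 0.0

    @given(groups, groups, st.floats(-5, 5, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_bounded_and_sign_follows_source(self, a, b, sign_source):
        got = bhattacharyya_modified(a, b, sign_source)
        assert -1.0 <= got <= 1.0
        if sign_source > 0:
            assert got >= 0
        elif sign_source < 0:
            assert got <= 0

    def test_magnitude_invariant_under_common_affine_rescaling(self):
        a, b = [1.0, 2.0, 4.0], [5.0, 6.0, 9.0]
        base = bhattacharyya_modified(a, b, 1.0)
        scaled = bhattacharyya_modified([2 * x + 3 for x in a], [2 * x + 3 for x in b], 1.0)
        assert abs(scaled) == pytest.approx(abs(base), abs=1e-9)


class TestTranslationalEfficiency:
    def test_equal_medians_give_unity(self):
        assert translational_efficiency((2, 3, 4), (4, 3, 2), 0.0) == 1.0

    def test_exact_ratio(self):
        assert translational_efficiency((10, 10, 10), (2, 2, 2), 0.0) == 5.0

    def test_te_ratio_consistent_with_separate_fold_changes(self):
        rng = np.random.default_rng(8)
        ip_c = rng.gamma(5, 10, 3)
        ip_t = rng.gamma(5, 10, 3)
        in_c = rng.gamma(5, 10, 3)
        in_t = rng.gamma(5, 10, 3)
        te_ratio = translational_efficiency(ip_t, in_t, 0.0) / translational_efficiency(
            ip_c, in_c, 0.0
        )
        implied = 2.0 ** (
            log2_fold_change(ip_c, ip_t, 0.0) - log2_fold_change(in_c, in_t, 0.0)
        )
        assert te_ratio == pytest.approx(implied, rel=1e-12)

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ValidationError):
            translational_efficiency((1, 1), (0, 0), 0.0)


def rule_oracle(ssmd_v, bc_v, log2fc, th: DEThresholds):
    fc = 2.0 ** log2fc
    if log2fc > 0 and ssmd_v >= th.ssmd_min and bc_v >= th.bc_min and fc >= th.fc_min:
        return "increased"
    if log2fc < 0 and ssmd_v <= -th.ssmd_min and bc_v <= -th.bc_min and fc <= 1 / th.fc_min:
        return "decreased"
    return "unchanged"


class TestCallDE:
    def test_threshold_grid_matches_rule_oracle(self):
        th = DEThresholds()
        eps = 1e-9
        ssmd_grid = [-1.2, -0.9 - eps, -0.9, -0.9 + eps, -0.5, 0.0, 0.5, 0.9 - eps, 0.9, 1.2]
        bc_grid = [-0.7, -0.5 - eps, -0.5, -0.5 + eps, 0.0, 0.5 - eps, 0.5, 0.7]
        lfc_grid = [
            -1.0,
            -math.log2(1.33) - eps,
            -math.log2(1.33),
            -math.log2(1.33) + eps,
            0.0,
            math.log2(1.32 / 1.0) / 1.0,
            math.log2(1.33) - eps,
            math.log2(1.33),
            1.0,
        ]
        for s in ssmd_grid:
            for bc in bc_grid:
                for lfc in lfc_grid:
                    assert _classify(lfc, s, bc, th) == rule_oracle(s, bc, lfc, th), (
                        s,
                        bc,
                        lfc,
                    )

    def test_fc_just_below_threshold_is_unchanged(self):
        th = DEThresholds()
        assert _classify(math.log2(1.32), 1.2, 0.6, th) == "unchanged"
        assert _classify(math.log2(1.5), 1.2, 0.6, th) == "increased"

    def test_call_de_consistent_with_component_functions(self):
        rng = np.random.default_rng(1)
        th = DEThresholds()
        for _ in range(50):
            vals_c = tuple(rng.gamma(3, 10, 3))
            vals_t = tuple(rng.gamma(3, 10, 3))
            ranks_c = tuple(rng.uniform(0, 100, 3))
            ranks_t = tuple(rng.uniform(0, 100, 3))
            summary = GeneGroupSummary("g", vals_c, vals_t, ranks_c, ranks_t)
            res = call_de(summary, th, pseudocount=0.01)
            lfc = log2_fold_change(vals_c, vals_t, 0.01)
            assert res.log2fc == pytest.approx(lfc, abs=1e-12)
            assert res.ssmd == pytest.approx(ssmd(ranks_c, ranks_t), abs=1e-12)
            assert res.bc_mod == pytest.approx(
                bhattacharyya_modified(vals_c, vals_t, lfc), abs=1e-12
            )
            assert res.call == rule_oracle(res.ssmd, res.bc_mod, res.log2fc, th)

    def test_label_swap_negates_statistics_and_swaps_calls(self):
        rng = np.random.default_rng(6)
        th = DEThresholds()
        for _ in range(30):
            vals_c = tuple(rng.gamma(3, 10, 3))
            vals_t = tuple(3 * rng.gamma(3, 10, 3))
            ranks_c = tuple(rng.uniform(0, 50, 3))
            ranks_t = tuple(rng.uniform(50, 100, 3))
            fwd = call_de(GeneGroupSummary("g", vals_c, vals_t, ranks_c, ranks_t), th)
            rev = call_de(GeneGroupSummary("g", vals_t, vals_c, ranks_t, ranks_c), th)
            assert rev.log2fc == pytest.approx(-fwd.log2fc, abs=1e-12)
            assert rev.ssmd == pytest.approx(-fwd.ssmd, abs=1e-12)
            assert rev.bc_mod == pytest.approx(-fwd.bc_mod, abs=1e-12)
            swap = {"increased": "decreased", "decreased": "increased", "unchanged": "unchanged"}
            assert rev.call == swap[fwd.call]


class TestRunDEAnalysis:
    def test_null_dataset_yields_no_calls(self):
        from traplate import GeneratorConfig, generate_translatome_dataset
        from traplate.simulate import null_config

        cfg = null_config(GeneratorConfig(n_genes=2000, seed=5))
        matrix, sheet, _ = generate_translatome_dataset(cfg)
        results = run_de_analysis(matrix, sheet)
        called = [r for r in results if r.call != "unchanged"]
        assert len(called) / len(results) <= 0.01

    def test_planted_effects_recovered(self, small_dataset):
        from traplate import score_recovery

        _, matrix, sheet, truth = small_dataset
        results = run_de_analysis(matrix, sheet)
        sens, spec, sign = score_recovery(results, truth)
        assert sens >= 0.9
        assert spec >= 0.99
        assert sign == 1.0

    def test_vectorized_path_matches_per_gene_scalar_path(self, small_dataset):
        """The production (vectorized) analysis must equal gene-by-gene calls."""
        from traplate import (
            FilterThresholds,
            define_gene_universes,
            percentile_rank,
            quantile_normalize,
        )

        _, matrix, sheet, _ = small_dataset
        th = DEThresholds()
        results = run_de_analysis(matrix, sheet, thresholds=th)
        frame = de_results_frame(results)

        transcriptome, translatome = define_gene_universes(matrix, sheet, FilterThresholds())
        ip = sheet.samples_for(fraction="IP")
        ctrl = sheet.samples_for(fraction="IP", group="control")
        cond = sheet.samples_for(fraction="IP", group="condition")
        norm = quantile_normalize(matrix.subset_samples(ip), transcriptome)
        analysis = norm.subset_genes(translatome)
        ranks = percentile_rank(analysis)
        rng = np.random.default_rng(0)
        for g in rng.choice(analysis.gene_ids, size=200, replace=False):
            summary = GeneGroupSummary(
                g,
                tuple(analysis.data.loc[g, ctrl]),
                tuple(analysis.data.loc[g, cond]),
                tuple(ranks.data.loc[g, ctrl]),
                tuple(ranks.data.loc[g, cond]),
            )
            expected = call_de(summary, th, pseudocount=0.01)
            assert frame.loc[g, "log2fc"] == pytest.approx(expected.log2fc, abs=1e-10)
            assert frame.loc[g, "ssmd"] == pytest.approx(expected.ssmd, abs=1e-10)
            assert frame.loc[g, "bc_mod"] == pytest.approx(expected.bc_mod, abs=1e-10)
            assert frame.loc[g, "call"] == expected.call

    def test_missing_group_is_an_error(self, small_dataset):
        from traplate import SampleSheet

        _, matrix, sheet, _ = small_dataset
        ctrl_only = sheet.records[sheet.records["group"] == "control"]
        sub = SampleSheet(ctrl_only)
        with pytest.raises(ValidationError):
            run_de_analysis(matrix.subset_samples(sub.sample_ids), sub)
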