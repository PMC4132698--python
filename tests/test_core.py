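"""The entropy score: deviations, probabilities, score, Weibull background."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from arhseq.core import (
    ArhParams,
    DegenerateFitError,
    DeviationVector,
    ScoringError,
    WeibullBackground,
    arh_pvalue,
    arh_score,
    deviation_probabilities,
    entropy,
    fit_weibull_background,
    score_gene,
    score_genes,
    splicing_deviation,
)
from arhseq.quantify import CombiTable


def dev_from_s(s) -> DeviationVector:
    s = np.asarray(s, dtype=float)
    return DeviationVector(
        gene_id="g",
        exon_ids=[f"e{i}" for i in range(s.size)],
        logfc=s.copy(),
        baseline=0.0,
        deviations=s,
    )


class TestSplicingDeviation:
    def test_uniform_fold_change_cancels(self):
        dev = splicing_deviation([10, 10, 10, 10], [5, 5, 5, 5])
        assert dev.deviations == pytest.approx([0, 0, 0, 0])

    def test_single_dropout_exon(self):
        dev = splicing_deviation([10, 0, 10, 10], [10, 10, 10, 10])
        assert dev.baseline == pytest.approx(0.0)
        expected = math.log2(0.5 / 10.5)
        assert dev.deviations == pytest.approx([0, expected, 0, 0])
        assert expected == pytest.approx(-4.39232, abs=1e-5)

    def test_median_baseline_absorbs_expression_shift(self):
        case, control = [10.0, 2.0, 7.0, 4.0], [5.0, 9.0, 3.0, 8.0]
        base = splicing_deviation(case, control, ArhParams(alpha=0.0))
        shifted = splicing_deviation(
            [8 * c for c in case], control, ArhParams(alpha=0.0)
        )
        assert shifted.logfc == pytest.approx(base.logfc + 3.0)
        assert shifted.deviations == pytest.approx(base.deviations)

    def test_single_exon_gene_rejected(self):
        with pytest.raises(ScoringError, match="2 exons"):
            splicing_deviation([1.0], [1.0])

    def test_gene_sum_baseline_option(self):
        dev = splicing_deviation(
            [20, 20], [10, 10], ArhParams(alpha=0.0, baseline="gene_sum")
        )
        assert dev.baseline == pytest.approx(1.0)


class TestProbabilitiesAndEntropy:
    def test_zero_deviation_gives_uniform(self):
        p = deviation_probabilities(dev_from_s([0, 0, 0, 0]))
        assert p == pytest.approx([0.25] * 4)

    def test_single_deviating_exon(self):
        p = deviation_probabilities(dev_from_s([3, 0, 0, 0]))
        assert p == pytest.approx([8 / 11, 1 / 11, 1 / 11, 1 / 11])

    def test_worked_dropout_probabilities(self):
        s = math.log2(0.5 / 10.5)  # 2^|s| = 21 exactly
        p = deviation_probabilities(dev_from_s([0, s, 0, 0]))
        assert p == pytest.approx([1 / 24, 21 / 24, 1 / 24, 1 / 24], abs=1e-9)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = deviation_probabilities(dev_from_s(rng.normal(0, 2, 6)))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "p,expected",
        [([0.5, 0.5], 1.0), ([0.25] * 4, 2.0), ([8 / 11, 1 / 11, 1 / 11, 1 / 11], 1.277613)],
    )
    def test_entropy_examples(self, p, expected):
        assert entropy(p) == pytest.approx(expected, abs=1e-6)

    def test_entropy_handles_zero_probability(self):
        assert entropy([1.0, 0.0]) == 0.0

    def test_entropy_matches_naive_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.dirichlet(np.ones(int(rng.integers(2, 12))))
            naive = -sum(pi * math.log2(pi) for pi in p if pi > 0)
            assert entropy(p) == pytest.approx(naive, abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ScoringError):
            entropy([0.5, 0.4])


class TestArhScore:
    def test_zero_when_no_deviation(self):
        assert arh_score(dev_from_s([0, 0, 0, 0])) == 0.0

    def test_worked_single_exon_example(self):
        assert arh_score(dev_from_s([3, 0, 0, 0])) == pytest.approx(0.316045, abs=1e-6)

    def test_worked_dropout_example(self):
        s = math.log2(0.5 / 10.5)
        assert arh_score(dev_from_s([0, s, 0, 0])) == pytest.approx(0.599198, abs=1e-6)

    def test_zero_iff_all_abs_deviations_equal(self):
        # reciprocal two-exon deviations have uniform |s| -> score 0
        assert arh_score(dev_from_s([1.7, -1.7])) == pytest.approx(0.0, abs=1e-12)
        assert arh_score(dev_from_s([2.0, 2.0, 2.0])) == pytest.approx(0.0, abs=1e-12)
        assert arh_score(dev_from_s([2.0, 1.9, 2.0])) > 0

    def test_range_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            s = rng.normal(0, 3, int(rng.integers(2, 15)))
            score = arh_score(dev_from_s(s))
            assert 0.0 <= score < 1.0

    def test_exon_permutation_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(0, 2, 8)
        base = arh_score(dev_from_s(s))
        for _ in range(10):
            assert arh_score(dev_from_s(rng.permutation(s))) == pytest.approx(base)

    def test_monotone_in_single_exon_deviation(self):
        sweep = np.linspace(0.05, 12, 120)
        scores = [arh_score(dev_from_s([s, 0, 0, 0, 0])) for s in sweep]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_differential_expression_independence_alpha_zero(self):
        rng = np.random.default_rng(4)
        params = ArhParams(alpha=0.0)
        case = rng.uniform(1, 50, 9)
        control = rng.uniform(1, 50, 9)
        base = score_gene(case, control, params)
        for k in (0.01, 0.5, 13.0):
            scaled = score_gene(k * case, control, params)
            assert scaled.deviations == pytest.approx(base.deviations, rel=1e-9)
            assert scaled.arh == pytest.approx(base.arh, rel=1e-9)

    def test_differential_expression_effect_vanishes_with_depth(self):
        # with the default pseudocount, scaling one condition perturbs the
        # score by an amount that shrinks as counts grow
        base_vec = np.array([4.0, 1.0, 2.0, 3.0])
        drift = []
        for scale in (1.0, 100.0, 10000.0):
            case, control = scale * base_vec, scale * base_vec[::-1].copy()
            r0 = score_gene(case, control)
            r1 = score_gene(10 * case, control)
            drift.append(abs(r1.arh - r0.arh))
        assert drift[0] > drift[-1]
        assert drift[-1] < 1e-3

    def test_spiked_gene_beats_null_at_every_exon_count(self):
        # the score declines with exon number for a fixed single-exon
        # deviation, but stays far above the no-signal background
        rng = np.random.default_rng(5)
        for n in (3, 10, 25, 50):
            spiked, null = [], []
            for _ in range(100):
                noise = rng.normal(0, 0.2, n - 1)
                spiked.append(arh_score(dev_from_s(np.r_[4.0, noise])))
                null.append(arh_score(dev_from_s(rng.normal(0, 0.2, n))))
            assert np.median(spiked) > 5 * np.median(null)
            assert np.median(spiked) > 0.05


class TestScoreGenes:
    def make_tables(self):
        case = CombiTable(
            "case",
            {"a1": 10.0, "a2": 0.0, "a3": 10.0, "a4": 10.0, "b1": 5.0, "b2": 5.0},
            {"ga": ["a1", "a2", "a3", "a4"], "gb": ["b1", "b2"]},
        )
        control = CombiTable(
            "control",
            {"a1": 10.0, "a2": 10.0, "a3": 10.0, "a4": 10.0, "b1": 5.0, "b2": 5.0},
            {"ga": ["a1", "a2", "a3", "a4"], "gb": ["b1", "b2"]},
        )
        return case, control

    def test_skip_gene_scores_higher(self):
        results = {r.gene_id: r for r in score_genes(*self.make_tables())}
        assert results["ga"].arh > results["gb"].arh
        assert results["ga"].arh == pytest.approx(0.599198, abs=1e-6)

    def test_all_zero_gene_not_scored(self):
        case, control = self.make_tables()
        for t in (case, control):
            t.values.update({"z1": 0.0, "z2": 0.0})
            t.genes["gz"] = ["z1", "z2"]
        results = {r.gene_id: r for r in score_genes(case, control)}
        assert results["gz"].status == "not_scored"
        assert math.isnan(results["gz"].arh)

    def test_deterministic_order_and_values(self):
        r1 = score_genes(*self.make_tables())
        r2 = score_genes(*self.make_tables())
        assert [r.gene_id for r in r1] == [r.gene_id for r in r2] == ["ga", "gb"]
        assert [r.arh for r in r1] == [r.arh for r in r2]

    def test_gene_set_mismatch_rejected(self):
        case, control = self.make_tables()
        del control.genes["gb"]
        with pytest.raises(ScoringError):
            score_genes(case, control)


class TestWeibullBackground:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(10)
        x = 0.18 * rng.weibull(0.44, 50_000)
        bg = fit_weibull_background(x)
        assert bg.scale == pytest.approx(0.18, rel=0.02)
        assert bg.shape == pytest.approx(0.44, rel=0.02)
        assert bg.n_fit == 50_000

    def test_agrees_with_reference_mle(self):
        rng = np.random.default_rng(11)
        x = 0.7 * rng.weibull(1.3, 2000)
        bg = fit_weibull_background(x)
        shape_ref, _, scale_ref = sps.weibull_min.fit(x, floc=0)
        assert bg.shape == pytest.approx(shape_ref, rel=1e-3)
        assert bg.scale == pytest.approx(scale_ref, rel=1e-3)

    def test_exponential_special_case(self):
        rng = np.random.default_rng(12)
        bg = fit_weibull_background(rng.exponential(1.0, 50_000))
        assert bg.shape == pytest.approx(1.0, rel=0.02)
        assert bg.scale == pytest.approx(1.0, rel=0.02)

    def test_standard_errors_shrink_with_n(self):
        rng = np.random.default_rng(13)
        small = fit_weibull_background(0.18 * rng.weibull(0.44, 1000))
        large = fit_weibull_background(0.18 * rng.weibull(0.44, 30_000))
        assert large.se_scale < small.se_scale
        assert large.se_shape < small.se_shape

    def test_zeros_dropped_and_reported(self):
        rng = np.random.default_rng(14)
        x = np.r_[np.zeros(50), rng.weibull(0.5, 500)]
        bg = fit_weibull_background(x)
        assert bg.n_fit == 500
        assert bg.n_dropped_zero == 50

    def test_too_few_scores_advises_pooling(self):
        with pytest.raises(ScoringError, match="pool"):
            fit_weibull_background(np.full(50, 0.3))

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_weibull_background(np.full(500, 0.3))

    def test_serialization_round_trip(self, tmp_path):
        bg = WeibullBackground(0.18, 0.44, 2.5e-4, 2.0e-4, 12345, 7)
        path = tmp_path / "bg.txt"
        bg.to_file(path)
        back = WeibullBackground.from_file(path)
        assert back == bg


class TestPvalues:
    bg = WeibullBackground(scale=0.18, shape=0.44, se_scale=0, se_shape=0, n_fit=1000)

    def test_zero_score_gives_one(self):
        assert arh_pvalue(0.0, self.bg) == 1.0

    def test_score_at_scale_gives_inverse_e(self):
        assert arh_pvalue(0.18, self.bg) == pytest.approx(math.exp(-1))

    def test_printed_gate_corresponds_to_score_half(self):
        # P < 0.2 under the reported background ties to a score near 0.53
        assert arh_pvalue(0.53, self.bg) == pytest.approx(0.2002, abs=2e-4)

    def test_survival_decreasing_from_one(self):
        grid = np.linspace(0, 1, 50)
        sv = self.bg.survival(grid)
        assert sv[0] == 1.0
        assert np.all(np.diff(sv) < 0)

    def test_negative_score_rejected(self):
        with pytest.raises(ScoringError):
            arh_pvalue(-0.1, self.bg)
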