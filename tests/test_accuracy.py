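"""Accuracy statistics: confusion counts, CIs, paired comparison, power."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from nasodx.accuracy import (ConfusionCounts, PowerSpec, achieved_power,
                             confusion_one_vs_rest, evaluate_methods,
                             paired_method_comparison, required_total_n,
                             sens_spec_ci)
from nasodx.errors import ConfigError, ValidationError

AR = frozenset({"AR"})
DNS = frozenset({"DNS"})
NONE = frozenset()


class TestConfusion:
    def test_direct_count(self):
        c = confusion_one_vs_rest([AR, AR, NONE], [AR, NONE, NONE], "AR")
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 1)

    def test_perfect_agreement(self):
        gold = [AR, DNS, NONE, frozenset({"AR", "DNS"})]
        c = confusion_one_vs_rest(gold, gold, "AR")
        assert c.fn == c.fp == 0

    def test_controls_positive_means_empty_set(self):
        c = confusion_one_vs_rest([NONE, AR], [NONE, NONE], "Controls")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 0)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            confusion_one_vs_rest([AR], [AR, NONE], "AR")

    def test_margins_partition_the_sample(self):
        rng = np.random.default_rng(7)
        labels = ["AR", "CRSwNP", "DNS"]
        pred = [frozenset(l for l in labels if rng.random() < 0.4)
                for _ in range(50)]
        gold = [frozenset(l for l in labels if rng.random() < 0.4)
                for _ in range(50)]
        for cond in labels + ["Controls"]:
            c = confusion_one_vs_rest(pred, gold, cond)
            assert c.tp + c.fn + c.tn + c.fp == 50


class TestSensSpecCI:
    def test_point_estimates(self):
        r = sens_spec_ci(ConfusionCounts(tp=7, fn=3, tn=8, fp=2))
        assert r.sensitivity == pytest.approx(0.70)
        assert r.specificity == pytest.approx(0.80)

    def test_wilson_interval_closed_form(self):
        # frozen from the Wilson score interval for 10 successes of 14
        r = sens_spec_ci(ConfusionCounts(tp=10, fn=4, tn=0, fp=1))
        assert r.sensitivity == pytest.approx(10 / 14, abs=1e-9)
        assert r.ci_sens[0] == pytest.approx(0.45351, abs=1e-4)
        assert r.ci_sens[1] == pytest.approx(0.88279, abs=1e-4)

    def test_zero_sensitivity_boundary(self):
        r = sens_spec_ci(ConfusionCounts(tp=0, fn=5, tn=1, fp=0))
        assert r.sensitivity == 0.0
        assert r.ci_sens[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_stratum_flagged_undefined_not_raised(self):
        r = sens_spec_ci(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert r.sensitivity is None and r.ci_sens is None
        assert r.specificity == pytest.approx(0.75)

    def test_ci_brackets_point_estimate(self):
        for tp, fn in [(1, 9), (5, 5), (13, 1)]:
            for method in ("wilson", "clopper-pearson"):
                r = sens_spec_ci(ConfusionCounts(tp, fn, 1, 1), method=method)
                lo, hi = r.ci_sens
                assert 0 <= lo <= r.sensitivity <= hi <= 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            sens_spec_ci(ConfusionCounts(1, 1, 1, 1), method="wald")

    def test_wilson_coverage_simulation(self):
        """Wilson 95% interval keeps >=93% coverage at n=14, p=0.7."""
        rng = np.random.default_rng(20240901)
        n, p, reps = 14, 0.7, 10_000
        successes = rng.binomial(n, p, size=reps)
        covered = 0
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
        covered = np.mean((lo <= p) & (p <= hi))
        assert covered >= 0.93


def conditional_loglik(beta: float, n10: int, n01: int) -> float:
    """1:1 matched-pair conditional log-likelihood (discordant pairs)."""
    return n10 * beta - (n10 + n01) * math.log1p(math.exp(beta))


class TestPairedComparison:
    def _direct(self, n10, n01):
        pred_a, pred_b, gold = [], [], []
        for _ in range(n10):  # A correct, B wrong on a gold-positive
            pred_a.append(AR)
            pred_b.append(NONE)
            gold.append(AR)
        for _ in range(n01):
            pred_a.append(NONE)
            pred_b.append(AR)
            gold.append(AR)
        return paired_method_comparison(pred_a, pred_b, gold, "AR",
                                        "sensitivity")

    def test_closed_form_example(self):
        c = self._direct(10, 5)
        assert c.or_estimate == pytest.approx(2.0)
        assert c.log_odds == pytest.approx(0.6931, abs=1e-4)
        assert c.se == pytest.approx(0.5477, abs=1e-4)
        assert c.p_value == pytest.approx(0.2057, abs=1e-3)

    def test_symmetric_discordance(self):
        c = self._direct(7, 7)
        assert c.log_odds == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_identical_predictions_flagged(self):
        pred = [AR, NONE, AR]
        gold = [AR, AR, AR]
        c = paired_method_comparison(pred, pred, gold, "AR", "sensitivity")
        assert c.flag == "identical"
        assert c.p_value is None

    def test_one_sided_discordance_flagged_degenerate(self):
        c = self._direct(4, 0)
        assert c.flag == "degenerate"

    def test_empty_stratum(self):
        c = paired_method_comparison([AR], [AR], [AR], "AR", "specificity")
        assert c.flag == "empty_stratum"

    def test_swap_symmetry(self):
        a = self._direct(9, 3)
        b = self._direct(3, 9)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.log_odds == pytest.approx(-b.log_odds)

    def test_specificity_stratum_counts_correct_negatives(self):
        pred_a = [NONE, AR, NONE]
        pred_b = [AR, AR, NONE]
        gold = [NONE, NONE, NONE]
        c = paired_method_comparison(pred_a, pred_b, gold, "AR",
                                     "specificity")
        assert (c.n11, c.n10, c.n01, c.n00) == (1, 1, 0, 1)

    def test_closed_form_matches_numeric_conditional_ml(self):
        """ln(n10/n01) maximizes the conditional likelihood (100 tables)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n10 = int(rng.integers(1, 40))
            n01 = int(rng.integers(1, 40))
            res = minimize_scalar(
                lambda b: -conditional_loglik(b, n10, n01),
                bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10})
            assert math.log(n10 / n01) == pytest.approx(res.x, abs=1e-6)
            c = self._direct(n10, n01)
            assert c.log_odds == pytest.approx(res.x, abs=1e-6)


class TestPower:
    def test_published_sample_size(self):
        assert required_total_n(PowerSpec(effect_size=0.3)) == 175

    def test_published_achieved_power(self):
        p = achieved_power(PowerSpec(effect_size=0.3, n_total=71))
        assert round(p, 2) == 0.43

    def test_larger_effect_needs_quarter_the_sample(self):
        assert required_total_n(PowerSpec(effect_size=0.6)) == 44

    def test_null_effect_power_is_half_alpha(self):
        p = achieved_power(PowerSpec(effect_size=0.0, n_total=500))
        assert p == pytest.approx(0.025, abs=1e-6)

    def test_inverse_consistency(self):
        for h in (0.2, 0.3, 0.5, 0.8):
            spec = PowerSpec(effect_size=h)
            n = required_total_n(spec)
            achieved = achieved_power(PowerSpec(effect_size=h, n_total=n))
            assert achieved >= spec.power_target - 1e-9

    def test_power_monotone_in_n_and_effect(self):
        ns = [20, 50, 100, 200]
        powers = [achieved_power(PowerSpec(effect_size=0.3, n_total=n))
                  for n in ns]
        assert powers == sorted(powers)
        hs = [0.1, 0.3, 0.5, 0.7]
        powers = [achieved_power(PowerSpec(effect_size=h, n_total=100))
                  for h in hs]
        assert powers == sorted(powers)

    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            PowerSpec(alpha=0)
        with pytest.raises(ConfigError):
            achieved_power(PowerSpec(n_total=None))


class TestEvaluateMethods:
    def test_perfect_classifier_all_ones(self):
        gold = [AR, DNS, NONE, frozenset({"AR", "DNS"}), frozenset({"CRSwNP"})]
        report = evaluate_methods(gold, list(gold), gold)
        for condition, acc in report["accuracy"].items():
            for method in acc.values():
                if method["n_pos"]:
                    assert method["sensitivity"] == 1.0
                if method["n_neg"]:
                    assert method["specificity"] == 1.0
        for comp in report["comparison"].values():
            for stratum in comp.values():
                assert stratum["flag"] in ("identical", "empty_stratum")

    def test_power_block_at_study_size(self):
        gold = [AR] * 36 + [NONE] * 35
        report = evaluate_methods(gold, gold, gold)
        assert report["power"]["n_required"] == 175
        assert round(report["power"]["achieved_power"], 2) == 0.43
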