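"""Diagnostic-accuracy statistics.

One-vs-rest sensitivity and specificity with confidence intervals,
paired comparison of two diagnostic methods by conditional logistic
regression on 1:1 matched observations, and the power / sample-size
calculations for a two-group comparison of proportions with a
Cohen-type effect size h.

Each condition (AR, CRSsNP, CRSwNP, DNS) is scored one-vs-rest against
the gold-standard diagnosis; "Controls" is its own one-vs-rest label
whose gold-positives are the participants with an *empty* gold set.

The paired comparison conditions on the matched pair: within the gold
stratum (positives for sensitivity, negatives for specificity) each
participant contributes (method A correct?, method B correct?).  For a
1:1 design the conditional maximum-likelihood estimate depends on the
discordant pairs only and has the closed form

    log OR = ln(n10 / n01),   SE = sqrt(1/n10 + 1/n01),

with a two-sided Wald p-value.  Concordant pairs carry no information
about the method effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet, Optional, Sequence, Tuple

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigError, ValidationError
from .rules import CONDITIONS

__all__ = [
    "ConfusionCounts",
    "AccuracyResult",
    "PairedComparison",
    "PowerSpec",
    "confusion_one_vs_rest",
    "sens_spec_ci",
    "paired_method_comparison",
    "required_total_n",
    "achieved_power",
    "evaluate_methods",
    "EVALUATION_LABELS",
]

#: One-vs-rest labels in report order; Controls = empty gold set.
EVALUATION_LABELS = CONDITIONS + ("Controls",)

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts for one condition, one method."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def _is_positive(ds: FrozenSet[str], condition: str) -> bool:
    if condition == "Controls":
        return len(ds) == 0
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    return condition in ds


def confusion_one_vs_rest(predicted: Sequence[FrozenSet[str]],
                          gold: Sequence[FrozenSet[str]],
                          condition: str) -> ConfusionCounts:
    """Count TP/FN/TN/FP for one condition over aligned diagnosis lists."""
    if len(predicted) != len(gold):
        raise ValidationError(
            f"predicted ({len(predicted)}) and gold ({len(gold)}) lists "
            "must be aligned and equally long"
        )
    tp = fn = tn = fp = 0
    for p, g in zip(predicted, gold):
        pp, gp = _is_positive(p, condition), _is_positive(g, condition)
        if gp:
            tp += pp
            fn += not pp
        else:
            fp += pp
            tn += not pp
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class AccuracyResult:
    """Sensitivity/specificity with CIs; None where the stratum is empty."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ci_sens: Optional[Tuple[float, float]]
    ci_spec: Optional[Tuple[float, float]]
    n_pos: int
    n_neg: int
    ci_method: str = "wilson"
    level: float = 0.95


def sens_spec_ci(counts: ConfusionCounts, level: float = 0.95,
                 method: str = "wilson") -> AccuracyResult:
    """Point estimates and CIs for sensitivity and specificity.

    ``method`` is "wilson" (score interval, default) or
    "clopper-pearson" (exact).  A zero-denominator side is returned as
    None (flagged undefined) rather than raising.
    """
    if method not in _CI_METHODS:
        raise ConfigError(
            f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}"
        )
    sm_method = _CI_METHODS[method]

    def one(successes: int, n: int):
        if n == 0:
            return None, None
        lo, hi = proportion_confint(successes, n, alpha=1 - level,
                                    method=sm_method)
        return successes / n, (float(lo), float(hi))

    sens, ci_sens = one(counts.tp, counts.n_pos)
    spec, ci_spec = one(counts.tn, counts.n_neg)
    return AccuracyResult(
        sensitivity=sens, specificity=spec,
        ci_sens=ci_sens, ci_spec=ci_spec,
        n_pos=counts.n_pos, n_neg=counts.n_neg,
        ci_method=method, level=level,
    )


@dataclass(frozen=True)
class PairedComparison:
    """Conditional-logistic comparison of two methods on matched pairs.

    ``flag`` is "ok", "identical" (no discordant pairs — the methods
    agreed on every participant in the stratum), "degenerate" (all
    discordance in one direction; the MLE is infinite) or
    "empty_stratum".
    """

    n11: int
    n10: int
    n01: int
    n00: int
    log_odds: Optional[float] = None
    or_estimate: Optional[float] = None
    se: Optional[float] = None
    p_value: Optional[float] = None
    flag: str = "ok"


def paired_method_comparison(pred_a: Sequence[FrozenSet[str]],
                             pred_b: Sequence[FrozenSet[str]],
                             gold: Sequence[FrozenSet[str]],
                             condition: str,
                             stratum: str = "sensitivity") -> PairedComparison:
    """Compare two methods within one gold stratum for one condition.

    ``stratum`` selects gold-positives ("sensitivity") or gold-negatives
    ("specificity"); within it a participant is a hit for a method when
    that method classifies them correctly (positive in the sensitivity
    stratum, negative in the specificity stratum).
    """
    if not (len(pred_a) == len(pred_b) == len(gold)):
        raise ValidationError("pred_a, pred_b and gold must be aligned")
    if stratum not in ("sensitivity", "specificity"):
        raise ConfigError("stratum must be 'sensitivity' or 'specificity'")
    want_positive = stratum == "sensitivity"

    n11 = n10 = n01 = n00 = 0
    for a, b, g in zip(pred_a, pred_b, gold):
        if _is_positive(g, condition) != want_positive:
            continue
        hit_a = _is_positive(a, condition) == want_positive
        hit_b = _is_positive(b, condition) == want_positive
        if hit_a and hit_b:
            n11 += 1
        elif hit_a:
            n10 += 1
        elif hit_b:
            n01 += 1
        else:
            n00 += 1

    if n11 + n10 + n01 + n00 == 0:
        return PairedComparison(0, 0, 0, 0, flag="empty_stratum")
    if n10 == 0 and n01 == 0:
        return PairedComparison(n11, n10, n01, n00, flag="identical")
    if n10 == 0 or n01 == 0:
        return PairedComparison(n11, n10, n01, n00, flag="degenerate")

    log_odds = math.log(n10 / n01)
    se = math.sqrt(1.0 / n10 + 1.0 / n01)
    z = log_odds / se
    p = 2.0 * norm.sf(abs(z))
    return PairedComparison(
        n11=n11, n10=n10, n01=n01, n00=n00,
        log_odds=log_odds, or_estimate=n10 / n01, se=se, p_value=p,
    )


@dataclass(frozen=True)
class PowerSpec:
    """Design for the two-group proportion comparison power model."""

    effect_size: float = 0.3
    alpha: float = 0.05
    power_target: float = 0.80
    n_total: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ConfigError("power_target must lie in (0, 1)")
        if not self.effect_size >= 0:
            raise ConfigError("effect_size must be non-negative")


def required_total_n(spec: PowerSpec = PowerSpec()) -> int:
    """Total sample size for the target power at effect size h.

    Per-group n = ((z_{1−α/2} + z_{power}) / h)²; the total is the
    ceiling of twice that.
    """
    if spec.effect_size <= 0:
        raise ConfigError("effect_size must be strictly positive here")
    z_alpha = norm.ppf(1 - spec.alpha / 2)
    z_power = norm.ppf(spec.power_target)
    per_group = ((z_alpha + z_power) / spec.effect_size) ** 2
    return math.ceil(2 * per_group - 1e-12)


def achieved_power(spec: PowerSpec) -> float:
    """Power achieved at ``spec.n_total`` participants (two equal groups).

    power = Φ(h·√(n/2) − z_{1−α/2}), Φ the standard normal CDF.
    """
    if spec.n_total is None or spec.n_total < 2:
        raise ConfigError("n_total must be at least 2")
    z_alpha = norm.ppf(1 - spec.alpha / 2)
    return float(norm.cdf(
        spec.effect_size * math.sqrt(spec.n_total / 2.0) - z_alpha
    ))


def evaluate_methods(pred_a: Sequence[FrozenSet[str]],
                     pred_b: Sequence[FrozenSet[str]],
                     gold: Sequence[FrozenSet[str]],
                     level: float = 0.95,
                     ci_method: str = "wilson",
                     effect_size: float = 0.3,
                     alpha: float = 0.05,
                     power_target: float = 0.80,
                     method_names: Tuple[str, str] = ("method_a", "method_b"),
                     ) -> dict:
    """Full evaluation report comparing two diagnosis methods to gold.

    Returns a nested dict: per condition × method accuracy (sens/spec +
    CIs), per condition × stratum paired comparison, and a power block
    at the observed sample size.
    """
    report = {"n_participants": len(gold), "accuracy": {}, "comparison": {}}
    name_a, name_b = method_names
    for condition in EVALUATION_LABELS:
        acc = {}
        for name, pred in ((name_a, pred_a), (name_b, pred_b)):
            counts = confusion_one_vs_rest(pred, gold, condition)
            r = sens_spec_ci(counts, level=level, method=ci_method)
            acc[name] = {
                "sensitivity": r.sensitivity, "ci_sens": r.ci_sens,
                "specificity": r.specificity, "ci_spec": r.ci_spec,
                "n_pos": r.n_pos, "n_neg": r.n_neg,
            }
        report["accuracy"][condition] = acc
        comp = {}
        for stratum in ("sensitivity", "specificity"):
            c = paired_method_comparison(pred_a, pred_b, gold, condition,
                                         stratum)
            comp[stratum] = {
                "n11": c.n11, "n10": c.n10, "n01": c.n01, "n00": c.n00,
                "log_odds": c.log_odds, "or": c.or_estimate,
                "se": c.se, "p_value": c.p_value, "flag": c.flag,
            }
        report["comparison"][condition] = comp
    n = len(gold)
    power_block = {
        "effect_size": effect_size, "alpha": alpha,
        "power_target": power_target, "n_total": n,
        "n_required": required_total_n(
            PowerSpec(effect_size=effect_size, alpha=alpha,
                      power_target=power_target)),
    }
    power_block["achieved_power"] = (
        achieved_power(PowerSpec(effect_size=effect_size, alpha=alpha,
                                 power_target=power_target, n_total=n))
        if n >= 2 else None
    )
    report["power"] = power_block
    report["ci_method"] = ci_method
    report["level"] = level
    return report
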