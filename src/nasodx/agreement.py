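"""Krippendorff's alpha for multi-rater reliability.

Alpha is a chance-corrected agreement coefficient that handles any
number of raters, missing ratings and ordered category metrics, making
it the natural choice for endoscopic grading panels where raters may
mark a structure "not visualized".

Computed from the coincidence-matrix formulation:

    alpha = 1 − D_o / D_e
    D_o   = Σ_{c,k} o_ck · δ²_ck / n
    D_e   = Σ_{c,k} n_c n_k · δ²_ck / (n (n − 1))

where o_ck counts value pairs within units (each unit with m ratings
contributes each ordered pair with weight 1/(m−1)), n_c are its
marginals and δ² is the metric difference function:

* nominal  — δ² = 0 if c = k else 1;
* ordinal  — δ²_ck = (Σ_{g=c..k} n_g − (n_c + n_k)/2)², the squared
  cumulative margin between the two ranks;
* interval — δ² = (x_c − x_k)².

Units with fewer than two non-missing ratings carry no pairable
information and are excluded.  Confidence intervals come from a
percentile bootstrap over units (participants are the sampling units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ValidationError
from .grading import MISSING

__all__ = [
    "AgreementResult",
    "krippendorff_alpha",
    "bootstrap_alpha_ci",
    "classify_agreement",
    "agreement_analysis",
]

METRICS = ("nominal", "ordinal", "interval")


def _clean_units(ratings) -> list:
    """Normalize a units × raters grid to lists of non-missing values."""
    units = []
    for row in ratings:
        vals = []
        for v in row:
            if v is None or v is MISSING:
                continue
            if isinstance(v, float) and np.isnan(v):
                continue
            vals.append(v)
        units.append(vals)
    return units


def _coincidence(units: list, categories: list) -> np.ndarray:
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    o = np.zeros((k, k))
    for vals in units:
        m = len(vals)
        if m < 2:
            continue
        w = 1.0 / (m - 1)
        for i in range(m):
            for j in range(m):
                if i != j:
                    o[index[vals[i]], index[vals[j]]] += w
    return o


def _delta_sq(categories: list, marginals: np.ndarray, metric: str) -> np.ndarray:
    k = len(categories)
    if metric == "nominal":
        return 1.0 - np.eye(k)
    values = np.asarray([float(c) for c in categories])
    if metric == "interval":
        return (values[:, None] - values[None, :]) ** 2
    if metric == "ordinal":
        d = np.zeros((k, k))
        for c in range(k):
            for g in range(c + 1, k):
                cum = marginals[c:g + 1].sum() - (marginals[c] + marginals[g]) / 2.0
                d[c, g] = d[g, c] = cum ** 2
        return d
    raise ConfigError(f"unknown metric {metric!r}; choose from {METRICS}")


def krippendorff_alpha(ratings, metric: str = "nominal") -> float:
    """Krippendorff's alpha for a units × raters grid.

    ``ratings`` is any 2-D iterable; missing cells may be None, NaN or
    the package MISSING marker.  For ordinal and interval metrics the
    values must be numeric.  Degenerate data in which every pairable
    value is identical has zero expected disagreement; alpha is defined
    as 1.0 there.
    """
    units = _clean_units(ratings)
    pairable = [u for u in units if len(u) >= 2]
    if len(ratings) and max((len(r) for r in ratings), default=0) < 2:
        raise ValidationError("need at least 2 raters")
    if not pairable:
        raise ValidationError(
            "need at least one unit with two or more non-missing ratings"
        )
    if metric == "nominal":
        categories = sorted({v for u in pairable for v in u}, key=repr)
    else:
        categories = sorted({float(v) for u in pairable for v in u})
        pairable = [[float(v) for v in u] for u in pairable]
    o = _coincidence(pairable, categories)
    marginals = o.sum(axis=1)
    n = marginals.sum()
    delta = _delta_sq(categories, marginals, metric)
    d_obs = (o * delta).sum() / n
    d_exp = (np.outer(marginals, marginals) * delta).sum() / (n * (n - 1.0))
    if d_exp <= 0:
        return 1.0  # all pairable values identical: perfect by definition
    return float(1.0 - d_obs / d_exp)


def bootstrap_alpha_ci(ratings, metric: str = "nominal",
                       n_boot: int = 1000, level: float = 0.95,
                       seed: Optional[int] = None) -> Tuple[float, float]:
    """Percentile bootstrap CI for alpha, resampling units with replacement.

    Degenerate resamples (no pairable units, or zero expected
    disagreement with zero observed — alpha exactly 1) are retained as
    1.0 when well-defined and skipped when alpha is incomputable;
    reproducible for a fixed seed.
    """
    if n_boot < 100:
        raise ConfigError("n_boot must be at least 100")
    rows = [list(r) for r in ratings]
    rng = np.random.default_rng(seed)
    stats = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(rows), size=len(rows))
        sample = [rows[i] for i in idx]
        try:
            stats.append(krippendorff_alpha(sample, metric=metric))
        except ValidationError:
            skipped += 1
    if skipped:
        import logging
        logging.getLogger(__name__).info(
            "bootstrap: skipped %d degenerate resamples", skipped)
    if not stats:
        raise ValidationError("all bootstrap resamples were degenerate")
    lo = (1 - level) / 2 * 100
    return (float(np.percentile(stats, lo)),
            float(np.percentile(stats, 100 - lo)))


def classify_agreement(alpha: float, tol: float = 1e-12) -> str:
    """Band an alpha value: poor < 0.667 ≤ moderate < 0.800 ≤
    satisfactory < 1.000; perfect only at exactly 1 (within *tol*).

    The bands partition (−∞, 1]; the published banding lists 0.667 in
    two bands, resolved here by assigning boundary values upward.
    """
    if alpha > 1 + tol:
        raise ValidationError(f"alpha cannot exceed 1, got {alpha}")
    if alpha >= 1 - tol:
        return "perfect"
    if alpha >= 0.800:
        return "satisfactory"
    if alpha >= 0.667:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class AgreementResult:
    """Alpha with bootstrap CI and its agreement band."""

    alpha: float
    ci: Tuple[float, float]
    n_boot: int
    seed: Optional[int]
    level: str
    metric: str
    n_units: int
    n_raters: int


def agreement_analysis(ratings, metric: str = "nominal",
                       n_boot: int = 1000, ci_level: float = 0.95,
                       seed: Optional[int] = None) -> AgreementResult:
    """Alpha + bootstrap CI + band for one units × raters grid."""
    rows = [list(r) for r in ratings]
    alpha = krippendorff_alpha(rows, metric=metric)
    ci = bootstrap_alpha_ci(rows, metric=metric, n_boot=n_boot,
                            level=ci_level, seed=seed)
    return AgreementResult(
        alpha=alpha, ci=ci, n_boot=n_boot, seed=seed,
        level=classify_agreement(alpha), metric=metric,
        n_units=len(rows), n_raters=max(len(r) for r in rows),
    )
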