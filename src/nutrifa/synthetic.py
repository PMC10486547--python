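"""Seeded synthetic FA-profile cohorts with tissue-realistic composition.

Real per-animal FA tables for indigenous cattle tissues are not publicly
deposited, so every downstream stage of this package is exercised on
synthetic cohorts with the same compositional structure:

* the relative composition of each sample is drawn from a Dirichlet
  distribution over the FA simplex, parameterized by a mean composition
  (percent, summing to 100) and a single *precision* (the Dirichlet
  concentration sum): the variance of each component is
  ``p_i (1 - p_i) / (1 + precision)``, so one number controls how tightly
  a tissue's composition scatters around its mean;
* FAs with mean zero are structural zeros and stay exactly zero in every
  sample (adipose tissue contains no LC-PUFA — the generator reproduces
  that absence, not merely small values);
* the total FA content (mg/g, wet- or dry-weight basis) is log-normal,
  independent of composition.

The shipped templates place each tissue's class means inside the ranges
observed for cattle muscle, liver and adipose tissue and for pasture-grass
leaves, with dominant species 16:0 / 18:0 / 18:1n-9 in fat and a liver
rich in 18:0 and omega-3 LC-PUFA.  Precisions are calibrated so that the
simulated between-animal scatter matches the reported SEMs of the dietary
indexes (roughly 15-20% coefficients of variation), not the full
between-age, between-muscle ranges, which mix true cohort heterogeneity
with age effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import Basis, FAProfile

__all__ = [
    "TissueTemplate",
    "default_templates",
    "generate_cohort",
    "fit_precision",
    "with_component_mean",
]


@dataclass(frozen=True)
class TissueTemplate:
    """Generative parameters for one tissue's FA composition.

    ``mean_percent`` must sum to 100 within 1e-6 (it is stored re-closed
    exactly).  ``total_mean``/``total_cv`` parameterize the log-normal
    total FA content on ``total_basis``.  ``age_trend`` optionally maps
    FA labels to a per-month multiplicative log-trend applied to the mean
    composition before sampling (used only when ages are passed to
    :func:`generate_cohort`).
    """

    name: str
    mean_percent: dict[str, float]
    precision: float
    total_mean: float
    total_cv: float
    total_basis: Basis = Basis.MG_PER_G_WW
    age_trend: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError("Dirichlet precision must be > 0")
        if self.total_mean <= 0 or self.total_cv <= 0:
            raise ValueError("total FA distribution parameters must be > 0")
        if any(v < 0 for v in self.mean_percent.values()):
            raise ValueError("mean composition must be nonnegative")
        total = sum(self.mean_percent.values())
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(f"mean composition sums to {total}, not 100")
        closed = {k: 100.0 * v / total for k, v in self.mean_percent.items()}
        object.__setattr__(self, "mean_percent", closed)


def with_component_mean(template: TissueTemplate, label: str, new_mean: float) -> TissueTemplate:
    """Set one FA's mean percent, rescaling all others to keep the closure.

    Useful for injecting a known mean shift (e.g. +5 percentage points of
    16:0) while leaving the rest of the composition proportionally intact.
    """
    if label not in template.mean_percent:
        raise KeyError(f"{label!r} not in template {template.name!r}")
    if not 0 <= new_mean < 100:
        raise ValueError("new mean percent must be in [0, 100)")
    old = template.mean_percent[label]
    rest = 100.0 - old
    scale = (100.0 - new_mean) / rest
    means = {
        k: (new_mean if k == label else v * scale) for k, v in template.mean_percent.items()
    }
    return replace(template, mean_percent=means)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def generate_cohort(
    template: TissueTemplate,
    n: int,
    seed: int,
    *,
    basis: str | Basis = Basis.PERCENT,
    ages_months: list[int] | None = None,
) -> list[FAProfile]:
    """Draw ``n`` profiles from a template; fully determined by ``seed``.

    With ``basis="percent"`` each profile's values sum to exactly 100
    (Dirichlet closure).  With a mg/g basis the percent composition is
    scaled by a per-sample log-normal total.  Passing ``ages_months``
    (one per sample) activates the template's age trend, a monotone
    multiplicative tilt of the mean composition.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    basis = Basis(basis)
    rng = np.random.default_rng(seed)

    labels = list(template.mean_percent)
    means = np.array([template.mean_percent[k] for k in labels]) / 100.0
    support = means > 0  # structural zeros stay zero
    if ages_months is not None and len(ages_months) != n:
        raise ValueError("ages_months must have one entry per sample")

    comps = np.zeros((n, len(labels)))
    if ages_months is not None and template.age_trend:
        trend = np.array([template.age_trend.get(k, 0.0) for k in labels])
        for i, age in enumerate(ages_months):
            tilted = means * np.exp(trend * age)
            tilted /= tilted.sum()
            comps[i, support] = rng.dirichlet(template.precision * tilted[support])
    else:
        comps[:, support] = rng.dirichlet(template.precision * means[support], size=n)

    mu, sigma = _lognormal_params(template.total_mean, template.total_cv)
    totals = rng.lognormal(mu, sigma, size=n)

    profiles = []
    for i in range(n):
        if basis is Basis.PERCENT:
            values = dict(zip(labels, 100.0 * comps[i]))
        else:
            if basis is not template.total_basis:
                raise ValueError(
                    f"template {template.name!r} defines totals on "
                    f"{template.total_basis.value}, not {basis.value}"
                )
            values = dict(zip(labels, totals[i] * comps[i]))
        profiles.append(
            FAProfile(
                sample_id=f"{template.name}_{i:03d}",
                basis=basis,
                values=values,
                tissue=template.name,
                age_months=None if ages_months is None else int(ages_months[i]),
            )
        )
    return profiles


def fit_precision(cohort: list[FAProfile]) -> float:
    """Method-of-moments Dirichlet precision from a percent-basis cohort.

    Pools over components: for a Dirichlet with precision ``phi`` each
    component has variance ``m_i (1 - m_i) / (1 + phi)``, so
    ``phi = sum_i m_i (1 - m_i) / sum_i var_i - 1`` with sample moments.
    Structural-zero components are excluded.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two profiles to fit a precision")
    labels = sorted({k for p in cohort for k in p.values})
    mat = np.array([[p.values.get(k, 0.0) for k in labels] for p in cohort]) / 100.0
    keep = mat.any(axis=0)
    mat = mat[:, keep]
    m = mat.mean(axis=0)
    v = mat.var(axis=0, ddof=1)
    return float(np.sum(m * (1.0 - m)) / np.sum(v) - 1.0)


# -- shipped templates ------------------------------------------------------

_MUSCLE = {
    "14:0": 1.5, "15:0": 0.4, "i15:0": 0.2, "16:0": 20.0, "16:1n-7": 2.5,
    "17:0": 0.8, "ai17:0": 0.3, "18:0": 14.0, "18:1n-9": 28.0, "18:1n-7": 2.8,
    "18:2n-6": 10.3, "CLA": 0.3, "18:3n-3": 2.7, "20:3n-6": 0.7, "20:4n-6": 6.0,
    "20:4n-3": 0.6, "20:5n-3": 3.6, "22:5n-3": 4.6, "22:6n-3": 0.7,
}

_LIVER = {
    "14:0": 0.8, "15:0": 0.6, "16:0": 13.0, "17:0": 1.6, "18:0": 28.0,
    "16:1n-7": 1.5, "18:1n-9": 11.5, "18:1n-7": 3.3, "18:1n-5": 0.7,
    "18:2n-6": 8.8, "CLA": 0.2, "20:3n-6": 1.0, "20:4n-6": 8.0,
    "18:3n-3": 2.0, "20:4n-3": 1.4, "20:5n-3": 5.6, "22:5n-3": 7.5, "22:6n-3": 4.5,
}

# adipose tissue: no LC-PUFA at all (structural zeros by omission)
_ADIPOSE = {
    "12:0": 0.1, "14:0": 4.0, "15:0": 0.7, "i15:0": 0.2, "16:0": 28.0,
    "16:1n-7": 4.5, "17:0": 1.2, "ai17:0": 0.4, "18:0": 22.0,
    "18:1n-9": 33.5, "18:1n-7": 3.2, "18:1n-5": 0.4,
    "18:2n-6": 0.9, "18:3n-3": 0.7, "CLA": 0.2,
}

_PLANT_FRESH = {
    "12:0": 0.5, "14:0": 0.8, "15:0": 0.3, "16:0": 22.5, "16:1n-9": 0.6,
    "16:1n-5": 2.5, "17:0": 0.2, "18:0": 1.9, "18:1n-9": 2.2, "18:1n-7": 0.8,
    "18:2n-6": 10.0, "18:3n-3": 54.8, "20:0": 1.1, "22:0": 1.8,
}

_PLANT_WILTED = {
    "12:0": 1.2, "14:0": 2.7, "15:0": 0.7, "16:0": 34.1, "16:1n-9": 1.8,
    "16:1n-5": 1.0, "17:0": 0.7, "18:0": 5.7, "18:1n-9": 4.4, "18:1n-7": 2.4,
    "18:2n-6": 8.1, "18:3n-3": 33.6, "20:0": 1.7, "22:0": 1.9,
}


def default_templates() -> dict[str, TissueTemplate]:
    """Shipped tissue templates: muscle, liver, two adipose depots, plant leaf.

    Class-mean sanity (by construction): muscle SFA 37.2 / MUFA 33.3 /
    PUFA 29.5; liver SFA 44 / MUFA 17 / PUFA 39; adipose SFA 56.6 / MUFA
    41.6 / PUFA 1.8 with zero LC-PUFA; fresh plant leaves dominated by
    18:3n-3, 16:0 and 18:2n-6.  Muscle carries an optional age trend:
    16:1n-7 and 18:1n-9 tilt upward with age in months.
    """
    muscle_trend = {"16:1n-7": 0.004, "18:1n-9": 0.004}
    return {
        "muscle": TissueTemplate(
            "muscle", dict(_MUSCLE), precision=200.0,
            total_mean=9.0, total_cv=0.35, total_basis=Basis.MG_PER_G_WW,
            age_trend=muscle_trend,
        ),
        "liver": TissueTemplate(
            "liver", dict(_LIVER), precision=300.0,
            total_mean=16.0, total_cv=0.20, total_basis=Basis.MG_PER_G_WW,
        ),
        "subcutaneous_fat": TissueTemplate(
            "subcutaneous_fat", dict(_ADIPOSE), precision=100.0,
            total_mean=700.0, total_cv=0.10, total_basis=Basis.MG_PER_G_WW,
        ),
        "visceral_fat": TissueTemplate(
            "visceral_fat", dict(_ADIPOSE), precision=100.0,
            total_mean=750.0, total_cv=0.10, total_basis=Basis.MG_PER_G_WW,
        ),
        "plant_leaf": TissueTemplate(
            "plant_leaf", dict(_PLANT_FRESH), precision=200.0,
            total_mean=10.6, total_cv=0.12, total_basis=Basis.MG_PER_G_DW,
        ),
        "plant_leaf_wilted": TissueTemplate(
            "plant_leaf_wilted", dict(_PLANT_WILTED), precision=200.0,
            total_mean=5.3, total_cv=0.40, total_basis=Basis.MG_PER_G_DW,
        ),
    }
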