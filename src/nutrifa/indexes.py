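"""Lipid nutritional-quality indexes.

The cardiovascular-health value of a fat source is summarized by weighted
ratios of its fatty-acid classes.  With amounts taken from one profile
(the ratios are invariant to the measurement basis):

* index of atherogenicity  ``IA = (4*14:0 + 12:0 + 16:0) / UFA``
* health-promoting index   ``HPI = UFA / (4*14:0 + 12:0 + 16:0)`` (= 1/IA)
* index of thrombogenicity
  ``IT = (14:0 + 16:0 + 18:0) / (0.5*MUFA + 0.5*n6 + 3*n3 + n3/n6)``
* hypocholesterolemic/hypercholesterolemic ratio
  ``HH = (18:1n-9 + PUFA) / (12:0 + 14:0 + 16:0)``

plus the plain ratios n-6/n-3 and PUFA/SFA and, on the wet-weight content
basis, the EPA + DHA content in mg/g.  Lower IA/IT and higher HH/HPI mark
a product whose fat profile is the more favorable with respect to
atherosclerosis, thrombus formation and plasma cholesterol.

A zero denominator never produces a silent 0 or infinity: the affected
index is reported as undefined together with a machine-readable reason
code, and cohort aggregation excludes undefined values while counting them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nomenclature import ClassificationScheme, DEFAULT_SCHEME
from .profiles import Basis, FAProfile, class_sums, epa_dha, to_percent

__all__ = [
    "DietaryIndexes",
    "compute_indexes",
    "aggregate_indexes",
    "INDEX_NAMES",
]

INDEX_NAMES = ("IA", "IT", "HH", "HPI", "n6n3", "pufa_sfa", "epa_dha_mg_g")


@dataclass(frozen=True)
class DietaryIndexes:
    """The six quality metrics plus EPA+DHA content for one profile.

    Undefined metrics are ``None`` with an entry in ``reasons``;
    ``epa_dha_mg_g`` is ``None`` whenever the source profile was not on
    the mg/g wet-weight basis (no reason code — it is simply not
    measurable from a percent profile).
    """

    sample_id: str
    IA: float | None
    IT: float | None
    HH: float | None
    HPI: float | None
    n6n3: float | None
    pufa_sfa: float | None
    epa_dha_mg_g: float | None
    reasons: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def compute_indexes(
    p: FAProfile, scheme: ClassificationScheme = DEFAULT_SCHEME
) -> DietaryIndexes:
    """Compute all dietary indexes for one profile.

    Absent FAs contribute 0 to every term.  The ``n3/n6`` term of IT's
    denominator follows the convention: if both families are absent the
    term is 0; if only n-6 is absent while n-3 is present, IT is undefined
    (reason ``n6_zero``) rather than silently infinite.
    """
    reasons: dict[str, str] = {}
    # Work on the percent basis: the class totals scale with the profile but
    # IT's n3/n6 ratio term does not, so only the closed composition makes
    # every index exactly invariant under uniform rescaling of the input.
    pp = to_percent(p)
    cs = class_sums(pp, scheme)
    c12 = pp.get("12:0")
    c14 = pp.get("14:0")
    c16 = pp.get("16:0")
    c18 = pp.get("18:0")
    oleic = pp.get("18:1n-9")

    athero_num = 4.0 * c14 + c12 + c16

    if cs.ufa > 0:
        ia = athero_num / cs.ufa
    else:
        ia = None
        reasons["IA"] = "zero_ufa"
    if athero_num > 0:
        hpi = cs.ufa / athero_num
    else:
        hpi = None
        reasons["HPI"] = "zero_atherogenic_sfa"

    it: float | None
    it_num = c14 + c16 + c18
    if cs.n6 == 0 and cs.n3 > 0:
        it = None
        reasons["IT"] = "n6_zero"
    else:
        ratio_term = cs.n3 / cs.n6 if cs.n6 > 0 else 0.0
        it_den = 0.5 * cs.mufa + 0.5 * cs.n6 + 3.0 * cs.n3 + ratio_term
        if it_den > 0:
            it = it_num / it_den
        else:
            it = None
            reasons["IT"] = "zero_denominator"

    hh_den = c12 + c14 + c16
    if hh_den > 0:
        hh = (oleic + cs.pufa) / hh_den
    else:
        hh = None
        reasons["HH"] = "zero_hypercholesterolemic_sfa"

    if cs.n3 > 0:
        n6n3 = cs.n6 / cs.n3
    else:
        n6n3 = None
        reasons["n6n3"] = "zero_n3"
    if cs.sfa > 0:
        pufa_sfa = cs.pufa / cs.sfa
    else:
        pufa_sfa = None
        reasons["pufa_sfa"] = "zero_sfa"

    epa_dha_mg = epa_dha(p) if p.basis is Basis.MG_PER_G_WW else None

    return DietaryIndexes(
        sample_id=p.sample_id,
        IA=ia,
        IT=it,
        HH=hh,
        HPI=hpi,
        n6n3=n6n3,
        pufa_sfa=pufa_sfa,
        epa_dha_mg_g=epa_dha_mg,
        reasons=reasons,
    )


def aggregate_indexes(cohort: list[DietaryIndexes]) -> pd.DataFrame:
    """Mean ± SEM of each index over a cohort (mean of per-sample ratios).

    Per-sample index values are averaged directly — the mean of ratios,
    matching per-animal-then-average reporting — so e.g. the aggregated
    HPI need not equal the reciprocal of the aggregated IA.  Undefined
    values are excluded and counted in ``n_undefined``; SEM (sd/sqrt(n),
    ddof=1) is undefined at n = 1.

    Returns a DataFrame indexed by index name with columns
    ``mean, sem, n, n_undefined``.
    """
    if not cohort:
        raise ValueError("cannot aggregate an empty cohort of indexes")
    rows = {}
    for name in INDEX_NAMES:
        vals = np.array(
            [getattr(d, name) for d in cohort if getattr(d, name) is not None],
            dtype=float,
        )
        n = len(vals)
        mean = float(vals.mean()) if n else math.nan
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows[name] = {"mean": mean, "sem": sem, "n": n, "n_undefined": len(cohort) - n}
    return pd.DataFrame.from_dict(rows, orient="index")
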