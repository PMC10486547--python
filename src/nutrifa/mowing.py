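"""Before/after-mowing contrast for forage-plant FA tables.

Mowing (and the wilting that follows in the field) changes both the
relative FA composition of grass leaves and their absolute FA content.
This module contrasts two cohorts of plant profiles — before and after
mowing — per FA and per class:

* ``delta_pp`` — arithmetic difference of mean percentages (after −
  before), in *percentage points*.  This is distinct from the relative
  change, which is also reported (``rel_change_pct``) to keep the two
  notions unambiguous.
* ``fold_dw`` — before/after ratio of mean absolute content (mg/g dry
  weight), so losses during wilting show up as folds > 1.
* two-sample t-tests per FA on each basis (Welch by default), with a
  two-group letter display: lowercase letters for the mg/g basis,
  uppercase for the percent basis.

Percent inputs are used as given (not re-closed): printed tables carry
per-sample-mean percentages whose column sums may be 0.1 off 100, and
re-closing them would distort the printed deltas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import ClassificationScheme, DEFAULT_SCHEME
from .profiles import Basis, FAProfile, class_sums

__all__ = ["MowingResult", "compare_mowing"]

_CLASS_ROWS = ("SFA", "MUFA", "PUFA", "UFA", "BFA", "n3", "n6")


@dataclass(frozen=True)
class MowingResult:
    """Tabular before/after contrast; one row per FA, class and total."""

    table: pd.DataFrame
    alpha: float
    welch: bool

    def row(self, label: str) -> pd.Series:
        return self.table.loc[label]


def _check_cohort(profiles: Sequence[FAProfile], basis: Basis, name: str) -> None:
    if not profiles:
        raise ValueError(f"{name} cohort is empty")
    for p in profiles:
        if p.basis is not basis:
            raise ValueError(
                f"{name} cohort expected basis {basis.value}, got {p.basis.value} "
                f"for sample {p.sample_id!r}"
            )


def _per_sample_matrix(
    profiles: Sequence[FAProfile], scheme: ClassificationScheme
) -> pd.DataFrame:
    """Rows = samples, columns = FA labels + class rows + total."""
    recs = []
    for p in profiles:
        rec = dict(p.values)
        cs = class_sums(p, scheme)
        rec.update(
            {
                "SFA": cs.sfa,
                "MUFA": cs.mufa,
                "PUFA": cs.pufa,
                "UFA": cs.ufa,
                "BFA": cs.bfa,
                "n3": cs.n3,
                "n6": cs.n6,
                "Total FA": cs.total,
            }
        )
        recs.append(rec)
    return pd.DataFrame(recs).fillna(0.0)


def _ttest(before: np.ndarray, after: np.ndarray, welch: bool) -> float:
    if len(before) < 2 or len(after) < 2:
        return math.nan
    if np.ptp(np.concatenate([before, after])) == 0:
        return math.nan
    return float(stats.ttest_ind(before, after, equal_var=not welch).pvalue)


def _letters(mean_b: float, mean_a: float, p: float, alpha: float, upper: bool) -> tuple[str, str]:
    a, b = ("A", "B") if upper else ("a", "b")
    if not math.isnan(p) and p <= alpha:
        return (a, b) if mean_b >= mean_a else (b, a)
    return a, a


def compare_mowing(
    before_percent: Sequence[FAProfile],
    after_percent: Sequence[FAProfile],
    before_mg: Sequence[FAProfile] | None = None,
    after_mg: Sequence[FAProfile] | None = None,
    *,
    alpha: float = 0.05,
    welch: bool = True,
    scheme: ClassificationScheme = DEFAULT_SCHEME,
) -> MowingResult:
    """Contrast two cohorts of plant profiles before and after mowing.

    ``before_percent``/``after_percent`` must be percent-basis cohorts;
    the optional mg cohorts must be on the mg/g dry-weight basis and feed
    the ``fold_dw`` column and the lowercase letters.  Deltas are computed
    on cohort means; p-values are two-sided two-sample t-tests (Welch
    unless ``welch=False``) and are NaN when a side has fewer than two
    samples.
    """
    _check_cohort(before_percent, Basis.PERCENT, "before (percent)")
    _check_cohort(after_percent, Basis.PERCENT, "after (percent)")
    has_mg = before_mg is not None or after_mg is not None
    if has_mg:
        if before_mg is None or after_mg is None:
            raise ValueError("mg/g cohorts must be given for both periods or neither")
        _check_cohort(before_mg, Basis.MG_PER_G_DW, "before (mg/g dw)")
        _check_cohort(after_mg, Basis.MG_PER_G_DW, "after (mg/g dw)")

    mat_bp = _per_sample_matrix(before_percent, scheme)
    mat_ap = _per_sample_matrix(after_percent, scheme)
    if has_mg:
        mat_bm = _per_sample_matrix(before_mg, scheme)
        mat_am = _per_sample_matrix(after_mg, scheme)

    fa_labels = [
        c
        for c in dict.fromkeys(list(mat_bp.columns) + list(mat_ap.columns))
        if c not in _CLASS_ROWS and c != "Total FA"
    ]
    rows = fa_labels + list(_CLASS_ROWS) + ["Total FA"]

    out: dict[str, dict[str, float | str]] = {}
    for label in rows:
        b_pct = mat_bp.get(label, pd.Series(0.0, index=mat_bp.index)).to_numpy()
        a_pct = mat_ap.get(label, pd.Series(0.0, index=mat_ap.index)).to_numpy()
        mean_b, mean_a = float(b_pct.mean()), float(a_pct.mean())
        p_pct = _ttest(b_pct, a_pct, welch)
        let_b, let_a = _letters(mean_b, mean_a, p_pct, alpha, upper=True)
        rec: dict[str, float | str] = {
            "mean_before_pct": mean_b,
            "mean_after_pct": mean_a,
            "delta_pp": mean_a - mean_b,
            "rel_change_pct": (100.0 * (mean_a - mean_b) / mean_b) if mean_b > 0 else math.nan,
            "p_pct": p_pct,
            "letter_before_pct": let_b,
            "letter_after_pct": let_a,
        }
        if has_mg:
            b_mg = mat_bm.get(label, pd.Series(0.0, index=mat_bm.index)).to_numpy()
            a_mg = mat_am.get(label, pd.Series(0.0, index=mat_am.index)).to_numpy()
            mb, ma = float(b_mg.mean()), float(a_mg.mean())
            p_mg = _ttest(b_mg, a_mg, welch)
            lb, la = _letters(mb, ma, p_mg, alpha, upper=False)
            rec.update(
                {
                    "mean_before_mg": mb,
                    "mean_after_mg": ma,
                    "fold_dw": mb / ma if ma > 0 else math.nan,
                    "p_mg": p_mg,
                    "letter_before_mg": lb,
                    "letter_after_mg": la,
                }
            )
        out[label] = rec

    table = pd.DataFrame.from_dict(out, orient="index")
    # percent-basis deltas exclude the Total FA row by construction
    table.loc["Total FA", ["mean_before_pct", "mean_after_pct", "delta_pp", "rel_change_pct"]] = math.nan
    return MowingResult(table=table, alpha=alpha, welch=welch)
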