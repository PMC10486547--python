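"""Multi-group comparison chain and compact letter displays.

The decision tree used for comparing FA levels across tissues:

1. *Normality gate* — Shapiro–Wilk on every group; the comparison is
   parametric only if every group passes at the chosen alpha.
2. *Omnibus test* — one-way ANOVA (parametric) or Kruskal–Wallis
   (nonparametric).
3. *Post hoc pairwise* — Tukey HSD after ANOVA; Dunn's rank z-tests with
   Holm adjustment after Kruskal–Wallis.  Both post hoc procedures carry
   their own familywise error control, so — as in the standard R workflow
   of ``TukeyHSD`` followed by ``multcompView`` letters — pairs are *not*
   additionally conditioned on the omnibus p-value by default; pass
   ``require_omnibus=True`` for the protected variant (which makes the
   chain conservative: its familywise null rate drops well below alpha).
4. *Compact letter display (CLD)* — groups are labelled with letters such
   that two groups share at least one letter exactly when they do **not**
   differ significantly (insert-and-absorb construction).

Dunn's test is used for the nonparametric post hoc because it draws its
variance from the pooled Kruskal–Wallis ranks: unlike exact two-sample
rank-sum tests, its p-values can clear a Holm threshold even at the small
per-group sizes (n = 4–5) typical of tissue panels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SigMatrix",
    "GroupComparison",
    "GateError",
    "DegenerateDataError",
    "normality_gate",
    "compare_groups",
    "letter_display",
]


class GateError(ValueError):
    """A group is too small for the normality gate."""


class DegenerateDataError(ValueError):
    """All observations identical: no comparison is possible."""


@dataclass(frozen=True)
class SigMatrix:
    """Pairwise significance results for k groups.

    ``significant[i, j]`` is True when groups i and j differ at ``alpha``
    (symmetric, False diagonal).  ``method`` records the post hoc branch.
    """

    labels: tuple[str, ...]
    significant: np.ndarray
    alpha: float
    method: str
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.significant, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("significance matrix shape does not match labels")
        if m.diagonal().any():
            raise ValueError("diagonal of a significance matrix must be False")
        if not (m == m.T).all():
            raise ValueError("significance matrix must be symmetric")
        object.__setattr__(self, "significant", m)


@dataclass(frozen=True)
class GroupComparison:
    """Full result of the gate -> omnibus -> post hoc chain."""

    labels: tuple[str, ...]
    branch: str  # "parametric" | "nonparametric"
    omnibus_stat: float
    omnibus_p: float
    sig: SigMatrix
    means: dict[str, float]
    letters: dict[str, str]


def _as_groups(groups: Mapping[str, Sequence[float]]) -> tuple[list[str], list[np.ndarray]]:
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    return labels, arrays


def normality_gate(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> str:
    """Decide between the parametric and nonparametric branches.

    Returns ``"parametric"`` iff every group passes Shapiro–Wilk at
    ``alpha``.  A zero-variance (constant) group cannot be tested and is
    routed to the nonparametric branch.  Groups need >= 3 observations.
    """
    labels, arrays = _as_groups(groups)
    for label, a in zip(labels, arrays):
        if len(a) < 3:
            raise GateError(
                f"group {label!r} has {len(a)} observations; "
                "the Shapiro-Wilk gate needs at least 3"
            )
        if np.ptp(a) == 0:
            return "nonparametric"
        if stats.shapiro(a).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


@lru_cache(maxsize=128)
def _tukey_qcrit(alpha: float, k: int, df: int) -> float:
    """Critical value of the studentized range (cached: the ppf is costly)."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def _tukey(arrays: list[np.ndarray], alpha: float, compute_pvalues: bool):
    """Tukey HSD decisions (and optionally p-values) from q statistics.

    Equivalent to ``scipy.stats.tukey_hsd`` (Tukey-Kramer at unequal n)
    but the significance decision uses a single cached critical value, so
    repeated calls in simulations stay cheap.
    """
    k = len(arrays)
    ns = np.array([len(a) for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    df = int(ns.sum()) - k
    if df <= 0:
        raise ValueError("Tukey HSD needs more observations than groups")
    mse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays) / df
    if mse == 0:
        raise DegenerateDataError("zero within-group variance")
    qmat = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        qmat[i, j] = qmat[j, i] = abs(means[i] - means[j]) / se
    sig = qmat > _tukey_qcrit(alpha, k, df)
    np.fill_diagonal(sig, False)
    pmat = None
    if compute_pvalues:
        iu = np.triu_indices(k, 1)
        pvals = stats.studentized_range.sf(qmat[iu], k, df)
        pmat = np.ones((k, k))
        pmat[iu] = pvals
        pmat.T[iu] = pvals
    return sig, pmat


def _dunn_pvalues(arrays: list[np.ndarray]) -> np.ndarray:
    """Unadjusted two-sided Dunn z-test p-values on pooled ranks."""
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term
    bounds = np.cumsum([0] + [len(a) for a in arrays])
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))]
    k = len(arrays)
    pmat = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_factor * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pmat[i, j] = pmat[j, i] = 2.0 * stats.norm.sf(abs(z))
    return pmat


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    *,
    branch: str | None = None,
    require_omnibus: bool = False,
    compute_pvalues: bool = True,
) -> GroupComparison:
    """Run the full comparison chain on >= 2 groups of observations.

    ``branch`` forces "parametric"/"nonparametric"; by default it is
    decided by :func:`normality_gate`.  With ``require_omnibus=True``
    pairs are significant only when the omnibus test is significant at
    ``alpha`` (protected variant).  ``compute_pvalues=False`` skips the
    costly studentized-range p-values in the parametric branch; the
    significance decisions are identical.
    """
    labels, arrays = _as_groups(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups to compare")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all observations are identical")

    if branch is None:
        branch = normality_gate(groups, alpha)
    if branch not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown branch {branch!r}")

    iu = np.triu_indices(k, 1)
    if branch == "parametric":
        omnibus = stats.f_oneway(*arrays)
        sig, pmat = _tukey(arrays, alpha, compute_pvalues)
        method = "tukey"
    else:
        omnibus = stats.kruskal(*arrays)
        raw = _dunn_pvalues(arrays)
        pmat = np.ones((k, k))
        adj = multipletests(raw[iu], alpha=alpha, method="holm")[1]
        pmat[iu] = adj
        pmat.T[iu] = adj
        np.fill_diagonal(pmat, 1.0)
        sig = pmat < alpha
        np.fill_diagonal(sig, False)
        method = "dunn-holm"

    if require_omnibus and not (omnibus.pvalue < alpha):
        sig = np.zeros((k, k), dtype=bool)
    sigmatrix = SigMatrix(tuple(labels), sig, alpha, method, pmat)
    means = {label: float(a.mean()) for label, a in zip(labels, arrays)}
    letters = letter_display(sigmatrix, means)
    return GroupComparison(
        labels=tuple(labels),
        branch=branch,
        omnibus_stat=float(omnibus.statistic),
        omnibus_p=float(omnibus.pvalue),
        sig=sigmatrix,
        means=means,
        letters=letters,
    )


def letter_display(
    sig: SigMatrix,
    means: Mapping[str, float] | Sequence[float],
    *,
    uppercase: bool = False,
) -> dict[str, str]:
    """Compact letter display by insertion and absorption.

    Starts from a single letter covering all groups; every significant
    pair splits each letter column containing both members into two
    columns lacking one member each; columns that became subsets of
    another are absorbed.  The result is sound and complete: two groups
    share a letter iff their pair is not significant.  Letters are
    assigned in descending order of group means, so the highest-mean
    group carries "a" (or "A").
    """
    k = len(sig.labels)
    if isinstance(means, Mapping):
        mean_vec = [float(means[label]) for label in sig.labels]
    else:
        mean_vec = [float(m) for m in means]
        if len(mean_vec) != k:
            raise ValueError("means length does not match labels")
    # process splits in deterministic order
    order = sorted(range(k), key=lambda i: (-mean_vec[i], sig.labels[i]))
    rank = {g: r for r, g in enumerate(order)}

    columns: list[set[int]] = [set(range(k))]
    pairs = [(i, j) for i, j in itertools.combinations(range(k), 2) if sig.significant[i, j]]
    pairs.sort(key=lambda ij: (rank[ij[0]], rank[ij[1]]))
    for i, j in pairs:
        nxt: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                nxt.append(col - {i})
                nxt.append(col - {j})
            else:
                nxt.append(col)
        # absorb: drop empties, strict subsets and duplicates
        nxt = [c for c in nxt if c]
        keep: list[set[int]] = []
        for c in nxt:
            if any(c < other for other in nxt):
                continue
            if c not in keep:
                keep.append(c)
        columns = keep

    columns.sort(key=lambda c: sorted(rank[g] for g in c))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if uppercase else "abcdefghijklmnopqrstuvwxyz"
    if len(columns) > len(alphabet):  # pragma: no cover - never at sane k
        raise ValueError("more letter columns than letters")
    assigned: dict[str, list[str]] = {g: [] for g in sig.labels}
    for letter, col in zip(alphabet, columns):
        for gi in col:
            assigned[sig.labels[gi]].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in assigned.items()}
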