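import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import cld_oracle_maximal_cliques, sharing_matrix_from_letters
from nutrifa.groupstats import (
    DegenerateDataError,
    GateError,
    SigMatrix,
    compare_groups,
    letter_display,
    normality_gate,
)


def test_gate_requires_three_observations():
    with pytest.raises(GateError):
        normality_gate({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


def test_gate_constant_group_is_nonparametric():
    assert normality_gate({"a": [2.0, 2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0, 2.5]}) == "nonparametric"


def test_gate_outlier_forces_nonparametric():
    rng = np.random.default_rng(3)
    clean = rng.normal(0, 1, 10)
    spiked = np.append(rng.normal(0, 1, 9), 40.0)
    assert stats.shapiro(spiked).pvalue <= 0.05  # the outlier is what trips it
    assert normality_gate({"a": clean, "b": spiked}) == "nonparametric"


def test_gate_normal_groups_are_parametric():
    rng = np.random.default_rng(8)
    groups = {f"g{i}": rng.normal(0, 1, 20) for i in range(4)}
    assert normality_gate(groups) == "parametric"


def test_separated_groups_are_significant():
    rng = np.random.default_rng(11)
    res = compare_groups({"lo": rng.normal(0, 1, 5), "hi": rng.normal(10, 1, 5)})
    assert res.sig.significant[0, 1]
    assert res.letters["lo"] != res.letters["hi"]
    assert res.omnibus_p < 0.05


def test_single_group_and_degenerate_errors():
    with pytest.raises(ValueError):
        compare_groups({"only": [1.0, 2.0, 3.0]})
    with pytest.raises(DegenerateDataError):
        compare_groups({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})


def test_parametric_branch_matches_scipy_tukey():
    """Dual route: our q-statistic decisions against scipy's integration."""
    rng = np.random.default_rng(5)
    arrays = [rng.normal(0.8 * i, 1, 6) for i in range(4)]
    groups = {f"g{i}": a for i, a in enumerate(arrays)}
    res = compare_groups(groups, branch="parametric")
    ref = np.asarray(stats.tukey_hsd(*arrays).pvalue)
    iu = np.triu_indices(4, 1)
    assert np.allclose(res.sig.pvalues[iu], ref[iu], atol=1e-8)
    assert (res.sig.significant[iu] == (ref[iu] < 0.05)).all()


def test_omnibus_protection_is_optional_but_available():
    rng = np.random.default_rng(11)
    groups = {"lo": rng.normal(0, 1, 5), "hi": rng.normal(10, 1, 5)}
    protected = compare_groups(groups, require_omnibus=True)
    assert protected.sig.significant.any()  # omnibus is significant here too


def test_nonparametric_branch_uses_dunn_holm():
    rng = np.random.default_rng(13)
    spiked = np.append(rng.normal(0, 1, 9), 50.0)
    groups = {"a": spiked, "b": rng.normal(12, 1, 10), "c": rng.normal(0, 1, 10)}
    res = compare_groups(groups)
    assert res.branch == "nonparametric"
    assert res.sig.method == "dunn-holm"
    assert res.sig.significant[1, 2]  # b vs c strongly separated in ranks


def test_sigmatrix_validation():
    with pytest.raises(ValueError):
        SigMatrix(("a", "b"), np.array([[True, False], [False, False]]), 0.05, "tukey")
    with pytest.raises(ValueError):
        SigMatrix(("a", "b"), np.array([[False, True], [False, False]]), 0.05, "tukey")


# -- compact letter display -------------------------------------------------


def _sig(k, pairs):
    m = np.zeros((k, k), dtype=bool)
    for i, j in pairs:
        m[i, j] = m[j, i] = True
    return SigMatrix(tuple(f"g{i}" for i in range(k)), m, 0.05, "tukey")


def test_cld_no_significant_pairs_all_share():
    letters = letter_display(_sig(3, []), [3.0, 2.0, 1.0])
    assert set(letters.values()) == {"a"}


def test_cld_two_separated_groups():
    letters = letter_display(_sig(2, [(0, 1)]), [2.0, 1.0])
    assert letters == {"g0": "a", "g1": "b"}


def test_cld_four_group_example_is_valid():
    sig = _sig(4, [(0, 2), (0, 3), (1, 3)])
    letters = letter_display(sig, [4.0, 3.0, 2.0, 1.0])
    share = sharing_matrix_from_letters(letters, sig.labels)
    expected = ~sig.significant & ~np.eye(4, dtype=bool)
    assert (share == expected).all()


def test_cld_highest_mean_gets_a():
    letters = letter_display(_sig(3, [(0, 2)]), {"g0": 1.0, "g1": 5.0, "g2": 9.0})
    assert "a" in letters["g2"]


def test_cld_uppercase_option():
    letters = letter_display(_sig(2, [(0, 1)]), [2.0, 1.0], uppercase=True)
    assert letters == {"g0": "A", "g1": "B"}


def test_cld_permutation_consistency():
    pairs = [(0, 2), (1, 3), (0, 4)]
    sig = _sig(5, pairs)
    means = [5.0, 4.0, 3.0, 2.0, 1.0]
    base = sharing_matrix_from_letters(letter_display(sig, means), sig.labels)
    perm = [2, 0, 4, 1, 3]
    pm = np.zeros((5, 5), dtype=bool)
    for i, j in pairs:
        pm[perm.index(i), perm.index(j)] = pm[perm.index(j), perm.index(i)] = True
    psig = SigMatrix(tuple(f"g{perm[i]}" for i in range(5)), pm, 0.05, "tukey")
    pshare = sharing_matrix_from_letters(
        letter_display(psig, [means[perm[i]] for i in range(5)]), psig.labels
    )
    for a, b in itertools.combinations(range(5), 2):
        assert base[a, b] == pshare[perm.index(a), perm.index(b)]


def test_cld_random_matrices_match_clique_oracle():
    rng = np.random.default_rng(99)
    for _ in range(100):
        k = int(rng.integers(2, 7))
        m = np.zeros((k, k), dtype=bool)
        for i, j in itertools.combinations(range(k), 2):
            m[i, j] = m[j, i] = rng.random() < 0.4
        sig = SigMatrix(tuple(f"g{i}" for i in range(k)), m, 0.05, "tukey")
        letters = letter_display(sig, list(rng.normal(size=k)))
        share = sharing_matrix_from_letters(letters, sig.labels)
        cliques = cld_oracle_maximal_cliques(m)
        oracle_share = np.zeros((k, k), dtype=bool)
        for c in cliques:
            for a, b in itertools.combinations(sorted(c), 2):
                oracle_share[a, b] = oracle_share[b, a] = True
        assert (share == oracle_share).all()
        assert (share == (~m & ~np.eye(k, dtype=bool))).all()
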