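import math

import pytest
from hypothesis import given, strategies as st

from nutrifa.profiles import (
    Basis,
    BasisError,
    ClassSummary,
    FAProfile,
    PeakTable,
    ProfileError,
    QuantificationError,
    class_sums,
    epa_dha,
    quantify,
    to_percent,
)


def make(values, basis=Basis.PERCENT, **kw):
    return FAProfile(sample_id="s", basis=basis, values=values, **kw)


# -- quantify ---------------------------------------------------------------


def test_quantify_identity_ratio():
    pt = PeakTable(areas={"16:0": 100.0, "19:0": 100.0}, istd_area=100.0,
                   istd_mass_mg=1.0, sample_mass_g=1.0)
    assert quantify(pt).values == {"16:0": 1.0}


def test_quantify_hand_case():
    pt = PeakTable(areas={"16:0": 300.0, "18:0": 100.0}, istd_area=200.0,
                   istd_mass_mg=2.0, sample_mass_g=0.5)
    p = quantify(pt)
    assert p.values["16:0"] == pytest.approx(6.0)
    assert p.values["18:0"] == pytest.approx(2.0)
    assert p.basis is Basis.MG_PER_G_DW


def test_quantify_linearity():
    base = dict(istd_area=150.0, istd_mass_mg=1.5, sample_mass_g=0.4)
    p1 = quantify(PeakTable(areas={"16:0": 50.0, "18:1n-9": 80.0}, **base))
    p2 = quantify(PeakTable(areas={"16:0": 100.0, "18:1n-9": 160.0}, **base))
    for k in p1.values:
        assert p2.values[k] == pytest.approx(2 * p1.values[k])
    half = quantify(PeakTable(areas={"16:0": 50.0, "18:1n-9": 80.0},
                              istd_area=150.0, istd_mass_mg=1.5, sample_mass_g=0.8))
    for k in p1.values:
        assert half.values[k] == pytest.approx(p1.values[k] / 2)


def test_quantify_excludes_internal_standard_and_validates():
    pt = PeakTable(areas={"19:0": 10.0, "16:0": 10.0}, istd_area=10.0,
                   istd_mass_mg=1.0, sample_mass_g=1.0)
    assert "19:0" not in quantify(pt).values
    with pytest.raises(QuantificationError):
        quantify(PeakTable(areas={"16:0": 1.0}, istd_area=0.0,
                           istd_mass_mg=1.0, sample_mass_g=1.0))
    with pytest.raises(QuantificationError):
        quantify(PeakTable(areas={"16:0": 1.0}, istd_area=1.0,
                           istd_mass_mg=1.0, sample_mass_g=0.0))


# -- to_percent -------------------------------------------------------------


def test_to_percent_symmetry_and_idempotence():
    p = to_percent(make({"16:0": 2.0, "18:0": 2.0}, basis=Basis.MG_PER_G_DW))
    assert p.values == {"16:0": 50.0, "18:0": 50.0}
    again = to_percent(p)
    assert again.values == p.values
    assert sum(p.values.values()) == pytest.approx(100.0, abs=1e-9)


def test_to_percent_all_zero_errors():
    with pytest.raises(ProfileError):
        to_percent(make({"16:0": 0.0}, basis=Basis.MG_PER_G_DW))


# -- class_sums -------------------------------------------------------------


def test_class_sums_empty_profile_is_zero():
    cs = class_sums(make({}))
    assert cs.total == 0.0 and cs.sfa == 0.0 and cs.ufa == 0.0


def test_class_sums_identities():
    p = make({"16:0": 20, "15:0": 1, "18:1n-9": 30, "18:2n-6": 25,
              "18:3n-3": 20, "CLA": 4})
    cs = class_sums(p)
    assert cs.sfa + cs.ufa == pytest.approx(cs.total, rel=1e-9)
    assert cs.ufa == pytest.approx(cs.mufa + cs.pufa, rel=1e-9)
    assert cs.n3 + cs.n6 <= cs.pufa + 1e-12
    assert cs.bfa == pytest.approx(1.0)


@given(
    st.dictionaries(
        st.sampled_from(["14:0", "16:0", "17:0", "18:0", "18:1n-9", "16:1n-7",
                         "18:2n-6", "18:3n-3", "20:4n-6", "20:5n-3", "22:6n-3", "CLA"]),
        st.floats(0, 100, allow_nan=False),
        min_size=1,
    ),
    st.dictionaries(
        st.sampled_from(["12:0", "15:0", "i15:0", "ai17:0", "18:1n-7", "22:5n-3"]),
        st.floats(0, 100, allow_nan=False),
        min_size=1,
    ),
)
def test_class_sums_additive_over_disjoint_profiles(a_vals, b_vals):
    a, b = make(a_vals), make(b_vals)
    merged = make({**a_vals, **b_vals})
    ca, cb, cm = class_sums(a), class_sums(b), class_sums(merged)
    for f in ("sfa", "mufa", "pufa", "ufa", "bfa", "n3", "n6", "total"):
        assert getattr(cm, f) == pytest.approx(getattr(ca, f) + getattr(cb, f), abs=1e-9)


def test_percent_then_sums_commutes_with_sums_then_percent():
    p = make({"16:0": 3.0, "18:1n-9": 5.0, "18:3n-3": 2.0}, basis=Basis.MG_PER_G_DW)
    direct = class_sums(to_percent(p))
    raw = class_sums(p)
    assert direct.sfa == pytest.approx(100 * raw.sfa / raw.total, rel=1e-9)
    assert direct.pufa == pytest.approx(100 * raw.pufa / raw.total, rel=1e-9)


def test_trace_entries_contribute_zero_but_survive():
    p = make({"16:0": 60.0, "18:1n-9": 40.0}, traces={"12:0"})
    assert p.values["12:0"] == 0.0
    assert "12:0" in p.traces
    assert class_sums(p).sfa == pytest.approx(60.0)


def test_unparseable_labels_rejected_with_names():
    with pytest.raises(ProfileError, match="nonsense"):
        make({"16:0": 1.0, "nonsense": 2.0})


def test_en_dash_labels_canonicalized():
    p = make({"18:3n–3": 5.0})
    assert p.values == {"18:3n-3": 5.0}


# -- epa_dha ----------------------------------------------------------------


def test_epa_dha_requires_wet_weight_basis():
    with pytest.raises(BasisError):
        epa_dha(make({"20:5n-3": 1.0}))


def test_epa_dha_sum_and_insensitivity():
    p = make({"20:5n-3": 0.2, "22:6n-3": 0.13}, basis=Basis.MG_PER_G_WW)
    assert epa_dha(p) == pytest.approx(0.33)
    q = make({"20:5n-3": 0.2, "22:6n-3": 0.13, "16:0": 9.0, "18:0": 4.0},
             basis=Basis.MG_PER_G_WW)
    assert epa_dha(q) == pytest.approx(0.33)
    assert epa_dha(make({"16:0": 9.0}, basis=Basis.MG_PER_G_WW)) == 0.0
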