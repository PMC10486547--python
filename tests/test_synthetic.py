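import numpy as np
import pytest

from nutrifa.indexes import compute_indexes
from nutrifa.profiles import Basis, FAProfile, class_sums, epa_dha
from nutrifa.synthetic import (
    TissueTemplate,
    default_templates,
    fit_precision,
    generate_cohort,
    with_component_mean,
)


def test_template_means_sum_to_100(templates):
    for tpl in templates.values():
        assert sum(tpl.mean_percent.values()) == pytest.approx(100.0, abs=1e-9)


def test_template_class_means_in_reported_ranges(templates):
    ranges = {
        "muscle": {"sfa": (31, 45), "mufa": (18, 42), "pufa": (9, 46)},
        "liver": {"sfa": (41, 46), "mufa": (13, 19), "pufa": (34, 40)},
        "subcutaneous_fat": {"sfa": (41, 66), "mufa": (23, 53), "pufa": (1, 2)},
        "visceral_fat": {"sfa": (41, 66), "mufa": (23, 53), "pufa": (1, 2)},
    }
    for name, bounds in ranges.items():
        cs = class_sums(FAProfile("m", Basis.PERCENT, dict(templates[name].mean_percent)))
        for cls, (lo, hi) in bounds.items():
            assert lo <= getattr(cs, cls) <= hi, (name, cls)


def test_adipose_templates_have_no_lcpufa(templates):
    for name in ("subcutaneous_fat", "visceral_fat"):
        for label in ("20:3n-6", "20:4n-6", "20:4n-3", "20:5n-3", "22:5n-3", "22:6n-3"):
            assert label not in templates[name].mean_percent


def test_dominant_species(templates):
    fat = templates["subcutaneous_fat"].mean_percent
    top3 = sorted(fat, key=fat.get, reverse=True)[:3]
    assert set(top3) == {"16:0", "18:0", "18:1n-9"}
    muscle = templates["muscle"].mean_percent
    pufa_rank = sorted(
        (l for l in muscle if l in {"18:2n-6", "20:4n-6", "22:5n-3", "20:5n-3",
                                    "18:3n-3", "20:3n-6", "22:6n-3", "20:4n-3", "CLA"}),
        key=muscle.get, reverse=True,
    )
    assert set(pufa_rank[:4]) == {"18:2n-6", "20:4n-6", "22:5n-3", "20:5n-3"}
    plant = templates["plant_leaf"].mean_percent
    assert sorted(plant, key=plant.get, reverse=True)[:3] == ["18:3n-3", "16:0", "18:2n-6"]


def test_generation_is_seed_deterministic(templates):
    a = generate_cohort(templates["muscle"], 5, seed=7)
    b = generate_cohort(templates["muscle"], 5, seed=7)
    assert all(x.values == y.values for x, y in zip(a, b))
    c = generate_cohort(templates["muscle"], 5, seed=8)
    assert any(x.values != y.values for x, y in zip(a, c))


def test_compositional_closure_exact(templates):
    for p in generate_cohort(templates["liver"], 20, seed=1):
        assert p.total() == pytest.approx(100.0, abs=1e-9)


def test_structural_zeros_stay_zero(templates):
    for p in generate_cohort(templates["subcutaneous_fat"], 50, seed=2):
        assert epa_dha(FAProfile(p.sample_id, Basis.MG_PER_G_WW, dict(p.values))) == 0.0


def test_cohort_class_means_converge_to_template(templates):
    tpl = templates["liver"]
    cohort = generate_cohort(tpl, 2000, seed=13)
    target = class_sums(FAProfile("m", Basis.PERCENT, dict(tpl.mean_percent)))
    got = np.mean([[class_sums(p).sfa, class_sums(p).pufa] for p in cohort], axis=0)
    assert got[0] == pytest.approx(target.sfa, abs=1.0)
    assert got[1] == pytest.approx(target.pufa, abs=1.0)


def test_precision_recovery_method_of_moments(templates):
    cohort = generate_cohort(templates["muscle"], 500, seed=5)
    phi = fit_precision(cohort)
    assert abs(phi - 200.0) / 200.0 < 0.2


def test_mg_basis_uses_lognormal_totals(templates):
    cohort = generate_cohort(templates["liver"], 400, seed=9, basis=Basis.MG_PER_G_WW)
    totals = np.array([p.total() for p in cohort])
    assert totals.mean() == pytest.approx(16.0, rel=0.1)
    assert epa_dha(cohort[0]) > 0
    with pytest.raises(ValueError, match="totals on"):
        generate_cohort(templates["liver"], 2, seed=9, basis=Basis.MG_PER_G_DW)


def test_index_orderings_across_tissues(templates):
    idx = {
        name: compute_indexes(FAProfile("m", Basis.PERCENT, dict(tpl.mean_percent)))
        for name, tpl in templates.items()
    }
    assert idx["subcutaneous_fat"].IA > idx["muscle"].IA > idx["liver"].IA
    assert idx["liver"].HH > idx["muscle"].HH > idx["subcutaneous_fat"].HH
    assert idx["subcutaneous_fat"].pufa_sfa < 0.1 < idx["muscle"].pufa_sfa
    assert idx["subcutaneous_fat"].IT > idx["muscle"].IT


def test_with_component_mean_shifts_exactly_and_recloses(templates):
    tpl = templates["muscle"]
    shifted = with_component_mean(tpl, "16:0", tpl.mean_percent["16:0"] + 5.0)
    assert shifted.mean_percent["16:0"] == pytest.approx(tpl.mean_percent["16:0"] + 5.0)
    assert sum(shifted.mean_percent.values()) == pytest.approx(100.0, abs=1e-9)
    ratio = shifted.mean_percent["18:0"] / tpl.mean_percent["18:0"]
    assert shifted.mean_percent["18:1n-9"] / tpl.mean_percent["18:1n-9"] == pytest.approx(ratio)
    with pytest.raises(KeyError):
        with_component_mean(tpl, "24:0", 1.0)


def test_age_trend_is_monotone(templates):
    tpl = templates["muscle"]
    young = generate_cohort(tpl, 300, seed=17, ages_months=[7] * 300)
    old = generate_cohort(tpl, 300, seed=18, ages_months=[108] * 300)
    for label in ("18:1n-9", "16:1n-7"):
        assert np.mean([p.values[label] for p in old]) > np.mean(
            [p.values[label] for p in young]
        )


def test_invalid_templates_rejected():
    with pytest.raises(ValueError):
        TissueTemplate("x", {"16:0": 50.0}, precision=100, total_mean=1, total_cv=0.1)
    with pytest.raises(ValueError):
        TissueTemplate("x", {"16:0": 100.0}, precision=-1, total_mean=1, total_cv=0.1)
    with pytest.raises(ValueError):
        generate_cohort(default_templates()["muscle"], 0, seed=1)
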