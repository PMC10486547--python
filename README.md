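# nutrifa

Fatty-acid (FA) profile analysis and lipid nutritional-quality indexes for
animal tissues and forage plants.

The FA composition of a food fat largely determines its cardiovascular
health value: saturated 12:0/14:0/16:0 are atherogenic and thrombogenic,
while unsaturated FAs — above all the omega-3 long-chain PUFAs EPA
(20:5n-3) and DHA (22:6n-3) — are protective. `nutrifa` is for food and
meat scientists who measure FA methyl-ester profiles by GC and want to go
from raw peak tables or published percent tables to the standard quality
metrics with the statistics that the field reports alongside them.

## What it computes

For a profile with class sums SFA, MUFA, PUFA (n-3 and n-6 families), UFA =
MUFA + PUFA:

- index of atherogenicity  `IA = (4·14:0 + 12:0 + 16:0) / UFA`
- index of thrombogenicity `IT = (14:0 + 16:0 + 18:0) / (0.5·MUFA + 0.5·n-6 + 3·n-3 + n-3/n-6)`
- health-promoting index   `HPI = UFA / (4·14:0 + 12:0 + 16:0)`  (= 1/IA)
- hypo-/hypercholesterolemic ratio `HH = (18:1n-9 + PUFA) / (12:0 + 14:0 + 16:0)`
- the ratios n-6/n-3 and PUFA/SFA, and EPA + DHA content in mg/g wet weight

Around that core:

- a strict parser/formatter for shorthand FA nomenclature (`18:3n–3`,
  `ai15:0`, `CLA`, `c9,t11-18:2`, omega-dialects), with configurable
  classification into SFA/MUFA/PUFA/UFA, n-3/n-6, branched-and-odd (BFA)
  and LC-PUFA;
- single-point internal-standard quantification of GC peak areas
  (methyl nonadecanoate, 19:0) into mg/g content;
- a before/after-mowing contrast for forage plants (percentage-point
  deltas, dry-weight fold changes, per-basis t-tests and letters), with the
  published pasture-grass reference table packaged as data;
- the group-comparison chain used for tissue panels: Shapiro–Wilk gate →
  one-way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn (Holm) → compact
  letter display;
- a seeded synthetic-cohort generator (Dirichlet composition × log-normal
  total content) with templates for cattle muscle, liver, subcutaneous and
  visceral fat, and pasture-grass leaves.

## Worked example

```python
import nutrifa as nf

profile = nf.FAProfile(
    sample_id="steak_01",
    basis=nf.Basis.MG_PER_G_WW,           # mg per g wet weight
    values={"14:0": 0.14, "16:0": 1.80, "18:0": 1.26, "16:1n-7": 0.23,
            "18:1n-9": 2.52, "18:1n-7": 0.25, "18:2n-6": 0.93, "18:3n-3": 0.24,
            "20:4n-6": 0.54, "20:5n-3": 0.32, "22:5n-3": 0.41, "22:6n-3": 0.06},
    tissue="muscle",
)
cs = nf.class_sums(profile)
print(f"SFA {cs.sfa:.2f}  MUFA {cs.mufa:.2f}  PUFA {cs.pufa:.2f} mg/g ww (total {cs.total:.2f})")
d = nf.compute_indexes(profile)
print(f"IA {d.IA:.2f}  IT {d.IT:.2f}  HH {d.HH:.2f}  HPI {d.HPI:.2f}")
print(f"n-6/n-3 {d.n6n3:.2f}  PUFA/SFA {d.pufa_sfa:.2f}  EPA+DHA {d.epa_dha_mg_g:.2f} mg/g ww")
```

prints

```
SFA 3.20  MUFA 3.00  PUFA 2.50 mg/g ww (total 8.70)
IA 0.43  IT 0.59  HH 2.59  HPI 2.33
n-6/n-3 1.43  PUFA/SFA 0.78  EPA+DHA 0.38 mg/g ww
```

Low IA/IT with HH and HPI well above 2, an n-6/n-3 ratio near 1 (WHO
recommendation: below 8), PUFA/SFA about twice the recommended 0.4 floor,
and a third of a milligram of EPA+DHA per gram: the profile of a
grass-fed ruminant muscle that qualifies as a health food by every one of
these metrics. Indexes are computed on the closed (percent) composition,
so the same numbers result from a percent-basis profile; EPA+DHA content
additionally needs the wet-weight basis.

The same analyses are available from the shell:

```sh
nutrifa simulate --tissue liver --n 5 --seed 1 --out liver.csv
nutrifa indexes liver.csv --out liver_indexes.csv
nutrifa compare groups.csv --out letters.csv      # (group, value) CSV in, CLD out
nutrifa pipeline --config run.yaml
```

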