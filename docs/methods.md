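# Methods

## Scope and data model

`nutrifa` analyzes fatty-acid (FA) profiles of animal tissues and forage
plants. A profile is a map from canonical shorthand FA labels to
nonnegative amounts on one of three bases: percent of total FA, mg per g
dry weight, or mg per g wet weight. Amounts below the reporting threshold
are *trace* entries: they contribute exactly 0 to every sum but are
preserved through I/O, matching how measurement tables print "trace"
instead of a number. Percent-basis profiles are used exactly as given
(column sums of published tables are often 0.1 off 100 because each row is
a per-sample mean rounded to one decimal); re-closing them would distort
printed values, so normalization only happens where an operation requires
it.

## Nomenclature and classification

The parser accepts the `C:D` / `C:Dn-x` dialect family (any Unicode dash,
`ω-x`, `omega-x`), `i`/`ai` branch prefixes, the token `CLA` and
geometry-prefixed forms (`c9,t11-18:2` is conjugated because its double
bond positions are two apart; `c9,c12-18:2` is ordinary linoleic acid,
whose omega class follows from the last position). An unsaturated
straight-chain FA without an omega position is an error by default —
real tables only omit it for pooled isomer peaks, which require an
explicit opt-in — never a silent default.

Classification tags each FA as exactly one of SFA / MUFA / PUFA (UFA =
MUFA ∪ PUFA), with the omega families n-3/n-6, LC-PUFA (PUFA with ≥ 20
carbons) and the branched-and-odd overlay BFA. Two conventions are
configurable because published tables are inconsistent about them:

- odd/branched saturated FAs count inside SFA by default (tissue tables
  sum 15:0, 17:0 into the SFA row) while also appearing under BFA;
- CLA counts toward PUFA but not n-6 by default. Excluding CLA from PUFA
  is possible but leaves it outside the SFA/MUFA/PUFA partition; the
  default preserves the partition.

Only conjugated 18:2 (CLA) is representable as conjugated, which keeps
the canonical label round-trip exact.

## Quantification

Single-point internal-standard quantification: a known mass `m_istd` of
methyl nonadecanoate (19:0, absent from the samples) is spiked in before
extraction, and each analyte's content is
`c_i = (A_i / A_istd) · m_istd / m_sample` (mg per g of sample mass).
Response factors and detector calibration curves are out of scope; the
operation is exactly linear in each analyte area.

## Dietary indexes

IA, IT, HH and HPI as defined in the README, plus n-6/n-3, PUFA/SFA and
EPA+DHA (mg/g wet weight). Numerical conventions:

- Indexes are computed on the closed (percent) composition. All terms of
  IA, HH, HPI and the plain ratios are degree-zero homogeneous anyway, but
  IT mixes class sums with the dimensionless n-3/n-6 term, so only the
  closed composition makes every index exactly invariant under uniform
  rescaling of the input.
- The n-3/n-6 term in IT's denominator is 0 when both families are
  absent; when n-6 is absent but n-3 present, IT is undefined.
- Any zero denominator yields an undefined index with a machine-readable
  reason code — never a silent 0, infinity or NaN inside an aggregate.
- Cohort aggregation is the mean of per-sample values (mean of ratios,
  i.e. per-animal-then-average), SEM = sd/√n with ddof = 1, undefined at
  n = 1; undefined samples are excluded and counted.

## Mowing contrast

Two cohorts (before/after mowing) are contrasted per FA and per class on
two bases. Composition changes are reported as *percentage points*
(difference of mean percentages) — deliberately distinguished from
relative change, which is reported in a separate column, because "SFA
increased by 19.6%" in the percentage-point sense is a different claim
from a 19.6% relative rise. Absolute losses are before/after fold changes
on mg/g dry weight. Per-FA two-sample t-tests are Welch by default
(pooled-variance optional): at n = 4 per group, equal variances are an
assumption with no power to spare for testing. Letters are per basis
(lowercase mg, uppercase percent); with single-profile cohorts (e.g.
published group means) p-values are NaN and letters collapse to "a"/"A".

## Group comparison chain

1. Shapiro–Wilk on every group (≥ 3 observations; a constant group is
   routed nonparametric since the statistic is undefined); the chain is
   parametric only if all groups pass at α.
2. Parametric: one-way ANOVA, then Tukey HSD. Significance decisions
   compare the pairwise studentized-range statistic with a cached
   critical value (`studentized_range.ppf`), which is numerically
   identical to integrating p-values per pair but ~50× faster inside
   simulation loops; p-values are computed on demand.
3. Nonparametric: Kruskal–Wallis, then Dunn's z-tests on the pooled ranks
   with Holm adjustment. Dunn rather than pairwise Mann–Whitney because
   exact MWU p-values at n = 5 are bounded below by 2/252 ≈ 0.008 and can
   never clear a Holm threshold across 28 pairs — a post hoc that cannot
   reject is useless at panel sizes of k = 8, n = 4–5.
4. Post hoc decisions are **not** conditioned on the omnibus p-value by
   default, mirroring the standard R workflow (`TukeyHSD` on the fitted
   model, letters via multcompView) — both post hoc procedures carry
   their own familywise error control. Measured under a pure null (k = 8,
   n = 5, 4000 replicates), the familywise rate of the default chain is
   ≈ 0.042; the protected variant (`require_omnibus=True`) drops to
   ≈ 0.028, i.e. conservative. α = 0.05 throughout, configurable.

### Compact letter display

Insert-and-absorb: start with one letter column covering all groups; each
significant pair splits every column containing both members into two
columns lacking one member each; columns that became subsets are
absorbed. The construction is sound and complete — two groups share a
letter iff they are not significantly different — which is verified
exhaustively against an independent maximal-clique oracle for all 1,024
five-group significance matrices. Minimality of the letter count is not
guaranteed (nor needed for correctness). Letters are assigned in
descending order of group means, so "a" marks the highest group.

## Synthetic cohorts

Per-sample composition is Dirichlet on the FA simplex: mean composition
`p` (percent, closed to 100) and one precision `φ` (concentration sum),
giving component variances `p_i(1-p_i)/(1+φ)`. Mean-zero components are
structural zeros and remain exactly zero — adipose tissue contains *no*
LC-PUFA, and the generator reproduces the absence rather than a small
value. Total FA content is log-normal (mean, CV), independent of
composition; mg/g profiles are composition × total. A single integer seed
fully determines the output.

Template means are placed inside the reported class ranges for cattle
tissues (muscle SFA 31–45 / MUFA 18–42 / PUFA 9–46%; liver 41–46 /
13–19 / 34–40%; adipose 41–66 / 23–53 / 1–2%) with the reported dominant
species, and the plant templates use the packaged pasture table's percent
composition. Precisions (muscle 200, liver 300, adipose 100, plants 200)
are calibrated so that simulated index CVs match the reported SEM-implied
CVs of ≈ 15–20% — not the full min–max ranges, which span ages from 7
months to 9 years and five distinct muscles and therefore overstate
within-cohort noise. Totals: muscle 9 mg/g ww (CV 0.35, spanning the
reported 5.9–14.7), liver 16 mg/g ww (chosen so that liver EPA+DHA ≈ 1.6
mg/g ww emerges), adipose 700–750 mg/g ww, plants 10.6 / 5.3 mg/g dw
(fresh / wilted). The optional muscle age trend tilts 16:1n-7 and
18:1n-9 upward by 0.4% per month of age (log-linear, re-closed) — a
monotone tendency, not a claimed magnitude — and is off unless ages are
passed.

What passing tests on these cohorts do **not** show: the generator has no
FA covariance structure beyond the Dirichlet's (all pairwise negative),
no age–total-fat interaction, no measurement error model, and no
between-farm or between-season variation; conclusions about real tissue
data still require real tissue data.

## Problem sizes and tolerances in the test suite

Null calibration of the statistical chain uses 1000 replicates of k = 8
groups × n = 5 (band 0.05 ± 0.02); generator recovery uses n = 500
(precision within 20%) and power uses 200 replicates of n = 10 per group
(+5 pp shift in 16:0, power > 0.8); index identities use 10,000 random
profiles (IA·HPI within 1e-9). These sizes keep the full suite under a
minute while leaving each check's Monte-Carlo error well inside its
tolerance. Reproduction of printed one-decimal table values is asserted
after rounding to one decimal.

## Known limitations

- Double-bond geometry (cis/trans) is not modeled beyond the conjugated
  flag; IUPAC systematic names and lipid-class (TAG/PL) bookkeeping are
  out of scope.
- The internal-standard formula is single-point: no FAME response-factor
  correction.
- The Dunn+Holm post hoc is conservative; letters from it and from Tukey
  are not guaranteed to use a minimal alphabet.
- Printed class rows of the packaged pasture table are carried as data;
  recomputed sums can differ in the last decimal (printed totals reflect
  unrounded per-sample values, e.g. 10.6 vs a 10.5 column sum).
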