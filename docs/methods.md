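# Methods

## Evidence model

Each assigned ACMG/AMP criterion is resolved against a catalog
(`src/vusquant/data/catalog.tsv`) that records its polarity
(pathogenic/benign), base strength (stand-alone, very strong, strong,
moderate, supporting) and evidence type (population, functional/allelic,
clinical, computational, molecular impact). The catalog covers the
standard criteria plus the Mastermind-style clinical codes
`PPC`/`PPC HET`/`PPC HOM`/`PPC COMHET`, which are treated as pathogenic
clinical evidence at supporting strength because that is the group they
are curated under. Being a plain TSV, the catalog can be extended without
touching code.

A strength-modifier suffix re-weights a criterion without changing its
identity: `_VS`, `_S`, `_M`, `_P` map to very strong, strong, moderate,
supporting. Only `_M` occurs in practice (`PS4_M`, `PP1_M`); the full set
is supported for generality. Combinations without a scoring class (e.g. a
benign code forced to moderate) are rejected at parse time. Parsing is
case-insensitive on the root; two tokens that resolve to the same
criterion at the same strength compare equal regardless of spelling.

Profiles count evidence items by their **applied** strength — `PS4_M`
increments the PM count — and duplicates each count, since curated data
report multiplicities (a variant can carry PM5 twice).

## Points, tiers, VUS bands

Point values per strength class: BA −4, BS −4, BP −1, PP +1, PM +2,
PS +4, PVS +8; absent/indeterminate evidence contributes 0. A variant's
quantification is the count-weighted sum. Two deliberate choices:

* **BA scores −4**, the same as BS, although other published calibrations
  use −8 for stand-alone benign evidence. The points map is injectable
  (`RunConfig.points`) so alternative calibrations can be tested; the
  default is the calibration the analyses were built against.
* **−4 classifies as benign.** The source material is internally
  inconsistent about whether −4 is benign or likely benign; the tabular
  rule (benign ≤ −4, likely benign −3…−1) is adopted. Bins are open-ended
  (≤ −4, ≥ 10), so no clamping is needed.

Totals in the VUS bin (0–5) get a Low (0–1) / Mid (2–3) / High (4–5)
band; the band exists only for VUS totals.

Quantified tiers and curated tiers can disagree (24 of the 4,085 curated
VUS quantify to −1). Both labels are carried side by side and never
merged: curated tiers drive experiment eligibility, quantified tiers
drive transition reporting.

## AlphaMissense categorization

Scores are categorized benign below 0.34, ambiguous up to 0.564,
pathogenic above — the cutpoints of the public release's
likely_benign/ambiguous/likely_pathogenic classes. The printed ranges
(0–0.33 / 0.34–0.564 / 0.565–1) leave gaps at 0.33–0.34 and 0.564–0.565;
scores inside the gaps resolve to benign and ambiguous respectively.
Scores outside [0, 1] are rejected. When a record supplies both a score
and a precomputed category and they conflict, the score wins and the
conflict is logged. Variants missing from an AlphaMissense table are
flagged and excluded from AM-dependent analyses.

A pathogenic category converts to PP3, a benign one to BP4 (both
computational, supporting), an ambiguous one to nothing. Composed with
the points map this gives contributions of exactly +1 / −1 / 0, which is
what makes the per-row accounting of the augmentation experiment close:
eligible variants with ambiguous predictions are modified by nothing and
keep their points.

## Integration experiments

**Augmentation** touches only curated VUS with no computational-type
evidence of any polarity; each gets the single AM-derived item (or
nothing, if ambiguous). Every other variant passes through unmodified.
Per-variant deltas are therefore in {−1, 0, +1}. "Quantification changed"
counts any points delta, including sub-band moves within VUS; tier change
is reported separately. This resolves an apparent tension in the source
narrative between 878 and 934 changed variants: 934 is every points
change among eligible VUS, 878 those that remain VUS afterwards, and 56
those promoted to likely pathogenic.

**Replacement** removes all computational evidence — both polarities, all
multiplicities — from in-scope variants (curated VUS, or the whole cohort
with `scope="all"`), then appends the single AM item. Variants without
computational evidence simply gain the item, so replacement subsumes
augmentation on those. The operation is idempotent: the AM item is itself
computational and is swapped for itself on a second run.

Outcomes carry a tidy per-variant frame (points/tier/band before and
after, modified flag) and a 5×5 tier-transition matrix whose total equals
the cohort size and whose off-diagonal sum is the tier-change count.

## Concordance statistics

The 3×3 contingency table crosses AM category (pathogenic, ambiguous,
benign) with the collapsed curated tier (P/LP, VUS, B/LB). Two binary
collapses are computed:

* **pathogenic vs benign** — the ambiguous row and VUS column are dropped
  and TP/FP/FN/TN are the four corner cells;
* **pathogenic vs rest** — TP is the (pathogenic, pathogenic) cell, FP
  the rest of the AM-pathogenic row, FN the rest of the curated-pathogenic
  column, TN everything else. The verbal description of this scheme in
  the source conflicts with its own printed values; the cell assignment
  that reproduces the printed values is implemented and the discrepancy
  noted here. Under it the derived specificity is 41.5% (rendered 42)
  where 41 was printed — treated as reported-with-truncation and not a
  package claim.

Metrics are kept as raw fractions plus whole-percent renderings
(round half away from zero). A zero denominator yields an absent metric,
never 0 or 100, so degenerate tables stay honest. Chi-square is the
Pearson test without continuity correction (scipy); Spearman uses average
ranks for ties and is absent for constant vectors; the mean CI is the
two-sided Student-t interval.

## Fixtures and the synthetic generator

The real cohort is available only as printed summary tables, which
nevertheless determine per-variant cohorts exactly:

* `fixture_table2a` / `fixture_from_contingency` expand a 3×3 count table
  into records. P/LP and B/LB cells alternate deterministically between
  their two tiers; AM scores are drawn (seeded) uniformly inside the row
  category's interval so categories round-trip exactly.
* `fixture_vus_table5` expands the 20 published VUS evidence-combination
  rows (4,085 variants) with their strength profiles and per-row AM
  benign/pathogenic addition counts. Which concrete code realizes a
  strength count is underdetermined and immaterial to quantification; one
  canonical code per class is used (PS3, PM2, PP1, BP1, BS1), with PP3 or
  BP4 substituted for one supporting item in rows that must carry
  computational evidence (the rows printing no additions). Remainders
  beyond the addition counts get a mid-ambiguous score of 0.45: eligible
  for augmentation but inert. The published benign-addition counts sum to
  239 although the accompanying narrative says 308; the fixture follows
  the printed per-row counts. The fixture reproduces counts, not variant
  identities.
* `fixture_vus_table6` expands the 26 published post-replacement profile
  rows (4,085 variants) used to verify quantification of replacement
  outcomes. Summing its rows puts 50 variants at −1 where the narrative
  says 29; the printed rows are taken as normative.

`simulate_cohort` draws arbitrary-size cohorts from a `CohortSpec`: tier
proportions default to the published 1,576 P/LP : 184 B/LB : 4,085 VUS out
of 5,845 (each collapsed pair split evenly); evidence combinations are
drawn from per-tier weighted templates (the VUS templates are the 20
published rows at their published frequencies; the other tiers use small
hand-picked combinations consistent with their tier's point range); AM
scores come from per-collapsed-tier Beta mixtures parameterized by
(mean, concentration, weight). Defaults give class means of 0.30 (benign),
0.85 (pathogenic) and 0.64 (VUS), with the VUS density bimodal (modes
near 0.2 and 0.8, weights 4/15 and 11/15 chosen so the mean is exactly
0.64) — the component spreads are configuration, not claims. The draw is
a pure function of (spec, seed).

What the generator does **not** emulate: genomic coordinates and
sequence context, per-gene structure, gnomAD frequencies, correlation
between evidence combinations and AM scores within a tier, and the
curator behavior that produced the evidence in the first place. Tests
passing on simulated cohorts therefore validate the pipeline's
bookkeeping and statistics, not predictor performance on real data.

## Problem sizes and numerics

The table fixtures are full-size (4,085 and 5,845 records) and run in
seconds; simulated cohorts default to 5,845. Statistical sanity checks on
simulated data use 3-sigma / 3-standard-error bands at these sizes. All
arithmetic on points is exact integer arithmetic; the only floating-point
numerics are the score draws and scipy statistics.

## Known limitations

* Per-gene metric stratification is supported via the `gene` field but
  has no reference values to test against.
* The full-cohort (scope=all) replacement transition matrix has no
  printed per-variant source to validate against; it is covered by
  conservation-law and idempotence tests instead.
* The Spearman utility is provided for score–score comparisons (e.g.
  AlphaMissense vs REVEL) but no real predictor-score dataset ships with
  the package.
* The original Bayesian posterior framework (prior, odds of
  pathogenicity) is not implemented — only its integer point adaptation.
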