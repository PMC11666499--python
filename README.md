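# vusquant

Points-based quantification of ACMG/AMP variant classifications, with
AlphaMissense predictions injected as computational evidence.

## The problem

Clinical labs classify germline variants into five tiers — benign, likely
benign, variant of uncertain significance (VUS), likely pathogenic,
pathogenic — by combining named ACMG/AMP evidence criteria (PM2, PS4, BP4,
...). The VUS tier dominates curated cohorts and is clinically
non-actionable, so any systematic way to move variants out of it matters.
`vusquant` implements a quantitative workflow for asking whether a modern
in-silico predictor (AlphaMissense) can do that:

1. **Quantify** each variant's evidence with an integer point adaptation of
   the Bayesian pathogenicity framework: BA/BS −4, BP −1, PP +1, PM +2,
   PS +4, PVS +8. The total maps to a tier
   (≤ −4 benign, −3…−1 likely benign, 0…5 VUS, 6…9 likely pathogenic,
   ≥ 10 pathogenic), and VUS totals are stratified into Low (0–1),
   Mid (2–3) and High (4–5) bands.
2. **Categorize** AlphaMissense scores *s* ∈ [0, 1]: *s* < 0.34 benign,
   *s* ≤ 0.564 ambiguous, otherwise pathogenic; a pathogenic category
   becomes PP3 (+1), a benign one BP4 (−1), ambiguous contributes nothing.
3. **Integrate**: an *augmentation* experiment adds the AM-derived item
   only to VUS that carry no computational evidence; a *replacement*
   experiment strips all existing computational evidence and substitutes
   the single AM item. Both report per-variant before/after points, tiers
   and a 5×5 transition matrix.
4. **Benchmark** AM categories against collapsed curated tiers
   (P/LP, VUS, B/LB): 3×3 contingency table, two binary collapses with
   sensitivity/specificity/PPV/NPV, comparison-group labels
   (PATH-path … BEN-amb), chi-square, Spearman correlation.

Because the underlying 5,845-variant cohort (59 neuromuscular/neurological
disease genes) is only published as summary tables, the package ships
deterministic fixtures that expand those tables into per-variant cohorts,
plus a seeded generator for arbitrary-size cohorts with the same
statistical structure. See `docs/methods.md` for the model details.

## Worked example

```python
import vusquant as vq

cohort = vq.fixture_vus_table5()          # 4,085 curated-VUS variants
outcome = vq.run_augmentation(cohort)     # add AM-derived PP3/BP4
pv = outcome.per_variant
changed = pv[pv.points_after != pv.points_before]
print("points changed:     ", outcome.n_points_changed)
print("promoted to LP:     ", int((pv.tier_after == "likely_pathogenic").sum()))
print("newly likely benign:", int((changed.points_after < 0).sum()))
```

prints

```
points changed:      934
promoted to LP:      56
newly likely benign: 12
```

— of the VUS lacking computational evidence, 934 move by one point when
the AlphaMissense item is added; 56 of them cross the 6-point threshold
into likely pathogenic, and 12 drop to −1 (likely benign).
`outcome.transition_counts` holds the full 5×5 tier-transition matrix.

The same pipeline is scriptable from the shell:

```sh
vusquant fixtures table5 --out t5.tsv
vusquant augment --input t5.tsv --out report/
vusquant compare --input <(vusquant fixtures table2a --out /dev/stdout) --out cmp/
```

Subcommands: `quantify`, `classify-am`, `compare`, `augment`,
`replace --scope {vus,all}`, `simulate`, `fixtures`.

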