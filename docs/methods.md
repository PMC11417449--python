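# Methods

nutrikit implements the pipeline by which an epidemiological cohort's food
composition database is revised against a stack of newer reference tables,
and by which the effect of that revision on estimated nutrient intakes is
quantified. This note records the models, the defaults, and the choices
made where the procedure was genuinely open.

## Data model

A composition table holds per-100 g edible-portion nutrient values, one
row per food. A value may be MISSING (`None`), which is strictly distinct
from 0: a food analysed and found to contain no sodium covers sodium; a
food never analysed for sodium does not. Coverage statistics, the source
cascade and the intake estimator all depend on the distinction, so the
CSV dialect preserves it (empty cell = MISSING, `0.0` = zero) and the
writers round-trip values exactly via `repr` formatting.

Nutrient columns carry their unit as a header suffix (`sodium_mg`,
`retinol_µg`) and are validated against a nutrient registry. A unit
mismatch between a file and the registry is a hard error; explicit
conversion (`convert_unit`, exact power-of-1000 scaling within g/mg/µg)
is the only sanctioned path between units. This is deliberate: unit
drift between databases is one of the errors a revision exists to fix.

## Food matching

Foods are matched across tables in tiers:

1. **name_exact** — equal normalized name (Korean compared first, then
   English; NFKC case-fold, punctuation stripped, whitespace collapsed)
   *and* nutritional similarity.
2. **name_exact_substituted** — a same-name candidate exists but is
   nutritionally different; the most similar food overall is substituted
   (the classic example: stewed chicken with skin matched to stewed
   chicken breast).
3. **state_relaxed** — no name matches; the most similar food in the
   same preparation state is taken.
4. **unmatched** — a value, not an error.

Similarity compares energy, carbohydrate, protein, fat and water: every
available pairwise relative difference must be below the threshold
(default 0.20, i.e. the ±20% rule). Design choices where the procedure
is conventionally left to expert judgment:

- **Denominator** of the relative difference is the query food's value;
  a zero query against a positive candidate scores maximal dissimilarity
  (1.0). The query is the food whose intake is being estimated, so it is
  the natural reference.
- **Minimum evidence**: at least 3 of the 5 comparisons must be present,
  otherwise the pair is never similar. This prevents vacuous matches
  between sparsely characterized foods.
- **The rule is applied per nutrient**: any single breach disqualifies.
- **Tie-breaking** among similar candidates: smallest mean relative
  difference, then same preparation state, then lexicographic food id —
  a deterministic, row-order-independent stand-in for expert choice.
  Every non-`name_exact` outcome is flagged `needs_review` and exported
  in the review report, so the human audit step is preserved as data
  rather than replaced by an algorithm.

## Source cascade

Sources are ranked, rank 1 newest. Each (food, nutrient) cell takes the
value of the highest-priority source whose matched food reports it;
otherwise the existing database's value is retained (source id
`"retained"`), a retained MISSING staying MISSING. Provenance records
the supplying source and the match tier per cell, so analyses can
exclude values that arrived through substituted matches. Pure rank
order is implemented; any preference for domestic analytical values over
foreign ones is expressed by how the user orders the registry.

Derived nutrients — vitamin A as RE (retinol + β-carotene/6) and RAE
(retinol + β-carotene/12) — are by default **recomputed after the
cascade** from the resolved retinol and β-carotene, never cascaded
directly, because they are formulas, not measurements; stored vitamin-A
columns in legacy tables are frequently inconsistent with the printed
formula. A flag (`recompute_derived=False`) restores plain cascading
for sensitivity analysis. Recomputed cells carry provenance source id
`"derived"`, a third token alongside registered source ids and
`"retained"`. When exactly one of the two inputs is MISSING the derived
value is MISSING by default; `missing_carotene_as_zero` treats an
unreported β-carotene as 0 instead.

Fiber and vitamin B6 are handled as *semantics*, not arithmetic: crude
versus total dietary fiber, and pyridoxine-only versus total B6, are
different measurements sharing a column. `tag_semantics` labels the
nutrient per database and `semantics_warnings` flags label changes, so a
pre/post comparison can state that part of an intake shift (fiber
severalfold, B6 halved or worse) reflects a definition change.

## Intake estimation

FFQ: intake = frequency weight × portion multiplier × reference serving
(g) × nutrient per 100 g / 100, summed over items. Defaults, both
configurable in the instrument file:

- 9 frequency categories mapped to daily equivalents by the midpoint
  convention: never = 0, 1/month = 1/30, 2–3/month = 2.5/30, 1–2/week =
  1.5/7, 3–4/week = 3.5/7, 5–6/week = 5.5/7, 1/day = 1, 2/day = 2,
  ≥3/day = 3. The daily-equivalent weights of any specific instrument
  can be substituted exactly; these defaults follow standard FFQ
  processing practice and are declared, not claimed to match any
  particular questionnaire.
- 3 portion categories: small = 0.5, medium = 1.0, large = 1.5 × the
  reference serving.
- Seasonal items are answered per quarter and averaged with equal
  quarter weights over a 4-quarter denominator; an unanswered quarter is
  a zero-intake quarter.

24-hour recall: grams × nutrient/100 g summed within a day, averaged
over the available days (an empty day counts in the denominator).

A MISSING composition value contributes 0 to intake and increments a
per-nutrient coverage deficit on the result, because intakes of
sparsely covered nutrients are underestimates and should be reported as
such, not silently treated as complete.

The estimator is linear in the composition values. Consequently, for a
fixed set of responses the population-mean intake difference between two
databases decomposes exactly as Σ_foods (mean daily grams) × Δ(per
100 g)/100 — the identity behind `rank_contributors`, which ranks foods
by |contribution| to a nutrient's mean intake change.

## Pre/post comparison

Per nutrient: paired means ± SE, overall difference (post − pre), ratio
(post/pre × 100), percent change ((post − pre)/pre × 100), and a paired
t-test (t = d̄/(s_d/√n), two-sided p on n−1 df, computed via
`scipy.stats.ttest_rel` and cross-checked in the tests against the
textbook formula). Identical samples (zero-variance difference) report
t = 0, p = 1 by convention. Zero-baseline nutrients report percent
change as undefined (blank), not infinity. No multiple-testing
correction is applied by default, matching common practice of reporting
raw paired-t p-values for descriptive revision tables.

**Percent columns and rounding.** Percent columns are always recomputed
from full-precision means. They are *not* reproducible from a rounded
summary table: for example, fiber means displayed as 5.80 → 24.50 give
(24.5 − 5.8)/5.8 × 100 = 322.4%, whereas the full-precision figure
published alongside those rounded means is 348.4%. Only the absolute
"overall difference" column survives rounding (and even there, several
rows of a typical 2-decimal summary differ by one unit in the last
printed digit because the difference was computed before rounding).
nutrikit therefore treats displayed means as display only.

## Synthetic study generator

The generator emulates a desk-scale revision study with known ground
truth. Defaults: 60 foods, 3 sources, 500 persons, 40 FFQ items, 15%
seasonal items, 80% per-source food coverage, 10% per-cell missingness,
±5% multiplicative noise on source values — sizes chosen so the full
pipeline runs in seconds while every stage (partial overlap,
missingness, priority conflicts, seasonal averaging) is exercised.

Planted revisions mirror the magnitude of real staple-food updates: a
fermented-cabbage staple's sodium 1146.0 → 624.0 mg/100 g, a cooked
grain's fiber 0.1 → 1.2 g/100 g, a legume's fiber 4.0 → 20.8 g/100 g
with vitamin B6 0.54 → 0.05 mg/100 g. They are written into the
rank-1 source exactly and into the pre-database exactly, so their
post-cascade values and intake contributions are known in closed form.

Two constructions make the generator's `truth` map exact rather than
probabilistic:

- Energy and water lie on a multiplicative grid (factor 1.4), so any
  two distinct synthetic foods differ by far more than the 20%
  threshold on at least one reference nutrient even after ±10% noise.
  Cross-food similarity is therefore impossible by construction, and a
  food absent from a source is guaranteed `unmatched` there rather than
  accidentally tier-3 matched to a neighbour. This caps the supported
  noise scale at 0.10 and the food count at 100.
- `truth` assumes name-exact matching. The stress knobs —
  `name_perturbation_rate` (garbled source-row names) and
  `macro_outlier_food_ids` (reference nutrients scaled ×1.5) — exist to
  force non-exact tiers; foods they touch are excluded from `truth`,
  and under heavy stress configurations the guarantee for *other*
  foods' cells is no longer absolute (a garbled or outlying row can in
  principle shadow a neighbour's tier-3 search). Both knobs default to
  off; every truth-based test runs with them off.

What the generator does **not** emulate: real food-name text (names are
templated tokens, so the matcher's name normalization is exercised but
its behaviour on real Korean/English nomenclature is not validated
here); correlated nutrient profiles within food groups; instrument
measurement error; intra-person day-to-day variance structure in
recalls; and the scale of a real cohort (hundreds of thousands of
participants). Passing tests demonstrate the pipeline's arithmetic,
ordering and provenance logic, not the field performance of name
matching on real databases.

## Numerical and degenerate-input conventions

- Floats are written with `repr` and parsed with dot decimal; thousands
  separators are accepted on input, never written.
- Coverage percentages are reported to 1 decimal.
- `relative_difference(0, 0) = 0`; `(0, c>0) = 1.0`; MISSING propagates.
- Empty food subset for coverage, empty name for normalization,
  non-positive baseline for percent change: hard errors.
- All simulation randomness derives from one config seed through named
  `numpy` Generator streams (tables, instrument, responses, recalls), so
  identical configs give byte-identical files.

## Known limitations

- Matching is exact-on-normalized-names; no edit-distance or semantic
  matching, so spelling variants of the same food do not name-match
  (they may still state-relax into place if nutritionally similar).
- The cascade trusts the user-declared source order; it has no notion
  of per-food source preference.
- Only β-carotene contributes to RE/RAE; other provitamin-A carotenoids
  are not modelled.
- The FFQ frequency/portion defaults are conventions, not a claim about
  any specific instrument; studies should encode their instrument's
  actual weights.
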