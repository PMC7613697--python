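# Methods

## Scope and data model

`nbsheets` performs complete accounting of nutrient flows implied by
food-balance-sheet (FBS) style data. The unit of account is a commodity flow
cell: country × year × food category (FC) × element (production, imports,
exports, stock change, feed, seed, processing, other uses, losses, food),
with quantities in 1000 metric tonnes per year. Food categories are organised
in a four-level hierarchy — food products → ~98 FCs → ~21 subgroups (FSGs) →
4 reporting groups (starchy staples, nutrient-dense vegetal, animal source,
other) — with flags for catch-all "other/NES" categories (FCOs), fruits and
vegetables, and heme-iron sources (HSI). The composition table stores
nutrients per 100 g of edible portion, collapsed from food-item matches by
the arithmetic mean per FC; source values missing from composition databases
are set at their lower bound of zero and flagged as imputed, so downstream
uncertainty analyses can exclude those cells.

## Per-capita nutrient values and loss accounting

Annual flows convert to per-capita daily grams using a fixed 365-day year
(`g = Q·10⁹/(pop·365)`); leap years are ignored, consistent with annual
balance-sheet convention. The per-nutrient value of a flow is

    value = g · (1 − refuse) · p · c/100 [ · r_FLW · r_cook ]

Four estimate variants control which adjustments apply:

| variant | processing (p, flour split) | FLW + cooking |
|---|---|---|
| `raw` | no | no |
| `processing_only` | yes | no |
| `flw_cooking_only` | no | yes |
| `final_best` | yes | yes |

`final_best` is the best estimate of apparent intake. Cereal processing
splits grain mass into refined and whole flour using regional refined-flour
proportions and extraction rates (defaults in the fixture: wheat 80% refined
at 72% extraction, whole-grain at 100%); the flours then carry their own
composition records. Other processing factors are mass multipliers from
primary commodity to as-consumed form (they may exceed 1 for brewed
beverages, e.g. tea 119.05; sugar cane 0.11).

FLW retention is `(1−postharvest)(1−retail)(1−consumption)` per region ×
FSG, with post-harvest loss carried only for fish/seafood (a property of the
source data) and a set of exempt subgroups (sugar crops, sugars, pulses,
treenuts, vegetable oils, stimulants, spices, alcohol, animal fats, infant
foods) treated as lossless. FLW applies **only to the food element**: the FBS
"losses" element is a separate supply-side account, and applying survey-based
FLW fractions to it would risk double counting. Cooking retention is
per-(FC, nutrient), defaulting to 1 where no match exists.

Country-year aggregates sum the production element (excluding FCs flagged as
processed foods — vegetable oils, alcohol, butter/cream, fish oils — to avoid
double counting their raw commodities) and the food element (apparent
intake). Composition overrides are config-driven rules, not code: the shipped
defaults blend 70% red palm oil into domestically retained palm oil in a
configurable list of tropical-rain-belt Sub-Saharan countries (imports and
exports stay refined), and replace the rice record with parboiled polished
white rice for Bangladesh.

## Iron and zinc bioavailability

Total iron splits into heme (40% of iron in HSI categories) and non-heme
pools; heme iron is absorbed at a fixed 25%. Non-heme absorption is predicted
by one of three pluggable algorithms operating on a whole-diet profile
(non-heme iron, vitamin C, meat/fish/poultry grams, phytate, calcium, tea
polyphenols): a food-group log-linear regression (Conway), a saturable
enhancer/inhibitor ratio model fitted to test meals (Rickard; the default for
adequacy and intervention outputs), and a complete-diet log-linear equation
(Armah) evaluated at a constant serum ferritin of 21.7 µg/L, the value
corresponding to 40% reference-dose absorption. Predicted fractions are
clamped to (0.001, 1]. All coefficients live in a versioned, checksummed YAML
parameter file (`nbsheets/data/absorption_params.yaml`) with citation
strings; the file is the source of truth and can be re-transcribed or
extended without code changes. The engine enforces and tests the behavioural
contract every algorithm must satisfy — absorption in range, non-increasing
in phytate, non-decreasing in vitamin C — independently of the coefficient
values. Meat/fish/poultry grams are **edible (post-refuse, post-FLW)** mass
on the final-best food element; tea is the only polyphenol source carried,
as a single tannic-acid-equivalent value.

Absorbed zinc follows the updated Miller trivariate saturable model:
with daily zinc (TDZ) and phytate (TDP) supplies converted to mmol (molar
masses 65.38 and 660.04 g/mol),

    TAZ = ½ (A − √(A² − 4·Amax·TDZ)),  A = Amax + TDZ + Kr(1 + TDP/Kp)

with Amax = 0.091, Kr = 0.033, Kp = 0.68 mmol/day. TAZ is bounded by Amax
and by intake, increasing in zinc and decreasing in phytate.

## Requirements (NNRD)

The National Nutrient Requirement Database crosses 1-year age × sex
population counts with DRV tables. Pregnant women are estimated by
duration-weighting annual pregnancy outcomes (defaults: 40/52 year for live
births, 10/52 for induced abortions and miscarriages — editable, since the
surveillance method the convention derives from does not fix them); lactating
women are live births × 6 months. Both are drawn proportionally out of
female cells aged 15–49 (the maternal age allocation is not dictated by the
data, so proportional draw is the neutral choice) and added back as dedicated
DRV groups, conserving total population. Infants 0–5 months can be equated to
the number of exclusively breastfeeding mothers (fraction configurable,
default 1.0).

The weighted per-capita requirement is `Σ count_g · DRV_g / Σ count_g`. The
standard is the AR when the nutrient has one, else the AI; iron and zinc
adequacy of bioavailability-adjusted intakes uses the median physiological
(absorbed) requirement; protein DRVs in g/kg are converted with reference
body weights; carbohydrate/fat can use reference-intake range endpoints. The
weighted requirement always lies within the range of its group DRVs and is
invariant to splitting a cell within one DRV group.

## Adequacy surfaces and comparisons

Percent of requirement is `100·value/requirement`; the percent gap is that
minus 100. Gaps are binned into 10 ordered classes for choropleth-style
reporting: 8 interior half-open bins of width 15 pp with edges at −60, −45,
…, +60, plus open tails. The binning is symmetric about zero so that bin 5 is
[−15, 0) and bin 6 starts at 0; only the class count (10) and width (15 pp)
are externally fixed, so the anchor at zero is this package's choice (an
edge list spanning ±75 would produce 12 classes and is therefore not used).
Nutrient density is expressed per 2000 kcal. Min-max normalization maps a
pooled series (both comparison years together, production and intake
separately) onto [0, 100]. Implausible country-years are flagged by Tukey
fences on per-capita dietary energy (k = 1.5 by default) with both pooled and
per-group scoping available, since the exclusion scope is analyst-dependent.
Paired-series comparison against external estimates returns Pearson and
Spearman correlations with two-sided p-values (via scipy) and elementwise
percent differences `(x − y)/y·100`.

## Interventions

Deficit countries for a nutrient-year are those with per-capita apparent
intake below the per-capita requirement (absorbed basis for iron/zinc, with
the Rickard algorithm as the iron default). The annual deficit is
`Σ (req − intake) · pop · 365` over deficit countries; surpluses elsewhere
never offset it. Vitamin A capsules are sized either by requirement (infant
6–11 month requirements ÷ 30,000 µg per 100K IU capsule + child 1–4 year
requirements ÷ 60,000 µg per 200K IU capsule) or by protocol (1 capsule per
infant + 2 per child annually; "1–4 years" means 12–59 months). Fortified
flour required is `deficit / (level · bioavailability)` — defaults 3 mg/kg
retinol (100%), 35 mg/kg NaFeEDTA (10%), 30 mg/kg zinc oxide (30%) — reported
in 1000 MT/yr and as a percent of annual wheat-flour consumption, rounded
half-up to an integer for presentation with the unrounded value retained.
Percentages above 100 are meaningful and never clamped.

## Monte Carlo uncertainty for catch-all categories

Each draw assigns every FCO a convex combination of its candidate item
compositions with symmetric Dirichlet(1,…,1) weights — uniform over the
simplex, chosen because the sampling law for "many possible combinations" is
otherwise unspecified; the scheme is recorded in output metadata. The
baseline uses the candidate mean (the same collapse rule as the composition
table). Totals for every draw lie within the convex hull of the vertex
(single-candidate) assignments, which the tests verify by exhaustive vertex
enumeration on small candidate sets. Default 1000 draws; a nutrient is
flagged when the half-range exceeds ±5% of baseline. Only composition
identity is varied — quantity uncertainty is out of scope.

## Synthetic worlds and what the tests show

The fixture generator builds complete input bundles: 14 structural FCs plus
adjuster and filler categories across 8 FSGs (cereals with a wheat flour
split, vegetables/fruits/pulses with FCOs, meat and fish as heme-iron
sources, palm oil with a red-palm override, tea with a brewing factor),
3 countries across 3 regions, 2 years, demographics, reproductive statistics
and a synthetic DRV table exercising AR, AI-fallback, physiological and
per-kg bases. Baseline food masses are drawn from dietarily plausible ranges
(staples 100–300 g/day, meat 10–80 g/day) so bioavailability operates in a
realistic regime; FCO food masses are rescaled so the catch-all share of
total food mass matches the requested fraction (default 15%). A target
adequacy profile is honoured by inversion: the generator computes the
requirement, subtracts baseline intake and solves for the mass of a
single-nutrient adjuster food, erroring if the target is infeasible.
Ground truth — the full nutrient table under all four variants, country
aggregates, NNRD, bioavailability, adequacy and deficit summaries — is
computed at generation time by plain scalar loops that share no code with
the engine, making the full-pipeline comparison (at 10⁻⁹ relative) a genuine
oracle test.

These worlds are structural, not calibrated: they do not reproduce real
commodity baskets, FAO magnitudes, item-level composition variance or
reporting noise. Passing tests therefore demonstrate the correctness of the
accounting arithmetic, the weighting, and the algorithm plumbing — not the
empirical accuracy of any particular composition, FLW or DRV table, which
are inputs the user supplies.

## Numerical choices and degenerate inputs

- Population ≤ 0, negative quantities (outside stock change), refuse ≥ 1 and
  non-positive processing factors are hard errors; zero-variance comparison
  series, zero-energy densities and zero-intake bioavailability percentages
  are reported as missing with a warning rather than raised.
- Absorption fractions clamp to (0.001, 1]; the Miller discriminant is
  validated before the square root.
- Gap bins are half-open `[lower, upper)`, so a gap of exactly 0 falls in the
  first surplus bin.
- Fence-based exclusion requires ≥ 4 observations; fewer yields no flags and
  a warning.
- Pipeline problem sizes: test and acceptance runs use 3-country × 2-year
  worlds (~15 FCs, ~13,000 compared values), the scale at which exhaustive
  ground-truth bookkeeping stays exact.

## Known limitations

- Only iron and zinc carry bioavailability adjustments; other nutrients are
  apparent supplies.
- Serum ferritin is a fixed reference value: no individual-level iron-status
  modelling.
- The interaction between the FBS "losses" element and survey-based FLW
  percentages is unresolved upstream; this package applies FLW to the food
  element only and documents the convention.
- Iron-algorithm coefficients ship as an editable transcription of the cited
  models; users wanting a specific published calibration should verify or
  replace the parameter file (its checksum is recorded in run manifests).
- Capsule totals by requirement need infant/child population splits the FBS
  does not carry; the arithmetic is implemented, the split is an input.
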