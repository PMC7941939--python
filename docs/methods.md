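# Methods

`eprlink` re-creates, as a reusable and fully tested pipeline, the data
management workflow of a multi-site maternity trial that measures its
outcomes from routinely collected electronic patient records (EPR): four
extract types per hospital (maternity spine, neonatal, ultrasound,
hospital activity) are pseudonymised on site, quality-checked, harmonised
under a data dictionary, linked into pregnancy episodes, cleaned with a
clinical-plausibility outlier policy, and completed by multiple
imputation. Because real hospital extracts cannot be shared, the package
ships a synthetic EPR generator with full ground truth; every pipeline
stage is validated against that truth or against independent brute-force
oracles.

## Pseudonymisation

The automated study ID is a pure function of the two most reliable
maternal identifiers: NHS number and date of birth. Characters 1–19 are
the decimal rendering (mod 10^19) of a keyed BLAKE2b digest of
`nhs_number | iso_dob`, with a per-deployment salt as the digest key — the
salt realises the "seeded random component" of such schemes while keeping
the mapping deterministic per woman, so one woman keeps one ID across all
her pregnancies (the delivery date deliberately does not enter the
function). Character 20 is a check letter: a position-weighted sum of the
19 body characters, modulo 26, mapped to A–Z. The 19 weights are distinct
odd integers excluding multiples of 13, i.e. all coprime to 26; this
guarantees that any single-digit substitution changes the checksum
(weight × delta ≢ 0 mod 26 for delta 1–9), a property a naive 1..19
weighting would not have (13 × 2 = 26). At 10^5 records the 10^19-point
digest space makes collisions vanishingly rare (birthday bound ≈ 5×10⁻¹⁰);
the collision simulation at n = 100,000 with deliberately narrow date
ranges (DOB within two years, delivery dates within 23 months, to maximise
duplicate dates) is re-run by the test suite and acceptance script and
yields 0 duplicates.

Women lacking NHS number or DOB are never silently hashed: they receive a
manually issued ID in a disjoint namespace (first character `M`, then a
site tag and a 14-digit counter, same check letter). A manual ID denotes a
single pregnancy; a second birth of the same identifier-less woman gets a
fresh ID, because nothing links the two.

Before identifiers are destroyed, DOB yields age at delivery in completed
years (floor), and the postcode — normalised to upper case with a single
internal space — is joined to a deprivation lookup (IMD, LSOA, MSOA). The
bundled lookup is synthetic, a stand-in for the national postcode
directory. The key file (study ID against the identifiable quadruple)
is written only to a key sink that must lie outside the analysis output
tree. Satellite rows whose study ID has no birth on the maternity spine
are dropped, with counts reported.

## NHS numbers

Generated NHS numbers follow the national modulus-11 scheme: nine
identifying digits weighted 10..2, check digit `11 − (sum mod 11)` with 11
mapping to 0 and 10 never issued. The validator is used both by the
generator (all emitted numbers valid) and by pseudonymisation (invalid
numbers route to manual IDs).

## Synthetic EPR generator

One `SiteConfig` per site fixes the cohort size, source-system dialect,
twin rate (default 1.5%), neonatal admission probability (default 10%),
repeat-pregnancy probability within the study window (6%), the fraction of
women lacking identifiers (0.4%, matching the order observed in practice),
missingness mechanisms and defect rates. Maternity and neonatal tables are
wide (one row per baby); ultrasound and activity are long (one row per
scan or appointment/admission).

Ground truth is drawn first in canonical units: maternal height
~ N(1.645 m, 0.068), weight ~ N(68 kg, 13.5), parity ~ Poisson(0.85)
capped at 8, five ethnicity groups with site-typical mixes, gestational
age in completed days (singletons ~ N(279.5, 11), twins ~ N(258, 14),
clipped to 161–300), and birthweight from the linear model documented in
`eprlink.centiles` (mean 3400 g + 14.5 g/day of gestation beyond 280 +
110 g if male − 150 g per twin, SD 390 g). The same model's 10th centile
is the default SGA cut — an explicitly synthetic stand-in for a
customised-centile engine, which is pluggable wherever it is consumed.
Estimated date of conception is delivery date − gestational age + 14 days;
scans and activity events are drawn inside that pregnancy window.
Continuous values are quantised to the precision the site's system renders
(whole inches, whole pounds, 0.1 cm…) *before* being stored as truth, so a
defect-free bundle harmonises back to truth bit-exactly and unit
conversion itself is exact arithmetic.

Three maternity dialects (invented vocabularies, since real site
vocabularies are not public) exercise every harmonisation rule: ISO vs
day-first vs spreadsheet-serial dates; height in cm, feet+inches or
metres; weight in kg, pounds or stones+pounds; gestation as "40+2",
decimal weeks or integer days; distinct category wordings and binary
codings. Neonatal extracts share one national layout at every site, as in
the UK.

Injected defects, each logged cell- or row-exactly in the `TruthTable`:

* `duplicate_row` — an emitted maternity row repeated verbatim;
* `per_pregnancy_multiple` — the second twin's row dropped (the report was
  produced per pregnancy, not per baby);
* `out_of_window_date` — a scan/activity date shifted 8–120 days after
  delivery or 5–100 days before conception;
* `implausible_value` — height/weight/blood-loss/birthweight replaced by a
  value strictly outside the plausibility limits (all true values lie
  strictly inside);
* `affirmative_only_binary` — treated as a column-level gate rather than a
  per-row rate, because the defect is a property of the data-entry form
  (only the affirmative option existed): any positive rate renders the
  site's chronic-hypertension and severe-perineal-trauma columns with
  negatives blanked.

Missingness is MCAR (independent blanking at the configured rate) or MAR:
blanking probability `expit(logit(rate) + site_effect + 0.8·z(driver))`
with a continuous driver covariate and a ±0.5 logit-scale site effect; the
fitted coefficients and driver moments are recorded in the truth table so
tests recompute expected per-row probabilities exactly. Cells carrying an
injected implausible value are protected from blanking so that defect
accounting stays exact. Row conservation holds as
`rows_emitted = rows_true − dropped + duplicated`, with both sides logged.

What the generator does **not** emulate — and hence what green tests do
not establish about real extracts: clinically realistic joint
distributions (height, weight and ethnicity are independent here),
free-text fields, mid-trial system switches, within-woman longitudinal
consistency beyond shared identifiers, and any intervention effect.

## Harmonisation

Every variable is a dictionary entry named `<source>_<stage>_<short>`
(`mat`/`neo`/`uss`/`act`; `r` raw, `h` harmonised, `c` calculated) — one
concrete realisation of the standard "source + degree of management"
nomenclature. Per-site rules carry the raw column name, one of the unit
rules `identity`, `cm->m`, `ft_in->m`, `lb->kg`, `st_lb->kg`, `g->g`,
`ga_string->days` (the last parses "40+2", decimal weeks ≤ 45, or day
counts), a recode map, a binary mode, and the site's date rendering.
Dictionary validation reports nomenclature violations, recode targets
outside the declared category set and unknown sites, naming the offending
entries.

The engine renames each consumed raw column to its `_r_` name and never
touches it again (raw retention), writes the `h` columns, then computes
`c` entries (BMI = weight/height², age at delivery, and the multi-source
epidural merge). Unmapped category tokens and unparseable numerics become
missing but are audited separately from true missing, one audit note per
distinct token with its count. Binary columns follow two rules: where the
site recorded only affirmatives, missing becomes an explicit negative;
where negatives were recorded too, missing stays missing. When one
clinical fact has several source columns, any affirmative wins, a negative
requires at least one recorded negative and no affirmative, and missing
survives only if every source is missing — the engine's implementation is
tested against the exhaustive 3³ truth table. The related
"missing ≈ negative because prevalence matches external audit" case
(severe perineal trauma) is *not* an imputation: it is left to analysis
via the full-mode column, exactly as a `treat_missing_as_negative`
analysis flag.

The audit trail records every transform with its full rule parameters
embedded, plus informational notes; replaying the transform records on the
raw bundle re-executes the identical code path and therefore reproduces
the harmonised output bit-identically. Harmonisation is a fixed point:
re-running on its own output changes nothing, because the engine reads
from `_r_` columns when original raw names are absent. A site that never
collected a variable yields a fully missing column plus a report note
rather than an error.

At one configured site parity arrives only as nulliparous/multiparous:
nulliparous converts to parity 0, multiparous cannot be converted and is
left missing (audited), with the binary multiparity flag harmonised
alongside — this feeds the imputation parity floor below.

## Linkage

Episodes: within a woman (study ID) at a site, distinct delivery dates
sorted ascending receive suffixes `_1, _2, …`; babies sharing a delivery
date share the episode. Rows without a delivery date are flagged
unlinkable. Assignment is invariant to input row order.

Three deterministic rules attach satellites, with EDC = DOD − GA(days) +
14 days computed by exact calendar arithmetic:

* neonatal: same study ID and |neonatal DOB − DOD| ≤ 7 days;
* ultrasound and activity: same study ID and event date in the **closed**
  interval [EDC, DOD] — inclusive endpoints chosen so day-of-delivery
  scans and admissions count; postnatal events never link.

Tie-breaks (possible only through data error) are deterministic and
logged as ambiguous: neonatal prefers the smaller date difference then the
earlier episode; window linkage prefers the latest conception date. Within
an episode, neonatal rows pair one-to-one with baby rows by sex, then
nearest birthweight, then registered birth order. The engine is verified
against brute-force all-pairs filters on whole synthetic sites; the
per-site link report (matched / unmatched / ambiguous, linkage rate per
table) interprets the deliberately low neonatal rate against admission
prevalence, since only admitted babies have neonatal records.

## Quality checks and outliers

The first extract runs seven checks: dataset presence, duplicate study
IDs (classified true duplicate vs multiple birth, with a singleton fetal
count on the woman's antenatal scans overriding an apparent multiple
birth back to duplicate), ID matching across the four datasets, presence
of requested variables, completeness, continuous distributions (range,
median, 5th/25th/75th/95th centiles; linear interpolation between order
statistics, stated in the report header), and date ranges (events may
precede the birth window by up to 301 days, one full pregnancy). The
second download runs the reduced six-item list — resolution of previously
raised issues (omitted when there were none), duplicates, and
completeness/distribution/category-value/date checks focused on the
variables key to the primary outcome — flagging any key variable
completely missing at a site. Problems are report content (pass / warn /
fail with evidence), not exceptions.

Outlier handling is two-stage. Screening computes the ±3/4/5 SD limits
(sample SD of non-missing values) and the 1st/99th centiles and only
*highlights* candidates — these distributional cut-points are arbitrary
and never mutate data. The plausibility limits that do act are fixed by
clinical consensus — age 13–60 years, height 1.20–2.00 m (applied in
metres after harmonisation), weight 30–200 kg, BMI 13–70 kg/m², estimated
blood loss 1–15,000 mL, birthweight 100–6,000 g — and values strictly
outside them become missing; values on a limit are retained. The operation
is idempotent and only ever converts to missing. On synthetic data the
per-variable removal counts equal the generator's injection log exactly;
BMI removals additionally pick up corruption propagated from implausible
height or weight components, which is accounted for separately.

## Multiple imputation

An in-repo chained-equations engine (MICE) produces m = 10 completed
datasets by default. Families: continuous and ordinal-count variables use
Bayesian linear regression (coefficient and variance drawn from the
approximate posterior) followed by predictive mean matching with k = 5
donors, so imputed values are always observed values and ordinal counts
stay integral; binary and multi-category variables use (multinomial)
logistic draws from fitted class probabilities. Categorical draws omit the
coefficient-posterior step — a documented simplification; the continuous
path is fully proper. Ten burn-in cycles per chain by default; the
predictor set defaults to site, trial phase, the outcome triple, maternal
age, parity, height, weight, ethnicity, gestational age and infant sex.

Scoping: variables are fitted within cluster (site) wherever possible,
since case mix varies across maternity units; parity, height and weight
default to across-cluster pooling because individual sites may have
recorded nothing at all — a within-cluster variable that is 100% missing
in any site is a hard error naming the variable and site. RNG streams are
keyed by (imputation, cycle, variable, cluster identity), which makes each
site's within-cluster imputations invariant to how other sites' rows are
ordered, and makes runs reproducible under a fixed seed while observed
cells are restored (and asserted) bit-identical across all m datasets.

The three-category primary outcome (SGA detected on antenatal ultrasound /
SGA not detected / not SGA) is imputed in the chains like any other
variable so it can serve as a predictor, but the analysis outcome is then
recomputed in every completed dataset from its components — birthweight,
gestational age, sex through the pluggable centile function, plus the
episode's scan-flag — overwriting the chained draw. The parity floor runs
afterwards: an imputed parity of 0 for a woman whose binary flag says
multiparous is replaced by the pre-specified value 1 (nulliparity needs no
rule; it converts to parity 0 at harmonisation).

Observed-vs-imputed comparison tables report median [IQR] for continuous
and per-category percentages for categorical variables, per group
(e.g. arm × phase), with imputed statistics averaged over the m datasets —
summary pooling only; Rubin's-rules inference is out of scope.

## Pipeline and provenance

`RunConfig` fixes sites, seed, trial-phase windows (pre-randomisation /
washout / comparison; non-overlapping, validated), paths and imputation
settings; the key sink is refused if it lies inside the output tree,
before any stage runs. Stages execute as pseudonymise → QC → harmonise →
link → duplicate resolution + outlier policy → phase tagging → pooled
imputation, each writing CSV outputs; the manifest records seed, stage
list and SHA-256 digests of every output file, so a re-run under the same
configuration and seed is digest-identical. The two-download workflow is
two runs sharing a key sink, the second consuming the first's QC reports
and switching to the second-download checklist. Raw generated extracts
(which carry identifiers by construction) live only under `raw/`; no
identifier column appears in any artefact downstream of pseudonymisation,
which the tests verify by scanning every emitted file.

## Numerical and statistical conventions

* Percentiles: linear interpolation between order statistics throughout.
* Binomial checks in tests use exact (Clopper-style quantile) bounds at
  the stated confidence.
* The imputation-recovery oracle compares the pooled imputed mean with the
  mean of the blanked true values using the Monte-Carlo SE of that
  difference, σ·√(1/n_missing + 1/n_observed), since both subset means are
  estimates from one finite sample; the criterion is 3 SEs.
* Date parsing accepts ISO, day-first and spreadsheet-serial renderings
  (serials 20,000–80,000, i.e. years 1954–2118); anything else is missing.
* Linear algebra uses a 10⁻⁸ ridge and symmetrised covariance before the
  Cholesky posterior draw; constant design columns are dropped per fit.

## Problem sizes

Defaults used by the test suite and acceptance script, chosen as
desk-scale study conditions: collision simulation at the full n = 100,000;
linkage-oracle sites of ≤ 2,000 pregnancies; imputation recovery on a
5,000-woman cohort with ~20% MAR missingness in height and weight and
m = 10; the end-to-end demonstration on two sites of 250–400 women in
contrasting dialects.

## Known limitations

* The study-ID construction is this package's own design satisfying the
  stated contract (deterministic per woman, salted, check character, 20
  characters, collision-free at 10⁵); production deployments should treat
  the salt as a managed secret.
* The default centile function is a synthetic stand-in; real analyses must
  plug in a validated customised-centile engine.
* Categorical imputation ignores coefficient-posterior uncertainty, which
  slightly understates between-imputation variance for those variables.
* Deterministic linkage only: no probabilistic matching, and no cross-site
  linkage of women who moved between hospitals.
* The generator's marginals are plausible but its joint structure is
  simplistic; passing tests demonstrate pipeline correctness, not clinical
  realism.
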