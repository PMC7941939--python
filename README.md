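# eprlink

Data management for clinical studies that measure their outcomes from
routinely collected electronic patient records (EPR) across many maternity
units. When 13 hospitals export maternity, neonatal, ultrasound and
hospital-activity extracts from 22 different record systems, someone has to
pseudonymise them on site, check their quality, reconcile their vocabularies
and units, link every scan and admission to the right pregnancy, remove
implausible values, and impute what is missing — reproducibly, and without
identifiable data ever leaving the hospital. `eprlink` implements that whole
workflow as a tested Python library and CLI, together with a synthetic
multi-site EPR generator (with full ground truth) on which every stage is
validated.

It is written for trial data managers, perinatal epidemiologists and
methodologists working with heterogeneous routine health data.

## The core methods

**Pseudonymisation.** Each woman receives a 20-character study ID: 19
digits from a salt-keyed BLAKE2b digest of (NHS number, date of birth) —
deterministic per woman, so her pregnancies share one ID — plus one
alphabetic check character (position-weighted checksum mod 26, weights
coprime to 26 so every single-digit substitution is caught). Women without
the required identifiers get manual IDs in a disjoint `M…` namespace, one
per pregnancy. A collision simulation at n = 100,000 with deliberately
narrow date ranges verifies the no-duplicates contract. Age at delivery and
postcode-derived deprivation (IMD/LSOA/MSOA) are computed, then all four
identifiers (NHS number, hospital number, DOB, postcode) are removed; the
key file goes only to a separate key sink.

**Harmonisation.** A data dictionary maps every per-site raw variable to a
standard name `<source>_<r|h|c>_<short>` with unit rules (`ft_in->m`,
`st_lb->kg`, `"40+2" -> 282 days`, …), recode maps, and per-site binary
modes (affirmative-only columns have missing treated as negative; fully
recorded columns keep missing). Multi-source facts merge affirmatively.
Raw columns are always retained, and the audit trail replays to a
bit-identical harmonised dataset.

**Linkage.** Pregnancy episodes are numbered `study_id_n` by delivery date.
Neonatal rows link within ±7 days of delivery; scans and activity link
inside the closed window [EDC, DOD] with EDC = delivery date − gestational
age + 14 days. The engine is tested against brute-force all-pairs oracles.

**Quality.** A 7-item first-download checklist and 6-item second-download
checklist (completeness, distributions, duplicates classified against
multiple births, date ranges), plus a two-stage outlier policy: SD/centile
screening only highlights; clinical-consensus limits (age 13–60 y, height
1.20–2.00 m, weight 30–200 kg, BMI 13–70, blood loss 1–15,000 mL,
birthweight 100–6,000 g) convert strictly-outside values to missing.

**Imputation.** An in-repo MICE engine (m = 10): linear + predictive mean
matching for continuous/ordinal, logistic/multinomial draws for
categorical; variables imputed within cluster wherever possible, with
parity/height/weight pooled across clusters; a three-category primary
outcome (SGA detected / SGA not detected / not SGA) imputed in the chains
but recomputed from components via a pluggable centile function; and a
parity floor replacing imputed 0 with 1 for known-multiparous women.

## Worked example

```python
import datetime as dt
from eprlink.pseudonym import make_study_id, simulate_collisions

sid = make_study_id("9434765919", dt.date(1990, 6, 15), "example-salt")
print("study id:", sid.value)

d = simulate_collisions(
    100_000,
    dob_range=(dt.date(1989, 1, 1), dt.date(1990, 12, 31)),
    dod_range=(dt.date(2017, 1, 1), dt.date(2018, 11, 30)),
    seed=1,
)
print(f"duplicates: {d}/100000")
```

prints

```
study id: 5778503666419803320P
duplicates: 0/100000
```

`5778503666419803320P` is the woman's pseudonym: 19 digits derived from her
NHS number and DOB under the salt, and `P` the check letter that makes
transcription errors detectable. The second line is the collision
simulation: 100,000 women drawn with DOBs inside a two-year band and
delivery dates inside 23 months (to maximise duplicate dates) yield zero
duplicate IDs.

The full pipeline runs from one YAML config:

```sh
eprlink run --config run.yaml          # pseudonymise → QC → harmonise → link → clean → impute
eprlink simulate --sites 2 --women 300 --seed 1 --out demo/   # synthetic raw extracts
eprlink simulate-collisions --n 100000 --seed 1
```

Each stage writes CSV outputs plus a manifest of SHA-256 digests, so a
re-run under the same seed is verifiably identical; identifier columns
never appear downstream of pseudonymisation.

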