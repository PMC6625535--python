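# Methods

## Scope and model

`jjdq` treats a juvenile-justice case extract as a flat table with one row
per arrest ("case"), seven tri-state decision-point fields in a fixed
chronological order, and youth-level grouping derived from a shared youth
identifier, never stored. Quality is measured on three dimensions:
conformance (vocabulary membership of the raw tokens), completeness
(percent missing per decision point), and plausibility (five within-case
incompatibility rules). There is no fitted statistical model; the engine
is a deterministic rule evaluator plus accounting conventions, so the
package's correctness claims are exact (oracle equivalence, partition
identities, conservation) rather than estimative.

## Chronological accounting

Each rule is assigned an **anchor position** — the canonical position of
the decision point at which the pattern first becomes detectable:

* inconsistent petition and implausible case anchor at *petitioned* (3),
  where the diverted/petitioned pair completes;
* excess information anchors at the **earliest** offending later `yes`
  (adjudicated 4, probation 5, confined 6, waived 7);
* inconsistent adjudication anchors at the earliest offending disposition
  (probation 5 or confined 6);
* inconsistent waiver anchors at *waived* (7), where the waiver enters the
  record.

`first_inconsistency` returns the fired rule with the smallest anchor;
ties (possible only between excess information and inconsistent
adjudication, which can share an offending disposition) break by a fixed
priority list: petition > implausible > excess > adjudication > waiver.
The source material defines "first in chronology" and works one example
(petition before waiver) but not per-rule anchors or tie-breaks; these are
this package's conventions, chosen to reproduce that example and to be
deterministic. Detention is order-exempt and participates in no rule.

The per-case first error makes the five rule categories a partition of
flagged cases, so per-rule counts sum *exactly* to the at-least-one count
before rounding. Percentages are rounded half-up to one decimal
(`decimal.Decimal`), matching report-table formatting conventions rather
than banker's rounding.

An off-by-default switch `adjudication_missing_counts` lets a blank
adjudication field trigger the adjudication rule: in practice that error
usually arises from a blank field, but the printed rule is `no`, so the
default follows the printed rule.

## Conformance and parsing

The CSV encoding is this package's convention (the delivering systems'
native formats are not public): empty string is the canonical missing
token; `yes`/`no` case-insensitive and trimmed are the only conforming
non-missing tokens. A nonconforming token is recorded verbatim as a
conformance violation *and* the field set to missing, so completeness and
plausibility still run; conformance is reported separately. Structurally
malformed rows are rejected and counted so that parsed + rejected = total.
Demographic fields are parsed leniently (unknown token or out-of-range age
becomes missing, silently) because the conformance dimension is defined on
the decision points.

## Cleaning

Each rule's resolution strategies mirror the documented real-world causes.
Two need care:

* **Courtesy detention** (implausible case) excludes the case from the
  county's denominator rather than editing fields; exclusions are reported
  alongside the post extract so conservation (post + excluded = pre) is
  checkable.
* **Clerical** (implausible case) defers to full-chronology review: the
  case passes through unchanged, still flagged, and is listed as
  unresolved rather than in the action log.

Resolutions only guarantee that the *resolved* rule stops firing; an edit
can surface a new pattern (correcting a wrongly-filled diversion on a
never-petitioned case yields no+no, an implausible case), so the pipeline
re-audits the post extract instead of claiming global flag-freedom — the
realistic behaviour, since post-cleaning extracts in practice are not
error-free. Under a fixed policy cleaning is idempotent on generator
output with ground-truth scenarios; with hand-written policies that mix
scenarios creating new patterns, a second pass may act again (by design:
each pass resolves what the current audit flags).

## Synthetic generator

The generator is the test bed standing in for confidential county data.
Cases are built from four rule-free trajectory templates (diversion
terminal, petition path, waiver terminal, petition found not-true) fixed a
priori from the meaning of each path — *not* derived from the rule engine,
so "generated extracts are flag-free at zero rates" independently checks
both. Defaults emulate the shape of published county caseloads: four CMS
labels with one dominant vendor (79%), three counties per CMS, ~66% male,
age distribution over 10–18 with mean ≈ 15.2 (SD ≈ 1.6), charge-severity
marginals dominated by serious misdemeanors and status offenses, arrests
per youth = 1 + Poisson(mean − 1) with mean 1.3 (multiple arrests per
youth are documented; the count distribution is not, so a shifted Poisson
was chosen once as the simplest overdispersion-free option). All marginals
are configuration, not constants.

Corruption is layered so that ground-truth labels stay exact:

1. **Missingness** is an i.i.d. per-(case, point) Bernoulli mask drawn
   first and never altered afterwards — per-point completeness marginals
   are exactly binomial at the configured rate, unbiased by the later
   layers.
2. **Rule injection** assigns disjoint case subsets per rule with quota
   `round(rate × n)`, walking a seeded permutation and skipping cases
   whose mask covers a field the pattern needs (at 10% missingness a
   skip is rare; the quota is still filled from later cases). Each
   corruption is minimal and scenario-specific, chosen so that (a) exactly
   the injected rule fires first, and (b) applying the scenario's cleaning
   strategy restores the recorded pre-corruption original field-for-field.
   Two consequences of (b): the unlink scenario's original carries
   `missing` in the offending field (the true value for that arrest is
   unknowable once the mislinked value is removed), and the
   fix-diversion scenario's original carries `petitioned = missing`
   (yes would make the corruption an inconsistent petition, no would make
   the resolved case implausible). The waiver corruption flips
   *adjudicated* rather than a disposition, which would fire the
   adjudication rule at an earlier anchor and steal the attribution.
   Fix-diversion is excluded from the default scenario mix because its
   forced `petitioned = missing` perturbs that point's completeness
   marginal; it remains available in configuration.
3. **Conformance noise** replaces raw tokens (drawn from a small fixed
   vocabulary — only non-membership matters) per decision-point field at
   the configured rate, skipping pattern-pinned fields of injected cases.
   When combined with nonzero missingness the parsed missing rate exceeds
   the mask rate slightly (a noised yes/no parses as missing); the layers
   are calibrated separately, not jointly.

Everything is driven by one `numpy` generator seeded from the config, so a
fixed config reproduces byte-identical extracts.

What the generator does **not** emulate: calendar dates (chronology is
structural, by canonical position), dependence of trajectory on charge
severity or demographics, county-level geography beyond labels, cross-case
linkage errors, and real-world missingness mechanisms (which are
field-and-system specific and far from independent — e.g. an entire field
missing because its users had no stake in filling it). Passing tests
therefore demonstrate the correctness of the detector, accounting and
cleaning contracts — not that real extracts resemble the synthetic ones.

## Reporting

Demographics percents use all cases in the CMS as denominator, stated
explicitly because published tables sometimes use non-missing
denominators. Small-cell suppression replaces any count in (0, threshold)
— default 10 — with a `<10` sentinel and blanks its percent; zeros are
shown. Suppression applies to demographic cells only; rule and
completeness percentages are never suppressed. A CMS that supplied no
values for a dimension renders blank cells there, and a CMS without a
post-cleaning extract renders blank post columns. Post-cleaning
percentages use the exclusion-reduced denominator (courtesy detentions are
out of the county's totals); the conservation report keeps the excluded
records so the original denominator is recoverable.

## Problem sizes

The test suite and acceptance script audit up to 10,000 cases per run
(enough for the 3-standard-error binomial bands at 5% injection and 10%
missingness to be decisive at ±0.65 and ±0.9 percentage points), exercise
the rule engine exhaustively over all 3⁷ = 2,187 point assignments, and
check the suppression invariant over several hundred small random
extracts; the full suite completes in well under a minute.
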