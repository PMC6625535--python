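# jjdq — data-quality auditing for juvenile-justice case extracts

`jjdq` audits tabular case-management extracts from juvenile-justice
systems along the three data-quality dimensions used for electronic health
records — **conformance**, **completeness** and **plausibility** — applies
per-scenario resolutions to the inconsistencies it finds, and renders
pre/post-cleaning comparison tables. It is aimed at analysts preparing
county case-management-system (CMS) extracts for research use or for
linkage with other administrative data, where undetected logical
inconsistencies bias everything downstream.

## The data model

One row is one **case** (a single arrest of one youth; a youth may
contribute several cases). Each case records seven **decision points** in
chronological order — diverted (1), detained (2), petitioned (3),
adjudicated delinquent (4), placed on probation (5), confined (6), waived
to adult court (7) — each valued `yes`, `no` or `missing`. Detention is
*order-exempt*: it can occur at any time, so it participates in no
plausibility rule.

The three quality dimensions:

* **Conformance** — raw tokens outside `{yes, no, ""}` for a decision
  point. They are tallied verbatim and the field is treated as missing so
  the other checks still run.
* **Completeness** — percent of cases missing each decision point.
* **Plausibility** — five within-case logical inconsistencies:

  | rule | predicate |
  |---|---|
  | Inconsistent petition | diverted = yes ∧ petitioned = yes |
  | Implausible case | diverted = no ∧ petitioned = no |
  | Excess information | diverted = yes ∧ any later point (adjudicated, probation, confined, waived) = yes |
  | Inconsistent waiver | waived = yes ∧ any of adjudicated/probation/confined = yes |
  | Inconsistent adjudication | adjudicated = no ∧ (probation = yes ∨ confined = yes) |

  `missing` matches neither `yes` nor `no`, so it never fires a rule.

**First-inconsistency accounting.** A case can violate several rules, but
only one error is recorded per case: the rule whose pattern appears
earliest in the case chronology (smallest anchor position; fixed priority
order breaks ties). A case with both an inconsistent petition (anchor 3)
and an inconsistent waiver (anchor 7) is counted once, as an inconsistent
petition. This makes the per-rule categories a partition of the flagged
cases, so per-rule counts sum exactly to the "at least one inconsistency"
count — an identity the package enforces and tests.

Each rule has resolution strategies mirroring how the errors arise
(prosecutor overturned a diversion, courtesy detention for another county,
a later arrest mislinked onto a diversion, …); a declarative
`ResolutionPolicy` selects the scenario per rule or per case, and
`clean_extract` applies it, conserving records exactly (post + excluded =
pre).

Because real extracts are confidential, the package ships a synthetic
generator (`jjdq.synthetic`) that emulates their shape — four CMS vendors,
multiple arrests per youth, realistic demographic marginals — and injects
missingness, rule violations and nonconforming tokens at configurable
rates with exact ground-truth labels, so detector recall and first-error
attribution can be scored precisely.

## Worked example

```bash
cat > quality_demo.yaml <<'EOF'
n_youth: 2000
seed: 11
missingness_rates: {CONFINED: 0.30, WAIVED: 0.10}
injection_rates:
  IMPLAUSIBLE_CASE: 0.08
  INCONSISTENT_ADJUDICATION: 0.05
  INCONSISTENT_PETITION: 0.04
  EXCESS_INFORMATION: 0.01
EOF
jjdq simulate --config quality_demo.yaml --out-dir .
jjdq audit    --input extract_pre.csv --out audit.json
jjdq clean    --input extract_pre.csv --out-dir .
jjdq report   --pre extract_pre.csv --post extract_post.csv --out-dir .
```

The audit of the 2,608 generated cases reports 469 flagged cases
(`at_least_one: 18.0%`), split by first error exactly as injected —
implausible case 8.0%, inconsistent adjudication 5.0%, inconsistent
petition 4.0%, excess information 1.0%, inconsistent waiver 0.0% — and
completeness of 30.3% missing for confined and 10.3% for waived (the
injected 30%/10% rates plus sampling noise). Cleaning with the default
per-rule strategies resolves or excludes every flagged case
(2,399 post records + 209 courtesy-detention exclusions = 2,608), and
`report_plausibility.csv` shows the per-CMS pre/post columns:

```
inconsistency,CMS1 pre,CMS1 post,CMS2 pre,CMS2 post,CMS3 pre,CMS3 post,CMS4 pre,CMS4 post
Inconsistent petition,3.7,0.0,5.2,0.0,4.0,0.0,2.5,0.0
Implausible case,6.2,0.0,6.5,0.0,8.4,0.0,7.5,0.0
Excess information,0.0,0.0,0.0,0.0,1.1,0.0,1.9,0.0
Inconsistent waiver,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Inconsistent adjudication,3.7,0.0,7.2,0.0,5.0,0.0,5.0,0.0
At least one inconsistency,13.6,0.0,19.0,0.0,18.5,0.0,16.9,0.0
```

In every column the rule rows sum to the at-least-one row (pre-rounding),
because first errors partition the flagged cases. Omitting `--post`
renders blank post columns — the pattern of a system that never supplied a
second extract. The demographics table suppresses any count between 1 and
9 as `<10` to limit re-identification (`--suppress-threshold` configures
this).

The same pipeline is available as a library: `generate`, `audit`,
`clean_extract`, `build_report` operate on `Extract` objects read and
written with `read_extract` / `write_extract`.

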