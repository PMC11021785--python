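# dilinet

Pharmacovigilance signal detection over spontaneous adverse-event report
databases, with a drug–gene mechanism-analysis companion. The package was
built around a concrete use case — screening CDK4/6 inhibitors
(palbociclib, ribociclib, abemaciclib) for drug-induced liver injury
(DILI) signals in FAERS-style data — but every stage is generic:

- **Disproportionality analysis.** For a drug *D* and an event set *E*
  (one preferred term, or an expansion of a high-level term or a
  standardized query), reports are cross-tabulated against all other
  drugs in the database:

  |              | event in *E* | other events |
  |--------------|:---:|:---:|
  | drug *D*     | a | b |
  | other drugs  | c | d |

  The reporting odds ratio is ROR = (a·d)/(b·c) with the Woolf interval
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); a single zero cell
  triggers the Haldane–Anscombe +0.5 correction. A pair is a **positive
  signal** when a ≥ 3 and the lower 95% CI bound exceeds 1.
- **MedDRA-style hierarchy.** A license-free CSV dialect of the PT → HLT
  hierarchy plus SMQ term sets (narrow/broad scope, comprehensive queries
  expanding through child SMQs by set union).
- **Report handling.** Validated CSV reading, case-level deduplication
  (keep the highest case version; ties by receipt date then report id),
  primary-suspect filtering with drug-name normalization and brand-name
  synonyms, and descriptive cohort tables with time-to-onset quartiles.
- **Mechanism analysis.** Drug-target × disease gene-set intersection, a
  STRING-style PPI network thresholded at combined score ≥ 0.7 with
  degree-ranked hub genes, and hypergeometric pathway over-representation
  (GMT input) with Benjamini–Hochberg adjustment.
- **Synthetic databases with planted ground truth.** A generator that
  emulates spontaneous-report structure (duplicate case versions, missing
  demographics, onset dates, multi-suspect and concomitant drugs) under a
  logistic-odds event model, so the reporting odds ratio of any
  drug×event pair equals a configurable planted multiplier ω. This makes
  the whole chain testable without access to FAERS.

Intended users: pharmacoepidemiologists and methodologists who want a
tested, scriptable replica of the OpenVigil-style ROR workflow, and a
sandbox in which detection rules can be calibrated against known truth.

## Worked example

Everything below runs offline from the built-in synthetic fixture bundle
(seed 1), which plants, among others, ω = 3.5 on ribociclib × "alanine
aminotransferase increased":

```sh
dilinet fixture --out bundle --seed 1
dilinet signals --reports bundle/reports.csv --dict bundle/dict \
    --drug palbociclib --drug ribociclib --drug abemaciclib \
    --level smq --code SMQ_LIV_COMP \
    --synonyms bundle/synonyms.csv --out signals.csv
```

`signals.csv` then contains (display-rounded columns shown):

```
       drug         code  n  ror_2dp  ci_low_2dp  ci_high_2dp  positive
abemaciclib SMQ_LIV_COMP 16     1.26        0.71         2.25     False
palbociclib SMQ_LIV_COMP 22     1.12        0.68         1.86     False
 ribociclib SMQ_LIV_COMP 35     2.70        1.72         4.24      True
```

Reading: 35 deduplicated ribociclib reports carry at least one PT from
the comprehensive liver-injury query; relative to all other drugs in the
database, liver events are reported 2.70 times more often (95% CI
1.72–4.24), and because n ≥ 3 and the lower bound exceeds 1 the pair is
flagged as a signal — the planted ribociclib effect is recovered, while
the two drugs without a planted liver effect stay negative.

```sh
dilinet describe --reports bundle/reports.csv --dict bundle/dict \
    --drug ribociclib --smq SMQ_LIV_COMP \
    --synonyms bundle/synonyms.csv --out table3.json
# -> 35 of 121 ribociclib reports (28.9%) -> table3.json
```

The same library calls are available in Python (`dilinet.scan_signals`,
`dilinet.summarize_cohort`, …), and `dilinet run --config study.json`
executes the whole chain — simulate/load, clean, three-level signal scan,
descriptive tables, PPI network, pathway enrichment — writing a manifest
with per-stage counts and output checksums.

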