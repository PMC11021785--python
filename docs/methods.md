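# Methods

## Disproportionality model

The unit of counting is the deduplicated report. For drug *D* and event
PT-set *E*, a report falls in the drug margin if **any** of its retained
primary-suspect (PS) assertions names *D* after normalization, and in the
event margin if **any** of its PTs lies in *E*. ANY-match semantics at
report level prevent one report from being counted once per member PT of
a standardized query; consequently a + b + c + d always equals the number
of retained reports, and an SMQ-level scan is identical to a scan over
the union of its member PTs. The comparator is all other drugs in the
database, not a restricted class.

ROR = (a·d)/(b·c). The Woolf interval is computed on the log scale with
se = √(1/a + 1/b + 1/c + 1/d) and z = 1.96, which makes the point
estimate exactly the geometric mean of its bounds — the identity the
acceptance checks exploit against independently published rows. When any
single cell is zero, the Haldane–Anscombe correction adds 0.5 to all four
cells before estimation; the reported count n is always the raw a, so the
n ≥ 3 positivity criterion is unaffected by the correction. An empty drug
margin (a+b=0) or comparator margin (c+d=0) has no meaningful estimate
and raises a degenerate-margin error, which scans capture per pair
without aborting. No multiplicity adjustment is applied across a scanned
term grid; scan output retains negative rows so that the absence of a
signal is visible, and display columns are rounded half-up to two
decimals as regulatory tables are.

## Hierarchy dialect

Real MedDRA distributions are licensed, so the dictionary is a
project-defined four-file CSV dialect (pt/hlt/smq/smq_children). PT codes
map to exactly one HLT; SMQ membership is many-to-many with per-member
narrow/broad scope. The default query scope is `combined` (narrow plus
broad) — the maximal-sensitivity reading appropriate for a comprehensive
liver-injury search — with `narrow` available as a flag. Codes are opaque
case-sensitive identifiers; names are display labels and may repeat.

## Deduplication

Spontaneous-report databases carry follow-up versions of the same case.
Per case the retained report is the highest `case_version`, ties broken
by latest receipt date then lexicographically greatest report id — a
deterministic restatement of the convention that the latest FAERS case
version supersedes earlier ones. Within the retained report, repeated
(drug, PT) assertions collapse to one, keeping the strongest role
(PS > SS > C > I). Provenance counters (read = retained + superseded +
collapsed) are conserved and surfaced in the pipeline manifest. Cases
naming two or more study drugs as primary suspect are reported as a
diagnostic but never removed.

## Descriptive summaries

Cohorts are unique retained reports of one drug restricted to an event
set. Percentages are computed on the cohort size (half-up, two decimals;
the record fraction at one decimal). Time-to-onset is event onset minus
therapy start in whole days; reports missing either date are counted as
missing, and a negative interval — which the reader already rejects at
ingestion — is defensively routed to the missing count rather than
clamped. Quartiles use the median-of-halves convention with the overall
median excluded from both halves at odd n, so {10, 20, 30} yields exactly
(10, 20, 30); published tables rarely state their quartile rule, so one
convention is fixed and used everywhere.

## Synthetic database generator

The generator is a first-class, tested component, not a fixture dump. Its
event model is chosen so that the ROR is the estimand: each event's odds
for a case are baseline odds p/(1−p) multiplied by the planted ω of every
exposed drug carrying one. Because exposure indicators of other drugs do
not enter a pair's odds unless they carry their own multiplier, the
asymptotic ROR of a planted pair equals ω exactly, which an independent
logistic-odds simulation at n = 10⁶ confirms in the tests.

Structural features emulated: exposure as independent Bernoulli draws per
drug (cases drawing no drug are assigned one, weighted by the exposure
probabilities; an extra suspect drug is added with a configurable
probability, producing multi-suspect cases); a concomitant (role C)
non-suspect drug carrying no planted effect, so role filtering has
observable consequences; duplicate case versions for exactly
⌊duplicate_fraction·n⌋ cases, re-emitted with incremented version and
later receipt date; missing sex/age/onset at configurable rates; onset
intervals log-normal around a per-drug median (σ = 1 on the log scale)
with therapy start ≤ event onset by construction; demographics and
outcomes drawn from fixed categorical menus resembling a breast-cancer
pharmacovigilance cohort (90% female, age ≈ N(62, 12²) clipped to
[18, 95], outcomes led by "Other" and "Hospitalization").

Every case yields at least one event row: cases drawing no modelled event
receive a background filler PT. Reports without events do not exist in
spontaneous-report databases; dropping such cases instead would bias the
ROR away from the planted ω.

Determinism: all draws come from one seeded numpy Generator in a fixed
vectorised order — every quantity is drawn for all cases before
missingness masks apply — so identical config + seed reproduces the
report table byte for byte. This is implemented as a single shared stream
with a fixed draw schedule rather than per-case substreams; it is equally
deterministic and substantially faster for the replicate studies below.

What the generator does **not** emulate: reporting dynamics over time
(stimulated reporting, the Weber effect), narrative text, real MedDRA
coding practice, correlated missingness, or exposure denominators —
FAERS has none, and fixture magnitudes (exposure probabilities, baseline
event rates) are conventions, not calibrations to any real database.
Passing calibration therefore shows the estimator chain is correct under
its own model, not that real-data signals are unbiased.

## Calibration studies

Two standing experiments exercise the full simulate → deduplicate →
contingency → ROR chain on a minimal two-drug, one-event replicate
design (monitored drug exposure 0.15, comparator 0.50, baseline event
rate 0.05, 10% duplicated cases so deduplication stays on the tested
path):

- **Null**: ω ≡ 1, 2,000 cases, 500 replicates. The positive-signal rule
  (n ≥ 3 and CI lower bound > 1) is nominally a one-sided 2.5% test plus
  the count criterion; the observed false-positive rate (≈ 2–3%) is
  asserted against a loose 7% bound.
- **Recovery**: ω = 4, 5,000 cases, 200 replicates. The 95% CI covers
  4.0 in ≥ 90% of replicates (observed ≈ 95%) and the median ROR sits
  within [3.2, 5.0] (observed ≈ 4.0).

Replicate counts and sizes are the package's standing study conditions;
each replicate receives an independent child seed derived from one master
seed via numpy's SeedSequence.

## Gene network and enrichment

Gene symbols are trimmed, uppercased and optionally alias-mapped (a thin
stand-in for full identifier curation, which is out of scope). The PPI
edge dialect accepts STRING-style combined scores on either the 0–1000
integer or 0–1 real scale, auto-detected from the maximum score and
overridable; the network is undirected, thresholded at 0.7 by default,
with duplicate/reversed edges collapsed to the maximum score and
self-loops dropped. Hub ranking uses node degree (ties alphabetical) —
the one topological metric the workflow calls for; isolated intersection
genes carry no centrality signal and are excluded from ranking by
default, retained in exports behind a flag. The specific intersection
size and hub identities of any real analysis depend on annotation
database versions, so tests assert structure (intersection ⊆ inputs,
degree bookkeeping) rather than gene lists.

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) (evaluated via scipy's log-space survival function; exhaustive
enumeration for all universes N ≤ 12 is the test oracle) with
Benjamini–Hochberg step-up adjustment across all tested pathways — the
field's default when no correction is named; a flag disables it.
The default universe is the union of pathway members, the most
reproducible convention when the true background is unstated; an explicit
background list is accepted. Results rank by adjusted p, ties by larger
overlap then name, truncated to the top 20 by default, with a bubble-plot
export (x = overlap count, size = gene ratio, color = adjusted p).

## Numerical and interface choices

- Rounding for display is decimal half-up (not banker's), matching
  printed regulatory tables; full-precision columns are always written
  alongside.
- Drug-name normalization: case-fold, whitespace collapse, iterative
  stripping of common salt suffixes, then an alias→canonical synonym
  table (brand names).
- The pipeline validates every referenced path before any work, writes
  each stage's outputs as it goes, and records SHA-256 checksums in the
  manifest; two runs under the same config and seed agree checksum for
  checksum (manifest timings naturally differ).
- CLI exit codes: 0 success, 1 usage/configuration error, 2 data error.

## Problem sizes

The standard fixture bundle simulates 800 cases (≈ 1,500 assertion rows)
with four planted pairs — large enough that planted signals of ω ≥ 3.5
are detected while unplanted pairs stay negative, and small enough that
the whole suite, including the 700 calibration replicates, runs in about
a minute. The calibration experiments use the replicate sizes stated
above as their study conditions.

## Known limitations

- Signal detection implements the ROR only; PRR, IC/BCPNN and EBGM-type
  shrinkage estimators are out of scope.
- No probabilistic record linkage: deduplication trusts case ids.
- No multiplicity control across scanned term grids (flagged in output
  metadata by retaining all rows rather than filtering).
- Degree is the only network centrality; betweenness/eigenvector metrics
  and community detection are extensions.
- The synthetic generator's realism limits are listed above; conclusions
  about real FAERS extractions require the real data.
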