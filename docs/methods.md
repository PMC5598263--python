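# Methods

## The analysis model

The unit of analysis throughout is the **compound**, not the study.  A
compound's findings — spread over studies in different species, routes
and durations, over dose and sex groups, and over timepoints — are
condensed into one call per endpoint by the any-positive rule: the
compound is *positive* for an endpoint if at least one matching finding
row is flagged treatment-related, *negative* if matching rows exist but
none is flagged, *not examined* if no matching row exists.  The
treatment-related flag is always the expert judgement captured from the
original study report; the package never re-derives it retrospectively
from group means or incidences, so every downstream statistic inherits
the original pathologists' and toxicologists' reading of the raw data.

Consequences of this rule worth keeping in mind:

* A compound counts as "examined" for an organ when *any* of its studies
  examined that organ (any-study reading; nothing in the capture model
  distinguishes the alternative).
* Direction-specific quantitative endpoints (e.g. ALT *increase*) are
  positive only on flagged rows with the matching direction, but a
  direction conflict across studies makes the compound positive for each
  specific direction independently.
* Rows attached to control groups never contribute positive calls; a
  flagged control row is tolerated with a validation warning because it
  is self-contradictory.
* A missing treatment-related flag is read as "not flagged": the capture
  model records a judgement only where the report states one.

## Ontology mapping and roll-up

Verbatim report terms are mapped to preferred terms through a synonym
table; matching is case-insensitive after whitespace collapsing (legacy
reports are too heterogeneous for exact-case lookup; the normalization
is documented and reversible, and an unmapped verbatim is returned as
unmapped, never guessed).  Preferred terms form a forest; organ and
named-finding endpoints match a term together with all its descendants,
so findings recorded at different granularity aggregate correctly and a
compound is counted once per ancestor regardless of how many descendant
terms it hit.  Coverage is reported over distinct normalized verbatims
by default (with a per-record basis as an option), and term-level
analyses silently exclude unmapped verbatims pending curation.

## Secondary-target dose filter

Within each study, an organ's flagged histopathology rows are removed
iff the lowest dose carrying a flagged finding in that organ is strictly
greater than the lowest dose carrying *any* flagged histopathology
finding in the study.  The minimum is taken over histopathology findings
only, doses are the normalized mg/kg/day values pooled across sexes
(the capture model does not resolve the pooled-versus-per-sex choice;
pooled is the simpler reading and is what is implemented), and studies
with incomparable or missing doses are excluded from the comparison —
retained unfiltered — with a logged warning.  Organ co-occurrence is
then counted as compound-level intersections of positive calls among the
filter's surviving positives.

## Biomarker concordance

The evaluation base set for a parameter-versus-organ confusion matrix is
the set of compounds with **both** endpoints examined; for parameter
combinations all three endpoints must be examined, which is why combined
totals differ from single-parameter totals.  Metric conventions:

* MCC is 0 when any row or column marginal is zero (keeps rankings
  total);
* sensitivity/specificity are percentages, reported to 1 dp (MCC to
  4 dp) and *undefined* — not zero — on an empty marginal;
* the two-tailed Fisher exact p sums the hypergeometric probabilities of
  all tables with the observed margins whose probability does not exceed
  the observed table's ("sum of small p"; two-sided exact tests differ
  between definitions, so this choice is stated explicitly).  The
  implementation enumerates the support with exact integer binomial
  coefficients, so ties are resolved exactly rather than through a
  floating-point epsilon; the test suite checks it against both an
  independent rational-arithmetic oracle and `scipy.stats.fisher_exact`.
* Parameter ranking keeps parameters with p < 0.001 (the fixed filter;
  no further multiple-testing correction) sorted by MCC descending, ties
  broken lexicographically for determinism.
* Combining two calls: agreement passes through; disagreement resolves
  to negative under negative emphasis and to positive under positive
  emphasis.

## Structure queries

The default benzoic-acid pattern is the free (protonatable) carboxylic
acid on a benzene ring, SMARTS `c1ccccc1C(=O)[OX2H1]` — esters and
aliphatic acids do not match; the pattern is an argument everywhere.
Compounds without a resolvable structure (confidential entries) are
excluded from prevalence denominators with a logged count; when RDKit or
structures are unavailable the generator's boolean substructure column
is an equivalent chemistry-free path.  The co-occurrence query reports
the finding rate among pattern-bearing compounds against the rate over
all queried compounds; the attached Fisher exact test is an extension
beyond the direct comparison of the two proportions and is labelled as
such in its output.  Multi-parameter criteria are conjunctions evaluated
at the compound level ("concomitant" = co-occurring within one
compound's data, which may span studies and species); a per-study strict
mode is available as a flag.  An empty criteria list is the vacuous
conjunction and returns every compound.

## Synthetic data generator

Real shared repeat-dose databases are confidential, so the generator is
the package's source of test data, and its defaults *are* the study
conditions: 1214 compounds, 99% with histopathology data of which 61%
are positive, 79% with liver examined of which 42.5% are liver-positive,
duration-conditional GLP mixes (66% of <20-day studies non-GLP /
GLP-in-part / unknown; 77% of 20–35-day studies GLP), per-parameter
clinical-chemistry flag probabilities conditional on liver status taken
from the reference single-parameter concordance table (ALT 0.396/0.140,
ALP 0.328/0.104, …), a 1.1% benzoic-acid prevalence, and
treatment-related haematological findings in 18% of substructure-bearing
versus 26% of all compounds.  Species/route/duration mixes are
configuration values chosen to be realistic for this study population
(rat-dominant, oral-dominant, ~45% short-term studies); no external
value is asserted against them.

Design choices:

* one pseudo-random stream per table, all spawned from the master seed,
  so output is byte-deterministic and adding a table does not perturb
  earlier tables;
* compound-level latent states (liver status, per-parameter flags,
  haematology status, substructure) are drawn once per compound and
  propagated to every study, matching the compound-level analysis unit;
* the overall histopathology-positive rate is achieved by giving
  non-liver-positive compounds extra-organ positives at the
  complementary rate `q = (p_pos − p_liver_eff)/(1 − p_liver_eff)`, with
  extra organs drawn by weights that make liver the top-ranked organ and
  spleen/kidney/thymus the next tier in every duration bin;
* the substructure is encoded both as a benzoic-acid-containing SMILES
  and as a boolean column, keeping the chemistry dependency optional.

What the generator does **not** emulate: per-animal records, severity
progression, pharmacokinetics, correlated multi-organ syndromes beyond
the planted liver/biomarker and substructure/haematology links, and
inter-parameter correlation of clinical-chemistry flags.  That last
simplification means the *any-parameter* clinical-chemistry positive
rate implied by ten conditionally independent parameters comes out
higher than the corresponding marginal in real data of this kind, where
hepatic parameters co-flag; the per-parameter rates, which the
concordance analysis actually consumes, are planted exactly.  Passing
tests therefore demonstrate correctness of the pipeline's logic and
estimator behaviour under known truth — not that real archives satisfy
the generator's independence assumptions.

Two dedicated constructors plant exact scenarios: a secondary-target
scenario (236 thymus-positive compounds of which 100 are secondary by
dose construction, with 74/73 liver/spleen co-occurrence among the 136
survivors) and a case-study database in which exactly *n* compounds
satisfy the triple haematology criterion (haemoglobin down, platelets
and reticulocytes up), one hit carrying a dog study and two an "EP1
receptor antagonist" annotation, while every other compound is made to
fail at least one criterion.

## Numerical and I/O conventions

Tables are UTF-8, comma-delimited, RFC-4180-quoted CSV with a header
row; verbatim text round-trips byte-exact; booleans serialize as
`true`/`false`.  Doses are mg/kg/day; timepoints are integer days from
first dose (day 1 = first dosing day); duration bins are the closed
integer intervals [1,19], [20,35], [36,81], [82,101], [102,364],
[365,∞).  Rankings break ties lexicographically.  Validation collects
*all* violated invariants and reports the offending rows; it never
rejects a valid row.

## Problem sizes

The test suite and the acceptance script exercise generated databases of
120–5000 compounds (2000 for biomarker-recovery checks, repeated over 20
seeds; 5000 where a 1.1% prevalence needs a usable subset; 1000 for the
planted 20-hit query), sizes at which every planted rate is recoverable
within three binomial standard errors while the whole suite stays fast.

## Known limitations

* The secondary-target filter assumes comparable dose units within a
  study; it does not convert between dosing metrics.
* Coverage percentages depend on the chosen basis (distinct terms vs
  records); both are exposed because either reading is defensible.
* `not_examined` is inferred from the absence of finding rows; a study
  that examined an organ and recorded nothing at all is
  indistinguishable from one that never examined it.
* The exact Fisher enumeration is O(support) per table — instantaneous
  at compound-level sizes, but not intended for tables with totals in
  the millions.
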