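# Methods

## Data model and ingestion

The unit of analysis is the *integrated report row*: one (case, drug,
preferred term) combination, produced by inner-joining the DRUG and REAC
tables on the case identifier.  A case reporting `k` drugs and `m`
preferred terms (PTs) therefore contributes `k·m` rows.  Deduplication is
defined at the row level — at most one row per (case, drug, PT) triple,
first occurrence kept — which makes the operation idempotent and
order-stable.  When a `caseversion` column is present, only the highest
version of a case contributes, mirroring the versioned-submission
convention of FAERS.  Whether row-level or whole-case deduplication is the
"right" reading of duplicate-removal in spontaneous-report practice is
genuinely open; row-level was chosen because it reproduces a row-unique
integrated table without discarding distinct drug–event information, and
the choice is isolated in one function.

The monotherapy filter drops every row of any case listing two or more
distinct normalized drug names, regardless of suspect/concomitant role
codes.  Restricting to suspect drugs only is a plausible alternative; the
role column is retained so callers can pre-filter if they prefer.

Drug names and PTs are normalized to uppercase with collapsed internal
whitespace and serve as case-insensitive keys throughout.  DEMO ages are
converted to years via the `age_cod` unit (YR/DEC/MON/WK/DY/HR); converted
values outside [0, 130] years are kept as records but their age is set to
missing and counted, so demographic analyses silently exclude them while
report counting does not.

## Disproportionality statistics

For drug *D* and term set *S*, the 2×2 table counts integrated rows:
`a` = rows of *D* with PT ∈ *S*, `b` = *D*'s other rows, `c`/`d` = the same
split over all other drugs; the four cells always sum to the table size.

* **ROR** = (a·d)/(b·c).  When any cell is zero, Haldane's correction adds
  0.5 to *all four* cells (and only then) — tables without zeros are left
  untouched.  The correction feeds the point estimate and CI only.
* **CI**: Woolf's log-scale interval, exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
  z = 1.96 by default.  The Woolf method is the pharmacovigilance
  standard; nothing in the screen depends on the specific CI method.
* **Fisher exact p**: two-sided by the point-probability
  (minimum-likelihood) convention — the sum of hypergeometric point
  probabilities not exceeding the observed table's, with a 1+1e-7 relative
  slack against floating-point ties.  The test always runs on the raw
  integer cells; passing a corrected table is a hard error, because the
  continuity correction must never precede the exact test.  Two-sided
  conventions for Fisher's test differ across software; this one matches
  the common default and is verified in the test suite against exact
  rational enumeration for every table with N ≤ 40.
* **Flag rule**: ln ROR > 0 ∧ p < α ∧ (a+b) ≥ `min_drug_reports`.
  Defaults α = 0.05, 1000 reports for drug eligibility and 2000 reports
  for term eligibility in the matrix stage.  No multiplicity correction is
  applied by default (raw-p screening is the norm in signal detection); a
  Benjamini–Hochberg switch exists but is off.
* p-values are floored at 1e-300 before −log₁₀ so volcano coordinates stay
  finite.

Stratified RORs (sex, route) compare each stratum's cases against the
union of the other labelled strata; unlabeled cases are excluded.  The age
comparison reports group medians and a two-sided Wilcoxon rank-sum p
(`scipy.stats.ranksums`, no continuity correction, so identical groups
give p = 1 exactly); medians rather than means because report ages are
heavy-tailed.  Class summaries pool member drugs' (a, b) cells into one
class-level 2×2 against all non-member reports — one of several defensible
pooling schemes, chosen for its symmetry with the per-drug table.

## Scaffold cohort

The steroid pharmacophore is expressed as an any-carbon (`[#6]`), any-bond
(`~`) SMARTS over the fused 6-6-6-5 tetracyclic carbon skeleton (17 atoms,
20 bonds).  Element-only atoms and order-free bonds mean saturated,
Δ4-unsaturated and aromatic-ring systems all match, and no stereo or
charge constraints apply.  Matching is plain subgraph search (RDKit);
unparseable SMILES are a distinct *invalid* outcome, never a silent
non-match.  Names that denote classes, combinations or botanical extracts
rather than one structure are force-included via an allowlist, since such
entries do occur in reporting databases and carry reports.  Structure
standardization (salt stripping, tautomers) is deliberately out of scope;
the name→SMILES dictionary is expected to resolve one representative
structure per name.

## Synthetic reports and identifiability

Each simulated case draws one drug uniformly from the catalog, or exactly
two distinct drugs with probability `polypharmacy_prob` ("2+" is truncated
at two to keep the monotherapy arithmetic closed-form).  Given the case's
drugs, each PT *t* enters independently with probability
`o_t·m/(1+o_t·m)` where `o_t` is the baseline odds and *m* the product of
the drugs' odds multipliers θ(d, t).  Sex is Bernoulli, age is a normal
truncated to [0, 110] years (unit fixed to years), routes are sampled per
(case, drug), therapy start dates are uniform over a window, and with
probability `duplicate_prob` a case's reaction rows are emitted twice so
each of its integrated rows appears exactly twice (duplicating the drug
rows as well would square the join multiplicity).

Under this model the expected deduplicated monotherapy table is exact:
a mono case with drug *d* has probability `(1−polypharmacy)/n_drugs` and
contributes `q(d,t)` expected rows for term *t*, giving closed-form 2×2
cells and an expected ROR that converges to θ as baselines shrink.  This
is what makes the generator an *oracle*: recovery is judged against the
model's own expectation, not against θ nominally.

What the generator does **not** emulate: within-case PT correlation
(syndromes), name misspellings, time-varying reporting rates, stratified
confounding, fuzzy duplicates with new case ids, and cases with zero
reported events are possible (real reports always list at least one
reaction).  Passing calibration therefore demonstrates correctness of the
statistical machinery under independence, not robustness to real-world
reporting artifacts.

Calibration conditions (fixed in `thrombosignal.calibration`): the null
study uses 100 drugs × 20k cases × 100 seeds with the eligibility
threshold at 1 report so the statistical rule itself is what is measured —
at desk-scale counts a 1000-report filter would simply empty the screen.
Because the flag demands ln ROR > 0 *and* p < α, and Fisher's test is
conservative on discrete tables, the realized null rate sits well below α;
the documented property is the upper bound α + 3·SE.  The recovery study
plants θ = 3 on one (drug, term) pair at 50k cases (≈2000 monotherapy
cases for the target drug) and checks the 100-seed mean ROR within 10% of
the expectation.

## Multivariate stage

Matrix cells are ln ROR of (drug, single PT) tables — the same metric as
the screen, applied per term; Haldane guarantees finite cells.  PCA is on
the correlation scale (columns standardized to zero mean, unit variance;
population ddof) — sensible because per-term ln-ROR columns have
heterogeneous variances; covariance-scale PCA is available by flag.
Component signs are fixed by making each component's largest-|loading|
positive, and zero-variance columns are dropped with a warning.  With all
components retained the standardized matrix is reconstructed to 1e-8.

Ward clustering uses `scipy`'s Ward.D2 update on Euclidean distances over
the first three component scores (raw scores, not rescaled).  Merge
heights are monotone; the merge order is verified in tests against a
greedy from-scratch minimizer of the within-cluster sum-of-squares
increase for n ≤ 7.  Tie-breaking among exactly equal merge costs is
delegated to `scipy`'s deterministic ordering; all shipped analyses use
continuous scores where ties have measure zero.  Trees are exported as
nested JSON (round-trippable), Newick with branch lengths equal to merge-
height differences, and a flat drug/cluster/score table.

The venous-vs-arterial contrast compares a component's *term loadings*
split by SMQ scope (mixed excluded) with Welch's unequal-variance t.
Loadings rather than drug scores are compared because the scope labels
live on terms; a drug-level reading is possible but conflates a drug's
overall signal strength with its vessel preference.  Which component
carries the contrast is an empirical question — components are identified
by their loadings, not their rank — so `identify_vessel_axis` labels the
fitted component with the largest venous/arterial mean-loading gap before
the test is run.

## Term-set and class fixtures

`data/thrombosis_terms.tsv` ships 52 thrombosis PTs; the arterial/venous/mixed
scope labels are this package's own SMQ-based curation (ambiguous terms
such as EMBOLISM default to mixed) and are user-overridable by supplying a
different TSV.  `data/steroid_classes.tsv` maps the analysis steroids to 18
pharmacological classes by physiological function, receptor specificity
and ATC membership.  Both files are curated inputs, not ground truth.

## Problem sizes

The shipped studies run at 20k–50k cases and 10–100 catalog drugs — sizes
chosen so each calibration study completes in a couple of minutes on one
CPU while leaving per-cell counts in the tens-to-hundreds, the regime
where Haldane correction and exact-test discreteness actually matter.
Full-database extracts (10⁷–10⁸ rows) exercise the same code paths; the
pandas/numpy implementation is vectorized per stage and the per-drug exact
tests scale linearly in the cohort size.

## Known limitations

Reporting-odds ratios measure reporting disproportionality, not risk;
no causal reading is implied.  Dose and treatment duration are not
modelled.  The monotherapy filter trades power for attribution clarity.
The independent-PT event model understates the correlation structure of
real syndromic reporting, which inflates the apparent stability of PCA
axes relative to real data.
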