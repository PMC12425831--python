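# Methods

This note records the models, conventions and numerical choices behind
`faersig`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and deduplication

A *case* is one patient incident, identified by `caseid`; it may be filed
repeatedly, each filing being a *version* with a unique `primaryid` and an
FDA receipt date `fda_dt`. Child tables (drug mentions with role codes,
event PTs, outcome codes, therapy episodes, indications) reference the
version. Dates are `YYYYMMDD` integers with a precision marker; partial
dates (`YYYYMM`, `YYYY`) are padded to the first day/month and flagged so
onset analyses can exclude them.

Deduplication keeps, per caseid, the version maximizing `(fda_dt,
primaryid)` lexicographically; a missing `fda_dt` ranks below any date
(an undated version can never be "the highest receipt date"). Child rows
are taken only from the surviving version, never merged across versions —
the retained object is *the report*, singular. Deletion lists address
cases, not versions, so they are applied after version selection; the
order cannot change the surviving caseid set and this sequencing is
cheaper. Parsing is header-driven with a synonym table
(`ISR`→`primaryid`, `CASE`→`caseid`, `gndr_cod`→`sex`) so pre-2012-layout
files harmonize without positional assumptions; malformed rows are
tallied per file, never silently dropped.

## Cohort and descriptive conventions

A case enters the cohort when at least one drug mention has a kept role
code (default: primary suspect only, `PS`) and a name — brand or active
ingredient — containing a target pattern as a case-insensitive substring
(defaults `TIOTROPIUM`, `SPIRIVA`; substring matching catches formulation
suffixes such as "SPIRIVA RESPIMAT").

- **Counting units.** "Patients" are deduplicated cases; "AE reports" are
  distinct case-PT pairs. A case contributes each distinct PT once,
  whatever the number of duplicate REAC rows.
- **Bins.** Age (years): `<18, [18,45), [45,65), [65,75], (75,∞)` plus
  unknown — the boundary values 65 and 75 both fall in the 65–75 bin, as
  the conventional bin labels force. Weight (kg): `<73, [73,88), [88,104],
  (104,∞)` plus unknown. Onset (days from suspect-drug therapy start to
  event date): `[0,30], (30,180], (180,360], (360,720], (720,∞)`;
  negative, missing or date-imprecise onsets are excluded and tallied.
- **Percentages** are computed with exact rational arithmetic and rounded
  half-up to two decimals. Sex/age/weight/occupation blocks use the
  patient denominator. The outcome block counts one severity-prioritized
  outcome per case (order `DE > LT > HO > DS > CA > RI > OT`, i.e. death
  down to "other") and reports its own event-level denominator alongside:
  spontaneous-report outcome tallies are event-level in general, and the
  patient denominator would misstate them.
- **Annual mean** = floor(cohort size / number of calendar years in the
  reporting window), with years taken from the survivor's `fda_dt` (the
  receipt date is always present and defines the quarter a version is
  published in; event dates are frequently missing).
- PT→SOC aggregation uses a user-supplied two-column mapping (MedDRA is
  licensed and not bundled); each PT maps to exactly one SOC (the primary
  SOC convention), conflicts are fatal, and unmapped PTs are routed to an
  explicit `unmapped` sentinel rather than dropped. SOC-level signal
  tables reuse the PT machinery on distinct case-SOC pairs.

## The four disproportionality statistics

Each observed term gets the 2×2 table (a, b, c, d) of distinct case-term
pairs split by target drug × term presence; margins are shared across
terms, so N is constant at a given level.

**ROR.** `ad/(bc)` with the Woolf log-scale interval
`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`. When any cell is zero the
Haldane–Anscombe +0.5 correction is applied to all four cells (ROR only),
keeping estimate and interval finite.

**PRR and χ².** `[a/(a+b)]/[c/(c+d)]`. The conventional definition is
preserved for zeros: `c = 0` with `a > 0` yields +∞, flagged, not
corrected. The accompanying chi-square is the 2×2 statistic with the
Yates continuity correction `Σ (max(|O−E|−0.5, 0))²/E` by default; plain
Pearson is available behind a flag because both conventions circulate in
the pharmacovigilance literature and either can be matched.

**BCPNN IC.** The information component is
`IC = log₂ p₁₁/(p₁·p₂)` for the joint and marginal reporting
probabilities. Following the standard shrinkage setup, the posteriors are
independent Betas: `p₁ ~ Beta(1+n₁, 1+N−n₁)`, `p₂ ~ Beta(1+n₂, 1+N−n₂)`
(priors Beta(1,1) against total 2), and `p₁₁ ~ Beta(1+a, γ−1+N−a)` with
`γ = (N+2)²/((n₁+1)(n₂+1))` chosen so the prior expectation of IC is
zero. Rather than the historical delta-method approximation, the package
evaluates the *exact* posterior moments of IC under this model via the
digamma/trigamma identities for log-Beta moments
(`E[ln X] = ψ(α) − ψ(α+β)`, `Var[ln X] = ψ′(α) − ψ′(α+β)`); the two agree
asymptotically, but the exact form is verifiable against a
posterior-sampling oracle to Monte-Carlo precision, which is how the test
suite checks it. `IC025 = E[IC] − 1.96·sd` by default; a −2·sd variant is
provided since both conventions appear in practice.

**MGPS EBGM.** Counts follow `a ~ Poisson(λE)` with
`E = (a+b)(a+c)/N`, and λ carries a two-component gamma mixture prior.
Hyperparameters maximize the marginal likelihood — a two-component
negative-binomial mixture across all terms of a level — starting from the
classic initialization (α₁=0.2, β₁=0.1, α₂=2, β₂=4, p=1/3), in
log/logit-transformed space (Nelder–Mead followed by an L-BFGS-B polish).
The transformed parameters are boxed to ±12 (shapes and rates in
[e⁻¹², e¹²]): when the empirical λ distribution is nearly discrete — as in
synthetic corpora with a single planted odds multiplier — the likelihood
climbs indefinitely toward point-mass components, and the box keeps the
optimizer finite while still admitting essentially degenerate priors. A
fit that stops on the box or fails the optimizer's own criterion is
flagged `converged=False` with the best-found parameters; a
single-component mode (p pinned at 1) gives a plain gamma-Poisson
shrinker. The posterior of λ given a is again a two-component gamma
mixture (shapes αⱼ+a, rates βⱼ+E, weights ∝ component marginal
likelihoods); `EBGM = exp(Σ wⱼ (ψ(αⱼ+a) − ln(βⱼ+E)))` and EBGM05 inverts
the mixture CDF at the 5th percentile by Brent's method bracketed between
the component quantiles. EBGM05 is defined as the posterior 5th
percentile (the standard published "EB05") even where source material
loosely calls it "the lower limit of the 95% CI"; a 2.5th-percentile mode
is provided so either reading can be matched.

**Joint rule.** A term is a signal iff `a ≥ 3` *and* ROR CI lower
bound > 1 *and* (`PRR ≥ 2` and `χ² ≥ 4`) *and* `IC025 > 0` *and*
`EBGM05 > 2`. Rankings are descending by frequency (a) or by EBGM05, ties
broken by the other key then by term name. No multiplicity correction is
applied — the joint conjunction is the screening filter.

## The synthetic reporting system

The generator produces the statistical structure the pipeline consumes,
not a behavioral model of FAERS. Per case: a suspect drug is drawn from a
Zipf(1) frequency law over `n_drugs` (the target drug occupying a
configurable rank, default 5 of 50, ≈4% of cases); the number of event
draws comes from a geometric law (mean 2, matching ≈2 distinct PTs per
patient in large reporting cohorts) truncated at 8; PTs are drawn with
replacement from a categorical and collapsed to the distinct set. For
target-drug cases, each planted PT's weight is multiplied by its
reporting-odds multiplier ρ and the weights renormalized. Drawing with
replacement and collapsing (rather than sequentially without replacement)
is deliberate: the analyzed unit is the distinct case-PT pair either way,
but the collapse law has an exact closed form for the expected 2×2 cells,
`P(case includes PT j) = E_k[1 − (1−w_j)^k]`, on which the
parameter-recovery and law-of-large-numbers tests rest. In a symmetric
two-PT, one-draw configuration the expected ROR of the planted PT equals
ρ exactly; in rich configurations the realized ROR sits somewhat below ρ
because the tilt also raises the target cohort's total event count — the
closed form quantifies this exactly, and tests compare realized against
expected cells rather than against ρ.

Around the event core: receipt dates are uniform over the configured
window (2004–2024) and define quarterly packaging; event dates trail
receipt by an exponential lag (mean 30 d); onsets are lognormal
(median 100 d, σ=1.4 on the log scale) with ≈65% of therapy-start dates
missing, matching the heavy attrition of evaluable onsets in real
extracts. Demographics follow the shape of large respiratory-drug
reporting cohorts (≈64% female among known, age ≈ N(70,12²), ≈50% age
missingness, ≈80% weight missingness, consumers ≈74% of reporters, one
dominant reporting country). With probability 0.1 a case is emitted as
2–3 versions: duplicates perturb only `fda_dt`/`primaryid` (and
occasionally one demographic field), never the event list, so the dedup
contract is isolated from signal logic; one third of duplicates share the
survivor's receipt date to exercise the primaryid tie-break. 2% of cases
land on deletion lists. The ground-truth sidecar records every emitted
version, the retention-rule survivor (computed independently of the dedup
module), the target caseids and the planted multipliers.

What the generator does **not** emulate: stimulated reporting and secular
trends, duplicate cases filed under different caseids, free-text drug
name noise, correlated event co-occurrence, covariate-dependent reporting
(age/sex-specific AEs). Passing tests therefore demonstrate correctness
of the pipeline's logic and calibration under a known law — not that any
particular real-world signal is true.

## Problem sizes and test design

Unit tests run at small n with fixed seeds. The heavier validations use:
synthetic corpora of 100,000 cases × 50 drugs × 200 PTs with 20 planted
PTs at ρ=5 (recovery) and none (null calibration), each aggregated over
10 seeds in the test suite and 3 seeds per arm in the acceptance script;
1,000 random tables for the closed-formula cross-checks; 4×10⁶ draws per
table for the IC posterior-sampling oracle (the standard error of the
sampled sd uses the fourth-moment form, since IC draws are skewed);
adaptive quadrature and CDF inversion for the EBGM oracle at 10⁻⁶
relative tolerance; 500 random version sets against a brute-force argmax
oracle for dedup. Descriptive arithmetic is validated by reconstructing a
patient-level cohort whose marginals equal published counts of a
65,045-patient tiotropium reporting cohort and checking the summarizer
reproduces the published percentages exactly; two cells of the published
table (age >75: printed 17.23 vs exact 17.22; weight 88–104: printed 3.14
vs exact 3.13) disagree with exact arithmetic on their own counts by one
unit in the last digit and are asserted at the exactly recomputed value.

## Known limitations

- Exact-caseid deduplication only; probabilistic cross-caseid duplicate
  detection is out of scope.
- No stratified or covariate-adjusted MGPS, no time-scan statistics.
- Country strings are uppercased tokens, not harmonized ISO codes.
- The empirical-Bayes prior is fitted per level (PT or SOC) on the
  analyzed terms only; with very few terms the fit is weak and EBGM05 is
  conservative.
- Headline signal values from the full 2004–2024 FAERS corpus are not
  reproducible at desk scale; validation is therefore exact descriptive
  arithmetic plus calibrated synthetic recovery, as described above.
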