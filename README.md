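# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event report data.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect millions of drug adverse-event (AE) reports filed by
consumers, clinicians and manufacturers. Pharmacovigilance screening asks,
for a given drug, which AE terms are reported *disproportionately* often
compared with the rest of the database. `faersig` implements that workflow
end to end for people who analyze FAERS quarterly extracts: reading the
`'$'`-delimited quarterly tables (DEMO / DRUG / REAC / OUTC / THER / INDI /
RPSR), collapsing multi-version cases, building a target-drug cohort (the
default configuration targets tiotropium, a long-acting muscarinic
antagonist used in COPD and asthma), aggregating MedDRA Preferred Terms
(PTs) into System Organ Classes (SOCs), and computing four standard
disproportionality statistics per term with a joint positivity rule.

Because the real corpus is tens of gigabytes and MedDRA is licensed, the
package also ships a synthetic FAERS generator with *known ground truth* —
planted drug-event associations of chosen reporting-odds strength,
duplicate case versions, deletion lists, demographic missingness — so the
entire pipeline is testable offline.

## The statistics

For each term, distinct case-term pairs form a 2×2 table: `a` target-drug
pairs with the term, `b` without; `c`/`d` the same for all other drugs.
With N = a+b+c+d and E = (a+b)(a+c)/N the count expected under
independence:

- **ROR** (reporting odds ratio): `ad/(bc)`, 95% CI
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` (Woolf); Haldane–Anscombe +0.5
  on all cells when any cell is zero.
- **PRR** (proportional reporting ratio): `[a/(a+b)]/[c/(c+d)]` with the
  2×2 chi-square (Yates-corrected by default; plain Pearson via a flag).
- **BCPNN IC** (information component):
  `IC = log₂ P(drug,event)/(P(drug)·P(event))` under Beta posteriors with
  the standard shrinkage priors; the package reports the exact closed-form
  posterior mean and the lower bound `IC025 = E[IC] − 1.96·sd[IC]`.
- **MGPS EBGM** (empirical-Bayes geometric mean): `a ~ Poisson(λE)` with a
  two-component gamma mixture prior on λ fitted by marginal maximum
  likelihood across all terms; `EBGM = 2^E[log₂ λ | a]` and `EBGM05` is the
  posterior 5th percentile of λ.

A term is a **signal** only when all criteria hold simultaneously:
`a ≥ 3`, ROR CI lower bound > 1, `PRR ≥ 2` with `χ² ≥ 4`, `IC025 > 0`, and
`EBGM05 > 2`.

## Worked example

Generate a 50,000-case synthetic corpus with two planted associations at
odds multiplier 5, run the pipeline in memory, and print the flagged
signals:

```python
from faersig import GeneratorConfig, CohortSpec
from faersig.synthetic import generate
from faersig.pipeline import analyze

config = GeneratorConfig(
    n_cases=50_000,
    seed=7,
    planted_associations=(("pt_0001", 5.0), ("pt_0002", 5.0)),
)
corpus = generate(config)
result = analyze(corpus.as_quarter_data(), corpus.meddra_map,
                 spec=CohortSpec(name_patterns=("TIOTROPIUM",)))

counts = result.manifest["counts"]
print(f"{counts['versions_read']} versions -> {counts['cases_after_deletions']} cases "
      f"({counts['target_cases']} in the tiotropium cohort)")
for row in result.pt_rows:
    if row.is_signal:
        print(f"{row.term}: a={row.a} ROR={row.ror:.2f} "
              f"({row.ror_ci95[0]:.2f}-{row.ror_ci95[1]:.2f}) PRR={row.prr:.2f} "
              f"chi2={row.chi2:.1f} IC025={row.ic025:.2f} EBGM05={row.ebgm05:.2f}")
```

Output:

```
56046 versions -> 49014 cases (2120 in the tiotropium cohort)
pt_0001: a=84 ROR=4.51 (3.56-5.71) PRR=4.44 chi2=184.4 IC025=1.56 EBGM05=3.96
pt_0002: a=104 ROR=4.82 (3.89-5.97) PRR=4.73 chi2=250.3 IC025=1.67 EBGM05=3.96
```

The two planted terms — and only they — pass the joint four-criterion
rule, with point estimates near the planted odds multiplier (slightly
below 5 because tilting the event law toward the planted terms also
inflates the target cohort's overall event count).

The same workflow is available from the shell:

```sh
faersig simulate --out corpus/ --n-cases 50000 --seed 7
faersig run --quarters corpus/ --meddra corpus/meddra_map.tsv \
    --drug TIOTROPIUM --out results/
```

which writes the baseline demographics table, annual counts, the
time-to-onset histogram, PT- and SOC-level signal tables, top-30 rankings
by frequency and by EBGM05, and a manifest recording the attrition flow
(versions read → cases after dedup → after deletions → cohort).

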