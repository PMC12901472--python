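# adcea — cost-effectiveness of anti-amyloid therapy in early Alzheimer's disease

`adcea` is a Markov cohort cost-effectiveness model comparing the two
FDA-approved anti-amyloid-β antibodies — lecanemab and aducanumab, each
added to standard of care (SoC) — against SoC alone for early Alzheimer's
disease (mild cognitive impairment or mild dementia due to AD), from the
US healthcare-system perspective.  It is written for health-economics and
HTA analysts who want a transparent, scriptable, fully tested
re-implementation of this comparison: every modelling convention is an
explicit, logged parameter, and every figure-ready table is a CSV.

## The model

A five-state cohort model — MCI, mild, moderate and severe dementia due
to AD, and death — advances in 1-year cycles over a lifetime horizon.
Annual SoC transition probabilities are modified per strategy by a
treatment hazard ratio (lecanemab HR 0.69 on MCI→mild and mild→moderate;
aducanumab HR 0.83 on MCI→mild), death is resolved first as a competing
risk from age-banded all-cause mortality scaled by stage mortality HRs,
and state occupancy accrues discounted (3%/yr) life-years, QALYs and
costs (drug, administration, ARIA monitoring, outpatient, inpatient).
Pairwise incremental cost-effectiveness ratios,

ICER = ΔCost / ΔQALY,

are compared with a willingness-to-pay threshold of $150,000/QALY.
Uncertainty is handled with a one-way (tornado) analysis over printed
parameter ranges and a 1,000-draw probabilistic sensitivity analysis
(lognormal HRs, beta utilities/probabilities, gamma costs; moment-matched
to mean = base value, SD = SE) summarized as cost-effectiveness
acceptability curves.  See `docs/methods.md` for the full specification
and the rationale of every frozen convention.

## Worked example

```python
import adcea

params = adcea.default_parameters()          # the shipped configuration
strategies, comparisons = adcea.base_case_frames(params)
print(comparisons.to_string(index=False))
```

prints

```
              comparison  incremental_cost  incremental_ly  incremental_qaly  icer_per_ly  icer_per_qaly label  cost_effective_at_wtp
      Aducanumab vs. SoC         100307.70            0.08              0.08   1183179.92     1252561.45                        False
       Lecanemab vs. SoC         130632.68            0.33              0.33    396315.49      398240.32                        False
Lecanemab vs. aducanumab          30324.98            0.24              0.25    123856.41      122306.42                         True
```

Reading the rows: adding aducanumab to SoC buys 0.08 QALYs for ~$100k
(ICER ≈ $1.25M/QALY) and lecanemab buys 0.33 QALYs for ~$131k
(ICER ≈ $398k/QALY) — neither is cost-effective against SoC at
$150,000/QALY.  Head to head, lecanemab gains 0.25 QALYs over aducanumab
for ~$30k more, an ICER of ≈ $122k/QALY, below the threshold: lecanemab
delivers better value than its predecessor even though neither clears the
bar against standard of care.

The same pipeline is scripted as numbered analyses:

```bash
python analysis/01_base_case.py         # incremental table above
python analysis/02_tornado.py           # one-way sensitivity, all comparisons
python analysis/03_psa_ceac.py          # 1,000-draw PSA + CEAC crossings
python analysis/04_convention_sweep.py  # why the shipped conventions are frozen
```

or driven from the shell via the `adcea` CLI
(`adcea base-case|osa|psa|vbp|synth --help`), which supports per-parameter
overrides such as `--override utility.MILD=0.55` and writes an audit dump
plus a run log of every resolved assumption.

## Layout

```
src/adcea/          parameters, markov engine, economics, sensitivity,
                    synthetic instances, CLI
src/adcea/data/     the shipped model configuration (YAML)
analysis/           numbered narrative drivers writing results/*.csv
tests/              unit, property and acceptance suites
docs/methods.md     model specification, conventions, limitations
```
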