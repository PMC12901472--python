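# Methods

## Model

`adcea` implements a five-state Markov cohort model of early Alzheimer's
disease (AD) from the US healthcare-system perspective.  The states are
mild cognitive impairment (MCI) due to AD, mild, moderate and severe
dementia due to AD, and death; death is the unique absorbing state, and
MCI + mild dementia constitute the treated "early AD" population.  The
cohort advances in 1-year cycles over a lifetime horizon (age cap 100
years, or until the alive fraction falls below 1e-6).  Three strategies
are compared: standard of care (SoC) alone, aducanumab + SoC, and
lecanemab + SoC.

Per cycle and alive state, the transition matrix is built as:

1. **Death.** The annual all-cause mortality probability of the band
   containing floor(cohort age) — 0.02 / 0.05 / 0.16 for ages 65–74 /
   75–84 / ≥85 — multiplied by the state's mortality hazard ratio (MCI
   1.82, mild 2.92, moderate 3.85, severe 9.52) and capped at 1.
2. **Progression.** Each alive→alive annual probability of the SoC arm
   (e.g. MCI→mild 0.32, mild→moderate 0.36, moderate→severe 0.40) has the
   strategy's treatment hazard ratio applied (lecanemab 0.69 on MCI→mild
   and mild→moderate; aducanumab 0.83 on MCI→mild; all other transitions
   HR 1), then is scaled by (1 − p_death): death is resolved first as a
   competing risk, which guarantees a valid row for every input (e.g.
   severe-stage mortality at age ≥85 saturates at 1).
3. **Residual.** The diagonal absorbs the remaining mass; the
   construction makes it nonnegative.

Rewards attach to start-of-cycle occupancy, discounted at 3%/year with
cycle 0 undiscounted.  Life-years accrue on the alive fraction; QALYs
weight occupancy by state utilities (MCI 0.73, mild 0.69, moderate 0.53,
severe 0.38; death 0).  Costs per cycle are outpatient ($3,237.26) plus
inpatient ($17,935.84) on the alive fraction, plus — for treated arms —
drug price, administration and ARIA (amyloid-related imaging
abnormalities) monitoring on the treated fraction.  The untreated SoC arm
accrues its own ARIA monitoring cost ($66.73/yr) on the alive fraction.
Treatment costs accrue while the cohort occupies early AD
(`treatment_rule: while_early_AD`); a `lifetime` rule is available.
ARIA monitoring costs are the printed annual dollar values (lecanemab
$154.82, SoC $66.73); the generating formula 3 × MRI unit cost × annual
ARIA rate is exposed as `economics.aria_annual_cost`, but the two printed
dollar rows imply slightly inconsistent MRI unit prices (back-solved
$344.04 vs $370.72), so the dollars are taken as authoritative and the
ARIA occurrence rates enter the model only as bookkeeping.

The incremental analysis divides unrounded discounted cost deltas by
unrounded effect deltas (ICER per QALY and per LY), labels dominance, and
flags cost-effectiveness against a willingness-to-pay (WTP) threshold of
$150,000/QALY.  A closed-form threshold-price solver
(`economics.value_based_price`) exploits the linearity of discounted cost
in the annual drug price.

## Frozen modelling conventions

Several structural choices are not determined by the published inputs
alone.  `analysis/04_convention_sweep.py` enumerates them and scores each
configuration by its maximum relative error against the published
incremental table; the shipped `conventions` block freezes the minimizer
(max relative error 0.075 over all fifteen table quantities):

* **HR transform: `multiplicative`** (p' = min(1, p·hr)).  The
  rate-based actuarial transform 1−(1−p)^hr is implemented and selectable,
  but under-predicts both arms' effect deltas here.
* **Treatment accrual: `while_early_AD`**, no half-cycle correction.
* **Shared starting cohort mix.**  The published unrounded increments are
  exactly additive across the three pairwise comparisons, which is only
  possible when all arms are simulated from a common starting cohort.  The
  shipped default therefore starts every arm with the antibody-trial mix
  (61.5% MCI / 38.5% mild dementia); the SoC trial arm's own mix (66.2%
  MCI) is retained in the file as a documented override
  (`start_mci_fraction.soc=0.662`).  Starting ages keep their printed
  per-arm values (71.4 drug arms / 71.0 SoC); under floor-age band lookup
  these are trajectory-equivalent, so the base case is unchanged while the
  one-way analysis can still vary each age separately.
* **Administration cost scales with infusion frequency.**  The printed
  administration cost ($3,654.17/yr ≈ 26 × $140.5) corresponds to the
  biweekly lecanemab schedule; aducanumab is infused every 4 weeks
  (13 infusions/yr) and so incurs half the annual fee
  (`admin_frequency_factor: 0.5`).  Without this scaling the
  aducanumab arm's incremental cost is ~5% high and the (small)
  lecanemab-vs-aducanumab cost delta ~20% low.
* **Aducanumab population and pricing.**  The aducanumab cohort inherits
  the lecanemab arm's starting description (`population: lecanemab`), and
  its price schedule is $20,500 in the first year and $28,200 thereafter.
  Its ARIA rate and monitoring cost are not separately reported and are
  set equal to the lecanemab values (ARIA monitoring is <0.6% of annual
  drug cost, so this is immaterial at table precision).

Every run logs the resolved conventions (`run_log.txt`), so two runs are
comparable by diffing their logs.

## One-way sensitivity analysis

For each parameter in `osa_ranges` (the printed lower/upper limits —
generally ±20% of base, discount 0–8%, starting ages 65–75; aducanumab
rows without printed limits use ±20%), the full base case is re-run twice
with that single parameter at its limit — no incremental shortcuts — and
entries are ranked by the spread of the ICER per QALY.  A limit that
violates a structural invariant skips the parameter with a warning.  When
a limit flips the sign of the QALY delta the spread is reported as
infinite; this happens for the per-arm discount and starting-age rows in
the vs-SoC comparisons, which is why those bars top the vs-SoC tornados.
The flat parameter names (`utility.MILD`, `tp.MCI->MILD`,
`cost.drug.lecanemab`, `discount.soc`, ...) are the single addressing
scheme shared by the one-way analysis, the PSA and CLI `--override`.

In the lecanemab-vs-aducanumab tornado the two drug-price bars rank first
(spreads ≈ $175k and $148k) ahead of the mild-dementia utility (≈ $46k):
the ±20% price ranges move the ~$30k incremental cost by ~±$20k over ~4
discounted treated years, an effect no utility parameter can match.  This
ranking differs from the published tornado narrative (mild-dementia utility
first); we find that ordering unreachable in any configuration that also
reproduces the published incremental table.

## Probabilistic sensitivity analysis

Each uncertain parameter is drawn independently, moment-matched so the
distribution mean equals the deterministic value and the SD equals the
standard error (reported SE where available, otherwise mean/10):

* hazard ratios (treatment effects and stage mortality): lognormal with
  σ² = ln(1 + se²/m²), μ = ln m − σ²/2 (mean-matched, not median-matched);
* utilities and SoC transition probabilities: beta with
  ν = m(1−m)/se² − 1, α = mν, β = (1−m)ν; a transition row whose drawn
  outgoing probabilities exceed 1 is redrawn wholesale;
* costs (administration, outpatient, inpatient, ARIA): gamma with shape
  (m/se)², scale se²/m;
* fixed in every draw: drug prices, mortality band rates, starting ages,
  ARIA occurrence rates, the discount rate.  Starting ages are held fixed
  because no sampling family is stated for them and fractional age draws
  interact with the floor-based band lookup to produce a discretization
  artifact (about half the SoC draws delay a whole mortality band by one
  year, which collapses the small aducanumab effect delta).

A strategy's progression HR is drawn once and applied to all of its
affected transitions (the trials report a single HR per drug); this is
configurable through the distribution map.  All three arms are evaluated
on the same draw, so incremental deltas are additive across comparisons
within every sample.  The pairwise cost-effectiveness acceptability curve
(CEAC) reports, on a $0–$2,000,000 grid in $10,000 steps, the fraction of
draws with positive net monetary benefit λ·ΔQALY − ΔCost; crossings are
linearly interpolated.  `ceac_multiway` additionally reports the frontier
curves (fraction of draws in which each strategy has the highest NMB), the
form in which three-strategy CEACs are usually plotted.

A structural note on crossings: the 50% crossing of a pairwise CEAC is the
median of the PSA ICER distribution, and mean-matched draws keep that
median near the deterministic ICER.  Our lecanemab-vs-SoC crossing
(~$400k at 1,000 draws) accordingly tracks the base-case ICER; the published analysis
reports a substantially higher figure (~$880k), which cannot arise from a
mean-preserving same-draw PSA consistent with the published base case.
The aducanumab-vs-SoC crossing (~$1.24M) lands near the reported ~$1.4M.

## Synthetic instances and oracles

`synthetic.generate_instance` produces random, structurally valid model
configurations (valid transition rows with off-diagonal sums < 0.9,
strictly decreasing utilities, three-band mortality on [65, ∞),
non-negative costs, a known ground-truth intervention HR), reproducible
from a seed; `effect_hr=1` with zero drug price yields a null intervention
with exactly zero incremental cost and effect.
`synthetic.analytic_two_state_fixture` builds a one-alive-state instance
with constant death probability p and discount d whose discounted life
expectancy has the closed form Σ_t ((1−p)/(1+d))^t; the engine matches it
to 1e-12 per cycle and 1e-6 on accumulated totals.  `synthetic.recover_hr`
inverts the HR transform from a one-step probe trace and recovers a known
HR to 1e-9, and flags transform mismatches.

## Problem sizes and numerics

The deterministic base case simulates ≤29 cycles per arm and runs in
milliseconds; the tornado re-runs it twice per configured parameter
(~70 evaluations, <1 s); the PSA uses 1,000 Monte Carlo draws (seconds).
Row sums are enforced to 1e-12, occupancy conservation to 1e-10; all
arithmetic is double precision with rounding only in presentation layers
(2 decimals for dollars and effects).  Ties in the multiway CEAC go to the
reference arm; a beta draw whose variance is infeasible
(se² ≥ mean(1−mean)) raises an error naming the parameter.

## What the synthetic generator does and does not emulate

Synthetic instances exercise the full pipeline (validation, simulation,
economics, sensitivity) without the shipped configuration, but they are
cohort-level constructs: they do not emulate individual-level trial data,
censoring, HR estimation error, treatment discontinuation or time-varying
effects.  Passing tests on synthetic instances therefore demonstrate
structural correctness of the engine and analysis layers, not the clinical
realism of any particular configuration.

## Known limitations

* The model inherits the published analysis's scope: no infusion-reaction or
  ARIA-treatment costs beyond MRI monitoring, no societal costs, no
  APOE-ε4 subgroup structure, no treatment waning or discontinuation,
  and a single deterministic cohort age (no age mixture).
* Two published findings are not reproduced and are documented above as
  structural inconsistencies rather than tolerances to be widened: the
  lecanemab-vs-aducanumab tornado ranking, and the lecanemab-vs-SoC CEAC
  50% crossing.
* The aducanumab administration scaling and the shared starting mix are
  reconstructions of unstated implementation choices; both are exposed as
  ordinary parameters so either can be overridden.
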