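# Methods

## Power model

All design quantities derive from the exact power function of the two-sided
pooled-variance two-sample t-test with equal per-group size n:

- degrees of freedom `df = 2n − 2`;
- noncentrality `ncp = d·√(n/2)` for a true standardized effect d (Cohen's
  d, `(µ_test − µ_control)/σ`);
- `power(d; n, α) = P(|T| > t_{1−α/2, df})` with `T ~ noncentral-t(df, ncp)`.

The noncentral-t distribution is used throughout rather than the normal
approximation: at the per-group sizes this design lives at (7–50) the
approximation misstates the minimum detectable effect in the second decimal
place, which is the precision the schedule is quoted at. `required_n`
inverts the power function over integers (seeded by the normal
approximation, resolved to the smallest n whose exact power reaches the
target; ties return the smaller n); `minimum_detectable_d` root-finds the
unique positive d with Brent's method on (0, 20], tolerance 1e−12.

Two numerical notes. `scipy.stats.nct` tail probabilities underflow to NaN
far beyond double precision; the power function computes the upper tail via
the survival function and zeroes NaN terms, which can only occur when the
true mass is unrepresentably small. And power saturates at exactly 1.0 in
double precision for large `ncp`, so strict monotonicity in d and n holds
only below that ceiling (the property tests encode this).

A Welch option is exposed on the data-facing tests (`interim_decide`,
`final_analyze`); under the equal-n, equal-variance planning model the Welch
and pooled tests coincide, so design numbers are always pooled.

## Sequential boundaries

With one interim per allele group at information fraction t₁ (interim
per-group n over final per-group n — sample-size information under equal
variance), the interim and final z-statistics are bivariate normal with
correlation √t₁. Two boundary families are implemented against the exact
joint crossing probability (scipy's multivariate-normal rectangle
integration; Monte-Carlo fallback, with a warning, above four looks):

- **Lan–DeMets O'Brien–Fleming spending**: cumulative spend
  `a(t) = 2(1 − Φ(z_{α/2}/√t))`; the interim nominal level is `a(t₁)` and
  the final level is solved so the overall two-sided error equals α.
- **Classic O'Brien–Fleming**: boundary `z_k = C/√t_k` with C solved the
  same way.

The deployed study's interim efficacy levels (0.0013, 0.0023, 0.0055) are
**not** reproducible from either construction at the schedule's information
fractions (spending at t = 15/50 gives ≈ 3.5 × 10⁻⁴); the exact software
configuration that produced them is not recoverable. They are therefore
shipped as fixed design constants, used whenever the design matches the
default budget (100/15/3 groups), and every plan records provenance
(`alpha_source`: `design_constant`, `supplied`, or `computed`). Any other
configuration computes its levels from first principles.

## Planner

Stage-k final per-group size: `⌊(total_n − interim_n·(k−1))/2⌋`. Floor, not
round: parity between the live test group and the control arm is what the
shared-control analysis requires, and the floored allocation is the unique
one reproducing all three published futility cutoffs (0.57/0.62/0.68 ↔
n = 50/42/35). The futility cutoff is the minimum detectable effect at the
stage's final size (80% power, α = 0.05); the required interim effect is the
minimum detectable effect at the interim size and the stage's efficacy
level.

The published schedule's stage-2 row pairs α = 0.0023 with a required
interim effect of 1.52; inverting the power function at that α gives 1.55.
The two printed numbers are internally inconsistent with the convention that
reproduces rows 1 and 3 exactly, and which of them is authoritative cannot
be determined; the planner emits the computed 1.55 (the efficacy alpha, as
the operational quantity, is taken as the constant).

By default the final analysis tests at α = 0.05 even after an interim — the
O'Brien–Fleming interim spends so little that the final level is barely
affected, and the quoted futility cutoffs are computed against 0.05. A
`strict_spending` mode subtracts the interim spend from the final level for
users who want exact overall control.

## Interim decision rule

Futility is assessed through predicted power at the observed |d̂| (two-sided:
a large wrong-direction effect counts as "powered", consistent with the
two-tailed test), with no shrinkage or small-sample correction of d̂. A
prediction exactly at the target continues (the rule stops only on strictly
under-target predictions). Monotonicity of power makes the rule equivalent
to `|d̂| ≥ futility_d`; the suite verifies the equivalence on 10⁴ random
datasets, allowing disagreement only within root-finder tolerance of the
cutoff. The decision input schema is participant-level `(group, endpoint)`
CSV or summary statistics — genotype never enters the decision path.

## Simulator

`simulate_fixed_effect` draws complete trials (control N(µ, σ), test
N(µ + dσ, σ); defaults µ = 0, σ = 1, and decisions are exactly invariant to
the scale chosen), applies the real interim rule to the first `interim_n`
per arm, the final test to the full data, and scores interim decisions
against the completed trial: a halt of a trial whose final test rejects is a
false-negative halt; passing a trial whose final test does not reject is a
false-positive continuation. Defaults: 10,000 replicates per cell, final
size 50 per group, bootstrap 95% CIs formed by resampling 100 results 1,000
times.

`interim_timing_sweep` answers the interim-timing question. Its default
emulated interim is a significance check on the interim subset (`rule=
"significance"`), which is the natural emulation of "run the same t-test
early" and has the clean boundary property that an interim containing
everyone is always scored correct. The actual futility rule
(`rule="futility"`) and the full futility-plus-efficacy rule (`rule="full"`)
are selectable; all three reproduce the qualitative design conclusion that
the marginal value of interim participants beyond ~15 per group is small.

`simulate_adaptive_study` runs the whole sequential study: one shared
control arm (its first 15 observations serve every stage's interim —
decisions across stages are therefore positively correlated, and the
probability that all null groups halt exceeds the independence product, as
the tests check), per-stage budget bookkeeping, and pathway frequency
accounting. Budget conservation (≤ total_n consumed in every replicate) is
asserted inside the simulator.

All randomness flows from one root `SeedSequence`; every grid cell and
purpose (data vs bootstrap) receives a spawned child stream, so results are
bit-reproducible and independent of evaluation order.

## Synthetic cohort

The generator emulates the recall sampling frame, not the population:

- **Genotypes**: Hardy–Weinberg at MAFs 0.40, 0.10, 0.16, 0.15, 0.15; the
  two linked pairs are sampled as two haplotypes per individual from the
  frequencies implied by `D = sign·√(r²·p_a(1−p_a)·p_b(1−p_b))` (r² = 0.51
  and 1.0). Minor alleles are placed in coupling phase (sign = +1) by
  default — the true haplotype phase is not stated in the source data, and
  coupling is the configuration under which double-homozygote recall groups
  exist at r² = 1. Infeasible (MAF, r²) requests fail with the Fréchet
  bound named.
- **Eligibility**: per-locus imputation certainty `1 − Exponential(0.002)`
  capped at 1, giving ≈ 0.7% of calls below the 0.99 bar and ≈ 96.7% of
  individuals eligible at all five loci — a deliberately optimistic
  imputation profile for common, well-imputed variants; the scale is
  configurable.
- **Recall**: controls are dosage-0 at all five loci; test group k requires
  dosage 2 at its defining locus/loci only (genotypes elsewhere are left
  free — the recall criterion constrains only the group definition;
  requiring major-homozygosity elsewhere would shrink the rare pools
  further and is not implied by the group construction). Selection is
  uniform without replacement; shortfalls raise an error reporting the
  expected yield.
- **Screening**: eight independent Bernoulli exclusion criteria
  (neurological disorder, regular/recent analgesics, pregnancy, pain
  conditions, severe anxiety/depression, allergies, recreational drugs)
  with configurable prevalences defaulting to plausible healthy-young-adult
  rates totalling ≈ 25% attrition.
- **Phenotypes**: baseline heat pain threshold N(42, 2.5²) °C; the
  post-sensitization value keeps SD 2.5 °C, shares the subject effect with
  correlation 0.7, and adds a −3 °C mean sensitization shift plus the
  configured group effect Δ (°C). Holding the post-sensitization SD at
  exactly 2.5 is what makes a Δ = 4 °C group effect a d = 1.6 comparison,
  so the abstract-scale and cohort-scale simulations agree. Secondary QST
  endpoints load on a single common subject factor (loading 0.4) around
  round-number normative means; the sensitization pain rating is an integer
  0–10. No thermode safety cap is applied by default (a cap truncates the
  normal model); an optional 50 °C censor flag exists.

What passing tests show: the decision engine and simulator behave correctly
on data whose distributional assumptions (normal endpoints, common variance,
independent subjects, exact HWE, two-locus LD only) hold by construction.
They do not validate those assumptions against real QST data, real LD
structure beyond pairwise r², imputation error correlated with genotype, or
recruitment biases.

## Problem sizes

Analytic checks run in well under a second each. Monte-Carlo checks use
10,000 replicates for operating characteristics (matching the design's own
simulation scale), 4 × 10⁵ replicates for the brute-force t-test oracle,
2 × 10⁶ draws for the bivariate boundary-crossing oracle, one million
haplotypes for LD recovery, and 4,000 replicate cohorts for the end-to-end
interim-power reproduction; all comparisons are made within three
Monte-Carlo standard errors of the analytic value.
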