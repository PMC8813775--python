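# Methods

## Scope and model overview

`stagegate` simulates a clonally propagated crop's stage-gate breeding
pipeline — crossing block, seedling nursery, then clonal evaluation (CE),
preliminary (PYT), advanced (AYT) and uniform (UYT) yield trials — and
uses that simulator to compare resource allocations in the crossing
block (number of parents, number of crosses, progeny per cross) and
parent-recycling policies at a fixed program size. The package has two
halves: a declarative data model for breeding schemes (stages with their
crossing/evaluation/selection decisions, market segments, product
profiles) and a forward-in-time quantitative-genetics engine driven by
such a scheme.

## Scheme formalisation

A `BreedingScheme` is an ordered stage table. Invariants enforced at
load time: the head stage is the only crossing stage, selection never
exceeds entries, the evaluation chain conserves material
(`n_entries_in` of stage k+1 equals `n_selected_out` of stage k), at
least one stage is a recycling source, and stage years are
non-decreasing. Violations are returned as data (stage, field, rule) so
a file can be repaired in one pass.

Derived metrics:

- **Selected percentage** of stage k is
  `100 · n_entries_in(k) / n_entries_in(k−1)`, rounded half-up to three
  significant figures — the convention that reproduces the mixed
  printed precision (7.35, 53.3, 37.5, 100) of program summary tables.
- **Expected cycle time** of a recycling policy is the quota-weighted
  mean of the recycling stages' year indices (a multi-year stage
  contributes its final year). The baseline mixed policy (half PYT,
  year 3; half AYT, year 4) gives 3.5 years.
- **Plots per stage** count entries × locations × reps; check plots are
  deliberately excluded because the program accounting tracked entries
  only.
- The DOT flowchart expands multi-year stages into one node per
  stage-year (the six-row baseline renders as seven nodes) with dashed
  back-edges from recycling sources to the crossing block.

The bundled baseline (`data/baseline_scheme.json`) encodes the
east-African cassava pipeline: 4 parents, 12 reciprocal crosses × 136
progeny = 1,632 F1; CE in 1 location × 1 rep; PYT 120 entries in 2×2;
AYT 64 in 2×3; UYT 24 in 2×3 over two seasons; recycling from PYT and
AYT. One published description places recycling at PYT and UYT, but the
cycle-time arithmetic and the policy comparison both use PYT and AYT;
the scheme flags PYT and AYT.

## Founder genomes

Standing variation comes from a discrete-generation Wright–Fisher
burn-in rather than a coalescent: `effective_population_size` (default
30) random-mating diploids evolve for `burn_in_generations` (default
1,000, far beyond the ~4Ne generations needed for mutation–drift
equilibrium at this size) with symmetric per-site mutation and Poisson
recombination. Small Ne stands in for a history of natural and
artificial selection; no explicit selection acts during burn-in. Four
non-inbred founders are then sampled and sites monomorphic among them
are pruned.

The genome is a fixed panel of candidate sites, not sequence: per
chromosome (default 18), `sites_per_chromosome` (default 500) positions
uniform on a 1.43-Morgan map, with physical positions derived from the
constant rate 1.43 M / 8×10⁸ bp = 1.7875×10⁻⁹ (displayed 1.8×10⁻⁹)
Morgans per bp. Each candidate site absorbs the mutation flux
(2×10⁻⁹ per bp) of the sequence stretch it represents, so the per-site
scaled mutation rate — and hence the fraction of sites segregating —
follows automatically from panel density. At the recurrent-mutation
rates this implies, the folded site-frequency spectrum is flatter than
the infinite-sites 1/i expectation; the test suite checks it against an
msprime finite-sites coalescent oracle instead.

Meiosis is Poisson crossover without interference or obligate chiasma:
per chromosome the crossover count is Poisson(map length), positions
uniform, starting haplotype fair. Recombination fractions therefore
follow Haldane's map function, and the expected crossover count per
chromosome equals its Morgan length. No new mutation occurs after
burn-in; all trait variation segregates from founding.

## Trait model

One additive trait represents a selection index of the program's target
traits. QTN (default 100 per chromosome, 1,800 total) are drawn from
segregating founder sites. Allele effects are linear in an
environmental covariate w — a(w) = b + m·w — so an individual's genetic
value is linear in w with slope Σx·m and intercept Σx·b: exactly a
Finlay–Wilkinson regression, verified to machine precision.

Intercepts and slopes start standard-normal and are rescaled by
Monte-Carlo calibration against a random-mating expansion of the
founders (default 2,000 individuals, keeping calibration error to a
few percent): b so the base population's genetic
variance at w = 0 equals `var_G` (default 1), m so the variance of the
slope score Σx·m is exactly 1. Closed-form scaling is not available
because linked QTN covary. With the slope score at unit variance, the
covariate decomposition w[year, loc] = u[year] + v[year, loc] carries
the interaction targets directly: var(u) = `var_GxY` (default 2),
var(v) = `var_GxL` (default 1), and the genotype-by-year-by-location
component is their sum (3). The interaction defaults are inferred from
an ambiguously printed source table and are configurable.

Phenotypes add plot noise e ~ N(0, var_e(stage)) to the genetic value
at the plot's (year, location) covariate; the entry mean averages
locations × reps. Stage error variances derive from plot heritability
h² = var_G / (var_G + var_GxYxL + var_e), single-plot basis. The stage
defaults — CE 0.2, PYT 0.3, AYT 0.4, UYT 0.45 — are package choices
(unreplicated early stages get lower plot h²), not published estimates,
and are configurable per stage, or overridable with direct error
variances. Trial designs (augmented at CE, RCBD later) are not modelled
explicitly; their effect enters only through replication counts and
error variance.

## Program engine

Each simulated year: occupied trial cohorts are phenotyped and their
true genetic mean and variance at w = 0 recorded (main-effect scale, so
gain is comparable across years despite GxE); parents are recycled from
this year's data; crossing and nursery multiplication happen within the
same year; cohorts then shift one stage. Crossing and the nursery
sharing a year makes a clone crossed in year y reach CE in year y+1 and
PYT in year y+2, so PYT-recycled parents are 3 years old and
AYT-recycled parents 4 — the logged mean parental age under the mixed
policy equals the scheme's expected cycle time of 3.5 years.

Details:

- **Advancement** is truncation selection on entry-mean phenotype (no
  BLUP or index), ties broken by ascending id for determinism.
- **Recycling** apportions the crossing block across policy stages by
  largest remainder (ties to the earlier stage) and takes each stage's
  top entry means. The crossing block is rebuilt every year; nobody is
  held over unless re-selected.
- **Cross plans** sample distinct non-self pairs (unordered unless
  reciprocals are allowed). Uniform sampling alone cannot guarantee
  that every parent is used when the plan is much smaller than the
  half-diallel, so a random near-perfect matching covering all parents
  is laid down first and the remainder drawn uniformly from unused
  pairs. The baseline's 12 crosses among 4 parents require
  reciprocals; grid treatments use unordered pairs under the
  half-diallel cap.
- The terminal UYT cohort is phenotyped again in its second season as
  product-development bookkeeping; it is not a recycling source here
  and contributes no extra records.
- The nursery is pure multiplication: no loss, no selection.

A program run starts from the founders as the initial crossing block,
ramps the cohort ladder up, and applies the baseline configuration for
a 20-year "recent breeding" burn-in before the treatment under study
takes over. Until the recycling sources are first phenotyped (years
1–2), the current crossing block is reused.

## Experiment design

The treatment grid crosses parent levels {4, 8, 16, 32, 64} with cross
levels {6, 12, 24, 48, 96, 204, 408, 816} subject to
crosses ≤ parents(parents−1)/2 and crosses × progeny = 1,632 — exactly
24 treatments, with progeny per cross 272, 136, 68, 34, 17, 8, 4, 2
down the cross ladder.

A replicate is one founder realisation plus one burn-in, deep-copied
(forked) for every treatment, so the burn-in segment of the records is
bitwise-shared and treatment contrasts are within-replicate (paired).
`compare` reports the mean paired gain difference with its standard
error and attaches a direction only beyond 2·SE. All randomness flows
from one master seed through named substreams, so runs are bitwise
reproducible.

## Problem sizes

Full published scale (100 replicates, 20–60 year horizons, 500 sites
per chromosome) is supported but slow on one core. The shipped desk
profile — 10 replicates, 200 candidate sites per chromosome, 50 QTN per
chromosome (900 total, keeping QTN demand below the segregating-site
supply of the smaller panel), 20-year burn-in + 20 treatment years —
runs a four-treatment comparison in minutes and reproduces the two
directional findings: mixed PYT+AYT recycling beats AYT-only recycling,
and 8–16 parents beat 64 parents, both at the 20-year horizon with
paired differences several SE above zero. Gains are summarised at CE
(the largest cohort); the stage is a parameter.

## What the generator does and does not emulate

Emulated: small-Ne equilibrium standing variation, linkage on a
realistic genetic map, additive GxE of the Finlay–Wilkinson form,
stage-calibrated phenotyping precision, overlapping cohorts with
clonal recycling. Not emulated: sequence-level realism, selection
during burn-in, dominance or epistasis, multi-trait selection, genomic
prediction, mortality or cost structure, spatial field trends. Passing
tests therefore demonstrate the comparative behaviour of allocation
policies under this idealised genetic architecture, not forecasts of
absolute gain in a real program.

## Numerical choices

- Percentages: half-up, 3 significant figures (see above).
- Selection ties: ascending id; apportionment ties: earlier stage.
- Variance calibration tolerances: exact on the calibration
  population; ±10% (genetic variance) and ±15% (GxY:GxL ratio) checked
  on independent populations at default scale.
- Degenerate inputs raise typed errors: zero-entry predecessor stages,
  h² = 0, cross counts over the combinatorial cap, QTN demand over the
  segregating supply (naming the shortfall per chromosome).
- Records store genetic variance with ddof = 1; single-survivor cohorts
  record 0.

## Known limitations

The burn-in defaults (1,000 generations) equilibrate drift and
mutation at Ne = 30 but do not replicate a 100,000-generation
coalescent's fine-scale LD. Entry-mean selection ignores the augmented-
design adjustment an actual CE analysis would use. The GxE covariate is
drawn fresh per (year, location) with no spatial or temporal
autocorrelation. The 60-year horizon results reported at full scale are
supported by the engine but not exercised by the default test suite.
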