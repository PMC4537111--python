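# Model and methods

## Overview

`guildsim` simulates a guild of foragers exploiting a patchy, renewing
resource over evolutionary time.  Three nested clocks drive the model:

1. **Within-patch / tick clock** — consumer–resource interaction in a
   single cell: saturating extraction, logistic-with-reservoir regrowth.
2. **Generation clock** — `n` ticks (default 100) of synchronous
   movement decisions and foraging; an agent's biomass at tick `n`,
   B_a(n), is its fitness.
3. **Epoch clock** — `G` generations (default 200) of hard truncation
   selection and reproduction with annealed mutation.

## Landscape

A rectangular cellular array (default 20 × 20 = 400 patches, toroidal)
holds a scalar resource stock R_k per cell.  After extraction leaves a
residue R*, the stock regrows as

    R(t+1) = R* + r (1 − R*/s)(R* + g)

with growth rate r = 0.1/tick, saturation s = 20 and reservoir g = 0.1
(all resource units).  On [0, s] this map is strictly increasing, fixes
s, and maps into (0, s], so stocks remain positive and bounded; the
reservoir term reseeds a patch driven to zero.  At the start of an
epoch every cell draws its stock uniformly from [R_min, R_max] =
[2.99, 3.00] — a nearly homogeneous landscape whose 0.01 spread is just
enough to randomise early movement.

**Landscape persistence.**  The landscape is initialised once per epoch
and *persists across generations*; each generation only re-places the
agents at random and resets their biomass.  The standing crop of
resources therefore carries the guild's exploitation history from one
generation to the next, and is the mechanism that couples population
density to per-capita productivity: two agents on 400 patches forage on
an essentially ripe landscape (final-generation mean fitness ≈ 32),
one hundred agents keep it cropped down (≈ 6–8 per head).  A
per-generation re-initialisation is available
(`EpochConfig.fresh_landscape_each_generation`); under it every
generation spends ~35 ticks re-ripening from R ≈ 3 and the attainable
fitness ceiling drops by roughly a fifth.

## Perception and movement

Each tick every agent builds a 36-entry environmental vector over slot
0 (its own cell) and slots 1..8 (the Moore neighbours in fixed
row-major-offset order): resource R_ℓ, neighbourhood-mean resource
R_ℓ^M, occupancy J_ℓ, neighbourhood-mean occupancy J_ℓ^M.  J_0
excludes the focal agent itself (the competition penalty is about
*other* foragers; configurable).  Each slot is scored

    V_ℓ = R_ℓ − δ J_ℓ + α (R_ℓ^M − δ J_ℓ^M)

with heritable weights α (neighbor-discount: how much second-tier
information counts) and δ (competition-tradeoff: resource-equivalent
penalty per competitor).  The decision rule, with heritable movement
threshold ρ:

    stay  iff  V_0 > 0 and ρ·V_ℓ < V_0 for all ℓ = 1..8
    else  relocate to argmax V_ℓ over ℓ = 0..8 (ties uniform at random)

Small ρ makes an agent reluctant to move (it leaves only once its patch
is depleted to a small fraction of the best neighbour); ρ near 1 makes
it leave whenever any neighbour looks marginally better; ρ ≥ 1 can
never stay on a homogeneous landscape.  The inequality is strict, so in
an exactly uniform positive world ρ = 1 produces a relocation.  A
relocation whose argmax is slot 0 is a *move in place*: the agent keeps
its cell but forgoes extraction like any other mover.  At the
two-agent baseline the evolved optimum sits at ρ in the low 0.7s —
leave once the best neighbour is worth about 1.35× your own patch —
the reference behaviour this model is calibrated to reproduce.

**Cost of moving.**  A mover extracts nothing during its move tick;
this forgone intake is the cost of moving under the baseline
conditions.  A multiplicative biomass deduction B ← (1 − c)B per move
(c = 0.1) is additionally available (`ForagingParams.deduct_move_cost`)
but is off by default: because it compounds on the accumulated stock,
it caps lifetime biomass near g(1 − c)/c of the per-move-cycle gain
(≈ 13 biomass units at the baseline), far below the productivity an
evolved two-agent guild sustains, and drives the evolved ρ down to
≈ 0.45.

## Foraging

Stayers in cell k form the extractor set of size N_k; each receives the
per-capita extraction

    F_k = min{ R_k / N_k,  u R_k / (h + R_k + q N_k) }

with maximum rate u = 10, half-saturation h = 20 and interference
q = 0.5 — a saturating functional response capped by equal sharing of
the stock, so N_k F_k ≤ R_k always.  A stayer gains κ F_k biomass
(conversion κ = 0.1).  All decisions are synchronous (based on the
pre-movement state); extraction happens after movement; regrowth after
extraction; occupancy is recomputed last.

## Genetic algorithm

Fitness is B_a(n).  Selection is hard truncation: the fittest half
reproduce (ties broken by agent id, stably).  The maximum mutation
perturbation anneals over generations,

    μ(T) = (μ0 − μ∞) / (1 + (T/ψ)³) + μ∞ ,

with μ0 = 0.1, μ∞ = 0.001, ψ = 50 generations (so μ(ψ) lies halfway
between μ0 and μ∞).  Perturbations are uniform on [−μ, μ] and never
clamped; slightly negative evolved trait values are legitimate.

Three reproduction modes (population size N_A constant):

* **Clonal** — survivors persist unchanged; each adds one clone whose
  three traits are independently perturbed.  Requires even N_A.
* **Averaging sexual** — survivors pair at random (shuffle, pair
  consecutive); each pair leaves 4 progeny whose traits are the
  parental means, then mutated.  A deliberately naive haploid stand-in
  for sex.  Requires N_A divisible by 4.
* **Diploid random mating** — hermaphroditic pairs; two alleles per
  trait; each progeny inherits one allele per trait from each parent by
  random segregation, independently across traits (no linkage); every
  inherited allele is mutated; the phenotype is the arithmetic mean of
  the two alleles (codominance, exact).  Alleles carry integer lineage
  tags through mutation, so allele identity in analyses is by descent,
  never by rounding values.

Initial populations draw each trait (each allele, in diploid mode)
uniformly from [0, 1].  The α and δ ranges mirror ρ's documented
initial range; all three are configurable.

## Analyses

* **Morph classification** — single-linkage clustering of phenotypes in
  trait space, cut at a gap threshold (default 0.03, the scale of
  late-epoch mutation noise: μ∞-driven scatter stays merged, evolved
  gaps split).  The clustering metric can be restricted to a subset of
  traits (e.g. ρ-morphs); summaries always cover all three traits and
  fitness.  Single linkage is the right shape here because a morph is a
  mutation-connected cloud, not a sphere.
* **Hardy–Weinberg** — allele frequencies from unordered genotype
  counts, p_i = (2n_ii + Σ n_ij)/(2N); expected counts N p_i² and
  2N p_i p_j over every genotype constructible from the observed
  alleles; chi-square over classes with positive expectation,
  df = #classes − #alleles (the frequencies are estimated from the same
  sample).  Genotype classes with zero expected count are excluded from
  the sum.  Note that a progeny sample containing whole families is
  over-dispersed relative to the multinomial null (siblings share
  parents); the HW property is exact at the level of gamete union and
  should be tested on unrelated progeny.
* **Mode comparison** — replicate epochs per reproduction mode with
  seeds base + run index; per-generation total biomass Σ_a B_a(n);
  phase totals over generation ranges (default 1–125 and 126–250);
  Welch two-sided t-test between modes and a two-sided F variance-ratio
  test across runs.

## Numerical and design choices

* One `numpy` PCG64 generator per epoch with a fixed draw order
  (placement → resource init (first generation) → one (n_agents, 9)
  tie-break block per tick → reproduction draws), so an integer seed
  reproduces a whole trajectory bit-exactly.
* The engine is vectorised across agents and cells; an independent
  per-agent pure-Python reference implementation in the test suite
  must agree with it bit-for-bit over multi-tick trajectories.
* Initial biomass B_a(0) = 0 (configurable): fitness is accumulated
  intake, and reported fitness magnitudes are consistent with pure gain
  over 100 ticks.
* Neighbourhood means at bounded-grid edges divide by the actual
  neighbour count; missing slots take no part in the movement rule.
* Bounded (non-toroidal) grids are supported for sensitivity checks;
  the default is toroidal, which removes edge effects and makes every
  neighbourhood exactly 8 cells.
* SDs reported in generation records and morph tables are population
  SDs (ddof = 0).
* `run_generation` accepts n = 0 ticks (returns the initial biomass as
  fitness); negative tick counts are configuration errors.

## What the simulation does and does not show

All experiments are self-generating; there is no external data.  The
baseline configuration above *is* the study condition, and the test
suite checks emergent, not scripted, outcomes: two-agent epochs evolve
movement thresholds with final fitness ≈ 32; hundred-agent epochs
self-organise into 3–7 movement-type morphs with ρ confined to
[0.25, 0.65] and a trait-SD trajectory that dips mid-epoch and rises as
the polymorphism assembles; diploid random mating keeps progeny in
Hardy–Weinberg proportions while maintaining polymorphism.  Two caveats
are documented honestly rather than patched: across seeds the
two-agent evolved ρ spreads over ≈ [0.3, 0.76] (the fitness surface is
nearly flat along a ridge of (α, ρ) combinations implementing the same
leave-the-patch policy), and during the burn-in phase clonal guilds
*under*-produce random-mating guilds (a monomorphic clonal guild
over-exploits the shared landscape before polymorphism spreads it out),
with the clonal advantage emerging only in the second half of the
epoch.  At very small population sizes (N_A = 2) a few percent of
epochs collapse entirely when drift fixes a non-foraging strategy
before selection engages — a real property of tiny evolving
populations under annealed mutation.

The model omits — deliberately — sensory noise, memory,
heterospecifics, patch-specific growth parameters, soft selection,
assortative mating, dominance, linkage and distinct sexes.  Nothing
here is fit to data from real organisms; passing tests demonstrate
internal consistency and reproduction of the reference simulation design,
not predictions about any field system.

## Problem sizes used in the checks

Epoch-level checks run at the full baseline scale (G = 200, n = 100)
for 2–100 agents; the clonal-vs-random-mating comparison runs a
scaled design of 10 replicate runs per mode at 100 agents and G = 250
(the full reference design uses 50 runs per mode at three densities), which
is sufficient for the direction and significance of the mode contrast.
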