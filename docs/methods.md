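# Methods

`aodsim` is a forward-time Wright–Fisher simulator for the fate of a
chromosomal-inversion supergene created by introgression, together with the
statistics used to analyse it: associative overdominance (AOD), the
decomposition of regional fitness load into drift and mutational components,
and the classification of long-lived polymorphisms into viable, half-lethal
and balanced-lethal states.

## Model

**Genome and coordinates.** Two chromosomes of 10 Mb on one linear 0-based,
half-open axis (chromosome 2 offset by 10 Mb). Chromosomes assort
independently (an obligate recombination point at the boundary fires with
probability 1/2 per meiosis). Selected mutations arise only inside 40
uniformly spaced 5 kb "allelic content" segments (200 kb of 20 Mb); by
default the genome-wide mutation input μL per gamete is concentrated into
these segments (`compensate_segment_mu`), so the per-gamete rate is the
full-genome one. Recombination operates over the whole genome.

**Inversion.** A fixed interval covering the central half of chromosome 1
(2.5–7.5 Mb; one quarter of the genome). The inverted arrangement A is fixed
in population P2, the standard arrangement B in P1. In heterokaryotypes (AB)
crossovers are suppressed inside the inversion interval (zero crossover rate
there, drawn on the remaining genome at the usual per-bp rate); gene
conversion remains active everywhere and is the only gene flux between
arrangements inside the inversion. Gene conversion never relabels an
arrangement.

**Mutation.** Deleterious mutations at rate μ per bp per generation with
|s| ~ Gamma(shape α=0.5, rate β=10) (mean 0.05) and a fixed dominance
coefficient h (0 or 0.1); s is the homozygous effect, negative for
deleterious mutations. β is interpreted as a rate parameter: the scale
interpretation would give a mean effect of 5, i.e. almost exclusively
super-lethal mutations. Beneficial mutations (post-admixture only) at a
1000× lower rate with |s| ~ Exponential(mean κ=0.001) and h=0.5; κ is
interpreted as the mean, the rate interpretation being equally absurd.
Infinite sites: every mutation occupies a distinct bp; a colliding draw is
resampled.

**Fitness.** Multiplicative and relative to a genotype free of currently
segregating mutations: w = Π(1+s) over homozygous sites × Π(1+hs) over
heterozygous sites. Any non-positive factor makes the genotype inviable
(w=0); mutations with 1+s ≤ 0 are effective recessive lethals. Mutations
fixed within a population are pruned from all genotypes and moved to a
per-population fixed registry; pruning multiplies every fitness by the same
factor and cannot change relative fitnesses. During burn-in the registries
are per-population, so private fixed load is recoverable at admixture.

**Reproduction.** Constant-size Wright–Fisher: each offspring draws two
parents independently with probability proportional to fitness (selfing
allowed), one meiosis per parent. Only two chromatids are modelled per
meiosis. Crossover breakpoint counts are Poisson(ρ·permitted length); gene
conversion initiations Poisson(γL) with tract length Poisson(λ=500 bp),
tracts copying the homologous chromatid's content rightward from the
initiation point (overlapping tracts toggle the source). If every individual
has fitness 0 the population is extinct: an error during burn-in, a recorded
terminal status afterwards.

**Pipeline.** (1) Burn-in: P1 and P2 evolve in isolation for T_BI
generations from mutation-free founders (divergence time = burn-in length);
beneficial mutations off. (2) P1 is bottlenecked to N, then a single
randomly chosen P2 individual replaces a random resident at generation 1
(migrant cannot be lost to the bottleneck; N is conserved). Mutations fixed
privately in either population re-materialize as segregating sites: resident
haplotypes carry P1's private fixed set, the migrant's carry P2's; mutations
fixed in both stay pruned. (3) Post-admixture: Wright–Fisher with beneficial
mutations until the inversion fixes or is lost, the population goes extinct,
or the generation cap T_max; time series on the standard sampling grid
(10 … 200 000, divided by the rescaling factor), outcome classification at
checkpoints (100k/150k/200k, likewise divided).

## Statistics

**AOD.** s1′ = 1 − W̄_AA/W̄_AB, s2′ = 1 − W̄_BB/W̄_AB, s′ = min(s1′, s2′),
symmetry = |s1′ − s2′|, from arithmetic mean fitness per karyotype class.
Undefined components (empty class, W̄_AB = 0) propagate as NaN. For recorded
time series and for the outcome classifier, an absent class is scored by the
expected fitness of random (ordered, with replacement) pairings of the
standing haplotypes of the required arrangements — immediately after
admixture there is no AB individual, and a lethal homokaryotype class is
absent from the standing population precisely when it matters; realized
class means are used whenever the class is present. All ordered pairs are
enumerated up to 256 pairs, beyond that 256 random pairs are drawn.

**Load decomposition.** For a region: mutational load = 1 − mean fitness
computed from segregating region mutations only; drift load = 1 − Π(1+s)
over deleterious mutations fixed in the focal population but not in the
reference population; segregation load composes multiplicatively,
1 − L_seg = (1 − L_drift)(1 − L_mut), consistent with multiplicative
fitness; drift fraction = L_drift/L_seg.

**Outcome classes.** With both arrangements segregating, a homokaryotype
class with mean fitness below 0.01 is inviable: both viable → polymorphic
with viable homokaryotypes; exactly one inviable → half-lethal; both →
balanced lethal.

**Invasion.** The inverted arrangement invaded if still present after N
generations (N = post-admixture size; fixation before then counts, loss at
or before then does not).

## Desk-scale profile

The study conditions (N_BI = 2500, T_BI = 2·10⁵–5·10⁵, 10⁵ replicates per
parameter set) are cluster-scale. The desk profile
(`experiment.desk_scale_config`) divides population sizes and durations by
Q = 100 and multiplies the recombination rates by Q — an exact rescaling of
the transmission process (Nρ L and Nγ L preserved) — while keeping the
mutation rate and the effect-size distributions at their nominal values.
Full diffusion rescaling (s × Q) is impossible at this depth: multiplicative
fitness requires Qs ≲ 1, and beyond that the gamma tail becomes a flood of
recessive lethals under which a small population melts down (verified
empirically); inflating μ by Q instead saturates the drift load so that
homokaryotypes are already inviable at admixture. Keeping μ and the DFE
nominal reproduces the study's burn-in state — a drift-dominated supergene
load with viable homokaryotypes and positive AOD — in a population 100×
smaller.

Consequences to keep in mind: with N E[s] 100× smaller, fixation
probabilities of deleterious mutations are inflated, so the absolute drift
load after a scaled burn-in (≈0.2–0.4 in the supergene region) and hence the
initial AOD (≈0.3–0.8) are larger than the study's (AOD of order 0.01–0.05);
the drift fraction of segregation load is correspondingly pushed toward the
top of the study's 60–90% range. Ratio- and ordering-based quantities
(fixed-count linearity in divergence time, invasion increasing with AOD,
drift-load dominance) are robust to this inflation.

For the outcome-map experiment (the fate of long-lived polymorphisms) two
further calibrations are required. First, the time for a sheltered
arrangement to accumulate a lethal recessive load must fall inside the
simulated horizon, as it does in the study (degeneration over ~10⁵ of 2·10⁵
generations); at nominal μ the desk degeneration timescale measured ≈2–3×
the horizon (surviving runs reach homokaryotype fitness 0.03–0.16 at the
cap), so the map profile (`experiment.map_profile`) raises the deleterious
and beneficial mutation rates by 1.5×. Second, the "large population" cell
must actually sit in the regime where purifying selection on exposed
homokaryotypes opposes degeneration (N·s̄·exposure ≳ 1, i.e. N ≳ 50 with the
nominal DFE); the map burn-in therefore runs at N_BI = 50 for 4000
generations — preserving the study's divergence time of 80 × N_BI — and the
desk cells use N ∈ {12, 50}. The study's 25-fold size contrast cannot be
represented below N ≈ 10, where a balanced-lethal population of size N loses
all 2N offspring with probability 2^−N per generation and demographic
extinction takes over. Within the gene-conversion-off cells the
half-lethal-rate gradient in N is below desk resolution (the study resolved
a 99.99% concentration at the largest N with 10⁵ replicates per set); the
desk checks therefore test the gene-conversion axis of the half-lethal
concentration statistically and the population-size axis of the
balanced-lethal containment exactly.

Problem sizes used by the test-suite and the acceptance script: burn-ins of
2000 and 5000 generations at N_BI = 25 (five runs each; the two populations
of a run are independent), and outcome-map cells of ≤50 replicates per
(N, GC) combination. These sizes are the package's desk defaults; all
statistical checks use tolerance bands or rank tests sized for them.

## Numerical choices

Pruning of fixed mutations runs every 5 generations (and always before any
measurement); delayed pruning cannot change relative fitness. Mutation
catalogs are append-only arrays (id = row); burn-in catalogs are compacted
to surviving mutations before reuse. Replicate seeds derive from a root seed
via `numpy` `SeedSequence([root, cell, burnin, replicate])`; no global RNG
state. Snapshots are JSON-lines + TSV with 17-significant-digit floats and
round-trip parsing, making every state bit-reproducible from disk.

## What the synthetic fixtures do and do not emulate

`fixtures` builds populations with exact, hand-chosen karyotype counts,
mutation placements and fixed registries — enough structure to unit-test
fitness, AOD, loads, classification and admixture bookkeeping against
closed forms (e.g. s′ = 1 − (1+s)^k for k symmetric private recessives).
They do not emulate linkage disequilibrium beyond their explicit placements,
nor segregating within-population variation unless specified. Passing
fixture tests therefore validates the statistics and bookkeeping, not the
evolutionary dynamics; those are covered by the scaled simulation tests,
within the desk-scale caveats above.

## Known limitations

- No sexes, overlapping generations, spatial structure, crossover
  interference, or arrangement-changing mutations; neutral mutations are not
  simulated.
- Desk-scale inflation of drift load and AOD (above); absolute probabilities
  of rare outcomes are not comparable to the study's, only orderings and
  ratios.
- At N ≲ 10 demographic extinction of balanced-lethal populations is a desk
  artifact absent at the study's sizes.
- The expected-pairing fallback scores whole-genome fitness, so at small N a
  genome-wide load contributes to "lethality" of a homokaryotype class; the
  classifier is therefore conservative about calling classes viable at desk
  scale.
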