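# Methods

## Founder genomes

Founders are simulated with msprime under a three-subspecies split model:
an ancestral population splits into the *mellifera* lineage and the common
ancestor of *ligustica* and *carnica*, which later splits into those two.
Published parameter estimates for honeybee demography vary widely, so the
model is a configurable stand-in: every effective size and split time is
exposed on `SplitDemography`. Defaults (Ne = 3000 per population,
lineage splits at 1000 and 3000 generations) are demonstration-scale round
numbers chosen so that subspecies show the expected nesting of genetic
distances (between-subspecies ≥ within) while coalescent simulation with
the honeybee's extreme recombination rate stays fast. Anyone studying a
question where absolute diversity or divergence matters should supply
their own demography; the simulator's downstream behaviour depends only on
the founder haplotypes, not on how they were obtained — phased VCFs or
plain 0/1 haplotype matrices can replace the coalescent entirely
(`import_haplotypes`, with haploid drone sources duplicated into fully
homozygous founders and non-segregating sites dropped).

Mutations use a binary model; the mutation rate is chosen adaptively
(starting from a Watterson argument, doubling until enough segregating
sites exist) and sites are thinned evenly to exactly the requested count
per chromosome, so requested dimensions are exact. Genetic map positions
are `bp × 2.3e-7` Morgans. The genome's often-quoted total of ~23 Morgans
is inconsistent with that per-bp rate over 250 Mbp (it implies 57.5 M); the
per-bp rate is treated as authoritative and the total is never used as a
constraint.

Default chromosome size is 1 Mbp (0.23 M) — a demonstration scale, like
the 3-chromosome × 100-site demo genome. Full-genome constants
(16 chromosomes, 250 Mbp total) are provided for realistic runs.

## Meiosis and inheritance

Haldane model per chromosome: crossover count ~ Poisson(map length),
positions uniform on the genetic map, no interference, no obligate
chiasma, starting haplotype fair-coin. This is the simplest standard model
and the only one compatible with treating map length as `bp × rate`.
Drone gametes are verbatim copies (clonal sperm). Identity-by-descent is
tracked as founder-haplotype labels carried through every gamete;
breakpoints coincide with crossovers by construction.

The csd window is given zero genetic width (all window sites share one map
position), which makes within-window recombinants impossible — exact and
branch-free, rather than rejection sampling recombinant gametes.

## csd locus

The allele space is the set of binary words over the window; window length
is `log₂(n_csd_alleles)`, so the allele count must be a power of two ≥ 2.
Founder editing deals the words round-robin along the haplotype sequence:
frequencies are as uniform as integer counts allow, all alleles occur when
there are at least as many haplotypes as alleles (a warning is issued
otherwise), and each founder receives two consecutive — hence distinct —
words, making every founder heterozygous. Base virgin queens are redrawn
until csd-heterozygous, because a homozygous egg would never have
developed.

Each fertilised egg draws its father uniformly from the spermatheca
(no paternity skew — nothing in the biology here pins down a skew model,
and uniform is the natural default). Homozygous brood is removed, counted
on the queen, and never topped back up: requesting 100 workers from a
queen with `pHomBrood = 0.25` yields Binomial(100, 0.75) survivors.

## Castes and colonies

Base virgin queens derive one-to-one from founders as two meiotic gametes
of the same founder (the "recombined founder genome" reading; the
alternative — verbatim founder haplotypes — was rejected to keep every
simulated individual a product of meiosis). Virgin queens may mother
drones only to bootstrap a simulation; workers never reproduce.

Colony events follow beekeeping semantics; choices the biology leaves open
are fixed as follows and exercised by tests:

- Rounding of `p × n_workers` is round-half-to-even (deterministic,
  unbiased).
- Swarm keeps the colony id on the swarm (identity follows the queen);
  split keeps it on the remnant, for the same reason.
- Both partitions of a swarm (or split) carry the event flag — flags record
  the event, not the role.
- `combine` keeps the strong colony's queen; the weak queen is discarded
  (marked dead).
- Virgin queens raised by swarm/split/supersedure default to the
  `n_virgin_queens` global, overridable per call.
- A collapsed colony keeps its members (for post-mortem genetics) and
  refuses all further mutating operations.
- Production turns on only at build-up and off at swarm, collapse,
  downsize, or being split off.

Counts and proportions may be numbers or samplers (fixed / Poisson /
zero-truncated Poisson counts; fixed / uniform / strength-dependent beta
proportions). The beta sampler's contract is monotonicity: its mean is
`p_max · s / (s + half_strength)`, increasing in colony strength s, with a
fixed beta precision — stronger colonies swarm with a larger worker share.

Each colony draws from its own RNG substream keyed by (root seed, colony
id), so vectorized MultiColony operations and colony-by-colony loops
produce identical traces, and any simulation is exactly reproducible from
the root seed.

## Mating

A DCA is a pooled drone population; a mating station pools drones from
sister daughter queens of one sire colony. Mating promotes the virgin
queen, stores the drones as her immutable father set, marks them dead, and
removes them from any pool — no drone can appear in two spermathecae.
Unused drones of a provided group remain available. Polyandry defaults to
15 fathers (within the biological 6–24 mating range; a truncated-Poisson
sampler reproduces that range distributionally).

## Quantitative genetics

Only additive architectures are implemented; statistical decomposition
into breeding values and dominance/epistasis deviations is out of scope
(the standard formulae assume Hardy–Weinberg equilibrium, which colonies
violate structurally).

QTL are sampled uniformly per chromosome outside the csd window (and SNP
chips avoid QTL). Raw per-QTL effect vectors are i.i.d. multivariate
normal with the requested correlation. Effects are then linearly
transformed so a Monte-Carlo sample (default 2000 genomes) of the *base
virgin-queen* distribution realizes the target covariance exactly, and
intercepts set the target means. The scaling sample includes the csd
heterozygosity screen, because on short chromosomes the screen measurably
shifts dosage variance at window-linked QTL; scaling against unscreened
genomes leaves realized variances systematically low. Realized
(co)variances in a fresh base population are then unbiased around the
targets (tests verify ±10% on variances and ±0.15 on the correlation at
n = 200 over 20 replicates).

Drones are scored as doubled haploids (dosage 0/2), keeping all values on
the diploid scale. Phenotypes redraw environmental deviates on every
`set_pheno` call; colony phenotypes use the latest stored values (drawn
lazily once if absent). The default colony value is queen-effect value of
the queen plus the *sum* of worker-effect values (the additive model
established for traits like honey yield); a mean-based variant and fully
custom mappings are supported.

## What the generator does and does not emulate

Synthetic founders reproduce segregating biallelic variation with a
subspecies split structure and the honeybee's recombination regime. They
do not model real linkage-disequilibrium decay, selection at csd beyond
the initial balanced editing, recurrent mutation, laying workers, drifting
between colonies, spatial mating, or environment-by-location effects.
Passing tests therefore demonstrate correctness of inheritance,
bookkeeping, event semantics, and calibration of the trait machinery —
not predictive accuracy for any specific real population.

## Problem sizes

Tests and the demo run at demonstration scale — tens of founders, 3 × 100
site genomes, colonies of 10–100 workers, 1000-trace event fuzzing,
20-replicate calibration checks at n = 200 — chosen so the whole suite
completes in about a minute while keeping every distributional check at
3 Monte-Carlo standard errors or better. All dimensions scale up by
configuration only.

## Known limitations

- The demography stand-in is not a fitted model; absolute diversity levels
  are arbitrary.
- `pHomBrood` for a *specific* father set is the formula value; the
  textbook 25% for brother mating is its expectation over random brothers
  and is realized exactly only when the brother group carries the two
  maternal alleles equally.
- Colonies have no within-season age structure; queen age is bookkeeping
  only.
- Performance is adequate for demonstration and method-development scales,
  not for 60 000-worker colonies.
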