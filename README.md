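# hivesim

Stochastic simulation of honeybee (*Apis mellifera*) populations and
breeding programs, for honeybee geneticists and breeding researchers who
need to test selection, mating, and conservation strategies in silico
before deploying them in real populations.

Honeybees break most assumptions of generic breeding simulators:

- **Haplodiploidy** — females (queens, workers) are diploid; drones develop
  from unfertilised eggs, are haploid, and produce clonal sperm.
- **Complementary sex determination (csd)** — fertilised eggs heterozygous
  at the *csd* locus become females; homozygotes are killed by workers, so
  the realized brood of an inbred queen falls short of the eggs laid.
- **Social organisation** — the operational and phenotypic unit is the
  colony (one polyandrous queen, her stored fathers, workers, drones,
  virgin queens), not the individual, and colonies undergo events: build-up,
  swarming, splitting, supersedure, downsizing, combining, collapse.

hivesim simulates individual genomes forward in time from coalescent
founders and aggregates individuals into colonies and apiaries.

## Model summary

**Genome.** Tracked loci are biallelic segregating sites with physical
positions; genetic positions are `bp × c` Morgans with a recombination rate
of `c = 2.3 × 10⁻⁷` per bp per meiosis. Meiosis follows the Haldane model:
per chromosome the crossover count is Poisson with mean equal to the map
length, crossover positions uniform on the map, no interference. Founders
come from an msprime coalescent under a configurable three-subspecies
split model (*A. m. mellifera* vs the ancestor of *ligustica* and
*carnica*), or from user haplotypes (phased VCF / 0/1 matrix).

**csd.** The locus is a window of `log₂(n_alleles)` non-recombining SNPs
(zero genetic width); the binary word along the window is the allele.
Founder windows are edited to `n_alleles` balanced, individually
heterozygous alleles. For a queen with alleles {a₁, a₂} mated to k fathers
with alleles f₁…f_k, the expected homozygous-brood proportion is

```
pHomBrood = (1 / 2k) · Σⱼ ( [fⱼ = a₁] + [fⱼ = a₂] )   ∈ [0, 1/2]
```

and every fertilised egg is screened accordingly (removals accumulate in
the queen's `n_hom_brood`).

**Quantitative genetics.** Additive traits: per-QTL effect vectors drawn
from a multivariate normal with genetic correlation `cor_a`, centred and
scaled so the base virgin-queen population realizes the target means and
variances; phenotypes add multivariate-normal environmental deviates.
Colony values use the additive queen/worker mapping: queen-effect value of
the queen plus the sum of worker-effect values of the workers. Genomic
relationships use VanRaden method 1.

## Worked example

```python
import hivesim as hs

founders = hs.simulate_founder_genomes(n_car=10, n_chr=3, n_seg_sites=100, seed=1)
sp = hs.SimParamBee(founders, n_workers=100, n_drones=10, n_csd_alleles=32, seed=1)

vqs = hs.create_virgin_queens(founders, 10, sp=sp)
colony = hs.create_colony(vqs[0], sp=sp)
dca = hs.create_dca(hs.create_drones(vqs[1], 1000, sp=sp), sp=sp)
group = hs.pull_drone_groups_from_dca(dca, 1, 15, sp=sp)[0]
hs.cross(colony, drones=group, sp=sp)
colony.build_up()
print(colony)
print("pHomBrood:", hs.p_hom_brood(colony.queen, sp=sp))
```

prints

```
Colony id: 1
Location: NA
Queen: 1
Number of fathers: 15
Number of workers: 100
Number of drones: 10
Number of virgin queens: 0
Has swarmed: False
Has split: False
Has superseded: False
Has collapsed: False
Is productive: True
pHomBrood: 0.0
```

Ten carnica founders were simulated with three chromosomes of 100
segregating sites each. The first base virgin queen founded a colony and
mated with 15 drones pulled from a 1000-drone congregation area: she is
promoted to queen, the 15 drones become her stored fathers, and the colony
has no virgin queens left. Build-up added the default 100 workers and 10
drones and switched production on. `pHomBrood = 0.0` because her csd
alleles share nothing with her fathers' — none of her brood was lost. Had
she instead mated with her own brothers, a quarter of the brood would be
expected homozygous (`pHomBrood = 0.25`), and `create_workers` would
return correspondingly fewer survivors.

A complete breeding-program demo (founders → base queens → DCA mating →
build-up → yearly events → colony values → selection) is available from
the command line:

```bash
hivesim run-demo --seed 1 --out demo_out
hivesim simulate-founders --seed 1 --out founders_out
```

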