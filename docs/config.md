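# Configuration schema

`hivesim run-demo`, `simulate-founders` and `export` read a YAML (or JSON)
document mirroring `hivesim.cli.RunConfig`. All keys are optional; unknown
keys are rejected. `--seed` and `--out` on the command line override the
file.

| key | type | default | meaning |
|-----|------|---------|---------|
| `seed` | int | 1 | root seed for every stochastic step |
| `n_founders` | int | 10 | coalescent founder individuals (carnica) |
| `n_chr` | int | 3 | chromosomes |
| `n_seg_sites` | int | 100 | tracked segregating sites per chromosome |
| `bp_per_chr` | int | 1000000 | physical chromosome length (bp) |
| `n_csd_alleles` | int | 32 | csd alleles (power of two ≥ 2); window = log2 SNPs |
| `n_workers` | int | 100 | full-size colony worker count |
| `n_drones` | int | 10 | full-size colony drone count |
| `n_fathers` | int | 15 | drones a queen mates with |
| `n_virgin_queens` | int | 3 | virgin queens raised by swarm/split/supersedure |
| `n_colonies` | int | 3 | apiary size |
| `years` | int | 1 | simulated years of colony events |
| `p_swarm` | float | 0.2 | per-colony yearly swarming probability |
| `p_supersede` | float | 0.1 | per-colony yearly supersedure probability |
| `p_collapse` | float | 0.05 | per-colony yearly collapse probability |
| `selection_prop` | float | 1.0 | fraction of colonies kept at selection |
| `with_traits` | bool | true | simulate queen/worker-effect traits |
| `n_qtl_per_chr` | int | 10 | QTL per chromosome |
| `trait_means` | [float, float] | [10, 1] | base means (queen effect, worker effect) |
| `trait_vars` | [float, float] | [1, 1] | base additive variances |
| `trait_cor_a` | float | -0.5 | genetic correlation between the two effects |
| `trait_var_e` | [float, float] | [1, 1] | environmental variances |
| `out_dir` | str | hivesim_out | output directory |

The `SimParamBee` constructor accepts the same caste-size and proportion
fields programmatically, plus samplers in place of numbers (see
`hivesim.make_count_sampler` / `make_proportion_sampler`) and
`swarm_p`, `split_p`, `downsize_p` event-proportion defaults.

Example:

```yaml
seed: 7
n_founders: 20
n_colonies: 5
years: 3
p_swarm: 0.3
selection_prop: 0.6
out_dir: run7
```
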