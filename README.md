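# redpiranha

Red Piranha Optimization (RPO): a three-phase swarm metaheuristic for
box-bounded continuous problems, its binary variant (BRPO) for subset
search, and a wrapper feature-selection pipeline scored by Gaussian
Naive Bayes accuracy.

The optimizer splits its iteration budget uniformly over three phases:

1. **Searching** — randomly drawn scouts lead clusters; members take
   exploratory jumps relative to their scout with step coefficients
   whose support is `[-2, -1) ∪ (1, 2]`, followed by a greedy
   best-of-history selection at the end of the phase.
2. **Encircling** — the `k` fittest agents define a virtual prey (their
   componentwise mean) that agents spiral toward on a logarithmic
   spiral, again with end-of-phase greedy selection.
3. **Attacking** — agents contract toward the prey with coefficients
   drawn from a linearly shrinking interval, accepting each step only if
   it improves the objective; optional pairwise collision checks at
   scheduled checkpoints relocate the weaker of any two agents closer
   than twice the safety-shield width `δ`.

The binary variant applies the same update rules to 0/1 vectors read as
reals and pushes every continuous result through a sigmoid transfer
function. The package also ships a synthetic clinical-table generator
(minority positive class, configurable effect size, missingness,
discretized columns) so the feature-selection pipeline is fully testable
offline, plus packaged fixtures that replay a fully worked numeric
example cell by cell.

## Command line

All commands honor `--seed`; identical inputs give byte-identical result
files. Progress goes to stderr, results to files. Exit codes: 0 success,
1 reproduction failure, 2 usage/config error.

```bash
# continuous optimization of a registered objective
redpiranha optimize --objective example_quadratic \
    --lower=-5,-5 --upper=5,5 --agents 10 --iterations 50 \
    --seed 1 --out results/opt.json --trace-out results/trace.tsv

# generate a synthetic clinical-style table (CSV + informative-mask sidecar)
redpiranha make-dataset --samples 500 --features 30 --informative 5 \
    --effect-size 1.0 --missing-rate 0.1 --seed 1 --out results/data.csv

# wrapper feature selection with the Naive Bayes fitness
redpiranha select-features results/data.csv --label-col label \
    --agents 20 --iterations 30 --seed 1 \
    --informative-mask results/data.informative.json \
    --out results/selection.json

# replay the packaged worked example and verify every checkable cell
redpiranha repro-example --verbose
```

`optimize` and `select-features` accept `--config <file>` with a flat
YAML key-value mapping mirroring the run parameters (`n`, `z`, `xi`,
`k`, `b`, `delta`, `n_ck`, `collision_enabled`, `seed`, ...); CLI flags
override file values.

## Python API

```python
import numpy as np
from redpiranha import ObjectiveSpec, RPOConfig, run_rpo, get_objective

spec = ObjectiveSpec(dimension=2, lower=np.array([-5., -5.]),
                     upper=np.array([5., 5.]),
                     objective=get_objective("example_quadratic"))
result = run_rpo(spec, RPOConfig(n=10, z=50, seed=1))
print(result.best_position, result.best_fitness)
```

For subset search, `run_brpo(fitness, f, config)` maximizes any
callable over nonempty bit vectors; `select_features` wires it to the
Naive Bayes fitness on a fixed stratified train/test split.

## Notes on the worked-example fixtures

The packaged tables reproduce the published worked example cell by
cell. A handful of printed cells carry typographically corrupted
coefficient draws and do not reproduce; they are kept in the fixtures
with `update_checked: false` and reported informationally. The printed
coordinates of the encircling-phase spiral updates are not consistent
with the stated spiral rule at all (the implied spiral factor differs
from the formula's); for that table only the distance vectors, prey
means, spiral parameters and objective values are enforced.
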