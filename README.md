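# explora

Explorability and dynamical robustness of sparse interaction networks
under generalized Lotka-Volterra (GLV) dynamics.

A system of S interacting units `dx_i/dt = x_i (alpha_i + sum_j w_ij x_j)`
has a stationary state `x* = -w^{-1} alpha` whose local stability is set
by the spectral abscissa of the Jacobian `J_ij = x*_i w_ij`.  This
package measures two properties of an interaction *topology* (the
pattern of non-zero weights):

- **Explorability** `V_E = 1 - x*_c`: sweeping the homogeneous fixed
  point `x*_i = x*` and re-solving the tunable weights row by row, the
  system is typically unstable below and stable above a single marginal
  abundance `x*_c`; the smaller `x*_c`, the larger the volume of
  feasible stable states reachable by tuning interactions.
- **Dynamical robustness** `R`: starting from the edge-of-stability
  matrix `w_edge` (abscissa exactly zero), random perturbations of the
  dynamics reduce to a perturbed Jacobian `J'_ij = xi'_i w_ij` with
  `xi' ~ U[0,1]^S`; `R` is minus the fifth percentile of the perturbed
  abscissa distribution.

Sparse "tree-like" topologies (one off-diagonal outgoing link per node,
connectivity `C = 2/S`) with a 3-node loop maximize explorability
(`V_E = 2/3`) and score highly on robustness; both measures decline, on
average, as connectivity grows.  The package also includes stochastic
hill climbing of the extra-link weights, the inverse-scaling fit
`C = c1/S` for empirical (S, C) tables, and a Monte-Carlo demonstration
that `C ~ 1/S` makes the classic random-matrix instability criterion
`sigma * sqrt(C S) > d` independent of system size.

## Library overview

| Module | Purpose |
| --- | --- |
| `explora.topology` | tree-like (functional-graph) topologies, adjacency masks, random extra links, joins |
| `explora.glv_core` | fixed points, spectral abscissa, validation ODE integration |
| `explora.explorability` | inverse-weight solver, marginal-stability scans, `P(V_E\|C)`, heterogeneous sampling |
| `explora.robustness` | edge-of-stability matrices, perturbed abscissas, the percentile statistic `R` |
| `explora.optimize` | stochastic hill climbing (single-, multi-objective, alternating) |
| `explora.sparsity` | `C = c1/S` fitting, synthetic scaling tables, instability-criterion demo |
| `explora.interface` / `explora.cli` | experiment orchestration and the `explora` command |

```python
import explora

topo = explora.make_tree_like(S=20, loop_length=3, seed=1)
res = explora.scan_marginal_homogeneous(topo)    # V_E = 2/3, x_c = 1/3
dist = explora.sample_explorability_distribution(topo, C=0.5, sigma_eps=0.1,
                                                 n_realizations=1000, seed=2)
rob = explora.sample_robustness_distribution(topo, C=0.5, sigma_eps=0.1,
                                             n_eps=100, n_xi=100, seed=3)
```

## Command line

Every subcommand writes CSV tables, a `summary.json` and a
reproducibility `manifest.json` into `--out-dir`:

```sh
explora --out-dir runs/tree --seed 7 explorability --size 20 --n-samples 100
explora --out-dir runs/dense --seed 7 robustness --size 20 --connectivity 0.5 \
        --n-eps 100 --n-xi 100
explora --out-dir runs/opt --seed 7 optimize --size 10 --connectivity 0.5 \
        --objective both --steps 200 --delta-eps 0.01
explora --out-dir runs/synth --seed 7 synth-table --c1 3.8 --n 83
explora --out-dir runs/fit fit --input runs/synth/scaling_table.csv
explora --out-dir runs/may may-demo --sizes 50,100,200
```

A JSON config file can supply parameters (`--config cfg.json`);
explicitly typed flags override it.

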