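# brainnet

Graph-theoretical analysis of task-fMRI functional connectivity, built
for within-subject comparisons of two task conditions. The pipeline
takes region-averaged BOLD time series (e.g. 90 AAL regions), removes
nuisance signals (global mean, white matter, CSF, six head-motion
parameters) by linear regression, computes the N×N Pearson connectivity
matrix per subject and condition, and binarizes it over a grid of
*sparsities* — the fraction of the N(N−1)/2 possible edges kept — so
every subject's network has the same edge count at every threshold.

On each binary network it computes the standard small-world and
centrality parameters:

- clustering coefficient `Cp`, characteristic path length `Lp`,
  global efficiency `Eglob`, local efficiency `Eloc`,
  nodal betweenness centrality `BC_i` (Brandes);
- normalized small-world statistics `γ = Cp/⟨Cp_rand⟩`,
  `λ = Lp/⟨Lp_rand⟩`, `σ = γ/λ`, where the reference ensemble consists
  of Maslov–Sneppen degree-preserving rewired surrogates
  (100 per network by default).

Threshold dependence is removed by integrating each metric over the
sparsity grid (rectangle rule, `aX = Σ_k X(s_k)·Δs`, default grid
0.10–0.49 in steps of 0.01). Hubs are regions whose group-level
normalized integrated betweenness (each subject's aBC vector divided by
its own mean, then averaged over subjects) exceeds the across-region
mean by more than one SD. Conditions are compared with paired t-tests
on the integrated parameters, screened by a Monte-Carlo Lilliefors
normality test and corrected with Benjamini–Hochberg FDR per family
(global parameters; nodal betweenness).

Because datasets of this kind are rarely shareable, the package includes
a synthetic-cohort generator with a known planted ground truth — a
small-world graph with hub regions and a modular two-level correlation
structure (0.6 within modules, 0.2 between, positive-definite projected)
plus white noise and recorded nuisance contamination — so every stage of
the pipeline can be validated against a known answer.

## Worked example

```python
import brainnet as bn

atlas = bn.default_atlas()                       # bundled 90-region AAL table
d = bn.simulate_cohort(bn.GroundTruthSpec(seed=7), 2)[0]
ts = bn.RegionalTimeSeries(d.timeseries, atlas.labels)
C = bn.pearson_matrix(bn.regress_nuisance(ts, d.nuisance))

for s in (0.10, 0.25, 0.49):
    net = bn.threshold_by_sparsity(C, s)
    r = bn.small_world(net, n_random=20, seed=1)
    print(f"sparsity {s:.2f}: Cp={r.cp:.3f} Lp={r.lp:.3f}  "
          f"gamma={r.gamma:.2f} lambda={r.lambda_:.2f} sigma={r.sigma:.2f}")
```

prints

```
sparsity 0.10: Cp=0.535 Lp=2.745  gamma=5.39 lambda=1.21 sigma=4.45
sparsity 0.25: Cp=0.486 Lp=1.843  gamma=1.76 lambda=1.05 sigma=1.68
sparsity 0.49: Cp=0.646 Lp=1.510  gamma=1.31 lambda=1.00 sigma=1.31
```

At every threshold the network keeps much more clustering than its
degree-matched random surrogates (γ well above 1) at essentially random
path length (λ ≈ 1), i.e. it is small-world across the whole sparsity
range — the regime expected for functional brain networks. The
`examples/` directory has one short script per capability (simulation,
connectivity, small-world statistics, AUC integration and hubs, paired
condition comparison).

A thin CLI mirrors the library stages:

```sh
brainnet simulate --out sim --n-subjects 21 --seed 1
brainnet connect sim/manifest.tsv --out conn
brainnet integrate conn --out-prefix int
brainnet hubs int_bc.tsv --out hubs.tsv
brainnet compare int_global.tsv int_bc.tsv --out-prefix cmp
brainnet run-all --config config.yaml --out report   # all of the above
```

`run-all` is deterministic: a fixed config and seed produce byte-identical
report tables.

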