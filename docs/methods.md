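# Methods

## Pipeline

For each subject and task condition the analysis proceeds:

1. **Region averaging** (optional): voxel time courses are averaged
   within each atlas region (1-based region labels; label 0 =
   unassigned). Any atlas with N ≥ 3 contiguous indexed regions is
   accepted; the bundled table has the 90 AAL regions, 45 per
   hemisphere, odd indices left and even right.
2. **Nuisance regression**: each regional series is replaced by the OLS
   residual of a regression on an intercept plus K nuisance columns
   (global mean, white-matter and CSF signals, six motion parameters in
   the standard design). Residuals are orthogonal to every regressor;
   rank-deficient designs are rejected with the offending columns named.
3. **Connectivity**: Pearson correlation between all region pairs,
   giving a symmetric N×N matrix with unit diagonal.
4. **Binarization**: at sparsity `s`, the `E = round(s·N(N−1)/2)`
   off-diagonal pairs with the largest |r| become edges (round half up;
   ties at the cutoff are broken by lowest (row, column) index so
   networks are bit-reproducible). Ranking by |r| is the default
   because nuisance regression of the global signal necessarily
   produces negative correlations and magnitude ranking is the dominant
   convention for binarized small-world analysis; `rank_by="positive"`
   switches to signed ranking.
5. **Graph metrics** on the binary network: Watts–Strogatz clustering
   (`C_i = 2E_i/(k_i(k_i−1))`, 0 for degree < 2, all nodes kept in the
   mean), BFS path length, Latora–Marchiori global and local
   efficiency, and Brandes betweenness counted over unordered pairs
   with endpoints excluded. Any consistent betweenness convention
   cancels in the hub normalization below.
6. **Null models**: γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ against
   Maslov–Sneppen double-edge-swap surrogates (default 100 surrogates,
   10 attempted swaps per edge — far past mixing at these sizes).
   Surrogate i uses seed `seed + i`, so ensembles are reproducible and
   parallel-safe. A network is small-world when γ > 1 and σ = γ/λ > 1;
   the stronger empirical observation σ > 1.1 is reported, not
   hard-coded.
7. **AUC integration**: every metric profile over the sparsity grid
   (default 0.10–0.49, step 0.01, endpoints included → 40 points) is
   summarized by the rectangle-rule area `Σ_k X(s_k)·Δs`, matching the
   plain-sum definition of the integrated parameters; a constant metric
   `x` integrates to `0.4·x` on the default grid.
8. **Hubs**: each subject's integrated betweenness vector aBC is
   divided by its own mean over regions (so each subject contributes a
   mean-1 profile), the normalized vectors are averaged over subjects,
   and regions above mean + 1 sample SD (over regions, strict
   inequality) are hubs. The alternative grand-mean normalization is
   available as a sensitivity flag (`mode="global"`), and the statistics
   are over regions of the group vector — the reading consistent with
   one reported value per region per condition.
9. **Statistics**: paired two-sided t-tests (df = M−1) on each
   integrated parameter, since the design is within-subject; an
   unpaired variant exists as a sensitivity flag. Normality of the
   paired differences is screened with a Lilliefors test whose p-value
   is Monte-Carlo simulated (default 10,000 standard-normal samples of
   the same length, seeded), which works at any sample size; the screen
   is skipped below 5 subjects. FDR (Benjamini–Hochberg) is applied
   within two separate families — the 6 global parameters and the N
   nodal betweenness tests — because the two tables are reported
   separately; raw p is always reported next to q.

Degenerate inputs: graphs with unreachable pairs return the
reachable-pairs mean path length together with an explicit
`disconnected` flag (global efficiency handles disconnection natively
via 1/∞ = 0); an edgeless graph has no defined path length and raises.
A star graph admits no legal degree-preserving swap; its surrogate
ensemble equals the graph itself and γ is defined as 1 there (both
clusterings are 0).

## Synthetic cohort generator

The generator exists so that every downstream stage can be tested
against a known ground truth. Defaults (chosen once, as the study
conditions):

| parameter | default | meaning |
|---|---|---|
| `n_regions` | 90 | atlas size |
| `n_timepoints` | 580 | ~20-min run at TR = 2 s minus discarded volumes |
| `backbone` | small_world | Watts–Strogatz ring lattice with rewiring |
| `base_degree` | 44 | lattice degree; planted density ≈ 0.51 |
| `rewiring_prob` | 0.05 | classic small-world regime |
| `hub_regions` | (0, 22, 45, 67) | planted hubs, one per quadrant |
| `hub_extra_degree` | 24 | ≈55% degree boost; hubs top the planted betweenness ranking |
| `n_modules` | 15 | contiguous six-region modules (functional-system scale) |
| `intra/inter_module_coupling` | 0.6 / 0.2 | target correlations on within/between-module edges |
| `condition_effect` | +0.1 | added to inter-module coupling in the "explicit" condition |
| `noise_sd` | 0.5 | white observation noise |

Two structural choices deserve explanation:

- **Backbone density spans the sparsity grid.** The planted graph's
  density (~0.51) sits just above the top of the default grid (0.49),
  so at *every* threshold the retained edges are genuine planted
  couplings and the binarized networks stay clustered and connected —
  the regime real functional networks occupy. A sparse backbone would
  make every threshold above its density fill up with noise edges and
  destroy small-worldness there.
- **Small modules.** With six-region modules the total budget of
  strong (0.6) within-module edges (~765) stays above the lowest
  threshold's edge budget (401 at s = 0.10) while leaving most lattice
  edges between modules, so low-sparsity networks remain connected
  rather than splitting into module components.

The covariance is built from the graph: target correlation 0.6 on
within-module edges, 0.2 (+ effect) on between-module edges, 0
elsewhere, unit diagonal, then projected to a positive-definite
correlation matrix by eigenvalue clipping at 1e-6 with diagonal
renormalization (iterated; any strictly positive-definite result is
accepted). Because the raw target is indefinite, projection attenuates
between-module targets (0.2 → ~0.15). Observation noise further
attenuates all observed correlations by 1/(1+noise_sd²) = 0.8. Both
attenuations are uniform, and sparsity thresholding ranks correlations,
so planted-structure recovery is unaffected; tests that check observed
edge correlations compare against the generator's own attenuated
target, not the nominal coupling.

Nuisance contamination is linear-additive with recorded per-region
mixing weights (a shared smooth global component, white-matter- and
CSF-like smooth signals, six random-walk motion drifts), which makes
nuisance regression exactly testable: residual correlations with the
planted components vanish to numerical precision.

Subject k draws from a generator seeded `seed + k`; the whole cohort is
bit-reproducible from the spec.

**What the generator does not emulate:** hemodynamic response
convolution, temporally autocorrelated BOLD noise, event/block task
structure, scanner drift nonlinearity, or inter-subject anatomical
variability. Passing tests therefore demonstrate that the *pipeline*
recovers known statistical structure from stationary Gaussian data of
realistic size — not that any particular empirical dataset has that
structure.

**Direction of the condition effect.** Raising inter-module coupling
uniformly changes which candidate edges win at the sparsity cutoff only
where couplings contend with the sampling-noise floor. In that regime
the "explicit" condition's stronger between-module couplings displace
spurious noise edges; since noise edges are uniformly random (the most
efficient shortcuts), integrated global efficiency is slightly *lower*
and clustering/local efficiency *higher* in the explicit condition
under this generator. The effect is reliably detected two-sided at
M = 21; the sign is a property of the generator's edge-competition
mechanism, not a general claim about task data.

## Numerical choices

- Edge counts use round-half-up (`floor(s·M + 0.5)`) so grid points
  like 0.10 × 4005 give the expected 401 under floating point.
- The rewiring kernel is numba-compiled with a pure-python fallback of
  identical RNG semantics (`np.random.seed`-driven; seeds reduced mod
  2^32); both are tested to produce identical surrogates.
- γ/λ profiles reuse one surrogate-seed stream per subject/condition
  (point k, surrogate i → `seed + k·n_random + i`), so integrated
  values are reproducible and independent of evaluation order.
- Matrix files are TSV with `%.17g` serialization: write→read
  round-trips are bit-exact; asymmetry ≤ 1e-8 on read is repaired by
  averaging, larger asymmetry is an error.
- Lilliefors Monte-Carlo p uses the (1 + #{D_mc ≥ D})/(n_mc + 1)
  estimator. Power against strongly skewed alternatives is ~0.97 at
  α = 0.05 for exponential samples of n = 50 (and ~0.84 at α = 0.01).
- A paired test with identically zero differences returns t = 0, p = 1
  (no evidence); constant non-zero differences raise, since t is
  undefined.

## Problem sizes used by the test and acceptance suites

Simulation-based checks run at sizes chosen to make their statistical
assertions sharp while completing comfortably on one CPU: the
small-world cohort check uses 10 subjects × 40 grid points × 20
surrogates at N = 90; hub recovery uses 10 replicates of 10-subject
cohorts with a 14-point grid; calibration and power of the paired
comparison use a reduced N = 30 cohort (base degree 6, fifteen
two-region modules, hubs at 0 and 15) with 400 null and 200
effect replicates at M = 21. The acceptance script reports the
cohort-median subject's minimum σ over the full grid for a 10-subject
cohort with 20 surrogates per grid point.

## Known limitations

- Weighted, directed, and partial-correlation networks are out of
  scope, as are modularity/rich-club/assortativity summaries and
  voxel-level preprocessing (the pipeline starts from regional series).
- Surrogate connectedness is not enforced; disconnected surrogates use
  the reachable-pairs path-length convention and are counted and
  warned about.
- The hub criterion's SD is taken over regions of the group-averaged
  normalized vector; the per-subject alternative is exposed only through
  the normalization flag.
- Lilliefors p-values are Monte-Carlo estimates; with the default
  10,000 draws their resolution is ~1e-4.
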