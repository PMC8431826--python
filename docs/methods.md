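# Methods

## Dynamics model and stabilization

The package models neural dynamics on an anatomical network as the
discrete-time, noise-free, time-invariant linear system
`x(t+1) = A x(t) + B_K u(t)`. `A` is the symmetric region-by-region
streamline-density matrix with an exactly zero diagonal; `B_K` stacks
canonical basis vectors for the control set `K`; `u(t)` is the control input.
Linear models of this form capture a useful share of slow neural dynamics and
make controllability quantities analytic; they ignore nonlinearity,
conduction delays and state-dependent gain, which is the standard trade-off
in network control analyses of diffusion-imaging data.

Two stabilization conventions are implemented:

- `mean-edge` (default): divide `A` by the mean over *nonzero* off-diagonal
  entries, each undirected edge counted once. Including structural zeros
  would make the scale depend on network density, whereas the intent is to
  normalize an edge-weight statistic. After rescaling, the mean nonzero edge
  weight is exactly 1. This convention does **not** bound the spectral
  radius: on realistic dense weighted networks ρ(A) > 1, so modal factors
  `(1 − λ_j²)` can be negative and φ can be negative. φ remains a valid
  (relative) ranking — its Spearman correlation with weighted degree is
  strongly negative either way — but users wanting φ ∈ (0, 1] should use:
- `spectral`: divide by `1 + |λ_max|`, guaranteeing ρ < 1.

Volume normalization (`counts_ij / (vol_i + vol_j)`), when used, is applied
at network construction, before stabilization: the normalized matrix *is* the
connectome; stabilization is a property of the dynamics model.

Input validation symmetrizes asymmetries up to 1e-9 by averaging (declared
symmetric data, numeric noise only) and rejects anything larger; diagonals
must be zero to 1e-12; node indices are 0-based internally with label files
as the source of region identity.

## Modal controllability

`φ_i = Σ_j (1 − λ_j²) v_ij²` over the eigenpairs of the stabilized matrix,
computed with the symmetric-matrix eigensolver (real spectrum guaranteed;
eigenpairs sorted by descending eigenvalue). φ is invariant to eigenvector
sign, eigenpair ordering and — for repeated eigenvalues — to the choice of
orthonormal basis within an eigenspace, because `Σ_j∈E v_ij²` is the
projection norm onto the eigenspace E.

The controllability Gramian `W = Σ_{t<T} Aᵗ B Bᵀ (Aᵀ)ᵗ` uses horizon
`T = N` by default (Cayley–Hamilton: longer horizons add no rank);
controllability verdicts use the numerical rank of `W` with tolerance
`N · eps · σ_max`. On symmetric matrices with distinct spectra this verdict
coincides with the PBH eigenvector test (node i controls the system iff no
eigenvector vanishes at i), which the test suite checks on random and
structured systems (path graphs driven from their midpoint are the canonical
uncontrollable case: odd modes have exact zeros there).

## Community structure and boundary controllability

Partitions maximize Newman–Girvan modularity with resolution γ,
`Q = (1/2m) Σ_ij [a_ij − γ k_i k_j/(2m)] δ(m_i, m_j)`, via seeded Louvain
optimization (networkx implementation). Because the modularity landscape is
highly degenerate, each resolution is optimized `n_opt` times (default 100)
over a γ grid (default 1.0–4.0 in steps of 0.1) and summarized by the mean
pairwise z-Rand score; the selected γ* maximizes that agreement, with ties
broken toward the smaller (coarser, more conservative) γ.

The z-Rand score z-normalizes the count `w` of node pairs co-clustered in
both partitions against its exact mean and variance under the null that both
partitions' group sizes are fixed and labels permuted (the
Traud–Kelsic–Mucha–Porter moments). The implementation matches exhaustive
permutation enumeration exactly on 6-node partitions. One caution the test
suite documents: the *raw* z-score of a partition with itself is not
guaranteed to dominate its z-score against every other partition — the null
variance depends on both group-size profiles, so z-scores are only comparable
at a fixed profile (where z is monotone in `w` and identity attains the
maximum `w`). Degenerate nulls (e.g. all-singleton vs all-singleton) return 0
with a warning.

The consensus partition re-clusters the co-assignment frequency matrix,
thresholded at the mean co-assignment expected under label permutations, with
the same Louvain procedure, iterating until all runs agree (or 10 iterations,
then the modal input partition is returned with a warning). An alternative
"pick the partition with maximal mean z-Rand to its peers" is available
behind `consensus_method="best-zrand"`.

Boundary controllability is operationalized deterministically: node i's
boundary fraction is the share of its strength on edges leaving its module;
nodes with at least one inter-module edge are ranked above purely
within-module nodes, ordered by descending fraction, then by the number of
distinct foreign modules reached, then node order; within-module nodes follow
by descending strength. Rank 1 is the strongest boundary controller and the
zero-centered rank `rank − (N+1)/2` is the covariate used in the behavioral
models (so *negative* centered ranks mean *stronger* boundary control). With
tied strengths the index tie-break makes ranks depend on node order;
boundary fractions themselves are exactly permutation-equivariant.

## Synthetic data

The connectome generator plants a weighted stochastic-block structure:
defaults 111 nodes (a whole-brain anatomical parcellation with cerebellum),
5 modules, within/between edge probabilities 0.4 / 0.05 (an 8:1 contrast, the
detectability margin at which the community stage is expected to recover the
planted modules), and log-normal weights with log-scale σ = 0.5 — positive
and right-skewed like streamline densities, with the dispersion chosen so
that planted structure at the 8:1 contrast is recoverable (ARI > 0.9); much
heavier tails bury block structure under single dominant edges. Node 0 is
labeled `LIFG` and designated the target.

The behavioral generator produces `log RT = fixed-effect linear predictor +
subject intercept + subject trial-order slope · order + Gaussian residual`,
`RT = exp(log RT)`. Defaults: 25 active / 16 sham subjects, 50 trials per
task per session; coefficient scale follows published moderation analyses of
this design (intercept 7.233; stimulation −0.030; session 0.024; boundary
−0.002; stimulation × session −0.088; stimulation × boundary 0.003;
stimulation × session × boundary −0.003; entropy 0.155; association −0.666;
entropy × boundary 0.001; task −0.49 for sentence completion against the
verb-generation reference). Random-effect SDs (intercept 0.20, trial-order
slope 0.002, residual 0.30 on the log scale) are typical of log-RT mixed
models; item covariates are independent Beta(2, 2) draws on [0, 1] standing
in for LSA entropy and association values (their corpus computation is out of
scope). Contamination: 1% implausibly fast (< 200 ms), 1% implausibly slow
(> 10,000 ms), 4.5% error-flagged — matching the mid-single-digit exclusion
percentages such experiments report.

What the generator does *not* emulate: item-level repetition structure and
counterbalancing, correlated entropy/association within items, non-Gaussian
residuals (true RT distributions are heavier-tailed than log-normal even
after the log), spatial embedding and distance-dependent connectivity, and
any genuine coupling between a subject's network and their behavior beyond
the boundary/modal covariates fed forward. Passing tests therefore certify
the estimators and the pipeline wiring, not claims about real cohorts.

## Mixed-effects models

All model families regress log RT (natural log; the choice is immaterial up
to scale) with maximum likelihood, a random intercept per subject and a
random slope for trial order per subject (a superset of the two random-effect
descriptions such designs use; `drop_slope=True` removes the slope).
Treatment coding references sham / pre / verb-generation / low. Demand
covariates are median-split per task (values at the median go to "low" — a
deterministic, documented tie rule) for categorical interactions, and
mean-centered per task when left continuous for interactions with the
controllability covariates.

Numerical choices: the random-slope design column is standardized internally
(raw trial order gives slope variances near 4e-6, which stalls quasi-Newton
optimizers); fixed effects stay on raw units. Fits try L-BFGS first and retry
once with the backend's default optimizer sequence from fresh start values;
non-convergence is flagged in the output, never silent. Fixed-effect tests
are Wald statistics with residual degrees of freedom — a Satterthwaite
approximation is not available in the fitting backend, and the fallback is
flagged as `df_method="residual"` in every output table. With trial-level
sample sizes in the thousands the difference is negligible; with very few
subjects the residual-df p-values for between-subject terms are mildly
anti-conservative (the Monte-Carlo calibration check in the acceptance suite
bounds the realized type-I rate at 5% ± 2% with 40 subjects).

The active-vs-sham comparison of per-subject boundary values is a two-sided
Wilcoxon–Mann–Whitney rank-sum test (exact for small untied samples).

## Pipeline and problem sizes

`run_pipeline` derives all stage seeds from one master seed via
`SeedSequence`, writes every table as TSV with repr-faithful floats, and
records configuration, seeds and SHA-256 hashes of all outputs in a JSON
manifest with no timestamps, so identical configurations reproduce identical
bytes. Orchestration defaults use a coarser sweep (γ step 0.5, 20
optimizations) than the single-network defaults so a full per-subject cohort
run stays interactive; both are configurable up to the study-faithful grid.
The test suite's Monte-Carlo experiments use 100 replicates at 200 subjects
for coverage/bias and 500 replicates at 40 subjects for type-I calibration;
the acceptance script analyzes one 41-subject cohort end to end.

## Known limitations

- The linear noise-free dynamics and the single-node control sets are
  idealizations; no control-energy or trajectory quantities are computed.
- Boundary controllability is an inter-module-strength surrogate chosen for
  exact testability; it is not the hierarchical multi-scale construction of
  the engineering literature.
- Heteroskedastic residual modeling is not implemented.
- Printed coefficients from any specific empirical cohort are not
  reproduction targets: they depend on raw data that is not redistributable,
  and the synthetic cohort only matches their scale, not their values.
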