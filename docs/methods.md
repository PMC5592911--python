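# Methods

## Model

One gene is an `N × p` block of counts `Y_ij` (samples × isoforms). The null
model is intercept-only per isoform with log link,

    log E(Y_ij) = μ + α_j,      γ_ij = exp(μ + α_j),

and the alternative adds per-isoform group effects `β_j x_i` with
`β ~ N(0, τ²I_p)`. Testing "any isoform differentially expressed" is testing
the variance component `H0: τ² = 0`, a boundary hypothesis handled by a score
test: only the null model is ever fitted, which keeps per-gene cost low and
makes genome-wide permutation feasible.

Counts are Poisson or NB. The NB dispersion convention is
`Var(Y) = γ + φγ²` throughout; `φ → 0` recovers Poisson, and every NB
quantity in the package reduces continuously to its Poisson counterpart in
that limit (property-tested).

### Null fit

The default (`mode="fixed"`) treats the `α_j` as free parameters, so the
fitted mean of isoform `j` is exactly its column mean — the intercept-only
MLE for both families. This follows the derivation of the test itself, in
which the baseline term is profiled out as a fixed parameter. A `random`
mode is available that shrinks the per-isoform intercepts with a
N(0, σ²) ridge penalty (Newton iterations on the Poisson likelihood;
dispersion estimated afterwards at the fitted means); it reduces to the
fixed fit as σ² → ∞ and exists for fidelity to mixed-model implementations
of the same test. The variance of `α` itself is never estimated — the score
statistic does not need it.

`(μ, α)` are only identified up to a shift; we report them under a
sum-to-zero constraint on `α̂`. Only `γ̂` enters the statistics, so the
choice is cosmetic.

Isoform columns with zero total count carry no information and are dropped
with a logged warning before fitting; a gene with no non-zero isoform is
reported as degenerate and skipped.

### Dispersion

`φ̂` maximizes the NB likelihood at the fixed fitted means, by bounded 1-D
search on log φ over [1e−8, 1e4]. Near the lower bound the NB likelihood is
flat and `gammaln(y + 1/φ)` noise dominates, so the estimate is snapped to
the boundary whenever φ ≤ 1e−6 or the (exactly computed) Poisson likelihood
is at least as good. The boundary is a valid return, not an error:
under-dispersed or constant columns land there. The adaptive family rule
(`choose_family`) uses NB unless the fit fails or `φ̂ < 1e−3` (threshold
configurable), mirroring the practice of falling back to Poisson when the
estimated dispersion is negligible.

## The score statistic and its two nulls

With `z̃ = Φ(Y − γ̂)` (`Φ = diag(1/(1+φγ))`, identity for Poisson) the score
in `τ²` collapses to a per-isoform form,

    U = ½ ( Σ_j (Σ_i x_i z̃_ij)² − Σ_i x_i² Σ_j w₀_ij ),

equal to the dense `Np × Np` matrix expression (oracle-tested to 1e−10).

**Covariate centering.** `test_gene` centers `x` before testing. This
matters: with per-isoform intercepts *estimated*, the residual columns are
centered, and for a raw 0/1 coding the quadratic term loses half its
variance while the trace term does not — `U` acquires a negative mean and
`Var(U)` falls far below the profile information `Ĩ` (we measured
`Var(U)/Ĩ ≈ 0.2` at typical settings), so a chi-square test on `U²/Ĩ`
rejects essentially never. Centering makes the variance-component score
orthogonal to the intercept scores, restoring `E[U] = 0` and
`Var(U) ≈ Ĩ` (verified by a 20,000-replicate known-parameter check at 15%
tolerance), and for balanced binary designs it also makes the trace term
invariant under label permutation, removing pure noise from the empirical
null. `score_statistic` itself is coding-faithful: it evaluates whatever
design vector it is given.

**Theoretical null.** `Ĩ = I_ττ − I_ᾶτᵀ I_ᾶᾶ⁻ I_ᾶτ` with

* `I_ττ = ¼ Jᵀ(A R A)J`, where `A` is the diagonal of `XXᵀ`
  (`a_i = x_i²`, replicated over isoforms) and `R` is block-diagonal with
  per-isoform `N × N` blocks: diagonal
  `r_ii = w⁴δ⁻⁴κ₄ + 2w² + e²κ₂ − 2w²δ⁻²eκ₃`, off-diagonal `2w_i w_i'`;
* `I_ᾶτ = ½ K̃ᵀ C ã` with `c_ii = w³δ⁻³κ₃ − e w δ⁻¹ κ₂` (for the log link
  this simplifies to `c_ii = w` in both families — a useful internal
  consistency check);
* `I_ᾶᾶ = K̃ᵀWK̃`, singular by construction (the `K̃` columns are linearly
  dependent), inverted by Moore–Penrose pseudo-inverse (relative cutoff
  1e−10).

Cumulants come from the exponential-family relations `κ₂ = V`,
`κ₃ = V′V`, `κ₄ = (V″V + V′²)V`; for the NB they agree with the closed-form
NB cumulants (tested symbolically and by Monte Carlo). Both `r_ii` and
`c_ii` are evaluated from the general expressions rather than
family-specific shortcuts; the general forms are exactly the per-observation
contributions to `Var(∂l/∂τ²)` and `Cov(∂l/∂α̃, ∂l/∂τ²)` (re-derived from
first principles) and reduce correctly as φ → 0.

The default reference is the 1-df chi-square on `U²/Ĩ`. Because the
variance-component alternative is one-sided (τ² > 0 only inflates U), a
one-sided normal p-value on `U/√Ĩ` is also reported; the chi-square default
is kept as the conventional scalar form, and is mildly conservative for the
one-sided alternative.

**Empirical null.** The H0 fit does not involve `x`, so residuals and
weights are computed once; B label permutations then reduce to one
`(B×N)·(N×p)` matrix product. The p-value is one-sided with the add-one
convention, `p = (1 + #{U_b ≥ U_obs})/(B + 1)`; ties count against
rejection. For two-level designs with at most B distinct label arrangements
the permutation distribution is enumerated exactly instead (and is then
invariant under any relabeling of the samples). Default B = 5,000;
simulation studies in this repository use B = 1,000, which changes the
α = 0.05 rejection threshold only in the fourth decimal.

## Synthetic data

`simulate_gene` draws `α_j ~ N(0, s)`, `β_j ~ N(0, l)` (zero under the
null), sets `mean_ij = exp(M + α_j + β_j x_i)` and samples Poisson or NB
counts; the design is `n_cases` ones then zeros (20/20 of N = 40 by
default — the balanced split is our choice; only the total is fixed by the
study design). `β` is redrawn per gene: each simulated gene is an
independent draw from the random-effects model. Per-gene seeds are
counter-based (`SeedSequence(seed, spawn_key=(k,))`), so results are
bit-identical regardless of parallel worker count.

What the generator does *not* emulate: library-size differences between
samples (the test is applied to non-normalized counts by design),
correlation between isoforms beyond the shared baseline, isoform-assignment
uncertainty from read mapping, and gene-gene dependence. Passing simulation
tests therefore demonstrates correctness of the statistic under the stated
generative model, not robustness to those real-data features.

### Mapping the study grid labels to model parameters

The simulation grid this package reproduces was originally run in R, and two
of its labels do not denote what a literal reading suggests. We infer from
the printed result surfaces (which are the authoritative record of what the
generating code did):

* the dispersion label `d ∈ {0.5, 2}` is the NB **size** (`rnbinom`'s
  `size`), i.e. model dispersion `φ = 1/d`. Power is higher at d = 2 than
  d = 0.5 in every printed cell, and Poisson-based competitors inflate worst
  at d = 0.5 — both impossible if d were φ itself (more overdispersion
  cannot raise power);
* the heterogeneity labels `s` and `l` are the **SD** argument of `rnorm`,
  i.e. model variances `s²` and `l²`. With variance-l effects the printed
  low-effect power cells are overshot by factors of two while the l = 1
  cells (where both readings coincide) are not; with SD semantics the whole
  surface fits to within a few percent.

`scenario_from_labels` implements this mapping; `Scenario` itself always
takes plain variances and `φ`, so the two layers cannot be confused.

## Replication accuracy and known limitations

With the label mapping above, the package reproduces the study's permutation
type-I error (≈ 0.05 everywhere, printed 0.049–0.071), its low-effect power
cells, and the theoretical-null power at the strongest setting (ours ≈ 0.81
vs printed 0.792). Two strong-effect permutation-power cells measure
0.03–0.04 below the printed values (0.946 vs 0.980 at l = 0.6, p = 8;
0.924 vs 0.958 at l = 1, p = 8, d = 0.5) — a real gap, plausibly from the
difference between our fixed-means ML dispersion estimate and the original
mixed-model (glmer.nb) estimate, whose bias under the alternative affects
the shrinkage `Φ̂` applied to the residuals. The original theoretical-null
column also behaves differently at intermediate settings (it collapses with
p, e.g. printed 0.107 at l = 0.6, p = 8 where its own permutation power is
0.980); that pattern is characteristic of an uncentered-covariate score
whose drift must be overcome before the chi-square threshold, and is not
reproduced by the centered statistic here, which keeps theoretical and
permutation power in close agreement.

Other limitations: a single covariate vector only (no covariate matrices);
no higher-order small-sample corrections; the scalar chi-square form rather
than exact mixture-chi-square weights; no normalization or library-size
correction; the simulation replicate counts used in tests and the
acceptance script (500–8,000 per cell) were chosen to keep Monte-Carlo
error comfortably below the comparison tolerances.
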