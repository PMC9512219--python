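# Methods notes

## Model and residuals

The Cox model is fit by Newton iterations on the partial likelihood
(tolerance 1e-9 on the score norm, at most 100 iterations, step-halving),
with **Breslow** tie handling and the Breslow baseline cumulative hazard;
Efron is available as an option. Breslow is the default because it keeps the
score identities Σ M_i = 0 and Σ M_i X_i = 0 exact at the maximizer, which
the downstream orthogonalization relies on; simulated event times are
continuous (tie-free), where Breslow and Efron coincide, and the test suite
cross-checks both residual types against lifelines on such data. With p = 0
the fit reduces to the Nelson–Aalen-style baseline. Monotone likelihood is
flagged (runaway Newton steps, or convergence at |β| > 10 — the score also
vanishes as |β| → ∞, so separation can look like convergence) and reported
as a warning rather than an error.

Deviance residuals apply D_i = sign(M_i) √(−2 {M_i + Δ_i log(Δ_i − M_i)})
exactly, with D = 0 at M = 0 and a domain check that names offending
samples. Residuals are computed once per dataset and never refit inside
permutations.

## Permutation scheme

All tests share one `PermutationPlan` (B index vectors from a seeded
generator; exhaustive enumeration available for tiny n). The residual
regressor is permuted, **re-orthogonalized against X and re-normalized at
every permutation**; the covariate projection of the taxon matrix is fixed.
Keeping X in the permuted model is what gives the adjusted tests their power
advantage over the unadjusted kernel score test, whose nulls permute the raw
Martingale residuals without re-adjustment — that design difference is
deliberate and reproduces its documented conservativeness under
confounding.

p-values use the add-one rank rule p = (1 + #{null ≥ observed})/(B + 1), so
p ≥ 1/(B+1) always. Comparisons carry a 1e-12 relative slack so a null
permutation mathematically equal to the observed statistic (the identity)
counts as at least as extreme despite floating-point jitter between the
vectorized and scalar code paths.

The min-p combination uses, for each permutation b, the leave-one-out null
p-value p_c^(b) = (1 + #{b′ ≠ b : stat ≥ stat_b})/B per component, takes
minima across components, and ranks the observed minimum among them. A
single-component combination returns that component's p-value exactly (a
property the rank rule implies; we shortcut it). Per-taxon combinations run
the same rule columnwise with each taxon's own permutation null — taxon
variances are heterogeneous, so nulls are never pooled across taxa. The
LDM-c test under abundance scenarios combines all four streams (2 scales ×
2 residuals) in one flat min-p rather than nesting scale-omnibus inside a
residual combination: the flat rule is the same machinery applied once and
is invariant to component relabeling; nesting would add a layer of rank
granularity without a statistical rationale.

Fixed B per analysis (default 5000 in the CLI, 1000 in the benchmark
harness); no sequential/adaptive stopping. Consequence: the smallest
attainable p is 1/(B+1), so BH detection at q = 0.10 with J ≈ 200 taxa
requires several taxa near the minimum simultaneously, and detected sets
inherit a mild "piggyback" granularity effect (see limitations).

## Statistics

Per taxon, F_j = U_j² / (‖z*_j‖² − U_j²) with U_j = r̃ᵀ z*_j; globally
F = Σ U_j² / Σ(‖z*_j‖² − U_j²). Degrees-of-freedom constants are omitted
(permutation-invariant). Degenerate taxa (zero covariate-adjusted norm, e.g.
constant presence columns) get F = 0 and p = 1, flagged. A regressor lying
in the covariate span is an error. With no covariates the global statistic
is a monotone transform of the linear-kernel score rᵀZZᵀr, so its
permutation p-value coincides with the kernel score test's on a shared plan
(asserted in tests).

PERMANOVA pseudo-F uses the Gower-centered squared-distance kernel
G = −½ C (D∘D) C: F = (r̃ᵀGr̃) / ((tr G − tr HGH)/(n − p − 2)) with H the
projection onto span(basis(X), r̃). Squaring applies to all metrics,
including the semimetric Bray-Curtis, matching standard PERMANOVA practice;
negative eigenvalues of G are retained as-is.

## Analysis scales and distances

relabund = count / library size, where the library size is the **original**
(pre-filter) row sum — prevalence filtering only drops columns; arcsinroot =
asin(√relabund), transformed first, centered after; presence = 1{count>0}.
Bray-Curtis pairs with relabund, Jaccard with presence (two all-zero rows
are defined as distance 0), Euclidean with anything. Rarefaction is
multivariate-hypergeometric (without replacement), seeded; samples below the
depth are dropped with a warning. Externally computed distances can be read
from square TSV.

## Synthetic data generator

The generator emulates a confounded microbiome–survival study:

* **Baseline frequencies** π₁: power-law j^(−γ) with γ = 1.0 by default,
  sorted decreasing and normalized, J = 856 taxa by default — a synthetic
  stand-in shaped like a real upper-respiratory-tract profile (strong
  dominance, long rare tail); a frequency file can substitute real
  estimates. γ = 1 makes the most abundant taxon ≈ 14–17% of the community
  at J = 200–856, comparable to dominated human microbiome profiles.
* **Confounding**: 100 randomly chosen taxa have their frequencies permuted
  among themselves to form π₂; subject frequencies are
  π̃(X_i) = (1 − β_XZ X_i) π₁ + β_XZ X_i π₂ with binary X (n/2 per group)
  and β_XZ = 0.8 for a strong confounder, 0 for a plain covariate.
* **Counts**: Dirichlet-multinomial with concentration (1 − θ)/θ (so the
  pairwise overdispersion parameter equals θ; θ = 0.02 default, 0.002 and
  0.0002 supported for the sparsity contrast; θ = 0 is plain multinomial).
  Library sizes ~ N(10000, (10000/3)²), redrawn while < 1000 ("left
  truncation by rejection"), then rounded.
* **Causal score**: S_i = Σ_{j∈A} δ_j Z_ij/Z̄_j on observed frequencies of
  the 10 most abundant taxa (model M1), or S_i = Σ δ_j 1{Z_ij>0} for 10
  taxa drawn from abundance ranks 11–100 (model M2); directions δ_j = ±1
  and the sets A are fixed per experiment seed, counts/survival vary with
  the replicate seed. Custom causal sets support single-taxon and rare-taxa
  scenarios; `score_scale` overrides the abundance/presence choice.
* **Survival**: Cox-Weibull T = 10 B^(−1/2) (−log V)^(1/2) (Weibull(2,0.01)
  baseline) with B = exp(β_XS scale(X) + β scale(S)), β_XS = 0.5; or
  accelerated hazards T = B⁻¹ exp(Φ⁻¹[1 − exp(B log V)]) with lognormal
  baseline, whose survival curves for B and 1/B cross (closed form
  S(t|B) = (1 − Φ(log Bt))^(1/B), checked deterministically). scale(·)
  standardizes with ddof = 1 (the R convention); a constant input maps to
  zero with a warning. Censoring ~ Exp(μ): μ = 0.03/0.08/0.2 give ≈
  25/50/75% censoring under the Weibull model, μ = 0.5 ≈ 50% under AH.

What the generator does *not* emulate: phylogenetic structure,
zero-inflation beyond the DM, library-size confounding (sizes are balanced
between groups), time-varying effects. Passing tests therefore say nothing
about those aspects of real data.

## Benchmark harness and problem sizes

Each replicate: simulate → filter taxa present in < 5 subjects → one Cox fit
→ all requested tests on one shared permutation plan. The taxon-by-taxon Cox
comparator fits every (X, one-taxon) model with a vectorized Newton solver
(Breslow ties); taxon covariates are standardized inside the fit (the Wald z
is scale-invariant) because raw relative abundances put true coefficients at
O(1/scale) where divergence guards would misfire. Non-converged, separated
or covariate-collinear taxa are flagged and assigned p = 1 (non-detections).

The acceptance runs use n = 100, J = 200 synthetic taxa, and R = 1000
replicates for type-I error (500 for the confounder-omission and
FDR/sensitivity runs, 300 for the overdispersion contrast) — sizes chosen so
the whole benchmark reruns in minutes while keeping Monte-Carlo standard
errors near 0.007 on a 5% rejection rate; the full-scale settings (J = 856,
R = 10000) remain configurable. Global (type-I/power) runs use B = 1000
permutations; the taxon-level FDR/sensitivity runs use B = 4000, because BH
detection at q = 0.10 with J ≈ 190 retained taxa sets thresholds of order
q·k/J ≈ 10⁻³ and p-values quantized at 1/(B+1) = 10⁻³ admit borderline
non-causal taxa alongside blocks of causal ones, overstating the
combination test's FDR by a few points purely through rank granularity. In the FDR/sensitivity experiments the
causal effect is β = 6, the onset of the taxon-level sensitivity plateau
under these conditions (≈ 0.30–0.35); ~50% sensitivity is not attainable at
J = 200 with B = 1000, because only a few causal taxa carry individually
detectable signal once δ-mixing and compositional renormalization dilute the
rest. Empirical FDR is V/max(R,1) averaged over replicates; sensitivity is
|detected ∩ A|/|A|.

## Known limitations

* Fixed-B permutation p-values are granular (1/(B+1)); with too few
  permutations relative to the BH thresholds, detected sets inherit a
  "piggyback" artifact that overstates taxon-level FDR. The taxon-level
  benchmark runs therefore use B = 4000 (see above); analyses of real data
  should scale B with J/q similarly.
* Under M1 the 10 causal taxa hold ~half the community mass at J = 200,
  γ = 1, so non-causal taxa are genuinely (compositionally) correlated with
  the causal score; "false" detections of such taxa are statistical
  associations, not method errors, and they keep the taxon-by-taxon Cox FDR
  elevated even for dense (θ = 0.0002) data.
* No Firth correction, stratified or time-varying Cox, clustered samples,
  UniFrac distances (no phylogeny input), analytic (Davies-type) kernel
  p-values, or sequential permutation stopping.
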