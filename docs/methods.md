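# Methods

This note documents the models and procedures implemented in
`hairpinldr`, the defaults and why they were chosen, what the synthetic
fixtures do and do not establish, and the numerical choices that matter.

## Class model and discriminant criteria

Both classes are modelled as multivariate Gaussians, x₁ ~ N(m₁, S₁) and
x₂ ~ N(m₂, S₂) with priors p₁ + p₂ = 1 (class 1 = pre-microRNA). All
statistics are sample estimates: means, biased (1/N) covariances (the
maximum-likelihood estimator matching the distributional model;
`bias=False` switches to 1/(N−1)), and priors either empirical (class
fractions, the default) or equal — which of the two the original
benchmark experiments used is not documented, so both are first-class
modes.

The within- and between-class scatters are S_W = p₁S₁ + p₂S₂ and
S_E = (m₁ − m₂)(m₁ − m₂)ᵗ. Three separability criteria are offered for
the projection y = Ax (A is d×n):

- **FDA** — J(A) = tr{(A S_W Aᵗ)⁻¹ A S_E Aᵗ}. Maximized by the top-d
  eigenvectors of the generalized problem S_E v = λ S_W v.
- **HDA** — same trace form with S_E replaced by
  S_E − S_W^{1/2} [(p₁ log Ŝ₁ + p₂ log Ŝ₂)/(p₁p₂)] S_W^{1/2},
  where Ŝᵢ = S_W^{−1/2} Sᵢ S_W^{−1/2}. By concavity of the matrix log the
  bracketed term is negative semi-definite, so covariance differences only
  add separability; when S₁ = S₂ the term vanishes and HDA collapses to
  FDA exactly (a tested invariant).
- **CDA** — the Chernoff distance of the projected pair:
  J(A) = p₁p₂·tr{(A S_W Aᵗ)⁻¹ A S_E Aᵗ} + log|A S_W Aᵗ|
  − p₁ log|A S₁ Aᵗ| − p₂ log|A S₂ Aᵗ|. No closed-form maximizer exists;
  see the optimizer below.

**Reduced dimension d.** With two classes S_E has rank one, so d = 1 is
the natural default and the one used throughout; HDA/CDA matrices can
have higher rank and d is configurable everywhere. (The benchmark
experiments never state the d they used.)

**CDA optimizer.** The source literature specifies only "gradient-based,
iterative", so the optimizer is this package's design: gradient ascent
with central-difference gradients (h = 1e−6), initialized at the FDA
solution, rows re-orthonormalized by QR after each step (J is invariant
to invertible row transformations, so this is a pure conditioning
device), backtracking line search that halves the step until the
objective increases, stopping at |ΔJ| < 1e−8 or 500 iterations. Because
the Chernoff landscape can be multimodal for heteroscedastic instances,
`CDAOptions.n_restarts` (default 4) adds seeded random orthonormal
restarts and returns the best iterate; the per-run objective trace is
non-decreasing by construction, and non-convergence sets a flag rather
than raising.

**Regularization.** Mapped cosine features can be near-collinear, so
every covariance is ridged as S + λ·(tr S / n)·I with λ = 1e−6
(configurable) before inversion/sqrt/log; matrix functions are applied
spectrally with an eigenvalue floor of 1e−12. Eigenvectors use a
deterministic sign convention (largest-magnitude component positive) and
stable ordering for tied eigenvalues.

## Explicit maps

The degree-2 polynomial map is implemented verbatim as
[1, x₁…xₙ, x₁²…xₙ², xᵢxⱼ (i<j)], dimension C(n+2, 2). The exact
factorization of the kernel (1 + x·y)² carries √2 factors on the linear
and cross terms which this form omits; the discrepancy is a fixed
diagonal scaling of the feature space, to which all the discriminant
criteria are invariant (asserted directly on J_FDA in the tests), so
classification is unaffected.

The randomized RBF map draws frequencies i.i.d. N(0, 2γ) and phases
uniform on [0, 2π), and transforms as z(x) = √(2/m)·cos(Wx + b), so that
E[z(x)·z(y)] = exp(−γ‖x−y‖²) — the same convention as scikit-learn's
`RBFSampler`, which the original implementation delegated to. The map is
frozen at fit time (frequencies, phases, seed) and serialized with the
model. Defaults γ = 1.5 and m = n + 15 follow the benchmark's stated
defaults; during feature selection m tracks the current subset size.
Features are z-scored per training fold before mapping (switchable off);
the benchmark description is silent on standardization, but without it
the γ scale is arbitrary. Note the kernel width is calibrated for small
post-selection subsets: at n ≳ 6 standardized features, γ = 1.5 makes
typical pairwise kernels ≈ 0 and the map carries little signal — which is
one reason selection precedes mapping.

## Classification and evaluation

The reduced-space classifier is Gaussian-Bayes: linear mode pools the
covariance as p₁S₁ + p₂S₂, quadratic keeps per-class covariances
("linear" could also be read as a threshold on the 1-D projection; pooled
Bayes is the standard reading and the one implemented). Exact
log-posterior ties break to the negative (majority) class — conservative
for false positives on an imbalanced problem.

Sensitivity is implemented as SE = TP/(TP+FN). (One printed formula in
the source literature reads SE = TN/(TP+FN), which contradicts its own
surrounding definitions of TP and FN; that is a misprint and is not
reproduced.)

Cross-validation is stratified k-fold (k = 10 default) with shuffling
under an explicit seed, backed by scikit-learn's `StratifiedKFold`;
per-fold class counts deviate from perfect proportionality by at most
one. All fitting happens on training folds only; the per-fold model
hashes exposed in `CVSummary` let the tests verify that corrupting
held-out rows leaves fitted parameters untouched. Reports carry both the
per-fold mean ± std (the headline, matching how the benchmark tables
present dispersion) and pooled-confusion metrics. Whether the published
"± std" figures are across folds or across repeats is not documented; the
per-fold reading is used here.

## Feature selection and grid search

Selection is beam search of width B = 10 up to K = 12 features: score all
C(n,2) pairs by CV mean Gm, keep the best 10, extend each survivor by
every unused feature, deduplicate, keep the best 10 triplets, and so on.
Ties break to the lexicographically smallest subset. This matches the
procedure the method's description actually spells out; the label
"floating forward" would suggest SFFS-style backward steps, which are not
specified and not implemented. A minimum-improvement early stop is
available but off by default. The fold seed is frozen across all subset
evaluations so scores are comparable, and every evaluation is cached in a
single-file JSON store keyed by (subset, mapping parameters, CV config,
data hash) — a rerun performs zero new CV evaluations, and a corrupt
cache file is rebuilt with a warning. Grid search evaluates every (γ, m)
cell with the same frozen fold seed (whether the original experiments
froze the partition per cell is unstated; freezing is the reproducible
choice), marks failing cells NaN instead of aborting, and exports the Gm
matrix for heatmap rendering.

## Sequence features

The 17 composition features (16 overlapping dinucleotide frequencies
normalized by L−1, plus (G+C)/L) are computed natively from FASTA
(T→U, case-folded; non-ACGU residues are rejected by record id). The
other 31 canonical features require an RNA secondary-structure engine and
are out of scope by design: the schema reserves their names — the classic
folding measures dP, dG, dD, dQ, dF with MFEI1/2 and their z-scores
(completing the miPred-style block of 29 + 19 newer features to the
stated 48; the source only sketches this block, so the standard set is
used), plus NEFE, Freq, Diversity, Diff, dS(/L), dH(/L), Tm(/L), base-pair
and per-stem statistics — and `merge_external_features` joins them by
record id, warning on names outside the registry. Exact formulas for dG,
zG and NEFE live in the external feature provider, not here.

## Synthetic worlds and what green tests mean

`SimSpec` emulates the benchmark's *shape*: ~1:13 imbalance (default
72 : 936), many uninformative i.i.d. noise columns, and a small planted
informative set in one of three structures — `gaussian_homo` (mean shift
of total Euclidean size `separation` under shared covariance),
`gaussian_hetero` (equal means, variance ratio `separation`), and `xor`
(diagonal blob pairs at ±separation/2 per class). Defaults
separation = 4, noise_sd = 1 were fixed once: for the Gaussian world this
gives a Bayes error of Φ(−2) ≈ 2.3% (hard enough that estimation quality
shows); for the XOR world it is the regime where the unmapped
heteroscedastic pipeline visibly fails while the RBF-mapped one succeeds
— with much wider blob spacing even the unmapped quadratic classifier
separates XOR through the projected-variance difference, and with much
narrower spacing nothing does. These fixtures do **not** simulate
realistic thermodynamic feature distributions or sequence-level hairpins,
so green tests establish the correctness and qualitative behaviour of the
machinery, not the benchmark's published Gm values (which need the real
9,939-sample dataset and a folding engine and are kept as reference
constants in `hairpinldr.benchmarks`).

The Monte-Carlo oracle applies the true-density Bayes rule to fresh
draws and reports SE/SP/Gm with binomial standard errors (delta method
for Gm). Two caveats it makes explicit: the Bayes rule minimizes error
and is *not* the Gm-maximizer, so a fitted pipeline's Gm can legitimately
sit slightly above the oracle's; and both sides of any comparison are
Monte-Carlo estimates, so ceiling tests combine the oracle's standard
error with the seed-level dispersion of the pipeline estimate.

## Known limitations

- CDA uses numerical gradients: fine at post-selection dimensionalities
  (tens of mapped features), slow if applied unmapped to hundreds.
- d > 1 reduced spaces are supported but lightly exercised; with rank-one
  S_E, FDA beyond d = 1 adds only regularization-scale directions.
- The XOR oracle (mixture densities) is not implemented; the generator's
  Gaussian structures are the only oracle-backed worlds.
- No ROC/AUC, nested CV, or backward-elimination selection.
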