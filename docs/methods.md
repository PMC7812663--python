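# Methods

## Model

Phenotypes follow the biological (genotypic-value) parameterization

y_i = μ + Σ_j z_ij a_j + Σ_j s_ij d_j + e_i,

with z = 1, 0, −1 and s = 0, 1, 0 for marker genotypes AA, Aa, aa. Random
additive and dominance effects have Cov(a) = **G** σ²_a and
Cov(d) = **D** σ²_d with

**G** = H_a H_a′ / SC_a,  **D** = H_d H_d′ / SC_d,

where H_a and H_d are n × m matrices of *centered scales*: for each marker
one coefficient per genotype, chosen so the marker's column mean is zero
under the marker's genotype frequencies. The scale triples and scaling
denominators for the six supported parameterizations are given in the
module docstring of `grmforge.scales` and summarized in the README table.
Writing Δ = p_AA − p_aa, the key quantities are:

- centered additive triple: (1−Δ, −Δ, −1−Δ); per-marker additive variance
  weight den = p_AA + p_aa − Δ²;
- centered dominance triple: (−p_Aa, 1−p_Aa, −p_Aa); variance weight
  p_Aa(1−p_Aa);
- Gram–Schmidt projection coefficient of dominance on additive:
  ⟨u, v⟩/⟨u, u⟩ = −p_Aa Δ / den; removing it reproduces the NOIA dominance
  triple, with variance weight 4 p_AA p_Aa p_aa / den;
- starting from the dominance vector instead gives the additive triple
  (2p_aa/(1−p_Aa), 0, −2p_AA/(1−p_Aa)) with weight 4 p_AA p_aa/(p_AA+p_aa);
- the orthonormal variant divides the orthogonal basis by the vector norms
  √(n·den) and √(n·4 p_AA p_Aa p_aa/den).

All scales use the *observed* per-marker genotype frequencies
(pairwise-complete over non-missing individuals). Because the expected
variance weights are computed under those same observed frequencies, on
complete data the realized column mean square equals the expected weight
exactly; this is why every non-HW method attains an average diagonal of
exactly 1 on complete panels, and why the `noia`/`gspa` pair (realized vs
expected trace) coincide in that case up to the treatment of excluded
markers. With missing genotypes the two denominator conventions genuinely
differ; the per-method convention follows the origin of each construction
(realized trace for `noia` and `gspn`, expected sums otherwise) and can be
overridden (`denominator=` / `--denominator`).

The frequency-weighted residual checks (`verify_orthogonality`) certify a
method as orthogonal when the largest |Σ_g p_g u_g v_g| over markers is
below 1e-10 — an absolute tolerance chosen far above double-precision
accumulation error at any realistic marker count, far below any real
violation (the non-orthogonal methods produce residuals of order p_Aa Δ).

## Orthogonality angle

For each marker, cos θ = n(−p_Aa)Δ / (‖u‖‖v‖) with
‖u‖ = √(n·den) and ‖v‖ = √(n·p_Aa(1−p_Aa)); θ is reported in degrees,
with the cosine clipped to [−1, 1] before arccos to absorb rounding. The
factor n cancels, so θ depends only on the genotype frequencies; θ = 90°
exactly when p_AA = p_aa, and the angle is undefined (NaN) when either
norm vanishes (no heterozygotes, or no additive variance).

## Exact HWE test

The per-marker test enumerates every heterozygote count compatible with
the observed allele counts, computes the conditional probabilities (a
multinomial kernel with the 2^nAa phase factor, normalized exactly in log
space), and sums the probabilities of all configurations no more probable
than the observed one (standard two-sided test, ties included, no mid-p
correction — matching the conventional SNP exact test). Log-gamma
arithmetic keeps the enumeration stable up to tens of thousands of
individuals. The test is conditionally exact and therefore conservative:
its rejection rate at α never exceeds α by more than discreteness.

## Degenerate markers

A marker is excluded from H_a when its additive variance weight is below
1e-12, and from H_d when its method-specific dominance weight is below
1e-12 (monomorphic markers, markers with no heterozygotes for dominance,
p_Aa = 1 for the dominance-first additive scale). Scale triples keep their
raw formula values where the formula is defined (so the reported triples
match the algebra), the per-marker SC contributions are zeroed, and the
corresponding H columns are zeroed at assembly; excluded markers are
flagged in `additive_ok` / `dominance_ok` and counted in the CLI log. An
all-degenerate panel is an error.

## Missing genotypes

Frequencies use per-marker complete cases; centered-scale entries for
missing genotypes are set to 0, which equals mean imputation after
centering and keeps every column sum exactly zero.

## Kullback–Leibler divergence

D_KL(P‖Q) = ½[tr(Q⁻¹P) + (μ_Q−μ_P)′Q⁻¹(μ_Q−μ_P) − n + ln(|Q|/|P|)],
computed via Cholesky factorizations with log-determinants from the factor
diagonals. Both matrices receive a ridge (default 1e-6) on the diagonal
before factorization because Gram matrices built from m < n markers are
singular; the ridge used is recorded in the result. Means default to zero
vectors — the natural reading for centered genetic effects — and can be
supplied explicitly. Matrix summaries (average diagonal/off-diagonal,
eigenvalue range) are computed on the *unridged* matrix with a symmetric
eigensolver; eigenvalues above −1e-8 are clamped to 0 in reports.

## REML

Fixed effects (intercept plus treatment-coded factors such as trial) are
removed exactly by projecting y onto an orthonormal basis K of the null
space of X′; REML is then maximum likelihood of
K′y ~ N(0, σ²_a K′GK + σ²_d K′DK + σ²_e I). The three variances are
optimized on the log scale with L-BFGS-B and analytic gradients
(∂/∂log σ²_k = ½σ²_k[tr(V⁻¹M_k) − y*′V⁻¹M_kV⁻¹y*]), from three start
points (equal split, additive-heavy, dominance-heavy), relative tolerance
1e-8, at most 200 iterations per start. Variances are bounded below at
1e-10 × var(y); estimates under 1e-6 × var(y) are reported as exact zeros.
Numerically identical G and D trigger a non-identifiability warning and a
`converged = False` flag. One Cholesky (plus one inverse for the gradient)
per iteration keeps a fit at n = 800 around ten seconds on one core.

## Simulator

`inbreeding_f` draws genotypes per marker from
(p² + Fpq, 2pq(1−F), q² + Fpq); F = −0.047 reproduces a genome-wide mean
heterozygote excess of 4.7%, the magnitude reported for Landrace ×
Large-White crossbreds. `f1_cross` draws the two parental-pool frequencies
separately and uses (p₁p₂, p₁q₂+p₂q₁, q₁q₂); diverged pools give a
locus-heterogeneous excess, the structural crossbred signature. Infeasible
(p, F) pairs are redrawn. Marker effects are drawn i.i.d. normal and then
rescaled so the *realized* sample variances of Σ z a and Σ s d equal the
targets exactly, giving recovery tests a well-defined truth; residuals are
drawn at the target variance without rescaling. Independent seeded streams
(frequencies, genotypes, missingness; effects, noise, trials) keep the
genotypes identical when trait settings change. The simulator draws
markers independently — no linkage, no pedigree, no selection — so tests
built on it validate the algebra and the estimators, not behavior under LD
or family structure.

## Study conditions for the recovery checks

- *Variance-component recovery* (n = 800, m = 1000, (σ²_a, σ²_d, σ²_e) =
  (2, 1, 1), 20 replicates, orthogonal (`noia`) matrices): panels are drawn
  at fixed p = 0.5 under HWE. The generative model uses the raw z/s codes,
  whose additive and dominance columns are correlated whenever
  p_AA ≠ p_aa; under any frequency law with E[p_AA − p_aa] ≠ 0 part of the
  simulated dominance variance is, by construction, additive variance in
  the orthogonal basis, and the simulated targets would not be the
  estimands. At p = 0.5 the two codes are orthogonal in expectation and
  the targets are the identifiable truth.
- *Null calibration* (no genetic signal, n = 500, 20 replicates): the panel
  is oligogenic, m = 30. The Fisher information separating σ²_a from σ²_e
  is ½Σ(λ_i − 1)² over the relationship eigenvalues, which scales roughly
  as n²/m; with m ≳ n the relationship matrix is too close to the identity
  for the components to separate and the null sampling spread of ĥ² sits
  well above 0.05. At m ≪ n the spread is a few percent and fitted h², d²
  stay at or below 0.05 in essentially all replicates.

## Known limitations

- The HW construction is included deliberately as the misspecified
  baseline; its D matrix is not centered off HWE, which is the phenomenon
  the diagnostics expose.
- REML standard errors are not reported; the profile-likelihood and
  perturbation checks in the test suite stand in for convergence
  diagnostics.
- KL divergences between near-singular relationship matrices depend on the
  ridge; comparisons should hold the ridge fixed.
- The statistical (allele-substitution) parameterization of breeding
  values, epistatic scales, multi-allelic markers and LD-aware simulation
  are out of scope.
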