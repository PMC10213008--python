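# Methods

`snpevals` selects individually important SNPs from a *multi-SNP* mixed
model fitted to nuclear-family data. This note records the model, the
resampling and selection machinery, the synthetic-data design, the numerical
choices, and the known limits of what the package's tests demonstrate.

## The ACE mixed model

For family $i$ with $n_i$ members (here: father, mother, two children),

$$ y_i = \alpha + G_i \beta_g + C_i \beta_c + \epsilon_i, \qquad
   \epsilon_i \sim \mathcal N(0, V_i), \qquad
   V_i = \sigma_a^2 \Phi_i + \sigma_c^2 \mathbf 1\mathbf 1^\top + \sigma_e^2 I, $$

where $G_i$ holds 0/1/2 allele dosages for all $p_g$ SNPs of a gene or
region jointly, $\Phi_i$ is the expected-relatedness matrix (twice the
kinship coefficients: 1 for MZ twins, 1/2 for parent–biological-child pairs,
DZ twins and full siblings, 0 for adoptive relations and spouse pairs), and
the three variance components are the classical ACE decomposition:
additive polygenic background, family-shared environment, and individual
noise. Families are independent, so everything factorises into per-family
blocks; no $n \times n$ matrix is ever formed.

**Fitting.** Fixed effects are profiled out by GLS at any variance-component
value; the three components are maximised on the log scale with L-BFGS-B
(Nelder–Mead fallback) from an equal-thirds split of the OLS residual
variance, convergence tolerance $10^{-8}$ on the log-likelihood. ML is the
default (REML is a switch; the fixed-effect caches the bootstrap reuses are
identical under both). $\sigma_e^2$ is floored at $10^{-6}$ of the total
phenotypic variance so every $V_i$ stays invertible; components that land
below $10^{-4}$ of the total are flagged as boundary estimates, not errors.
With all-identity $\Phi_i$ the split between $\sigma_a^2$ and $\sigma_e^2$
is a flat ridge (only their sum is identified); estimates on that ridge are
legitimate and the flags mark them.

**Numerical determinism.** The per-family normal equations are accumulated
in a canonical order (relatedness-pattern groups sorted by key, families
sorted by id within a group). Without this, float non-associativity in the
sums is amplified by the optimiser into $\sim 10^{-5}$ coefficient jitter
between runs that differ only in family order; with it the fit is exactly
permutation-invariant.

## Generalized bootstrap

The sampling distribution of $\hat\beta_g$ is approximated without
refitting: each bootstrap replicate solves the reweighted normal equations

$$ \beta_b = \Big(\sum_i w_{bi}\, X_i^\top \hat V_i^{-1} X_i\Big)^{-1}
             \sum_i w_{bi}\, X_i^\top \hat V_i^{-1} y_i , $$

with one positive i.i.d. weight per *family* (families are the independent
sampling units; individual-level weights would break the within-family
covariance logic) and the variance components frozen at the fitted values —
this freeze is what makes a draw cost one small solve, and a 500-draw
ensemble a single batched matrix product. Weights are
Gamma(shape $1/s_w^2$, scale $s_w^2$): mean 1, standard deviation $s_w$,
strictly positive support so the weighted cross-products stay positive
definite. Classical multinomial ($m$-out-of-$m$) weights are available as an
alternative law. To first order the coordinate-wise spread of the draws is
$s_w \times$ the GLS standard error, so $s_w$ directly scales the synthetic
bootstrap noise.

**Noise-scale convention.** The user-facing scale $s$ is interpreted per
individual: the total synthetic-noise scale is $\tau_n = s\sqrt n$ spread
over the $m$ family weights, giving $s_w = s\sqrt{n/m}$ ($= 2s$ for
4-member families). This convention was chosen because it reproduces the
intended operating regime of the method: with it, $s \in [0.2, 1]$ moves the
leave-one-SNP-out e-value distributions from clearly separated (causal SNPs)
to fully overlapping the full model's, and the prediction-error tuning
(below) finds its optimum inside the default $s$ grid. Under the plainer
convention $s_w = s$ (available as `weight_scale="family"`) the same regime
occurs only at roughly twice the $s$ values, outside the default grid's
dense part. The spread-calibration test uses the family convention, where
sd(draws) $\approx s \times$ SE holds by construction.

Two *independent* ensembles are drawn per $s$: a reference ensemble that
defines the normalising moments and an evaluation ensemble that supplies the
points being scored, avoiding self-evaluation bias ($B_{\mathrm{ref}} =
B_{\mathrm{eval}} = 500$ by default). A single-ensemble variant is a matter
of passing the same object twice.

## E-values and the quantile selection rule

A parameter point $x$ is scored against the reference moments through an
evaluation map on the standardised deviation $z = (x - \mathbb E X) /
\mathrm{sd}(X)$ (coordinate-wise; only the $p_g$ SNP coordinates enter):

$$ E_1(x) = \frac{1}{1 + \lVert z\rVert^2}, \qquad
   E_2(x) = \exp(-\lVert z\rVert). $$

Both are location–scale invariant in the reference distribution, lie in
$(0,1]$, and equal 1 exactly at the reference mean. (Note $E_1 \ge E_2$
everywhere, since $e^r \ge 1 + r^2$ for $r \ge 0$.) Scoring every
evaluation draw gives the full-model e-value sample $\mathbb E_*$; zeroing
coordinate $j$ of every draw before scoring gives the leave-$j$-out sample
$\mathbb E_{-j}$. Zeroing changes a single coordinate of $z$, so all $p_g$
reduced models are scored with one rank-one update of the squared norms.

Dropping a SNP that matters displaces the zeroed draws far from the
reference distribution, pushing $\mathbb E_{-j}$ toward 0. Because weak
signals separate better in the upper tail than at the mean, selection
compares empirical quantiles: SNP $j$ is kept when

$$ c_q(\mathbb E_{-j}) < t\, c_q(\mathbb E_*)
   \quad\text{for every } q \in \{0.5, 0.6, 0.7, 0.8, 0.9\}, $$

with $0 < t < 1$. Quantiles use the linear-interpolation inverse-CDF
convention throughout (both sides of the inequality come from samples of
equal size, so any one consistent convention works; mixing conventions would
not). Ties are not selected (strict inequality). The historical mean-rule
($\mu(\mathbb E_{-j}) < \mu(\mathbb E_*)$) is provided for comparison; it is
markedly more liberal and is not used by the pipeline.

## Tuning $(s, t)$ by holdout prediction error

Both the noise scale and the threshold are tuned by the fixed-effect squared
prediction error of the selected model on held-out families:

$$ \mathrm{PE}_t(s) = \sum_{\text{test individuals}}
   \big(y - x^\top \hat\beta_{\hat S_t(s)}\big)^2 . $$

$\hat\beta_{\hat S}$ is a *restricted GLS refit* (intercept, active SNPs,
covariates) on the training families with variance components frozen at the
full fit — refitting rather than zeroing coefficients because zeroed
full-model estimates carry omitted-variable bias inside correlated blocks.
Predictions include the intercept and covariate terms. The sum runs over all
members of each test family (a children-only variant would simply subset the
test rows). Only one full-model fit is ever performed per dataset,
regardless of grid size — an instrumented counter enforces this in the test
suite. Default grids: simulation-style $s \in \{0.1, 0.15, \dots, 0.95,
2\}$ with $t$ fixed per experiment; data-analysis-style $s = 0.2(0.2)3.0$,
$t = 0.1(0.05)0.8$ with a 75/25 family-level holdout split.

## Synthetic family-GWAS generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout:

- $m = 250$ families of four (parents + MZ twins); mixes with DZ twins,
  full siblings, adoptees and mixed biological/adopted pairs are supported.
- 50 SNPs in independent blocks of sizes (6, 4, 6, 4, 30) with block MAFs
  (0.2, 0.4, 0.4, 0.25, 0.25).
- Parental *allele vectors* (haplotype-like 0/1 vectors) are correlated
  within a block through a Gaussian copula: equicorrelated latent normals
  thresholded at the MAF quantile. A parent's genotype is the sum of two
  independent allele vectors; a child inherits one randomly chosen vector
  from each parent (MZ twins share both transmitted vectors, DZ twins and
  siblings transmit independently, adoptees come from fresh vectors). This
  yields Hardy–Weinberg marginals and Mendelian parent–offspring and
  sib–sib genotype correlations.
- The first SNP of each of the first four blocks is causal; phenotypes add
  the fixed SNP effects to ACE noise with components (4, 1, 1).

**Correlation-scale convention.** The target within-block correlation 0.7
is imposed on the *latent* scale by default, giving a binary-scale
correlation of roughly 0.45–0.5 at these MAFs (the value implied by the
bivariate-normal orthant probability — asserted in the tests). The
alternative `corr_scale="binary"` calibrates the latent correlation by
bisection so the binary-scale correlation is exactly 0.7. The latent default
was chosen because the reference operating characteristics this package
replicates (in particular the false-positive patterns of the marginal-scan
and linear-model baselines inside causal blocks) are consistent with the
weaker binary-scale correlation and inconsistent with a true binary
correlation of 0.7.

**Effect-size convention.** With genotype variance $2\,\mathrm{MAF}(1-
\mathrm{MAF})$, the default `variance_fraction` convention sets

$$ \beta_k = \sqrt{\frac{h}{100 \cdot 2\,\mathrm{MAF}_k(1-\mathrm{MAF}_k)}}, $$

so a causal SNP contributes absolute trait variance $h/100$, i.e. explains
$h/S$ percent of the total error variance $S = \sigma_a^2 + \sigma_c^2 +
\sigma_e^2 = 6$ (about 1.7% at $h = 10$). The alternative `scaled`
convention divides additionally by $S$, making the explained fraction
$h/(100\,S^2)$ — six-fold smaller here. The default was chosen because the
scaled form produces signals (marginal noncentrality $\approx 1.8$ at
$h = 10$) that no implemented method — joint, marginal, or penalised —
detects at rates anywhere near the operating points this package aims to
reproduce, whereas the variance-fraction form matches the intended
"each causal SNP explains a realistic single-digit percentage" design.

**What the generator does not emulate.** Real LD patterns (blocks are
equicorrelated and mutually independent), allele-frequency spectra,
genotyping error and missingness, non-Gaussian traits, covariate
confounding (the optional covariates are independent of genotype), and
ascertainment. Passing benchmarks here therefore demonstrates correctness
of the machinery and behaviour under the stated stylised conditions, not
performance on real cohort data.

## Baselines

- **Single-SNP scan + BH.** One ACE mixed model per SNP, with the variance
  components estimated once on the covariates-only null model and reused
  (re-estimation per SNP is a switch). Each SNP solve is *exact* GLS via a
  Schur complement over the shared base columns; Wald $t$-tests (df $= n -
  p - 2$), Benjamini–Hochberg step-up at FDR 0.05 through `statsmodels`.
  Monomorphic SNPs get $p = 1$ with a warning.
- **mBIC2 backward deletion.** Ordinary least squares on the stacked data —
  the family structure is ignored on purpose, as the comparison intends —
  minimising $n\log(\mathrm{RSS}/n) + k\log n + 2k\log(p_g/c) - 2\log k!$
  with $c = 4$ over greedy single-SNP deletions (intercept and covariates
  are never deleted). The criterion's FDR-like control assumes iid errors;
  under family-correlated errors it over-selects (its null false-positive
  rate is clean on iid data — unit-tested — but inflated on ACE data), which
  is part of what the method comparison illustrates.

## Benchmark protocol and problem sizes

The replicated benchmark runs generate → fit → select → score with
independent child seeds spawned from one master seed: 100 replications,
$m = 250$ training families plus an equally sized independent test set for
the PE tuning, $B_{\mathrm{ref}} = B_{\mathrm{eval}} = 500$, $s$ tuned over
the simulation grid per replication. Metrics: TP (share of the 4 causal
SNPs selected), TN (share of the 46 null SNPs not selected), RTP (share of
causal *blocks* hit), RTN (share of the 30 null-block SNPs not selected);
at $h = 0$ TP/RTP are undefined and TN covers all 50 SNPs. These sizes are
the package's default desk-scale protocol; the per-rate Monte-Carlo standard
error at 100 replications is roughly 0.02–0.04.

## Known limitations

- **Information ceiling of the MZ-only design.** For the default design the
  exact-GLS Fisher information per family for a SNP coefficient is 0.776 of
  the independent-individuals equivalent (MZ twins duplicate genotypes, so
  the lowest-variance within-family contrast carries no genotype signal; a
  DZ design reaches 0.97). At $h = 10$ this caps the marginal noncentrality
  at $\approx 3.6$ and the joint-model noncentrality at $\approx 2.9$, and
  correspondingly caps attainable TP rates (e.g. single-SNP + BH plateaus
  near 0.75–0.85, the e-value procedure near 0.8–0.9 at $t = 0.8$). Some
  published family-GWAS simulation studies report TP rates that imply
  $\approx 35\%$ more information than this bound; under this package's
  exactly-calibrated methods and the stated design those operating points
  are not reachable, and the benchmark reports what the methods actually
  deliver.
- Backward deletion for mBIC2 is greedy (local minimum of the criterion).
- The bootstrap requires $n > p_g + p + 1$ and a non-degenerate full fit;
  high-dimensional ($n < p$) settings are out of scope.
- General pedigrees (loops, three generations, half-sibs) and missing
  genotypes are not supported; readers reject them explicitly.
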