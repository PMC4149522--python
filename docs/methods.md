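# Methods

## The fixed-point property

A binary mixture of two fixed base densities, `g_p(t) = p f1(t) + (1−p) f2(t)`,
satisfies `g_p(t0) = f1(t0) = f2(t0)` at any point `t0` where the base
densities are equal, for every mixture proportion `p`.  When an experiment
manipulates only the mixing proportion across k ≥ 3 conditions, all
`k(k−1)/2` pairwise condition-density differences must therefore cross zero
at the same RT.  The package tests exactly that coincidence.  Two facts
make the test workable in practice:

* **Smoothing preserves the property.**  A Gaussian-kernel density estimate
  converges to the true density convolved with the kernel, and convolution
  is linear: a smoothed mixture is the same mixture of smoothed bases.  The
  common crossing of the *smoothed* condition densities sits at the
  crossing of the smoothed bases — generally not at the original `t0`, but
  still common to all pairs.  The null hypothesis is therefore unaffected
  by the choice of kernel SD `h`, which is why the test is robust over a
  wide range of `h`.
* **Coincidence is a null hypothesis.**  Supporting it requires quantifying
  evidence *for* the null, hence the default-prior Bayesian ANOVA rather
  than only significance tests.

## Estimation pipeline

Per subject: pool that subject's RTs across conditions; fix the kernel SD
`h` (see below); build one shared grid of 512 equally spaced points spanning
the pooled range padded by `3h` per side (so crossings near the tails stay
on-grid and the KDE mass on the grid stays within ~2% of 1); estimate one
KDE per condition, `f̂(x) = (nh)⁻¹ Σ φ((x−tᵢ)/h)`; form all pairwise
difference curves in a globally fixed condition order (ascending grand-mean
RT, ties by label, so a pair label names the same contrast for every
subject); and locate each pair's zero crossing by linear interpolation
between adjacent grid points of opposite sign.

**Crossing selection.**  KDE tails wiggle, so a difference curve can have
several sign changes.  Candidates are restricted to a window spanning the
union of the two conditions' interquartile ranges widened by one bandwidth
per side, and the candidate with the steepest interpolated slope wins (ties
toward the smaller RT).  The meaningful crossing separates the two modes,
where the difference curve moves fastest; tail crossings are shallow noise.
The window is deliberately *not* the inter-median interval: for strongly
right-skewed mixtures (e.g. inverse-Gaussian bases with a large mean
difference and a 0/.5/1 proportion design) the common crossing lies below
both condition medians, and an inter-median window would systematically
exclude it.  With no sign change in the window the pair is flagged
`missing`; subjects with any missing pair are excluded from inference
(complete-case, logged) so the repeated-measures design stays balanced.
Subjects with fewer than `min_trials` (default 10) trials in any condition
are excluded up front.

**Bandwidth.**  `h` is the SD of the Gaussian kernel, in the data's RT
units.  Data-driven rules are available (Silverman:
`0.9·min(sd, IQR/1.34)·n^(−1/5)`; Scott: `1.06·sd·n^(−1/5)`), but for
replication-style analyses a fixed `h` is the default choice: the
simulation studies here fix `h` at 1–2 data SDs, the range over which the
Bayes factors are empirically flat.  Below roughly 1 SD the estimate picks
up local noise; far above 2 SDs genuine bimodality smooths away.  There is
no boundary correction at t = 0 for positive RT data (a known limitation;
negligible when the density near zero is negligible).

## Inference on the crossing table

The crossing table (subjects × pairs) feeds two analyses.

**Classical ANOVA.**  One-way repeated measures with subject as blocking
factor: `F = MS_pair / MS_(pair×subject)`, df `(k−1, (k−1)(s−1))`.  No
sphericity correction by default; a Greenhouse–Geisser option exists
(`gg=True`).  With a between-subject factor, a standard mixed-design ANOVA
is fitted (between effect over the subject-within-group MS; within effect
and interaction over the pair×subject-within-group MS); group sizes must
be equal (the degenerate single-group case reduces exactly to the
repeated-measures ANOVA).

**Default-prior Bayes factor.**  Observations are modeled as
`y = µ1 + Σ_f X_f θ_f + ε`, `ε ~ N(0, σ²I)`, with Jeffreys priors on µ and
σ², effects coded with orthonormal sum-to-zero contrasts, and per block f a
g-prior `θ_f ~ N(0, g_f σ² I)` with `g_f ~ scaled-inv-χ²(df=1, scale=r_f²)`.
Prior scales: `r = 0.5` ("medium") for fixed blocks, `r = 1` ("nuisance")
for the subject block; both configurable.  Conditional on the g's the
marginal likelihood is closed-form; the Bayes factor integrates over the
g's numerically in `u = log g` space with a mode-centered, curvature-scaled
tensor Simpson rule (129/65/33/21 points per axis for 1–4 dimensions),
accepted when a Simpson-vs-trapezoid comparison agrees to 1e−3 relative and
refined once otherwise (an error carries diagnostics if refinement fails).
For balanced designs with mutually orthogonal blocks the per-point
evaluation reduces to scalars per block; otherwise a batched Cholesky path
is used.  The quadrature is validated in the test suite against a plain
Monte-Carlo prior-integration oracle (10⁶ prior draws, agreement within
2%).

`BF01` is reported as evidence **for** the fixed-point property (null:
no crossing-point differences); `BF10 = 1/BF01` always accompanies it.
Per-effect Bayes factors use single-term deletion respecting marginality:
in a mixed design each main effect is compared within the mains-only model,
and the interaction compares the full model against the both-mains model.

## Effect size

The separation of the two base distributions is summarized as
`d' = |µ2 − µ1| / sqrt((σ1² + σ2²)/2)` (root-mean pooling of the two
variances; for the inverse-Gaussian family `σ² = µ³/λ`).  The pooling
convention matters at large dispersion asymmetries; alternatives differ by
up to ~10% at the upper end of the ranges simulated here.

## Simulation harness

`gen_mixture_experiment` draws, per subject and condition, `trials` RTs
from the binary mixture (the latent strategy is Bernoulli per trial, so
realized per-base counts are random), plus one additive subject shift
`~ N(0, random_effect_sd)` applied to all of that subject's RTs (a
multiplicative effect would be an alternative reading; the additive form
is the plain one).  `gen_shift_experiment` builds the mean-matched
alternative without the fixed-point property: three distributions whose
means and dispersions are linearly interpolated between the two bases
(for the inverse-Gaussian effect-size sweep, the second base's shape grows
with its mean, `λ2 = λ1 + µ2 − µ1`, so SD rises roughly linearly with the
mean as in real RT data).

Presets reproduce the canonical validation conditions:

| preset | design | varies |
|---|---|---|
| sim1 | IG(0.8, 5)/IG(1.0, 5), p=.1/.4/.8, 50 subjects × 200 trials, subject SD 0.1, h=0.1 s | — |
| sim2 | IG(200, 100) vs IG(µ2, 100+µ2−200), p=0/.5/1, 50 × 200, h=100 ms | µ2 ∈ [225, 1175] × {mixture, shift} |
| sim3 | normal(0,1)/normal(1.5,1), p=.1/.5/.9, 200 trials | subjects ∈ {10, 50, 100} × h ∈ {1, 1.5, 2} |
| sim4 | as sim3, 50 subjects | trials ∈ {100, 200, 500} × h |

Only sim1 includes a subject random effect; the other designs specify
none.  Default replication counts are desk-scale (100 per cell; the
acceptance script uses 500 for its Bayes-factor target) — the original
studies used thousands per cell, and `run_study(..., replications=...)`
scales up when wanted.  Per cell the harness records the mean, median and
mode of `BF01`, the mean F, and the RMSD of the crossings around the
analytic fixed point of the generating bases.  The mode is computed as the
peak of a KDE-smoothed histogram of `log BF01` (the BF distribution is
heavily right-skewed; the log-scale mode is the stable "typical value").

**Mean versus mode of the Bayes factor.**  For s subjects the BF01 of the
pair effect is bounded above by its value at F = 0 (≈ 4.7 for s = 10,
k = 3, r = 0.5).  Under a true common crossing the F statistic is
calibrated (mean ≈ 1), so the *mean* BF01 over replicates sits well below
the bound (≈ 2.9 at s = 10), while the *mode* sits near the upper plateau
(≈ 4.2).  The modal summary is the meaningful "typical evidence" figure
for small samples and is what the acceptance script reports; both are in
every `run_study` summary.

## What the synthetic data does and does not show

The generators emulate the study conditions exactly: known base
distributions, exactly equal mixture proportions across subjects, additive
subject shifts, no contaminant trials, no slow drifts, no RT censoring or
anticipations.  Passing tests therefore demonstrate the method's behavior
under the mixture (and shift) models themselves — correct evidence
direction, sample-size scaling, bandwidth robustness, crossing precision
driven by trials-per-condition rather than subject count — not robustness
to the many artifacts of real RT data (outliers, censoring, proportion
heterogeneity across subjects).  On real data the complete-case rule and
the minimum-trials filter matter; both are logged and recorded in the
result settings.

## Numerical choices and degenerate inputs

* Root finding for the analytic fixed point brackets the interval between
  the two means (`brentq`, xtol 1e−12 relative); pairs whose densities do
  not change sign between the means raise a "no overlap crossing" error.
  Unequal-dispersion pairs cross twice; the between-means crossing — the
  one separating the modes — is returned.
* The inverse-Gaussian sampler is the Michael–Schucany–Haas transformation
  (guarded against cancellation at tiny chi-square values); it is checked
  against scipy's generator by moments and a KS test.
* All-zero difference curves (identical estimates) raise a degenerate-curve
  error rather than returning an arbitrary crossing.
* KDE evaluation chunks the kernel matrix to bound memory at ~40 MB
  regardless of sample size.
* Every simulation record stores its seed; `run_study` spawns independent
  child seeds per cell and replicate from one root `SeedSequence`, so
  summaries are bit-reproducible given the root seed.

## Known limitations

* The method is specific to *binary* mixtures; with three or more latent
  strategies there is no common crossing to find.
* Mixture parameters (p, base means) are not estimated — the test evaluates
  the mixture hypothesis without fitting it.
* Mixed designs require equal group sizes and a single between-subject
  factor.
* A `BF01 > 1` supports a common crossing, which is a necessary but not
  sufficient signature of a binary mixture; alternatives that mimic the
  crossing geometry are not distinguished (no likelihood-ratio comparison
  against a specific alternative is implemented).
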