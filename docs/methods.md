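# Methods

This note documents the statistical models implemented in chillrhythm, the
generative design of its synthetic data, the numerical choices that matter,
and the limits of what the test suite demonstrates.

## Lipid composition and unsaturation

Raw per-sample amounts (one row per lipid class × fatty acid) are
normalized to **mole percent** per sample: class mole % is
100 × class total / all-class total, and fatty-acid mole % is computed
analogously within the 16:n/18:n acyl pool. Compositions therefore sum to
100 exactly; an all-zero sample is a hard error naming the sample.

The **double bond index** is
`DBI = [(X:1)·1 + (X:2)·2 + (X:3)·3]/100` over mole % of 16:n/18:n fatty
acids (n ≤ 3), range [0, 3]. The **unsaturation index** is the
amount-weighted mean double-bond count over *any* acyl pool; on a pool
restricted to 16:n/18:n with n ≤ 3 the two quantities coincide, which the
tests assert to 1e-12 as a cross-operation oracle.

**Outlier screening** is two-stage. First a robust replicate-level screen
on fatty-acid abundances: residuals from the stratum median, scaled by the
normalized MAD, are converted to two-sided t tail probabilities
(df = n − 1) and a BH pass at Q = 10% drops flagged points. This is an
FDR-style reimplementation of robust-fit outlier removal; it is *not* a
numerical clone of any vendor tool and exact agreement with GraphPad's
ROUT is not claimed. Second, mole percents are screened within each
lipid class × genotype × temperature stratum against a window of
median ± k·IQR with k = 1 (the literal "one interquartile distance from
the median"; Tukey's 1.5·IQR fences are available via `iqr_k`). Quartiles
use linear interpolation (numpy's default, type 7); the source procedure
does not state a quartile rule. Strata with fewer than three values pass
through unscreened with a logged warning. Because the stratum pools time
points, strongly rhythmic series lose their extremes preferentially — a
property of the literal rule, kept as such.

**Group comparisons** at one time point offer Fisher's LSD (pairwise t on
the pooled within-group mean square, contrasts flagged only under a
significant omnibus F), Tukey's HSD (studentized-range adjusted), and a
mixed model with a random replicate intercept followed by
studentized-range-adjusted Wald contrasts. Methods and figure legends of
the source analyses cite both LSD and mixed-model-Tukey; both are provided
and the method used is recorded in the output, not guessed. Zero
within-group variance degrades to an exact equality test, logged.

## Cosinor rhythmicity

A fixed-period cosinor `y = M + A·cos(2π(t − φ)/P)` is linear in
`(M, b_cos, b_sin)` and fitted by OLS; `A = √(b_cos² + b_sin²)`,
`φ = atan2(b_sin, b_cos)·P/2π mod P`. Standard errors for `A` and `φ` come
from the delta method. Rhythmicity is the joint F-test of the two
trigonometric coefficients; a constant series returns amplitude 0 and
p = 1 by convention. The period is fixed at 24 h: a six-point single-cycle
design cannot support period estimation, and no harmonics beyond the
fundamental are fitted. Fits spanning less than one full period are
flagged in the log without asserting statistical adequacy — the
differential-rhythmicity framework this mirrors was designed for
multi-cycle data. Replicates enter as independent observations (no
replicate random effect), matching the regression framing of the cited
rhythm methods. Phase is reported in hours since stress onset; no
zeitgeber conversion is applied.

**Waveform comparison** fits the joint design
`y ~ 1 + g + cos + sin + g·cos + g·sin` and reports Δmesor, Δamplitude and
Δphase (wrapped into (−P/2, P/2]) with Wald p-values (delta method for the
polar parameters). The phase difference is declared unidentifiable — p set
to 1, flagged, warned — when either group's amplitude is within ~2
standard errors of zero. Numerically exact fits (residual variance below
1e-20 relative) are treated as noiseless so test statistics never become
ratios of rounding errors.

**Differential rhythmicity** across many series uses, per series, the
design `1 + condition + (sin, cos) + condition×(sin, cos)` on
replicate-level observations; the interaction-pair F-test p-value is
BH-adjusted across series, as are the per-condition rhythmicity p-values.
Ordinary per-series F-tests are used rather than empirical-Bayes variance
moderation, so exact count-level agreement with limma-backed
implementations is not guaranteed.

**Benjamini–Hochberg adjustment** is the standard step-up with enforced
monotonicity (delegated to statsmodels), shared by every module; the test
suite pins it against an independent textbook step-up computation.

## Cross-species DRO detection

T/C ratios are `(FPKM_trt + c)/(FPKM_ctl + c)` with pseudocount
c = 1 FPKM, pairing treatment and control by replicate index (how the
source analysis matched replicates is unstated; dividing by the control
time-point mean is the configurable alternative). Ratios are modeled raw
by default, log2 via a flag.

The **pair filter** is deliberately two-sided because "SD < 0.4 and
r² > 0.1 of the FPKM values" is ambiguous: the default SD metric is the
pooled between-replicate SD of log2(FPKM+1) per gene (a reproducibility
filter) and the default r² is the squared Pearson correlation between the
two species' mean T/C profiles (a pair-signal filter, the quantity the
permutation calibration operates on). Both are selectable.

The **per-gene LMM** places fixed time, species and time×species effects
on the ratio with a random intercept per biological replicate unit
(replicates nested in species; six units of six observations in the
reference design). For balanced complete data the fit is the closed-form
ANOVA/GLS route: for a balanced one-random-intercept design the ANOVA
moment estimator of (θ², σ²), truncated at zero, *is* the REML estimator,
and GLS under the implied block compound-symmetry covariance gives the
fixed effects and their model-based covariance. The joint Wald χ² on the
(J−1)(K−1) interaction contrasts (df = 5 here) yields the p-value.
Unbalanced data fall back to a numerical REML fit (statsmodels MixedLM);
the test suite verifies the two routes agree to ~1e-5 on balanced data.
When θ̂² truncates to zero the GLS fit equals OLS exactly and the result is
flagged. Model-based (not sandwich) standard errors are used, matching the
default of the mixed-model framework the method mirrors. BH-adjusted
FDR < 0.001 calls a pair DRO, FDR > 0.01 calls it CRO, and the unnamed gap
(0.001, 0.01] is labeled "ambiguous".

**Correlation clustering** pools both species' mean T/C profiles, computes
the correlation distance 1 − r, and cuts a deterministic average-linkage
tree at k clusters (k = 16 by default; the underlying clustering call in
the source analysis is underspecified, so a seed-free deterministic
algorithm was chosen and exact reproduction of published cluster
memberships is not promised). Zero-variance profiles go to a dedicated
flat cluster. Same-cluster pairs are CEOs, split pairs CC-DROs, and the
**permutation calibration** re-pairs each species-A gene with a random
different species-B gene (fixed-point-free permutation, 100 rounds by
default, fully seeded) to estimate the null co-clustering rate; the
recommended k maximizes the observed rate subject to a bounded null rate
(default ≤ 0.15). For k equal-size clusters the null rate has the closed
form Σ(s/n)² = 1/k, which the tests verify by Monte Carlo. HC-DROs are the
set intersection of CC-DROs and LMM DROs over the same retained-pair
universe.

## Lipidome–transcriptome integration

Correlations use per-time-point replicate means (pooling replicates would
change n and hence p). The expression grid (0.5, 1, 3, 6, 16, 24 h) and
lipid grid (0.17, 3, 6, 12, 16, 24 h) share length but not all values, so
the default alignment pairs the i-th sampled time of each grid (ordinal);
strict intersection of equal times is the alternative and an error directs
the user there when grid lengths differ. Pearson r with the two-sided
t-transform p (n − 2 df) labels each gene a buildup candidate (r > 0) or
breakdown candidate (r < 0) for the lipid — the sign convention of the
source analysis, which never defines the split formally; correlating
against first differences is available but off by default. Candidates are
ranked by |r| within lipid × species, flagging significant (p ≤ 0.05) and
marginal (p ≤ 0.10) results. Min–max normalization for heatmap export maps
constant series to all zeros with a warning rather than failing a batch.

## Synthetic data

The expression generator emulates the paired two-species design: six time
points (0.5, 1, 3, 6, 16, 24 h), two conditions, three biological
replicates. Per pair, a control mean trajectory
`c(t) = mesor + A·cos(2π(t − φ)/24)` (cosinor planted in a configurable
fraction of genes, amplitude capped at 0.8·mesor so means stay positive)
is shared by both species; a treatment/control ratio trajectory `r(t)`,
drawn iid log-normal per time point (log-SD 0.3 — the source states no
value; this makes the time main effect comparable in size to the planted
interaction), is also shared. Planted DRO pairs add `interaction_effect`
(default 1.0) to species B's ratio at the last three time points,
mimicking late-time divergence of differentially regulated orthologs.
Observed FPKM is the mean times `exp(N(0, noise_sd))` — multiplicative
log-normal, the natural model for right-skewed counts-derived abundances;
`noise_sd` is on the natural-log scale, default 0.3 (replicate dispersion
is not reported by the source; 0.3 ≈ 30% CV is a realistic biological
replicate spread). Exactly `round(frac·n)` pairs are flagged DRO (and
rhythmic), so truth counts are deterministic.

The lipid generator plants cosinor mole-percent trajectories per
(class, species, condition) over 11 default classes with a realistic
leaf-tissue baseline (galactolipid-dominated). Auto-generated parameters
are sum-preserving: the largest class absorbs the negated vector sum of
all other classes' cosine/sine components, so planted trajectories sum to
exactly 100 mole % at every instant and survive normalization unchanged
(noise-free recovery by the cosinor fitter is exact to ~1e-9).
User-supplied parameters are normalized at each time point; if they do not
sum to a constant the realized trajectories deviate from the planted ones
accordingly. Noise is Dirichlet-like — per-class log-normal jitter
(default log-SD 0.1) followed by renormalization — so compositions stay on
the simplex; renormalization makes the realized expectation differ from
the planted value by O(noise_sd²). Fatty-acid weights within a class are
fixed over time: the generator does not emulate rhythmic unsaturation, so
passing tests say nothing about unsaturation-rhythm recovery on real data.

Randomness: one root seed spawns named child streams (expression
parameters, expression noise, lipid parameters, lipid noise, permutation)
in a fixed documented order, so identical configs give byte-identical
tables and one table can be regenerated without disturbing the others.

What the synthetic data does **not** emulate: count-level sampling noise
(FPKM is treated as a smooth abundance), between-replicate-unit random
effects (θ² is typically estimated near zero, exercising the OLS-fallback
path), library-size artifacts, missing cells, and correlated noise across
genes. Passing tests therefore demonstrate correctness of the statistics
under the stated generative model, not robustness to every artifact of
real RNA-seq.

## Power of the interaction Wald test (known limitation)

For the balanced reference design the joint interaction Wald statistic has
noncentrality λ = 0.75·Δ²/v when Δ is added at the last three time points,
where v is the variance of a cell mean (σ²/3). At replicate log-noise 0.3
on both FPKM channels the T/C ratio has log-SD ≈ 0.42, giving λ ≈ 10;
even planting σ = 0.3 directly on the ratio gives λ = 25. Against the
BH-adjusted χ² threshold at FDR < 0.001 these correspond to sensitivities
of roughly 0.1 and 0.5 — detecting a ratio shift of 1.0 at this
replication level with high sensitivity at that stringency is not
achievable, which the acceptance checks report honestly. Power is high
(>95% at p < 1e-4 per gene) when replicate noise drops to 0.1.
Additionally, with ~20 residual degrees of freedom the χ² reference (used
to match the mixed-model convention) is anti-conservative in the extreme
tail relative to an F reference, and raw-ratio noise is right-skewed, so a
null run of 2000 pairs typically yields a few (~5–10) spurious DRO calls
where the nominal BH bound expects ≤ 2; modeling log2 ratios (available
via a flag) restores near-nominal null behavior at some cost in power.

## Numerical choices

- Quartiles: linear interpolation (type 7), configurable nowhere — stated
  here because the IQR screen depends on it.
- Cosinor and comparison fits: `numpy.linalg.lstsq`; degenerate
  (noiseless) fits detected at relative residual 1e-10 and reported with
  certainty semantics (p = 1 for zero estimates, p = 0 otherwise).
- GLS inverse via the rank-one block identity
  `(I + ρJ)⁻¹ = I − ρ/(1 + mρ)·J`, avoiding explicit 36×36 inversions.
- Phase deltas wrapped to (−P/2, P/2], boundary mapped to +P/2.
- BH on NaN-bearing families: NaNs are excluded from the family and
  propagated.
- Derangements for the permutation null: fixed points of a uniform random
  permutation are cyclically rotated, preserving uniformity well enough
  for rate estimation while guaranteeing no gene is re-paired with its
  true partner.
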