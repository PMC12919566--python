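# Methods

## Observation model and normalization

One analysis unit is a fly-day: 1440 per-minute beam-crossing counts.
Counts are normalized to percent of the day's total
(`100 * count / daily_total`), so every fitted day sums to 100 and flies
of different overall activity are comparable.  A day whose total is zero,
or that contains monitor gaps (missing minutes), cannot be normalized and
is excluded from fitting with a log message; recordings are split into
ZT-aligned whole days (lights-on = ZT0, 12:12 photoperiod by default),
discarding partial leading/trailing days and, by default, the first full
day as acclimation, keeping the next four.

Normalized activity is modeled as a k-state hidden Markov chain with
state-specific univariate Gaussian emissions.  The Gaussian family is a
modeling choice for a continuous response; the data are in fact discrete
(counts divided by the daily total), and the consequences are discussed
under "Degenerate solutions" below.

## Fitting

Baum–Welch EM with closed-form M-steps.  Key numerical choices:

* **Scaled linear-space recursions.**  The forward–backward pass uses
  per-timestep normalization of the forward/backward variables plus a
  per-value rescaling of emission densities (each observation value's
  maximum log-density is subtracted and re-added to the log-likelihood).
  This is algebraically equivalent to log-space log-sum-exp arithmetic —
  no quantity can under- or overflow for 1440-point days — and markedly
  faster.  Viterbi runs in log space, where max-product is max-sum, with
  ties broken toward the lower (more active) state index so decoding is
  deterministic.
* **Unique-value factorization.**  Normalized counts take few distinct
  values per day, so emission densities are computed once per distinct
  value per EM iteration.  This is exact, not an approximation, and is
  what makes thousand-restart consensus runs practical.
* **Convergence** when the relative log-likelihood change falls below
  `tol = 1e-8` (the per-iteration log-likelihood trace is retained and is
  non-decreasing up to 1e-10 roundoff), with a cap of `max_iter = 500`
  EM cycles per fit by default.  Near-unidentifiable data (e.g. a single
  Gaussian component fitted with k ≥ 2) walks a likelihood ridge and can
  need tens of thousands of cycles; order-selection studies therefore
  raise the cap (2,000–20,000) so that non-convergence flags reflect
  genuine failures rather than budget exhaustion.
* **SD floor** `sd_floor = 1e-6` (normalized-activity units): exact-zero
  runs drive emission variances to zero; the floor keeps the likelihood
  finite while still permitting a near-degenerate all-zero sleep state.
* **Parameter count** for model selection: p = (k−1) initial + k(k−1)
  transition + 2k emission parameters = k² + 2k − 1, with AIC = 2p − 2ℓ
  and BIC = p ln(1440) − 2ℓ per day; per-fly tables average criteria over
  days and the selected k minimizes mean BIC (ties toward smaller k,
  non-convergent candidates excluded).

## Restarts, consensus, ambiguity

Each fly-day is fitted T times (default 100).  Restart 1 uses the
structured transition start — transitions between the extreme states set
to 1e-5, rows renormalized, all other rows uniform — uniform π, emission
means at descending quantiles of the day's activity and SDs at the day's
sample SD.  Restarts 2..T redraw π from a flat Dirichlet; transition and
emission starts are deliberately left unchanged (an option to jitter
emission means exists for users wanting more restart diversity).  Every
converged fit is Viterbi-decoded and relabeled by descending emission
mean (mean ties broken toward larger SD, then original index).  The
consensus is the per-minute modal state over converged restarts (ties to
the lower index); the ambiguity score is (1 − n/T)·100 with n the
multiplicity of the most frequent whole-day sequence, compared as exact
1440-vectors.  A fly-day with no converged restart yields no phenotype
and is flagged excluded rather than raising.

Reproducibility: one global seed spawns a substream per fly-day keyed by
(seed, CRC32(fly_id), day_index), so results are independent of
processing order and bit-identical across runs.

## Degenerate solutions and what the synthetic tests show

The synthetic activity generator draws a sticky Markov chain (default
0.95 diagonal) with Poisson counts at state intensities (3, 1, 0.3, 0.01)
per minute — integer data with realistic overlap between adjacent states,
deliberately mismatched to the Gaussian inference model the way real
monitor data is.

Because normalized counts lie on a lattice (multiples of 100/daily
total), the Gaussian likelihood is maximized by near-point-mass states:
EM reliably converges to solutions where each state's mean sits on one
lattice value and its SD collapses to the floor.  Decoded states are then
effectively count-level classes.  Two consequences, both verified by the
test suite:

* Consensus sequences are extremely stable (ambiguity well under 2% at
  T = 100, and per-state durations from T = 100 and T = 1000 correlate at
  r > 0.99), because the degenerate optimum is reached from almost any
  initial π.
* Minute-level agreement with the *latent* chain of the Poisson generator
  plateaus near 50% — count levels, not dwell structure, drive the
  labels.  This is a property of the method itself, not of this
  implementation: even Bayes-optimal decoding under the true Poisson
  model with true parameters only reaches ≈ 88% on this generator, and
  fitted log-likelihoods in the tens of thousands of nats per day (as the
  4-state mean of 42,549.51 implies) are only attainable with emission
  SDs many orders of magnitude below the lattice spacing, i.e. lattice-
  degenerate fits.  Passing consensus-stability tests therefore shows
  robustness of the decoded sequences, not that decoded states equal the
  generator's hidden states minute-by-minute.

Order-selection behavior is instead studied on data simulated from the
Gaussian model itself (well-separated means, 2-unit spacing, SD 0.4,
sticky transitions), where BIC recovers k = 4 in ≳ 85% of replicates and
falls back to k = 2 on one-component data.

## Phenotypes and downstream statistics

* **Time in state**: per-day minutes per state per phase (day = ZT < 720),
  averaged over a fly's included days.  The conservation identities
  Σ_state 24h = 1440 and day + night = 24h hold exactly; with a
  power-of-two number of analysis days (the standard 1, 2 or 4) they are
  exact even in floating point, otherwise to one ulp.
* **Arousal thresholds**: a train's threshold is the weakest level of the
  ladder (default 0.24–1.20 g in five equal steps) that elicited
  movement; non-respondents are assigned the strongest level; flies
  mobile at onset are excluded ("immobile" operationalized as no movement
  in the preceding minute, window configurable).  Thresholds are grouped
  by the consensus state of the minute containing the train start and
  reported as mean ± SE with n; formal between-state tests are left to
  the user's statistics environment.
* **Variance components** by the expected-mean-squares method of moments
  on (near-)balanced line × sex × replicate layouts: σ²_E = MS_error,
  σ²_SL = (MS_line×sex − MS_error)/r, σ²_L = (MS_line − MS_line×sex)/(s·r),
  with the harmonic-mean cell size r absorbing mild imbalance and layouts
  missing > 20% of cells refused.  Negative moment estimates truncate to
  zero (logged).  Block/replicate terms of the full experimental design
  are absorbed into σ²_E, which can only shrink H² — a conservative,
  dependency-free estimator that is exactly testable against two-way
  ANOVA mean squares.  H² uses the combined-sex or per-sex formula as
  appropriate; r_G uses line-mean covariance over the supplied among-line
  variances and clamps to [−1, 1] (logged).
* **Window enrichment**: 1-Mb non-overlapping windows anchored at
  position 1 (1-based, inclusive ends: position 1,000,000 is in window 1),
  hypergeometric upper tail with the chromosome as the urn, BH-FDR pooled
  genome-wide.  Class over/under-representation uses the same
  hypergeometric machinery against a genome background.

## Synthetic-data realism

The generators reproduce the variance structure, response structure and
file formats the pipeline consumes, with known truth.  They do not model
circadian waveforms (no sinusoidal activity modulation), bout-length
heavy tails, inter-individual intensity heterogeneity, or monitor
artifacts (dead channels, status errors) beyond what tests construct
explicitly — so passing recovery tests demonstrates correctness of the
estimators under the stated models, not performance on every real
recording.

## Problem sizes used in validation

The end-to-end suites use 20 four-state flies × 4 days for consensus and
concordance studies (T = 100 and T = 1000), 50 replicates for
order-selection and heritability recovery (panels of 100 lines × 2 sexes
× 16 flies), 200 lines for null genetic correlations, and exhaustive
enumeration oracles at k ≤ 3, n ≤ 8 (≥ 100 random parameterizations)
for the recursions.

## Known limitations

* Emissions are univariate Gaussian only; covariate-dependent transitions
  and Poisson/negative-binomial emission variants are natural extensions.
* Per-fly heterogeneous state counts are not propagated into the
  genetics module (k = 4 is fixed there for comparability).
* REML on the full nine-term mixed model is out of scope; the
  method-of-moments estimator requires near-balanced designs.
* GWAS itself, gene mapping and network/GO analyses are out of scope:
  the enrichment module consumes SNP significance flags produced
  elsewhere.
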