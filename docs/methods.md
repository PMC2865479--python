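# Methods

## The evolutionary models

The package simulates the correlated evolution of a male score M and a
female score F along a rooted speciational phylogeny: all branch
lengths are 1, so change is concentrated at speciation events and each
branch contributes exactly one update. Input trees with arbitrary
branch lengths are converted with `as_speciational`; the original
lengths are discarded by design (no length-scaled variant is offered).
Polytomies are accepted — each daughter branch receives its own update.

The root state is (0, 0); the origin is irrelevant because every
downstream statistic is computed after standardization. Per branch the
state inherited from the parent node passes through three sequential
steps, each consuming the previous step's output:

1. *Brownian motion*: M += R_m, F += R_f with R_m, R_f independent
   N(0, 1). The increment SD is arbitrary (it cancels after
   standardization) and fixed at 1.
2. *Block reversed dimorphism*: if F > M, the constrained side is
   reset — F = M (constraint on females), M = F (constraint on males),
   or both to (M + F)/2 (mutual constraint). This encodes the empirical
   absence of reversed dimorphism in the study system; because the rule
   is exactly reversed between the one-sided models it introduces no
   bias between them.
3. *Constraint pull*: the constrained sex moves toward the other by a
   proportion C of the difference. Under mutual constraint both sexes
   move simultaneously from their pre-update values, which preserves
   (M + F)/2 along steps 2–3 and caps C at 0.5 (beyond that the sexes
   would cross); the one-sided models allow C up to 1.

The two one-sided models are exact mirrors: mapping (M, F) to
(−F, −M) and swapping/negating the Brownian draws maps one model's
trajectories onto the other's. The test suite exploits this for an
exact distributional check.

## Calibration of the pull constant

C is the single free parameter per model and is chosen so that the mean
Pearson correlation between extant male and female scores across
replicate simulations equals the observed cross-sex correlation, making
the three models equally parameterised. The solver is bisection on
[0, C_max] with **common random numbers**: one block of N(0, 1) draws
(shape nodes × replicates × 2) is generated once and reused for every
candidate C, so the mean-correlation curve is deterministic and
monotonically nondecreasing in C and bisection is well posed. Defaults:
500 replicates per evaluation, tolerance 0.005 on the mean correlation,
60 iteration cap. A target of exactly 1 returns C_max directly (the
pull then forces F = M at every step). The blocking step alone induces
a positive baseline correlation (~0.4–0.5 on 23-tip trees); targets
below that baseline are rejected with an error reporting it.

## Summary statistics

Statistics are computed after standardizing the *joint* distribution of
the 2N male + female values to mean 0, SD 1 (pooled, not per-sex; the
per-sex variant would erase exactly the dispersion signal DSD relies
on). Note that DSD is not scale-free — standardization divides it by
the pooled SD — so the standardize-first order is part of the
definition; SK and DRS are affine-invariant.

- DSD uses sample SDs (n − 1 denominator).
- SK is the D'Agostino (1970) normalized skewness Zg1: √b1 from central
  moments with denominator n, then the log/ sinh⁻¹ normalizing
  transformation; it is approximately standard normal under normality
  for n ≥ 8 (the transformation constants are undefined below that,
  hence the ≥ 4 species requirement). The implementation is checked
  against `scipy.stats.skewtest` to 1e-12.
- DRS = slope(F on M) − slope(M on F), computed via the closed form
  r·(SD_F/SD_M − SD_M/SD_F). The sign convention (female-on-male slope
  first) is applied identically to observed data and all nulls, so
  percentiles do not depend on it.

The vectorized batch path (`batch_statistics`) used for 1000-run nulls
is bridged to the scalar path by an equality test.

## Testing procedure

Null distributions use 1000 runs by default (minimum 40 for a 95% CI).
CIs are empirical 2.5/97.5 percentiles with linear interpolation
between order statistics; percentiles of observed values use the
midrank convention (#below + half the ties); the two-tailed P is
2·min(pct, 1 − pct), floored at 1/n_runs and capped at 1. Rejection is
"observed outside the closed CI", which agrees with P < 0.05 up to
interpolation ties in a hairline band around the bounds. A model is
*supported* only when it survives all three statistics and every
alternative is rejected by at least one; when no model or several
models survive, survivors are reported *indeterminate* rather than
forcing a winner.

Discriminability between models is the fraction of one model's
simulated statistic values inside another model's CI (type II error;
self-pairs sit at ~0.95 by construction). `discriminability_experiment`
tabulates this for all ordered pairs at each calibration target.

## Synthetic data

The generator reproduces the study conditions: a rooted 23-tip
speciational tree, cross-sex correlation targets 0.893 (carotenoid),
0.560 (melanin) and 0.848 (total coloration), and no reversed
dimorphism. The tree stand-in is a Yule topology (uniform random tip
splitting) because the original topology is not published; the tree is
an explicit input everywhere, so a real phylogeny can be substituted
directly. Measurement matrices for the scoring stage are one- or
few-factor models (default loading 0.8, noise SD 0.6, traits assigned
round-robin to factors), tuned so broken-stick retention recovers the
factor count with high probability.

What the synthetic data does *not* emulate: the topology and imbalance
of the real consensus tree, phylogenetic signal estimated from real
sequences, measurement error in museum-skin reflectance, and the actual
PC loadings of real colour data. Consequences observed in testing: the
pairwise discriminability bounds are topology-sensitive. On Yule
stand-ins the skew statistic's type II error (≥ ~88%) and the strong
separation of the two one-sided models at r ≈ 0.85–0.89 (≤ ~32%)
reproduce the qualitative profile robustly, but the minimum type II
error at the weak melanin calibration (r = 0.560) is ~63–71% on Yule
trees versus ~85% on a 23-tip pectinate tree — deeper, more unbalanced
topologies blur the models more. Passing tests therefore demonstrate
the method's behaviour, not properties of any real dataset.

## Composite scores

PCA runs on the correlation matrix — the measurements mix reflectance,
extents and categorical codes, so a unit-free analysis is the only
defensible one, and broken-stick expectations are defined for
correlation PCA (eigenvalues sum to the trait count). Retention is
consecutive from the first component; component signs are oriented so
each retained component's loading sum is positive (higher score = more
elaborate ornament); the composite is Σ eigenvalue_j · score_j over
retained components. When broken-stick retains nothing the error names
the Kaiser (eigenvalue > 1) fallback explicitly — it is never applied
silently. Male and female rows are scored in one shared PCA space,
which is required for cross-sex comparability.

## Numerical and design choices

- One master seed per entry point; internal seeds derive from a
  `numpy` `SeedSequence`. Runs are columns of one vectorized draw
  block, so any result is replayable bit-exactly from its config.
- Simulation state is carried as (n_runs,)-vectors through a single
  preorder traversal; 1000-run nulls and a full calibration take
  well under a second on one core at 23 tips.
- Degenerate inputs fail loudly: zero pooled variance, < 4 species,
  non-speciational trees, out-of-range C, unreachable calibration
  targets, < 40 runs for a CI.
- Default problem sizes follow the study conditions (23 tips, 1000
  runs, 500 calibration replicates); the full three-model analysis and
  the discriminability experiment each complete in seconds.

## Known limitations

- Brownian motion with a single rate and one step per branch; no
  Ornstein–Uhlenbeck or length-scaled variants.
- Two traits (one per sex); no multivariate extension.
- The discriminability bounds quoted for the original clade depend on
  its (unpublished) topology; on random Yule stand-ins the
  weak-correlation bounds are systematically lower (see above).
- Phylogenetic GLS / λ estimation is out of scope; the percentile test
  is the only inferential machinery provided.
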