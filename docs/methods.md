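# Methods

## Model

Disease liability *l* is standard normal in the population; an
individual is affected iff *l* exceeds the threshold *t* = Φ⁻¹(1−*K*)
for prevalence *K* (upper-tail convention; the probability of a tie is
zero, so > versus ≥ is immaterial).  Writing *z* = φ(*t*), the
truncated-normal geometry is

- mean liability of cases i_case = z/K, of controls i_ctrl = −z/(1−K);
- within-group variances v_case = 1 − i_case(i_case − t) and
  v_ctrl = 1 + t·i_ctrl − i_ctrl² (standard upper/lower truncation
  results);
- in a sample with case fraction P, the liability is a P:(1−P) mixture
  with variance var(l_cc) = P·v_case + (1−P)·v_ctrl +
  P(1−P)(i_case − i_ctrl)².

These satisfy, exactly: K·i_case + (1−K)·i_ctrl = 0;
K(v_case + i_case²) + (1−K)(v_ctrl + i_ctrl²) = 1; var(l_cc) = 1 at
P = K.  The test suite checks the moments against numerical integration
to ten significant digits.

Genetic values enter through the bivariate-normal regression of *g* on
*l* with slope h² (the variance fraction explained).  Selecting on
liability shrinks within-group (co)variances by the group liability
variance and separates the group genetic means by h²(i_case − i_ctrl);
mixing at P:(1−P) gives the ascertained-sample variances

    var(g_cc) = h²[P(1 − h²(1−v_case)) + (1−P)(1 − h²(1−v_ctrl))]
                + P(1−P) h⁴ (i_case − i_ctrl)²,

var(e_cc) the same with h² ↦ 1−h², and cov(g, l_cc) = h²·var(l_cc)
exactly.  At P = K the selection and mixture terms cancel and
var(g_cc) = h²; the forms were validated against a 2×10⁶-draw
Monte-Carlo of the generative model before being adopted (e.g.
var(g_cc) = 0.832 at h² = 0.5, K = 0.01, P = 0.5 — a 1.66-fold
inflation).

## Power

The 1-df χ² association test of a marker set explaining q² of liability
variance has non-centrality λ and power
P[χ²₁(λ) > central χ²₁ quantile at 1−α] (two-sided via the χ² form; at
λ = 0 power equals α exactly).  Default NCPs are the small-q² forms
(README table); they are first-order in q², the regime of single-marker
tests (q² ≤ 0.001).  `exact_inflation=True` substitutes the
ascertainment-inflated marker variance — var(g_cc) evaluated at q² — for
multi-locus marker sets: for BT_CC the inflated variance replaces q² in
the observed-scale transformation, for QT_CC
λ = N q⁴ var(l_cc)/var(g_cc)(q²) from the regression chain
b = cov/var(g_cc), λ = N b² var(g_cc)/var(l_cc).  At q² = 0.001 the two
variants differ by < 0.5%, below the third decimal of any power value.

The cases-only mixture response (QB_CC) records the liability for cases
and zero for controls.  Its variance is P·v_case + P(1−P)·i_case² and
its covariance with the marker is
q²[P·v_case + P(1−P)·i_case(i_case − i_ctrl)], giving
λ = N q² cov²/var; numerically this sits within 0.01–0.02 of the binary
BT_CC design throughout the ascertained regime (0.488 vs 0.478 at
K = 0.01, P = 0.5, N = 2000, q² = 0.001), confirming that scoring
severity only in cases adds little over the diagnosis itself, while a
quantitative score on everyone (QT_CC) adds materially more.

## Prediction accuracy

Per-marker least squares on N records has prediction error variance
≈ σ²/N per effect; summing over M markers and taking the ratio of true
to estimated genetic variance gives r² = N·h²ₒ/(N·h²ₒ + M) with h²ₒ the
variance fraction on the response scale and σ² approximated by the
response's phenotypic variance (1, K(1−K) or P(1−P)).  The
ascertained-sample transformation h²ₒ = h² z² P(1−P)/(K²(1−K)²) treats
the per-marker inflation factor as 1, valid once the signal is spread
over ≳20 markers (each marker's own inflation is second-order in its
variance share); `accuracy_disease_cc` warns below that.  At P = K all
disease formulas coincide, and at K = P = 0.5 they agree with the
quantitative formula applied to the observed scale (r = 0.491 at
N = M = 2000, h² = 0.5).

## Simulator

Cohorts follow an additive multilocus model: genotypes x_ij ~
Binomial(2, p) with p = 0.5, independent markers (no linkage
disequilibrium), equal positive effects β = √(h²/(2Mp(1−p))) so the
expected genetic variance is exactly h² (alternatives: normal or
exponential effect draws, rescaled to the same expected variance);
residuals N(0, 1−h²); liability y = Σ(x−2p)β + e; status y > t.
Ascertained cohorts are produced by batched rejection sampling —
population draws accumulate until the case quota round(N·P) and the
control complement are filled, with batch sizes set 10% above the
expected waiting count, capped at 2×10⁷ genotype entries, and a
10⁷-draw budget per replicate that raises a descriptive error when the
quota is unreachable.  One master `SeedSequence` spawns independent
per-replicate streams, so results are bit-for-bit reproducible and
earlier replicates are unchanged when the replicate count grows.

Association tests use the score form of the marginal regression: the
statistic N·r² (r the genotype–response correlation) referred to
χ²₁, asymptotically equivalent to the OLS Wald t² (the suite verifies
agreement to O(1/N) against statsmodels OLS) and exactly the df
convention of the analytic NCPs.  Monomorphic markers score 0 with
p = 1.  A constant response (possible when a rare-disease population
cohort contains no cases) can never reject and contributes zero
rejections; a constant predictor in validation contributes zero
correlation.

Empirical power pools all replicate × marker tests.  Two standard
errors are reported: the pooled binomial SE and the between-replicate SE
of the mean.  They differ because marker tests within a replicate share
the cohort — for rare diseases in population mode, the same handful of
cases — so the binomial SE understates the uncertainty under that
clustering; comparisons against analytic values use the larger of the
two.

Empirical accuracy trains per-marker slopes of the 0/1 status on allele
count in the (possibly ascertained) training cohort — the accuracy
theory is derived on the observed scale, so the 0/1 coding is used
regardless of the power-study response setting — and correlates
predicted with true genetic values in an independent, unascertained
population cohort of `N_validation` (default 2000) drawn with the same
true effects.  A population validation cohort is the natural reading of
"same genetic parameters as the original population" and reproduces the
reference simulation estimates (e.g. 0.690 at K = 0.01, N = M = 2000,
h² = 0.5); ascertained validation remains available by configuring the
validation step manually.

### What the simulator does and does not emulate

It emulates exactly the idealised architecture the analytic formulas
assume: independent markers, allele frequency 0.5, equal effects,
Gaussian residuals, perfect threshold diagnosis.  It does not model
linkage disequilibrium, realistic allele-frequency spectra, covariates,
diagnostic error, or shrinkage/BLUP effect estimation.  Agreement
between simulation and formulas therefore validates the derivations,
not their applicability to any particular real study — in real data the
effective number of independent tests and LD between causal and typed
variants move both power and accuracy.

## Numerical choices

- Probabilities (K, P) are validated strictly inside (0, 1) with a
  10⁻⁸ guard band: beyond it, z/K cancels catastrophically.
- h² and q² validated in [0, 1] / [0, 1); N, M positive integers.
- Power at λ = 0 returns α exactly rather than the survival-function
  round-trip.
- Genotypes are stored as int8 (a 2000×2000 cohort is 4 MB); the
  association scan and effect estimation are vectorised over markers.
- Analytic CLI output prints 6 significant digits; identical analytic
  invocations are byte-identical, simulation commands are reproducible
  given the seed.

## Problem sizes

Default replicate counts are chosen for interactive use: simulated
power runs at 20–30 replicates × 100 markers (2000–3000 tests, SE
≈ 0.01), simulated accuracy at 10–20 replicates (SE ≈ 0.005), with the
low-prevalence ascertained scenarios exercised at reduced cohort sizes
(N = M = 500) where rejection sampling would otherwise dominate;
`reproduce --full` restores the original 100-replicate scale.  The
acceptance script uses 100 replicates (10 000 tests) for the simulated
power target and 20 replicates for the simulated accuracy target.

## Known limitations

- The χ² asymptotics of the marginal test fail for extremely unbalanced
  binary responses: at K = 0.001 in a population sample of 2000 (about
  two cases), long-run empirical power is ≈ 0.039 against an asymptotic
  0.053 at q² = 0.001, and fixing the case count by quota makes the
  score test over-reject (null rate ≈ 0.105).  The analytic BT_POP
  value in that regime is an asymptotic idealisation.
- Two of the 36 analytic power values sit exactly at a third-decimal
  rounding boundary (QT_CC at K = 0.1, q² = 0.001: 0.3853; at K = 0.01,
  q² = 0.0005: 0.3324), so their rounded values are sensitive to
  sub-0.1% perturbations of var(l_cc).
- The exact multi-locus NCP variants are reconstructions pinned to the
  Monte-Carlo oracles; at single-marker q² they are indistinguishable
  from the defaults.
- No multiple-testing or effective-number-of-tests correction is
  applied; α is per test (use 5×10⁻⁸ for genome-wide scans, as
  `reproduce figure1` does).
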