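# Methods

## The model

Each expression feature *i* (an isoform or gene row; the package does not
care which) is modelled on the natural-log scale over the 2×2 design with
binary age *A* and genotype *G*:

    log(y_i) = β0_i + βA_i·A + βG_i·G + βA::G_i·A·G + ε_i

The design is saturated — four parameters, four cells — so the
least-squares estimates are exactly the condition-mean contrasts of the
transformed values: β0 = m00, βA = m10 − m00, βG = m01 − m00,
βA::G = m11 − m10 − m01 + m00, with mAG the mean of log(y + pseudocount)
in cell (A, G). This identity is the package's main algebraic oracle and
is tested to 1e−10 against independent solvers.

### Variance model and Wald tests

The fit is ordinary least squares on log(count + pseudocount) with a
pooled residual variance per feature, df = n − 4 (df = 8 for the default
12-sample design), and two-sided t-based Wald tests rather than normal
ones, because n is small. This is a deliberately transparent variance
model: it assumes homoskedastic residuals on the log scale across the four
cells and ignores quantification (technical) uncertainty below the count
level. Features with zero residual variance (all replicates identical
after transformation) are reported with p = 0 and a `degenerate` flag
instead of raising; all-zero features are flagged and excluded from
testing (p, q = NaN).

- **pseudocount**, default 0.5: added before the log to handle zeros; at
  count scale μ the transformation bias of log(y + 0.5) cancels to first
  order (the +0.5/μ shift against the −Var/2μ² Jensen term), and any
  remaining bias that is constant across cells drops out of the contrasts.
- **FDR**: Benjamini–Hochberg step-up, applied separately per coefficient
  column (three families across features), significant at q < 0.1. A
  pooled single-family correction is a defensible alternative; per-column
  matches the "any coefficient significant" calling convention and keeps
  the three signatures exchangeable.
- Gene-level signatures aggregate by "any significant feature of the gene".

## Interaction regimes

Features with all three coefficients significant are classified by the
geometry of (βA, βG, βA::G):

| label | rule |
|---|---|
| fast_aging | sign(βA::G) = sign(βA) |
| female_like | |βA + βA::G| ≤ tol·|βA| and sign(βA) = sign(βG) |
| slow_aging | opposite signs, |βA::G| < |βA| |
| rejuvenation | opposite signs, |βA::G| > |βA| |

The **tolerance** (default 0.25, relative to |βA|) operationalises "no
residual age effect in the mutant" for per-feature labels; there is no
canonical value, and the classification is a partition for any tolerance
in [0, 1). The *selection* of female-state features
(`select_female_state`) deliberately uses the looser sign-only rule — all
three significant, sign(βA) = sign(βG), sign(βA::G) = −sign(βA) — so that
the per-feature classifier and the population-level selection can be
compared; the selection equals the union of the three opposing-interaction
labels restricted to concordant main effects, a set identity under test.
Features with βA = 0 or βA::G = 0 exactly are unclassified (signs
undefined; measure-zero for continuous estimates).

## Epistasis plot

x = βA + βG is the additive expectation of the double perturbation,
y = βA::G the deviation from it. If both perturbations push a feature into
the same terminal state with effect *b*, then βA = βG = b and βA::G = −b,
so all points lie on y = −x/2: slope −0.5 with intercept 0. Purely
additive features lie on y = 0. A mixed population gives an intermediate
slope, which is why the headline recovery experiment simulates only
female-like and null features.

The default estimator is OLS of y on x with free intercept; an orthogonal
(total least squares) option exists because both axes carry estimation
error from the same fit. Estimation errors of x and y are in fact
negatively correlated (cov = −4σ²/r for within-cell variance σ² and r
replicates), which biases the OLS slope slightly below zero even for
additive truth; the bias shrinks as σ² → 0 and is tested to be within
three bootstrap SEs of zero at low dispersion. The slope SE is the
standard deviation of the slope over bootstrap resamples of the points
with replacement (default 1000, seeded); degenerate resamples with all x
equal are redrawn. Collinear input recovers the exact slope with zero
bootstrap SE.

## Enrichment

Hypergeometric upper tail P(X ≥ k) including the observed count
(enrichment, not depletion), computed through scipy's log-gamma-based
survival function and verified against exhaustive enumeration for all
population sizes ≤ 25. Expected = |query|·|term|/|background|, fold =
observed/expected, BH q across the terms of one collection. The
background defaults to all genes annotated in the collection and can be
overridden with the detected-gene universe; the choice matters and is the
caller's.

## The simulator

`simulate_dataset` emulates the factorial design: per feature, a regime
label, coefficients drawn for that regime, and counts drawn
negative-binomially with mean size_factor·exp(Xβ) and variance μ + φμ².
Defaults and why:

- **replicates_per_cell = 3** — the design being emulated.
- **dispersion φ = 0.05** — a conventional biological-replicate
  overdispersion for bulk RNA-seq of whole animals; no empirical estimate
  from the original samples exists, so this is a convention, not a
  calibration.
- **effect_scale = 1.5** with magnitudes uniform on [0.5, 1.5]·scale —
  non-null effects are bounded away from zero (≥ 0.5·scale) so regime
  labels remain identifiable; near-zero effects would make recovery tests
  ill-posed.
- **baseline β0 ~ U(3, 8)** — expected counts between ~20 and ~3000,
  spanning moderately to well-expressed features. Very low-count features
  (where the log-OLS approximation is weakest) are deliberately not the
  default regime.
- **regime mixture** — 50% null, 10% each aging-only/genotype-only/
  female-like, 5% each additive/fast/slow/rejuvenation: a null-dominated
  transcriptome with a visible female-like component.
- **size_factors = 1** — configurable to probe normalisation robustness;
  the fit itself performs no normalisation.

What the simulator does *not* emulate: read-level noise and isoform
quantification uncertainty, correlated features (counts are independent
across features given the design), GC/length biases, and library-size
estimation. Passing tests therefore demonstrate the statistics are
implemented correctly and behave as designed under the stated noise model
— not that the pipeline is robust to everything real data does.

## Problem sizes

The dataset-level suites use 1000–5000 features at 12 samples: large
enough that binomial noise on rates is small relative to the asserted
bands (type-I error 0.05 ± 0.015 at n = 5000; KS distance < 0.05 at
n = 2000; slope within ±0.05 at ~450 selected points with bootstrap SE
~0.003), and small enough to run in seconds. The headline recovery
experiment (500 female-like + 500 null features) mirrors the scale of the
real all-three-significant gene set.

## Known limitations

- The OLS/t variance model understates uncertainty for features whose
  counts are near zero in some cells; the simulator's baseline range keeps
  the default tests away from that zone on purpose.
- p = 0 for degenerate (zero-residual) fits is a reporting convention, not
  a probability statement; downstream FDR treats such features as maximally
  significant.
- The hypergeometric background is a modelling choice with real leverage
  on p-values; the package exposes it rather than deciding it.
- The epistasis slope of a mixed-regime population is not −0.5 and should
  not be compared against the single-pathway expectation without first
  restricting to the relevant gene set.
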