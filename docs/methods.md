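# Methods

## The classification problem

The package operationalises binge-drinking severity without fixed drink
cut-offs.  Seven candidate items describe a respondent's drinking: three
ordinal AUDIT codes (consumption frequency, drinks per typical day,
frequency of 6+-drink occasions; 0–4 each) and four AUQ-derived quantities
(consumption speed in drinks/hour; drunkenness episodes over the previous
six months; drunkenness episodes and hangovers per 10 drinking occasions,
both on a 0–10 scale, optionally ingested as 0–100 percentages and divided
by 10).  Records with any missing or out-of-range modelling item are
rejected listwise; optional fields (age, gender, AUDIT total, binge score)
pass through.

The dependent variable does not exist a priori: groups are *derived* by
K-means, then *reproduced* by an ordinal regression whose equations can be
applied to any new respondent.

## Group derivation

K-means (Lloyd's algorithm, squared-Euclidean WCSS objective) is run on the
raw, unstandardised seven items — the published group profiles are
separated chiefly by the raw drunkenness count (0.93 → 5.82 → 19.28 →
39.26), which implies unscaled clustering; a z-score option exists
(`standardize=True`).  Defaults: 25 random-row restarts, tolerance 1e-8, a
mandatory seed; an emptied cluster is re-seeded at the point farthest from
its centroid.  Each iteration's WCSS is recorded and is non-increasing by
construction.

The number of groups comes from the elbow of the WCSS-vs-K curve: the K
maximising the discrete second difference (ties to the smaller K).  The
default scan is **K = 2..8**.  K = 1 is deliberately excluded: it is not a
partition, and the huge WCSS drop from 1 to 2 clusters measures only "some
structure exists", swamping the curvature at every genuine elbow — with the
published group sizes and means the second difference would otherwise
always peak at K = 2, for any noise level.  On the default synthetic
cohort the scan selects K = 4.

Derived clusters are relabelled 1..K by a severity score: the mean of the
centroid coordinates after per-item z-scoring against the training sample
(so items on incommensurable scales weigh equally), ties broken by the raw
drunkenness centroid.  Relabelling is a pure permutation.

## Partial proportional odds model

Cumulative logits on the ordinal group index y ∈ {1..K}:

    P(y ≥ j | x) = expit(α_j + Σ_k β_kj x_k),   j = 2..K.

*Proportional* predictors share one β across thresholds; the published
structure keeps 6-drink frequency and drunkenness frequency shared and
gives speed, drunkenness/10 and hangovers/10 one β per threshold
(configurable per predictor).  Category probabilities are successive
differences of the cumulative curve.  Because per-threshold slopes are
unconstrained, interior differences can be negative for extreme covariates:

- at **prediction** time negative components are clamped to zero and the
  vector renormalised, with a warning;
- during **fitting** the log of a category probability below 1e-10 is
  continued linearly (a C¹ barrier), so the optimiser is pushed back into
  the valid region with a defined gradient.

Estimation maximises the multinomial log-likelihood with L-BFGS-B plus an
analytic gradient (intercepts start at the empirical cumulative logits,
slopes at zero), followed by damped Newton steps on the observed
information until the gradient's sup-norm is below 1e-7 — L-BFGS curvature
approximations otherwise stall short of tolerance on this likelihood.
Standard errors come from the inverse observed information (central
differences of the analytic gradient); Wald z = β/SE with standard-normal
two-sided p values, presented with one row per shared coefficient
("≥2, ≥3, =4") and one per threshold otherwise.  A condition number above
1e10 in the information matrix flags the fit as degenerate (collinear
design).  Non-convergence is a flag, never an exception.

The **frozen published classifier** uses the printed equations: intercepts
(−5.87, −7.37, −8.46), shared slopes 0.43 (6-drink) and 0.34 (drunkenness),
per-threshold slopes (0.20, 0.07, −0.13) for speed, (0.68, 0.11, 0.02) for
drunkenness/10, (0.36, 0.05, −0.34) for hangovers/10.  An alternative
"table-full-precision" set swaps in the five-decimal slope estimates; no
full-precision intercepts were ever printed, so that set pairs exact slopes
with rounded intercepts and is documented as such.  The fourth equation is
implemented as P(y ≥ 4), identical to P(y = 4) since 4 is the top level;
the two hangover variable spellings in the printed equations are treated as
the same variable.  Classification is arg-max of category probabilities
with ties resolved toward the lower (less severe) group.

**Item selection** fits the full-candidate model and drops predictors not
significant at the 0.05 level, judged by a likelihood-ratio test of the
model with and without each predictor (default).  Wald p values are
available (`criterion="wald"`), but when the outcome is the K-means
grouping itself the data are near-separable by construction; maximum-
likelihood slopes then drift large and Wald z collapses toward zero for
precisely the most decisive predictors (the Hauck–Donner effect), which
would absurdly discard everything.  The LRT compares attained
log-likelihoods and is immune.  Among surviving predictors, blocks with
pairwise |r| > 0.7 are collapsed to the single member with the strongest
evidence (LRT χ² or |z|), with an audit trail of every action.

## Validation

Internal validation cross-tabulates the gold K-means grouping against the
refit model's predictions on the same sample; per-group misclassification
is the off-diagonal row share and the overall error its size-weighted
mean.  Percentages are displayed half-up to one decimal; full precision is
kept internally.  External validation applies the frozen equations to a
new cohort and tabulates per-group sizes and item means (empty groups are
reported with n = 0, not an error).  Composition tables are emitted in
three normalisations — share of each attribute value across groups
(columns sum to 100), attribute shares within each group (rows sum to
100), and each group's share of the sample — because all three conventions
appear in practice.  `covariate_effect_on_error` refits the model with an
extra covariate and reports both error profiles side by side, purely
descriptively.

## Purchase-task analytics

Screening follows the standard nonsystematic-data criteria with
configurable thresholds: **trend** — log10-unit consumption drop per
log10-unit of price span across the positive-price rows (the zero-price
row cannot enter a log span; zero consumptions offset by 0.01), flagged
below 0.025; **bounce** — share of price-to-price consumption increases
exceeding 25% of intensity, flagged above 0.10; **reversal** — nonzero
consumption after ≥ 2 consecutive zeros, any occurrence flagged.  An
all-zero series is unusable rather than an error.

Observed indices: intensity (consumption at zero price, or at the lowest
price with a flag), Omax (max price × consumption), Pmax (price at Omax,
ties to the lowest price), breakpoint-1 (highest price with nonzero
consumption; undefined for all-zero series).  Breakpoint-0 is implemented
as the lowest price with zero consumption — the quantity is reported in
the source tables without a printed definition, so this reading is flagged
as an interpretation.

The exponentiated demand equation is fit by ordinary least squares on raw
consumption (a log10(Q + 0.01) loss is optional) with the zero price
mapped to 0.01 €, k fixed at 3.20, starting values Q0 = intensity and
α = 0.01, both bounded positive; at least three positive-consumption
points are required.  Q(C=0) = Q0 exactly, for any α and k.  Essential
Value is 1/(100·α·k^1.5).  A utility recomputes the sample-specific span
(widest participant log10 consumption range + 0.5) for users who prefer a
data-derived k.

## Synthetic cohort generator

The generator emulates the learning sample's statistical structure — it is
the package's study condition, not a tuning knob.  Each respondent is
drawn from a four-group mixture with weights 721/404/106/46 (of 1,277);
per-group item means are the published cluster means; per-group female
shares are 645/723, 279/402, 51/106, 12/46; per-group demand parameters
(Q0, α) are (6.36, 0.014), (10.45, 0.005), (12.37, 0.004), (16.66, 0.005).

Noise model, chosen to match the published per-group distributions rather
than invented: ordinal codes are Gaussian (SD 0.9, consistent with the
printed per-group AUDIT-2 code spread), rounded and clipped to 0..4; speed
is Gaussian (SD 1.3, reproducing the reported per-group shares drinking 4+
drinks/hour) clipped at 0; the per-10 items are Gaussian (SD 2.0, the
level implied by the published Wald standard errors rescaled to sample
size) clipped to [0, 10]; the drunkenness count is negative binomial with
size 50 — mild overdispersion that keeps each group's counts inside the
reported banding (group 4 concentrated in 30–50 episodes).  With all
dispersions zero the generator reproduces the (rounded, clipped) profile
means exactly.  Purchase-task curves are the demand equation evaluated at
the substituted price (0 → 0.01) times multiplicative lognormal noise,
rounded to integer drink counts; recovery tests use `round_counts=False`
because integer rounding alone perturbs parameters at the 1e-2 level.

What the generator does **not** emulate: within-group item correlations
(items are conditionally independent given the group), item skewness
beyond clipping, the real cohorts' response styles, and any relationship
between demand parameters and items beyond the group level.  Tests passing
on synthetic data therefore demonstrate algorithmic correctness and
statistical behaviour under the published group structure, not performance
on any real population.

## Numerical choices and limitations

- Optimiser tolerances: gradient sup-norm 1e-6 (fit flag), L-BFGS maxiter
  500, Newton polish ≤ 50 damped steps; SE finite-difference step
  1e-5·(1+|θ|).
- Sample sizes in the test suite and acceptance script (10,000 for
  clustering, 5,000 for refitting, 3,000 for most unit checks) were chosen
  so that sampling error is small relative to the effects asserted while a
  full run stays fast on one CPU.
- At n = 5,000 the sampling SE of the threshold-specific "=4" slopes is
  ≈ 0.1 (matching the published standard errors rescaled to that n), so
  single-draw recovery of those slopes is only reliable to ~±0.2–0.3; the
  shared slopes recover to ±0.05.
- K-means is a local optimiser; 25 restarts make the K=4 solution stable
  on cohorts of this size but offer no global guarantee.  The WCSS curve
  can be non-monotone at large K with few restarts; the elbow is computed
  anyway with a warning.
- The response scale of the speed-of-drinking item is stored as a
  nonnegative real (drinks/hour); an ordinal coding hook exists because
  source instruments differ on this point.
- Separation: when groups are perfectly predictable from the items
  (near-certain when reproducing a clustering of the same items), ML
  slope estimates are unbounded in principle; fits stop at finite values
  with `converged_=False` or degenerate-information flags, and item
  selection uses LRTs for exactly this reason.
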