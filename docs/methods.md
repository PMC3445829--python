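# Methods

## Model

A two-stage single-arm binomial trial is parameterized by (n1, n2, r1, rt):
X1 ~ Bin(n1, Π); the trial stops for futility when X1 ≤ r1, otherwise
X2 ~ Bin(n2′, Π) independent of X1, where n2′ is the attained second-stage
sample size (planned n2, possibly modified by a non-informative Δn2).  H0 is
rejected when the trial continues and S = X1 + X2 > rt.  The pair (M, S) —
stopping stage and total responses — is complete and sufficient for Π; its
pmf is the stage-1 binomial mass on s = 0..r1 plus, for continuations, the
convolution of the truncated stage-1 law (X1 > r1) with the stage-2
binomial.  All operating characteristics in this package are finite sums
over this support (or over the (x1, x2) path space), not simulations.

The printed support of the early-stopping branch in the source formula
starts at s = 1; s = 0 has positive probability under any Π < 1 and is
included (nothing else makes the distribution sum to one).

Key assumptions: binary endpoint, no early stopping for efficacy, interim
always performed on the planned n1, and any stage-2 over-/under-accrual
non-informative (independent of the response process).  Designs where n2 is
chosen adaptively from the stage-1 data are out of scope.

## Design search

Feasibility means type-I error ≤ α at Π0 and power ≥ 1 − β at Π1, both
computed exactly.  For each (n1, r1, n2) the final boundary is the smallest
rt whose rejection tail at Π0 fits under α; power is decreasing in rt, so
this choice maximizes power and decides feasibility, and it also makes the
stage-wise p-value test coincide with the design decision region.  The
search iterates n1 ascending, prunes r1 by the continuation constraint
(Pr_{Π1}(X1 ≤ r1) ≤ β), and prunes n2 by monotonicity of the objective
(expected null sample size for the optimal criterion, total size for the
minimax criterion) against the incumbent.  Minimax ties are broken by
smaller expected null sample size.  The default search bound n_max = 150
covers all designs in the scenario range of interest; the three reference
searches complete in well under a second.  Binomial pmf vectors are cached
per (n, p), keeping the search allocation-light; probabilities are computed
in linear space (scipy's binomial pmf/sf is log-space internally, so no
overflow at these sizes).

## Estimators

* **MLE** S/N, with N = n1 or n1 + n2′.  Its exact bias b(Π) is computed by
  enumeration; it is ≤ 0 everywhere for futility-stopping designs.
* **Whitehead** solves p + b(p) = MLE.  b(·) need not be monotone, so the
  solver scans a 201-point grid for a sign change and bisects inside it;
  when no sign change exists the grid point minimizing the residual is
  returned.
* **Guo–Liu** is the one-step version MLE − b(MLE), clamped to [0, 1].
* **UMVUE** E[X1/n1 | (M, S)]: s/n1 after a stop; for continuations the
  ratio of truncated convolution sums with C(n1−1, x1−1) numerator terms,
  evaluated in exact integer arithmetic (`math.comb`) so unbiasedness holds
  to ~1e−16 in the enumeration engine.  Because the construction never uses
  the stage-2 boundary, replacing n2 by the attained n2′ keeps it exactly
  unbiased under sample-size modification.
* **UMVCUE** E[X2/n2′ | M = 2, S]: same structure with C(n2′−1, s−x1−1)
  numerator; conditionally unbiased given continuation.  After an early
  stop the first-stage proportion s/n1 (equal to the UMVUE there) is
  reported.
* **Conditional MLE** maximizes s log p + (nt′−s) log(1−p) − log Pr_p(X1 > r1)
  (bounded Brent, bracket [1e−9, 1−1e−9], tolerance 1e−10, explicit
  boundary comparison).  It depends on the data only through s and never
  exceeds the unconditional MLE.
* **Median estimator**: the Π at which the trial's p-value is one half.
  For continuations the conditional-power p-value is inverted by bisection
  (tolerance 1e−8); at the planned sample size this is the stage-wise
  p-value.  The construction is undefined after an early stop; there the
  unconditional sample proportion s/n1 is reported, matching the fallback
  used for the other continuation-only estimators.  This early-stop
  convention noticeably affects unconditional summaries at Π near Π0,
  where most trials stop at stage 1.

## P-values

One-sided, for H0 : Π ≤ Π0, ordered as follows: naive (pooled binomial
tail, which sums over impossible paths with X1 ≤ r1), MLE ordering (mass of
outcomes with sample proportion ≥ observed, ties included), stage-wise /
UMVUE ordering (continuations are more extreme than any stop; closed-form
truncated-convolution tail), conditional on M = 2 (tail of the normalized
continuation law), and the conditional-power ordering for attained sizes
(below).  The stage-wise test with "reject iff p ≤ α" reproduces the
design's decision region outcome-by-outcome because the search picks the
minimal rt.

## Attained second-stage sample size

Given x1, the planned design would wrongly cross the final boundary with
conditional probability A(x1, n2, Π0) = Pr_{Π0}(X2 > rt − x1); the
attained-size rule rejects when the observed tail Pr_{Π0}(X2′ ≥ x2) fits
inside that budget, so the conditional (hence unconditional) type-I error
can only shrink.  The companion p-value maps the observed tail to an
equivalent rate Π* through A(x1, n2, ·) — a beta quantile, since the
binomial tail in p is a regularized incomplete beta — and aggregates
A(·, n2, Π*) over all continuation paths.  Rejection by the adjusted rule
is equivalent to this p-value not exceeding the design's **attained** α;
at the nominal α the equivalence can fail on the few paths whose p-value
falls between the attained and nominal levels.

Degenerate paths need conventions: when x1 > rt the conditional power is
identically one and the Π* equation has no solution; such interims have
already secured rejection and are scored as maximal evidence (Π* → 0).
When x2 = 0 the observed tail is one, Π* → 1, and the p-value equals the
continuation probability.  At the planned size (Δn2 = 0) the method is the
stage-wise p-value by definition; the Π*-ordering is used only when
n2′ ≠ n2.

## Confidence intervals

All intervals are equal-tail at two-sided level 1 − 2α (α = 0.05 gives the
conventional 90% interval) and are found by bisection (tolerance 1e−8) on
tails that are monotone in p; degenerate outcomes (minimum of the ordering,
maximum of the ordering) pin the corresponding bound at 0 or 1, the
standard Clopper–Pearson convention.  Mid-p variants put half weight on the
observed outcome in both tail equations and are always nested inside their
exact counterparts.  Conditional variants invert the tails of S given
M = 2.  The conditional score interval standardizes s around
E[S | M = 2] = E[X1 | X1 > r1] + n2′p with the matching truncated variance;
the continuity correction shifts s by ±½ before standardization.  The
source literature cites but does not reprint the exact score dialect; this
construction is the package's declared one, and no cross-study numeric
comparison depends on it.  The attained-size interval inverts the
conditional-power ordering in both directions, with the lower tail of the
ordering built from Pr(X2′ ≤ x2) symmetrically; among the tied
maximal-evidence paths (x1 > rt) the lower tail orders by x2.

## Evaluation engine

Methods depending on the data only through (M, S) are enumerated on the
(M, S) space (≈ n_t′ + 2 outcomes); the attained-size p-value, interval and
median estimator depend on (x1, x2) separately when Δn2 ≠ 0 and are
enumerated on the path space ((n1 − r1)(n2′ + 1) + r1 + 1 paths).  Exact
bias, RMSE, rejection and coverage are weighted sums; conditional versions
renormalize over continuations.  Per-outcome method values are cached per
(design, n2′), so grids over Π reuse them.  Full-precision values are kept
throughout; rounding to 3 decimals happens only at presentation.

## Simulator

`simulate_trials` draws trials directly from the model with a single
`numpy` Generator seeded by one integer; it exists as an independent
cross-check of the enumeration engine (agreement within Monte-Carlo error
is a standing test at 200k trials) and as a demo-data source.  It emulates
only the binomial two-stage mechanism — no accrual times, covariates or
informative dropout — so agreement says nothing about violations of the
non-informative-accrual assumption, only about the correctness of the
exact arithmetic.

## Known limitations

* No early-efficacy stopping, three-stage designs, or adaptive stage-2
  sizes.
* The median estimator's early-stop convention and the exact dialects of
  the conditional score correction and of the attained-size interval's
  opposite tail are declared choices; alternatives exist in the literature
  and change third-decimal summaries at rates near Π0.
* Conditional inference is undefined after an early stop; the package
  falls back to first-stage constructions and warns, rather than refusing.
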