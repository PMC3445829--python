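# simon2stage

Design and inference for Simon-type two-stage phase II trials — including
trials whose attained second-stage sample size differs from plan, and
inference conditional on having reached stage 2.

## The problem

Single-arm phase II oncology trials commonly use Simon's two-stage design:
enrol n1 patients, stop for futility if the number of responses X1 is at
most r1, otherwise enrol n2 more and reject H0 : Π ≤ Π0 when the total
number of responses S = X1 + X2 exceeds rt.  The stopping rule controls the
one-sided type I error α and the type II error β, but it also breaks naive
estimation: the sample proportion S/N is biased (the optional sampling
effect), binomial tail p-values sum over impossible sample paths, and
Clopper–Pearson intervals ignore the sequential outcome distribution.
Matters get worse when the trial actually accrues n2′ = n2 + Δn2 patients
in stage 2, or when inference is wanted conditionally on the trial having
continued.

`simon2stage` implements, in exact finite-sample arithmetic:

* **Design search** — Simon's *optimal* (minimal E[N | Π0]) and *minimax*
  (minimal n1 + n2) designs for given (Π0, Π1, α, β).
* **Seven point estimators** — the MLE S/N; Whitehead's bias-adjusted
  estimator solving p + b(p) = MLE; Guo–Liu's one-step correction
  MLE − b(MLE); the UMVUE (Rao–Blackwellisation of X1/n1 given the complete
  sufficient statistic (M, S)); the conditional MLE of the truncated
  (X1 > r1) likelihood; the UMVCUE (Rao–Blackwellisation of X2/n2′ given
  continuation); and the median-unbiased estimator solving p(Π) = ½.
* **Five p-values** — naive binomial, MLE-ordering, stage-wise ordering
  (equivalent to UMVUE ordering; reproduces the design's decision exactly),
  conditional on M = 2, and the Koyama–Chen conditional-power p-value for
  attained sample sizes.
* **Seven two-sided (1 − 2α) confidence intervals** — naive Clopper–Pearson,
  exact stage-wise, mid-p stage-wise, conditional exact, conditional score
  with continuity correction, conditional mid-p, and the Koyama–Chen
  interval.
* **Attained-size testing** — the adjusted stage-2 critical value that
  preserves the planned conditional type-I error A(x1, n2, Π0), with the
  duality "reject ⇔ p_k at or below the attained α".
* **Exact evaluation engine** — bias, RMSE, rejection probability and
  coverage probability of every method by enumeration of the outcome space
  (or of the (x1, x2) path space where needed), unconditionally or given
  M = 2, over grids of true rates and Δn2.
* **Monte-Carlo simulator** — an independent cross-check of the exact
  engine and a demo-data generator.

## Worked example

Find the optimal design for Π0 = 0.05 vs Π1 = 0.20 at α = 0.05, 90% power:

```sh
$ simon2stage design --pi0 0.05 --pi1 0.20 --criterion optimal
optimal design for pi0=0.05, pi1=0.2, alpha=0.05, beta=0.1
  n1=21  r1=1  n2=20  rt=4  nt=41
  PET(pi0)=0.7170  EN(pi0)=26.66
  attained alpha=0.0457  attained power=0.9017
```

So: enrol 21 patients, stop if ≤ 1 response; otherwise enrol 20 more and
declare the drug promising if more than 4 of 41 respond.  Under Π0 the
trial stops early 71.7% of the time and treats 26.7 patients on average.

Suppose the trial continued after x1 = 3 responses, but stage 2 closed at
18 patients instead of 20 (Δn2 = −2) with x2 = 4 further responses:

```sh
$ simon2stage analyze --n1 21 --n2 20 --r1 1 --rt 4 --x1 3 --x2 4 \
      --n2-actual 18 --pi0 0.05
design n1=21 r1=1 n2=20 rt=4; observed m=2 x1=3 x2=4 s=7 (attained n2'=18)
point estimates:
  mle              0.179
  whitehead        0.185
  guo              0.185
  umvue            0.183
  conditional_mle  0.171
  umvcue           0.175
  median           0.164
p-values (pi0=0.05):
  naive            0.0029
  mle_order        0.0029
  stagewise        0.0029
  conditional      0.0101
  koyama_chen      0.0064
90% confidence intervals:
  naive_exact        [0.087, 0.311]
  stagewise          [0.088, 0.312]
  midp               [0.095, 0.300]
  conditional_exact  [0.075, 0.309]
  conditional_score  [0.080, 0.313]
  conditional_midp   [0.083, 0.296]
  koyama_chen        [0.080, 0.299]
adjusted stage-2 rule at x1=3: reject iff x2 >= 2 (planned: x2 >= 2;
conditional type-I budget 0.2642)
```

The raw proportion 7/39 = 0.179 is pulled down by the stopping rule; the
bias-corrected and Rao–Blackwell estimators land slightly higher (UMVUE
0.183).  The exact stage-wise p-value 0.0029 rejects Π0 = 0.05, and the
adjusted stage-2 boundary (x2 ≥ 2, here coinciding with the planned rule)
confirms the rejection at the attained sample size.  The mid-p interval
[0.095, 0.300] sits strictly inside the exact one, reflecting its
near-nominal rather than conservative coverage.

Exact operating characteristics over a grid (here: bias and RMSE of the
MLE and UMVUE at Π = 0.05 with Δn2 = −2, written as CSV):

```sh
$ simon2stage evaluate --design 21,20,1,4 --pi0 0.05 \
      --pi-grid 0.05:0.05:0.01 --delta-n2 -2 \
      --estimators mle,umvue --tests stagewise --cis "" --out table.csv
```

From Python the same quantities are a couple of calls:

```python
>>> from simon2stage import TwoStageDesign, estimator_bias_rmse
>>> d = TwoStageDesign(n1=21, n2=20, r1=1, rt=4)
>>> estimator_bias_rmse(d, -2, 0.05, "mle")     # (bias, rmse)
(-0.00827..., 0.03769...)
>>> estimator_bias_rmse(d, -2, 0.05, "umvue")[0]  # exactly unbiased
5.2e-18
```

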