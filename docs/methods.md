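# Methods

## Statistical model

We consider a randomized two-arm parallel-group single-center trial with
1:1 target allocation, total sample size `N`, and `m >= 1` continuous
endpoints analysed once at trial end by pooled-variance two-sample
t-tests. Patient `j`'s response vector is

```
X_j = mu_E t_j + mu_C (1 - t_j) + tau_j + eps_j,
eps_j ~ N_m(0, Sigma) iid,   Sigma = diag(sigma) R diag(sigma),
```

with `t_j = 1` for assignment to treatment (E) and `0` for control (C).
The allocation vector is a realization of the chosen randomization
procedure (RP). `tau_j` is the allocation-bias shift: under the
convergence guessing strategy the investigator expects the next
assignment to favour the currently under-represented arm and enrols a
good responder (`+eta_k` on every endpoint), a bad responder (`-eta_k`)
or a neutral patient (0) according to the sign of the imbalance
`D_{j-1} = N_E(j-1) - N_C(j-1)`. The shift is attached to the patient's
recruitment position (it depends on `D_{j-1}` only), not on the realized
assignment: it models who is enrolled, not where they end up.

Assumptions: common covariance in both arms, no time trends, no interim
analyses, equal `eta_k` sign structure across endpoints (a "better"
patient is better on every endpoint). The analysis model ignores the
bias terms — the computed error rates quantify the cost of that
misspecification.

## Error rates for a fixed list

Conditionally on the list, each endpoint's t statistic is doubly
non-central t distributed with `df = N - 2`, numerator non-centrality
`delta_k` (driven by the between-arm imbalance of the shifts) and
denominator non-centrality `lambda_k` (the within-arm spread of the
shifts in variance units); the formulas are in the README and
`error_rates.py`. Two decision rules are evaluated:

* **Šidák / multiple primary endpoints** — reject globally if any
  endpoint rejects two-sided at `alpha* = 1 - (1-alpha)^(1/m)`. For
  independent endpoints the FWER is one minus the product of the
  per-endpoint acceptance probabilities. For correlated endpoints the
  responses are rotated into the principal-component basis of `Sigma`
  (eigenvectors by descending eigenvalue); the components are
  independent normal with variances the eigenvalues, the global test
  problems before and after rotation are equivalent, and the
  independent-endpoint formula applies to the rotated shifts
  `A^T tau_j` and component scales `sqrt(eigenvalue)`.
* **All-or-none / co-primary endpoints** — reject globally only if every
  endpoint rejects one-sided at `alpha`. Its type I error is the size of
  the intersection-union test: the supremum over the composite null
  (`H_0` = union of component nulls), attained at the least favourable
  configuration where all but the weakest component reject almost
  surely, hence `max_k F(t_df(alpha); df, -delta_k, lambda_k)`. No
  rotation is needed; the bound is valid under any dependence. Note this
  is a supremum, not the rejection probability at `mu_E = mu_C` (for
  independent endpoints that joint probability is near `alpha^m`); the
  simulation oracle therefore estimates it as the maximum of the
  per-component one-sided rejection fractions, and separately exposes
  the joint fraction for the intersection-union bound check.

With `eta = 0` both rates equal `alpha` exactly — Šidák exhausts the
level for independent endpoints, and the same-directed-effects
assumption makes the intersection-union test exact — which the tests
verify to 1e-10.

## Doubly non-central t CDF

`dnct_cdf` evaluates `F(x; df, delta, lam)` by conditioning on the
Poisson mixing index of the denominator's non-central chi-square:
given index `j`, the denominator is a central chi-square with `df + 2j`
degrees of freedom and the ratio reduces to a singly non-central t
variate scaled by `sqrt(df/(df+2j))`, so each mixture term is one
`scipy.special.nctdtr` call at `x*sqrt((df+2j)/df)`. Poisson weights are
computed in log space; the series is truncated once the neglected
Poisson mass falls below `tol` (default 1e-12), with a hard cap of
10 000 terms beyond which a convergence error reports the achieved
bound. In this application `lam <= sum_j tau_{j,k}^2 / sigma_k^2` is
well below one, so a handful of terms suffice. A memoized scalar entry
point rounds `(x, delta, lam)` to 12 significant digits for cache
identity, collapsing float noise from equivalent lists.

## Randomization procedures

All seven samplers draw from the exact distribution of the named
procedure; small-`N` chi-square tests against exactly enumerated
sequence probabilities are part of the suite. The maximal procedure is
sampled exactly by backward path counting: `count(j, d)` admissible
completions (paths to terminal balance that never exceed the maximum
tolerated imbalance `b`), computed in exact integer arithmetic, give the
forward transition probabilities. Terminal balance `D_N = 0` is part of
the maximal procedure's definition here, consistent with its use
alongside even `N`. Permuted blocks require `N` divisible by the block
size; truncated final blocks are rejected rather than silently
shortened. Forced assignments (big stick or Chen's design at the
imbalance boundary, maximal procedure with a single admissible arm) are
deterministic; the batch generator draws one uniform per patient per
list up front and ignores the draw on forced steps, so a study is
bit-reproducible from (configuration, seed).

## Monte-Carlo study

Per RP, `r` lists are drawn and each list's rate is computed
analytically. Because the bias matrix has rank one (`tau_{j,k} = eta_k
s_j` with responder signs `s_j` in {-1,0,+1}), a list's non-centrality
profile is determined by five integer counts (`n_E`, within-arm sums of
`s` and `s^2`); rates are evaluated once per distinct profile and
broadcast, so 100 000-list settings complete in a few seconds on one
CPU. Summaries are the mean rate and `P_RP(rate <= alpha)`, the
inclusive comparison carrying a 1e-12 absolute guard so the unbiased
case counts as controlled despite float noise. Degenerate lists (an
empty arm, probability `2^(1-N)` under complete randomization only) are
excluded and counted. Each RP gets an independent RNG sub-stream keyed
by a CRC of its label, so one procedure's sample is invariant to the
roster around it.

Default study conditions mirror the shipped configs: `alpha = 0.05`,
`r = 100 000`, `N` in {12, 32, 64}, `m` in {2, 5}, standard-normal
endpoints, homogeneous bias effects `eta = nu * E_N` with `nu` in
{0.01, 0.05, 0.1} and `E_N` the standardized effect size a trial of
size `N` detects with 80% power at two-sided 5% (`E_12 = 1.795`,
`E_32 = 1.024`, `E_64 = 0.711`); the RP roster is CR, EBC(0.67), BSD(3),
CHEN(2,0.67), MP(3), RAR, PBR(4). The five-endpoint planning example
(`N = 24`) uses pooled standard deviations, effect sizes and an
estimated correlation matrix from published developmental-scale data,
with `eta = nu * (0.114, 0.509, 0.315, 0.361, 1.034)` against
`sigma = (15.70, 14.19, 15.02, 21.37, 22.71)` in matching endpoint
order.

## Validation oracle

`oracle.empirical_rate` simulates full trials from the biased model
(multivariate-normal errors via a Cholesky factor, the same
pooled-variance t statistic with `1/(N-2)` scaling that the
distributional result describes) and applies the actual decision rules.
The acceptance suite checks formula/oracle agreement within three
binomial standard errors at 1e6 simulated trials per design over a grid
of small designs (`N` in {8, 12}, `m` in {1, 2, 3}, bias effects 0 to
0.5, exchangeable correlation 0 and 0.5). For correlated designs the
oracle tests the rotated components — the analysis the formula models;
whether the Šidák test on raw correlated components has the same
per-list FWER as on rotated components is a separate question the
oracle's `use_pca=False` switch exposes but the package does not assert.

## Numerical and design choices

* Central-t quantiles use the lower-tail convention
  (`t_df(alpha*/2) < 0`), matching the CDF-based rejection formulas.
* Eigenvector basis: eigenvalues sorted descending with a stable sort;
  each column's largest-magnitude entry is made positive (first maximum
  wins ties). Two-sided rejection probabilities are invariant to column
  signs; the convention only pins down a reproducible basis for repeated
  eigenvalues (e.g. exchangeable correlation).
* Zero eigenvalues (semidefinite `Sigma`) drop their component from the
  Šidák product — a degenerate component carries no test — while `m` in
  `alpha*` keeps the original endpoint count.
* The generator encodes treatment as 1 and control as 0; arm-swapping a
  list while holding the shifts fixed negates every `delta_k`, leaves
  `lambda_k` unchanged, and leaves the two-sided FWER invariant.

## What the tests do and do not show

The study is fully synthetic: the generator realizes the exact RP laws
and the biasing policy realizes the convergence strategy with known
effects, so passing tests demonstrate the analytic machinery and its
implementation, and the reproduced tables quantify bias impact *under
this model*. They do not validate the model against real investigator
behaviour: real selection bias involves imperfect guessing, partial
knowledge, heterogeneous patient pools and time trends, none of which
are modelled. Other known limitations: equal allocation only,
continuous endpoints only, no power analysis under alternatives (the
design types carry `mu_E`, `mu_C` for generality, but all shipped
settings are null configurations), and only the Šidák and all-or-none
rules — data-driven multiplicity adjustments (Holm, Hochberg) and closed
testing are out of scope.
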