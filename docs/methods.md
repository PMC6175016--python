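# Methods

## Setting and model

A two-stage trial compares an experimental treatment with control on a
normally distributed outcome with known standard deviation `sigma`. A
continuous biomarker with prespecified candidate thresholds partitions the
full population `F` into `K >= 2` partitions with known cumulative
prevalences `0 < p_1 < ... < p_K = 1` (per-partition prevalences
`w_i = p_i - p_{i-1}`). Candidate subpopulations are nested:
`S_i` = partitions `1..i`. True partition effects `delta_i` induce
subpopulation effects through the linear map
`theta_i = sum_{i'<=i} w_i' delta_i' / p_i`. The working convention is that
a higher biomarker value implies a smaller effect; a design flag negates
biomarker values on ingestion for the opposite orientation.

Stage-1 partition mean differences are independent,
`Xbar_1i ~ N(delta_i, tau2_1i)` with `tau2_1i = sigma^2 (1/n_E + 1/n_C)`
(`= 4 sigma^2 / n_1i` at 1:1 allocation). Subpopulation means are the
prevalence-weighted combinations `Ybar_1i = sum_{i'<=i} w_i' Xbar_1i' / p_i`.

**Variance of subpopulation means.** Because `Ybar` is defined by
prevalence weighting, its variance is
`sigma2_1i = sum_{i'<=i} w_i'^2 tau2_1i' / p_i^2`. When per-partition sample
sizes are proportional to prevalences — true for every design in the
reference setting (equal quartiles, equal sizes) — this equals the familiar
pooled form `4 sigma^2 / m_1i` with `m_1i = sum n_1i'`. The general form is
used so that the identity `Prob(F) = Phi((theta_K - b)/sigma_1K)` holds
exactly for arbitrary valid designs; both forms agree on all reference
numbers. `sigma` and the prevalences are treated as known; a plug-in pooled
`sigma` may be supplied by the user (the package does not estimate it).

## Selection rule and conditioning event

The trial continues with the largest `S_s` whose observed stage-1 mean is at
least the futility boundary `b` (`ybar_1s >= b`, ties continue), and stops
if every `ybar_1i < b`. For `s < K` this event is equivalent to
`b <= ybar_1s < u` with

    u = min_{j>s} [ p_j b - sum_{i=s+1}^{j} w_i xbar_1i ] / p_s ,

and, partition by partition, to `v_i <= xbar_1i < w_i` for `i <= s` with the
analogous displayed formulas. For `s = K` the upper limits are `+inf`
(`Phi(+inf) = 1`, `phi(+inf) = 0` downstream). All corrected estimators
condition on this event.

## Decision probabilities and conditional bias

With `Z_j = sum_{i<=j} w_i Xbar_1i = p_j Ybar_1j`, selection events are
rectangles: `S_s` (s < K) is `{Z_s >= p_s b} ∩ {Z_j < p_j b, j > s}`. The
increments `D_j = w_j Xbar_1j` are independent normals, so `Z` is a Markov
chain and any region probability or truncated moment factorises into nested
one-dimensional integrals. These are evaluated by a transfer-matrix
recursion: each level is represented on Gauss–Legendre nodes over the
marginal +-8.5-sd window (truncated at the threshold), and payload vectors
(probability flow, `Z_s`-weighted flow, increment-weighted flows) are pushed
through the normal transition kernel. The node count per level is at least
200 and grows to ~5 nodes per kernel sd when an increment is much narrower
than the level window (capped at 3000). Probabilities agree with scipy's
multivariate-normal rectangle probabilities to ~1e-6 and with 10^6-replicate
Monte Carlo within binomial error; `Prob(F)` matches its closed form to
~1e-10.

The conditional bias of the naive estimator
`theta_hat_{s,N} = t_s Ybar_1s + (1-t_s) Ybar_2s`,
`t_s = m_1s / (m_1s + m_2s)`, is

    Bias = t_s ( E[Z_s 1[S_s]] / (p_s Prob(S_s)) - theta_s ).

The stage-2 term is conditionally unbiased, so only the stage-1 fraction
carries bias; the expression vanishes when truncation does (no-boundary
limit), which fixes the reading of the published display. A probability
floor of 1e-12 guards the division; configurations below it raise an error
rather than return noise.

Per-partition conditional means follow from the same quadrature: for
`i <= s`, `(D_i, Z_s)` are jointly normal and the event acts on `D_i` only
through `Z_s`, giving
`E[Xbar_1i | S_s] = delta_i + w_i tau2_1i (E[Z_s|S_s] - m_s) / Var(Z_s)`;
for dropped partitions the increment expectations are accumulated inside
the recursion.

## Estimators

All estimators address `theta_s` conditional on the selection event.

- **Naive**: the two-stage weighted mean above; biased.
- **UMVCUE** (Rao–Blackwell on the subpopulation scale):
  `theta_N - sigma2_2s/sqrt(sigma2_1s+sigma2_2s) * [phi(f(b))-phi(f(U))]/[Phi(f(b))-Phi(f(U))]`
  with `f(x) = sqrt(sigma2_1s+sigma2_2s)/sigma2_1s (theta_N - x)`; the
  minimum-variance conditionally unbiased estimator.
- **Partition-wise unbiased**: the same correction per selected partition
  with limits `(V_i, W_i)`, combined with prevalence weights; unbiased but
  not minimum variance (it coincides with the UMVCUE when `S_1` is
  selected).
- **Single-iteration bias-adjusted (SI)**: naive minus the quadrature bias
  at the plug-in effect vector (two-stage means for selected partitions,
  stage-1 means otherwise).
- **Multiple-iteration bias-adjusted (MI)**: fixed point of
  `delta~ = delta_hat - b(delta~)` on the partition scale, iterated to
  max-norm 0.001 (default; max 100 iterations, non-convergence returns the
  last iterate with a warning). `theta_hat_MI` combines the adjusted
  selected-partition effects with prevalence weights.
- **Shrinkage L1**: per-partition empirical-Bayes shrinkage of stage-1 means
  toward the unweighted grand mean with factor
  `C+ = clip(1 - 2(K-3) sigma^2 / [n sum_j (xbar_1j - mean)^2], 0, 1)`
  (`2(K-1)` for `K < 4`), combined with stage-2 means via the stage-1
  fraction; `n` is the per-arm per-partition stage-1 size (geometric mean
  when sizes differ — a documented convention, the source does not state
  one).
- **Shrinkage L2**: exchangeable normal prior `delta_i ~ N(mu, nu^2)`
  (equivalently a correlated multivariate prior on `theta` through the
  linear map), hyperparameters from a damped moment ("Morris-type")
  iteration (damping 0.5, tolerance 1e-8, max 200 iterations, prior
  variance truncated at 0), posterior partition means combined with stage-2
  data as in L1. On iteration failure the estimate falls back to L1 with a
  recorded status.

**Numerical stability.** Every `phi/Phi` difference ratio is computed via
an exponentially scaled (`erfcx`) form when both arguments are in the same
tail, with the l'Hopital limit at coincident arguments; extreme truncation
intervals never produce 0/0.

## Design choices made where the source was open

- **MI dropped-partition scheme.** The published description iterates the
  bias equation over the full effect vector, but for dropped partitions the
  equation `E[Xbar_1i | S_s; delta] = xbar_1i` is nearly unidentified (the
  conditional mean is insensitive to `delta_i`), so joint iteration can
  drift to extreme values or fail to converge. The default therefore holds
  dropped partitions at their stage-1 plug-ins (identical to the SI
  plug-in rule) and iterates only the selected partitions; the literal
  joint scheme is available via `dropped="iterate"`. With the default the
  worked example gives 2.641 (reference value 2.666, whose exact
  computation the published description leaves open; the joint scheme
  gives 2.844). The SI
  estimate reproduces the reference 2.633 within 0.002, validating the
  underlying bias quadrature.
- **Shrinkage factor variant.** The stated `K >= 4` formula (`2(K-3)`)
  yields `C_hat = 0.584` and L1 = 2.427 on the worked example, while the
  printed L1 = 2.164 corresponds to the `2(K-1)` variant (complete
  shrinkage, `C+ = 0`). Both are exposed (`ShrinkageConfig.c_variant`);
  the default "auto" follows the stated K-dependent rule. `C_hat` is also
  clipped above at 1, since values above 1 would anti-shrink.
- **Shrink target.** Default is the unweighted mean of partition means; a
  prevalence-weighted target is available behind
  `ShrinkageConfig(target="prevalence")` (off by default).
- **L2 detail.** The reference L2 value (2.194) depends wholly on
  unpublished algorithmic detail; with the moment iteration here the
  estimated prior variance is 0 on the worked example and L2 equals the
  complete-shrinkage value 2.164. It is treated as a soft check (the value
  must lie between complete shrinkage and naive).
- **Boundary ties**: `ybar = b` continues; equality at `u` is outside the
  selection region (half-open interval).

## Synthetic data generator

`simulate_trial_means` draws stage-1 partition means from their exact
normal law (sufficient for every estimator; used for the
operating-characteristics study), and `simulate_patients` generates
patient-level records (uniform biomarker within partition edges, stratified
allocation with exact per-partition counts and 1:1 arms, normal outcomes)
for end-to-end pipeline tests. Default study conditions mirror the
reference simulation study: `K = 4` equal quartiles, `sigma = 1`, `b = 0`,
total two-stage enrolment 800 with stage-1 totals 200/400/600, stage-2
patients split equally over selected partitions and arms (enrichment); a
fixed per-partition stage-2 plan ("no enrichment") is also supported.
Splits that do not divide evenly raise an error rather than rounding.

What the generator does *not* emulate: covariate drift between stages,
unknown or estimated prevalences, biomarker measurement error, dropout, and
non-normal outcomes. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those departures.

The study harness evaluates conditional bias and MSE,
`bias = mean(est - theta_s | decision = s)`, per estimator and selection
cell, with decision frequencies cross-checked against quadrature. The
default replicate count is 10^5 (the reference study used 10^6; the
quadrature-validated estimators converge well within Monte-Carlo error at
10^5, and the full size is a parameter). The closed-form estimators are
vectorised over replicates; SI/MI require one quadrature per replicate and
are intended for small replicate counts.

## Reproducibility

All randomised entry points take either a `numpy.random.Generator` or an
integer seed; the study harness derives independent streams per (scenario,
decision) so that changing the estimator subset never perturbs the draws.
CLI runs log the package version, a design hash, the seed and tolerances.

## Known limitations

- Hypothesis testing, confidence intervals, and time-to-event outcomes are
  out of scope; only point estimation is provided.
- Prevalences and `sigma` are treated as known.
- The UMVCUE weighting uses the sample-size fraction `t_s`; in designs
  whose stage allocations are strongly non-proportional to prevalences the
  sample-size and precision weightings differ, and conditional
  unbiasedness is exact in the proportional regime that the reference
  setting assumes.
- The MI and L2 estimators implement documented, configurable readings of
  procedures whose published description is incomplete (see above).
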