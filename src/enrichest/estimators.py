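"""Point estimators of the selected-subpopulation treatment effect.

Seven estimators of ``theta_s``, all conditional on the futility-based
selection rule:

* ``naive``: two-stage weighted mean, biased by selection;
* ``umvcue``: Rao-Blackwell correction on the subpopulation scale, the
  uniformly minimum variance conditionally unbiased estimator;
* ``unbiased_weighted``: prevalence-weighted combination of per-partition
  UMVCUEs (unbiased, but not minimum variance);
* ``single_iteration_adjusted``: naive minus its conditional bias evaluated
  at a plug-in effect vector;
* ``multiple_iteration_adjusted``: fixed point of the iterated bias
  correction on the partition scale;
* ``shrinkage_l1``: Hwang-type empirical-Bayes shrinkage of stage-1
  partition means toward a grand mean, combined with stage-2 data;
* ``shrinkage_l2``: empirical-Bayes posterior means under an exchangeable
  normal prior with moment-estimated hyperparameters (Morris-type
  iteration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._stats import trunc_phi_ratio
from .design import StageSummary, TrialDesign, theta_from_delta
from .probability import naive_bias as _naive_bias_fn
from .probability import partition_bias as _partition_bias_fn
from .selection import SelectionOutcome

__all__ = [
    "ShrinkageConfig",
    "EstimateReport",
    "naive",
    "umvcue",
    "partition_umvcue",
    "unbiased_weighted",
    "single_iteration_adjusted",
    "multiple_iteration_adjusted",
    "shrinkage_factor",
    "shrinkage_l1",
    "shrinkage_l2",
    "estimate_all",
]


class EstimationError(ValueError):
    pass


def _require_continuation(outcome: SelectionOutcome):
    if outcome.stopped:
        raise EstimationError("trial stopped at stage 1: no stage-2 estimand")


def _t_s(stage1: StageSummary, stage2: StageSummary, s: int) -> float:
    m1s = stage1.m[s - 1]
    m2s = stage2.m[s - 1]
    return float(m1s / (m1s + m2s))


def naive(stage1: StageSummary, stage2: StageSummary, s: int) -> float:
    """Naive two-stage estimate ``t_s ybar_1s + (1 - t_s) ybar_2s``."""
    t = _t_s(stage1, stage2, s)
    return float(t * stage1.ybar[s - 1] + (1.0 - t) * stage2.ybar[s - 1])


def umvcue(
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
) -> float:
    """Conditionally unbiased (Rao-Blackwell) estimate of ``theta_s``.

    The naive estimate is corrected for the truncation event
    ``b <= ybar_1s < u``:

        theta_N - sigma2_2s / sqrt(sigma2_1s + sigma2_2s)
                  * [phi(f(b)) - phi(f(u))] / [Phi(f(b)) - Phi(f(u))],

    with ``f(x) = sqrt(sigma2_1s + sigma2_2s) / sigma2_1s * (theta_N - x)``.
    The phi/Phi ratio is evaluated in a scaled form that never divides by a
    vanishing CDF difference.
    """
    _require_continuation(outcome)
    s = outcome.s
    est = naive(stage1, stage2, s)
    s1 = design.sigma2_1[s - 1]
    s2v = design.sigma2_2(s)[s - 1]
    root = np.sqrt(s1 + s2v)
    f_b = root / s1 * (est - design.futility_b)
    f_u = root / s1 * (est - outcome.u)
    corr = s2v / root * trunc_phi_ratio(f_b, f_u)
    return float(est - corr)


def partition_umvcue(
    i_prime: int,
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
) -> float:
    """Conditionally unbiased estimate of the partition effect ``delta_i'``.

    Same Rao-Blackwell form as :func:`umvcue` on the partition scale, with
    truncation limits ``v_i' <= xbar_1i' < w_i'``.
    """
    _require_continuation(outcome)
    s = outcome.s
    if not 1 <= i_prime <= s:
        raise EstimationError(f"partition {i_prime} was not selected (s={s})")
    n1 = stage1.n[i_prime - 1]
    n2 = stage2.n[i_prime - 1]
    d_naive = (n1 * stage1.xbar[i_prime - 1] + n2 * stage2.xbar[i_prime - 1]) / (n1 + n2)
    t1 = stage1.partition_vars[i_prime - 1]
    t2 = stage2.partition_vars[i_prime - 1]
    root = np.sqrt(t1 + t2)
    f_v = root / t1 * (d_naive - outcome.v[i_prime - 1])
    f_w = root / t1 * (d_naive - outcome.w[i_prime - 1])
    corr = t2 / root * trunc_phi_ratio(f_v, f_w)
    return float(d_naive - corr)


def unbiased_weighted(
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
) -> float:
    """Prevalence-weighted combination of per-partition UMVCUEs."""
    _require_continuation(outcome)
    s = outcome.s
    parts = np.array(
        [partition_umvcue(i, stage1, stage2, outcome, design) for i in range(1, s + 1)]
    )
    w = design.partition_weights[:s]
    return float((w * parts).sum() / design.p[s - 1])


def _plugin_delta(stage1: StageSummary, stage2: StageSummary, s: int, K: int) -> np.ndarray:
    """Plug-in effect vector: two-stage means for i <= s, stage-1 otherwise."""
    d = np.array(stage1.xbar, dtype=float)
    n1 = np.asarray(stage1.n)[:s]
    n2 = np.asarray(stage2.n)[:s]
    d[:s] = (n1 * stage1.xbar[:s] + n2 * stage2.xbar) / (n1 + n2)
    return d


def single_iteration_adjusted(
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
    **quad_opts,
) -> tuple[float, float]:
    """Naive estimate minus its conditional bias at the plug-in effects.

    Returns ``(estimate, plug_in_bias)``.
    """
    _require_continuation(outcome)
    s = outcome.s
    d_hat = _plugin_delta(stage1, stage2, s, design.K)
    eff = theta_from_delta(d_hat, design)
    t = _t_s(stage1, stage2, s)
    bias = _naive_bias_fn(eff, design, s, t, **quad_opts)
    return float(naive(stage1, stage2, s) - bias), float(bias)


@dataclass(frozen=True)
class _MIResult:
    delta_mi: tuple[float, ...]
    estimate: float
    iterations: int
    residual: float
    converged: bool


def multiple_iteration_adjusted(
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
    tol: float = 0.001,
    max_iter: int = 100,
    dropped: str = "plugin",
    **quad_opts,
) -> _MIResult:
    """Iterated bias adjustment on the partition scale.

    Solves ``delta_tilde = delta_hat - b(delta_tilde)`` by fixed-point
    iteration to max-norm tolerance ``tol``; the adjusted partition effects
    of the selected partitions are combined with prevalence weights.
    Non-convergence is reported with a warning, returning the last iterate.

    ``dropped`` controls the treatment of the non-selected partitions in the
    fixed-point system.  With ``"plugin"`` (default) their effects stay at
    the observed stage-1 means, exactly as in the single-iteration
    adjustment; only the selected partitions are iterated.  With
    ``"iterate"`` the full vector is solved jointly, which matches the
    estimating equation ``E[delta_hat | S_s]`` = observed for every
    partition but can push dropped-partition solutions to extreme values
    (or fail to converge) when their observed means are far below the
    boundary, because the conditional mean of a dropped partition is nearly
    insensitive to its true effect.
    """
    _require_continuation(outcome)
    if dropped not in ("plugin", "iterate"):
        raise EstimationError(f"unknown dropped-partition scheme {dropped!r}")
    s = outcome.s
    d_hat = _plugin_delta(stage1, stage2, s, design.K)
    update = np.ones(design.K, dtype=bool)
    if dropped == "plugin":
        update[s:] = False
    d_tilde = d_hat.copy()
    converged = False
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        bias = _partition_bias_fn(theta_from_delta(d_tilde, design), design, s, **quad_opts)
        d_next = d_tilde.copy()
        d_next[update] = d_hat[update] - bias[update]
        residual = float(np.max(np.abs(d_next - d_tilde)))
        d_tilde = d_next
        if residual <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"bias-adjustment iteration did not converge in {max_iter} steps "
            f"(residual {residual:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    # final adjustment at the solution, applied to every partition
    final_bias = _partition_bias_fn(theta_from_delta(d_tilde, design), design, s, **quad_opts)
    d_mi = d_hat - final_bias
    w = design.partition_weights[:s]
    est = float((w * d_mi[:s]).sum() / design.p[s - 1])
    return _MIResult(
        delta_mi=tuple(d_mi),
        estimate=est,
        iterations=iterations,
        residual=residual,
        converged=converged,
    )


@dataclass(frozen=True)
class ShrinkageConfig:
    """Configuration of the empirical-Bayes shrinkage estimators.

    ``c_variant`` selects the degrees-of-freedom constant in the shrinkage
    factor: ``"auto"`` uses 2(K-3) for K >= 4 and 2(K-1) for K < 4;
    the explicit variants force one constant.  ``target`` chooses the
    shrinkage target: the unweighted mean of partition means (default) or
    the prevalence-weighted full-population mean.  The factor is clipped to
    [0, 1]; values above 1 would anti-shrink.
    """

    c_variant: str = "auto"  # "auto" | "k_minus_3" | "k_minus_1"
    target: str = "unweighted"  # "unweighted" | "prevalence"
    clip_upper: bool = True
    l2_damping: float = 0.5
    l2_tol: float = 1e-8
    l2_max_iter: int = 200


def _shrink_target(stage1: StageSummary, design: TrialDesign, config: ShrinkageConfig) -> float:
    if config.target == "prevalence":
        return float((design.partition_weights * stage1.xbar).sum())
    return float(stage1.xbar.mean())


def shrinkage_factor(
    stage1: StageSummary, design: TrialDesign, config: ShrinkageConfig | None = None
) -> tuple[float, float]:
    """Empirical-Bayes shrinkage factor ``(C_hat, C_hat_plus)``.

    ``C_hat = 1 - 2(K - 3) sigma^2 / [n sum_j (xbar_1j - target)^2]`` for
    K >= 4 (2(K-1) for K < 4), where ``n`` is the stage-1 per-arm
    per-partition sample size (geometric mean across partitions when sizes
    differ).  Zero spread gives complete shrinkage (``C_hat_plus = 0``).
    """
    config = config or ShrinkageConfig()
    K = design.K
    if config.c_variant == "k_minus_3":
        df = 2.0 * (K - 3)
    elif config.c_variant == "k_minus_1":
        df = 2.0 * (K - 1)
    elif config.c_variant == "auto":
        df = 2.0 * (K - 3) if K >= 4 else 2.0 * (K - 1)
    else:
        raise EstimationError(f"unknown c_variant {config.c_variant!r}")
    # per-arm stage-1 size in one partition
    n_arm = np.asarray(stage1.n, dtype=float) / 2.0
    n = float(np.exp(np.mean(np.log(n_arm))))
    target = _shrink_target(stage1, design, config)
    spread = float(((stage1.xbar - target) ** 2).sum())
    if spread == 0.0:
        return -np.inf, 0.0
    c = 1.0 - df * design.sigma**2 / (n * spread)
    c_plus = max(0.0, c)
    if config.clip_upper:
        c_plus = min(1.0, c_plus)
    return float(c), float(c_plus)


def shrinkage_l1(
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
    config: ShrinkageConfig | None = None,
) -> tuple[float, float, float]:
    """First shrinkage estimate: per-partition Hwang shrinkage of stage-1
    means toward the grand mean, combined with stage-2 data.

    ``delta_i,L = t_i [C+ xbar_1i + (1 - C+) target] + (1 - t_i) xbar_2i``,
    combined with prevalence weights.  Returns ``(estimate, C_hat, C_hat+)``.
    """
    _require_continuation(outcome)
    config = config or ShrinkageConfig()
    s = outcome.s
    c, c_plus = shrinkage_factor(stage1, design, config)
    target = _shrink_target(stage1, design, config)
    n1 = np.asarray(stage1.n)[:s]
    n2 = np.asarray(stage2.n)[:s]
    t_i = n1 / (n1 + n2)
    shrunk1 = c_plus * stage1.xbar[:s] + (1.0 - c_plus) * target
    d_l = t_i * shrunk1 + (1.0 - t_i) * stage2.xbar
    w = design.partition_weights[:s]
    return float((w * d_l).sum() / design.p[s - 1]), c, c_plus


def _morris_iteration(
    x: np.ndarray, tau2: np.ndarray, config: ShrinkageConfig
) -> tuple[float, float, list[float], bool]:
    """Moment-based estimation of the exchangeable prior N(mu, nu^2).

    Iterates precision-weighted moment equations with damping; the prior
    variance estimate is truncated at zero (complete shrinkage).
    Returns (mu, nu2, trace, converged).
    """
    K = x.size
    nu2 = max(float(np.var(x, ddof=1) - tau2.mean()), 0.0)
    trace = [nu2]
    converged = False
    mu = float(x.mean())
    for _ in range(config.l2_max_iter):
        w = 1.0 / (tau2 + nu2)
        mu = float((w * x).sum() / w.sum())
        q = (w * ((K / (K - 1.0)) * (x - mu) ** 2 - tau2)).sum() / w.sum()
        nu2_new = max(float(q), 0.0)
        step = nu2 + config.l2_damping * (nu2_new - nu2)
        trace.append(step)
        if abs(step - nu2) <= config.l2_tol * (1.0 + nu2):
            nu2 = step
            converged = True
            break
        nu2 = step
    return mu, nu2, trace, converged


def shrinkage_l2(
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
    config: ShrinkageConfig | None = None,
) -> tuple[float, list[float], str]:
    """Second shrinkage estimate via an exchangeable empirical-Bayes prior.

    An exchangeable normal prior ``delta_i ~ N(mu, nu^2)`` (equivalently a
    correlated multivariate prior on the subpopulation effects, by the
    linear map) is updated with the stage-1 partition means; hyperparameters
    come from a damped Morris-type moment iteration.  Posterior partition
    means are combined with stage-2 data exactly as in the first shrinkage
    estimator.  Returns ``(estimate, nu2 trace, status)``; on iteration
    failure the first shrinkage estimate is returned with status
    ``"fallback_l1"``.
    """
    _require_continuation(outcome)
    config = config or ShrinkageConfig()
    s = outcome.s
    x = stage1.xbar
    tau2 = np.asarray(stage1.partition_vars, dtype=float)
    mu, nu2, trace, converged = _morris_iteration(x, tau2, config)
    if not converged or not np.isfinite(nu2):
        warnings.warn(
            "Morris iteration for the second shrinkage estimator did not "
            "converge; falling back to the first shrinkage estimator",
            RuntimeWarning,
            stacklevel=2,
        )
        est, _, _ = shrinkage_l1(stage1, stage2, outcome, design, config)
        return est, trace, "fallback_l1"
    post = (nu2 * x + tau2 * mu) / (nu2 + tau2)
    n1 = np.asarray(stage1.n)[:s]
    n2 = np.asarray(stage2.n)[:s]
    t_i = n1 / (n1 + n2)
    d_l2 = t_i * post[:s] + (1.0 - t_i) * stage2.xbar
    w = design.partition_weights[:s]
    return float((w * d_l2).sum() / design.p[s - 1]), trace, "ok"


@dataclass(frozen=True)
class EstimateReport:
    """All seven estimates with their intermediates for one trial."""

    s: int
    t_s: float
    naive: float
    umvcue: float
    unbiased: float
    partition_umvcues: tuple[float, ...]
    si: float
    si_bias: float
    mi: float
    mi_delta: tuple[float, ...]
    mi_iterations: int
    mi_residual: float
    mi_converged: bool
    l1: float
    c_hat: float
    c_hat_plus: float
    l2: float
    l2_trace: tuple[float, ...]
    l2_status: str
    u: float
    v: tuple[float, ...]
    w: tuple[float, ...]
    f_b: float = np.nan
    f_u: float = np.nan
    f_v: tuple[float, ...] = ()
    f_w: tuple[float, ...] = ()
    statuses: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "s": self.s,
            "t_s": self.t_s,
            "estimates": {
                "naive": self.naive,
                "umvcue": self.umvcue,
                "unbiased": self.unbiased,
                "si": self.si,
                "mi": self.mi,
                "l1": self.l1,
                "l2": self.l2,
            },
            "partition_umvcues": list(self.partition_umvcues),
            "si_bias": self.si_bias,
            "mi": {
                "delta": list(self.mi_delta),
                "iterations": self.mi_iterations,
                "residual": self.mi_residual,
                "converged": self.mi_converged,
            },
            "shrinkage": {
                "c_hat": self.c_hat,
                "c_hat_plus": self.c_hat_plus,
                "l2_trace": list(self.l2_trace),
                "l2_status": self.l2_status,
            },
            "limits": {"u": self.u, "v": list(self.v), "w": list(self.w)},
            "truncation_args": {
                "f_b": self.f_b,
                "f_u": self.f_u,
                "f_v": list(self.f_v),
                "f_w": list(self.f_w),
            },
            "statuses": dict(self.statuses),
        }


def estimate_all(
    stage1: StageSummary,
    stage2: StageSummary,
    outcome: SelectionOutcome,
    design: TrialDesign,
    config: ShrinkageConfig | None = None,
    *,
    mi_tol: float = 0.001,
    mi_max_iter: int = 100,
) -> EstimateReport:
    """Run all seven estimators, capturing intermediates.

    A failure of the second shrinkage estimator does not block the others;
    its status is recorded in the report.
    """
    _require_continuation(outcome)
    config = config or ShrinkageConfig()
    s = outcome.s
    statuses: dict[str, str] = {}
    n_est = naive(stage1, stage2, s)
    umv = umvcue(stage1, stage2, outcome, design)
    parts = tuple(
        partition_umvcue(i, stage1, stage2, outcome, design) for i in range(1, s + 1)
    )
    w = design.partition_weights[:s]
    unb = float((w * np.asarray(parts)).sum() / design.p[s - 1])
    si, si_bias = single_iteration_adjusted(stage1, stage2, outcome, design)
    mi = multiple_iteration_adjusted(
        stage1, stage2, outcome, design, tol=mi_tol, max_iter=mi_max_iter
    )
    l1, c_hat, c_plus = shrinkage_l1(stage1, stage2, outcome, design, config)
    try:
        l2, trace, l2_status = shrinkage_l2(stage1, stage2, outcome, design, config)
    except Exception as exc:  # pragma: no cover - defensive aggregation
        l2, trace, l2_status = l1, [], f"fallback_l1: {exc}"
    statuses["l2"] = l2_status
    statuses["mi"] = "converged" if mi.converged else "max_iter"
    # truncation-correction arguments (subpopulation and partition scale)
    s1v = design.sigma2_1[s - 1]
    s2v = design.sigma2_2(s)[s - 1]
    root = np.sqrt(s1v + s2v)
    f_b = float(root / s1v * (n_est - design.futility_b))
    f_u = float(root / s1v * (n_est - outcome.u))
    n1 = np.asarray(stage1.n)[:s]
    n2 = np.asarray(stage2.n)[:s]
    d_naive = (n1 * stage1.xbar[:s] + n2 * stage2.xbar) / (n1 + n2)
    t1 = np.asarray(stage1.partition_vars)[:s]
    t2 = np.asarray(stage2.partition_vars)[:s]
    proot = np.sqrt(t1 + t2)
    f_v = tuple(proot / t1 * (d_naive - np.asarray(outcome.v)))
    f_w = tuple(proot / t1 * (d_naive - np.asarray(outcome.w)))
    return EstimateReport(
        s=s,
        t_s=_t_s(stage1, stage2, s),
        naive=n_est,
        umvcue=umv,
        unbiased=unb,
        partition_umvcues=parts,
        si=si,
        si_bias=si_bias,
        mi=mi.estimate,
        mi_delta=mi.delta_mi,
        mi_iterations=mi.iterations,
        mi_residual=mi.residual,
        mi_converged=mi.converged,
        l1=l1,
        c_hat=c_hat,
        c_hat_plus=c_plus,
        l2=l2,
        l2_trace=tuple(trace),
        l2_status=l2_status,
        u=outcome.u,
        v=outcome.v,
        w=outcome.w,
        f_b=f_b,
        f_u=f_u,
        f_v=f_v,
        f_w=f_w,
        statuses=statuses,
    )
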