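"""Synthetic trial generation and the operating-characteristics study.

Trials are simulated either at the sample-mean level (each stage-1 partition
mean drawn from its exact normal law, which is sufficient for every
estimator and fast enough for 10^6 replicates) or at the patient level
(individual biomarker values, arms and outcomes; used for end-to-end
pipeline checks).  The study harness applies the selection rule, runs the
estimators on every replicate that continues to stage 2, and tabulates
decision frequencies plus conditional bias and MSE per (estimator, selected
subpopulation) cell, in the same conditional sense used for the operating
characteristics of the design:

    bias = mean(estimate - theta_s | decision = s),
    MSE  = mean((estimate - theta_s)^2 | decision = s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import trunc_phi_ratio
from .design import StageSummary, TrialDesign, build_design, subpop_from_partitions, theta_from_delta
from .estimators import ShrinkageConfig
from .selection import SelectionOutcome, select

__all__ = [
    "Scenario",
    "SimulationResult",
    "TABLE_SCENARIOS",
    "study_design",
    "simulate_patients",
    "summarize_patients",
    "simulate_trial_means",
    "simulate_stage1_means",
    "vector_select",
    "vector_estimates",
    "run_study",
]

FAST_ESTIMATORS = ("naive", "umvcue", "unbiased", "l1", "l2")
SLOW_ESTIMATORS = ("si", "mi")


@dataclass(frozen=True)
class Scenario:
    """A named true-effect configuration with its ideal decision."""

    label: str
    delta: tuple[float, ...]
    ideal: str  # "F", "S_i" or "stop"


#: The seven effect configurations of the operating-characteristics study
#: (outcome SD 1, futility boundary 0, four equal-prevalence partitions).
TABLE_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("1", (0.3, 0.3, 0.3, 0.3), "F"),
    Scenario("2", (0.2, 0.1, 0.1, 0.1), "F"),
    Scenario("3", (0.0, 0.0, 0.0, 0.0), "F"),
    Scenario("4", (0.1, 0.0, 0.0, -0.2), "S_3"),
    Scenario("5", (0.1, 0.0, -0.2, -0.1), "S_2"),
    Scenario("6", (0.1, -0.2, -0.1, -0.1), "S_1"),
    Scenario("7", (-0.1, -0.1, -0.1, -0.1), "stop"),
)


def study_design(n1_total: int = 200, total: int = 800) -> TrialDesign:
    """Design of the simulation study: K=4 equal quartiles, sigma=1, b=0.

    Stage 1 splits ``n1_total`` equally over partitions and arms; if the
    trial continues, the remaining ``total - n1_total`` patients are split
    equally over the selected partitions and arms (enrichment convention).
    """
    if n1_total % 8 != 0:
        raise ValueError("stage-1 total must split equally over 4 partitions and 2 arms")
    n1 = n1_total // 4
    return build_design(
        (0.25, 0.5, 0.75, 1.0), 1.0, 0.0, (n1,) * 4, int(total - n1_total)
    )


def simulate_patients(
    delta: Sequence[float],
    design: TrialDesign,
    stage: int,
    rng: np.random.Generator,
    s: int | None = None,
) -> pd.DataFrame:
    """Patient-level table for one stage of one trial.

    Allocation is stratified: per-partition counts match the design exactly
    and split equally between arms (prevalences are known by design, so
    partition membership is not binomial).  Biomarker values are drawn
    uniformly within each partition's threshold interval (population
    quantile scale when no thresholds are specified).
    """
    delta = np.asarray(delta, dtype=float)
    if stage == 1:
        sizes = np.asarray(design.n1)
        k_eff = design.K
    else:
        if s is None:
            raise ValueError("stage 2 requires the selected index s")
        sizes = design.stage2_sizes(s).astype(int)
        k_eff = s
    edges = (
        np.concatenate(([0.0], design.p))
        if design.thresholds is None
        else np.concatenate(([design.thresholds[0] - 1.0], design.thresholds))
    )
    frames = []
    pid = 0
    for i in range(k_eff):
        n = int(sizes[i])
        if n % 2 != 0:
            raise ValueError(f"partition {i + 1} size {n} cannot split 1:1")
        arm = np.array(["control", "experimental"]).repeat(n // 2)
        mean = np.where(arm == "experimental", delta[i], 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(pid, pid + n),
                    "biomarker": rng.uniform(edges[i], edges[i + 1], size=n),
                    "partition": i + 1,
                    "arm": arm,
                    "stage": stage,
                    "outcome": rng.normal(mean, design.sigma),
                }
            )
        )
        pid += n
    return pd.concat(frames, ignore_index=True)


def summarize_patients(
    patients: pd.DataFrame, design: TrialDesign, stage: int, s: int | None = None
) -> StageSummary:
    """Aggregate a patient-level table to a stage summary."""
    sub = patients[patients["stage"] == stage]
    means = (
        sub.groupby(["partition", "arm"])["outcome"].mean().unstack("arm")
    )
    xbar = (means["experimental"] - means["control"]).sort_index().to_numpy()
    return subpop_from_partitions(xbar, design, stage, s=s)


def simulate_stage1_means(
    delta: Sequence[float], design: TrialDesign, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw ``n`` stage-1 partition mean-difference vectors (exact law)."""
    delta = np.asarray(delta, dtype=float)
    return rng.normal(delta, np.sqrt(design.tau2_1), size=(n, design.K))


def simulate_trial_means(
    delta: Sequence[float], design: TrialDesign, rng: np.random.Generator
) -> tuple[StageSummary, SelectionOutcome, StageSummary | None]:
    """One trial at the sample-mean level: stage 1, decision, stage 2 (or None)."""
    x1 = simulate_stage1_means(delta, design, rng, 1)[0]
    stage1 = subpop_from_partitions(x1, design, 1)
    outcome = select(stage1, design)
    if outcome.stopped:
        return stage1, outcome, None
    s = outcome.s
    x2 = rng.normal(np.asarray(delta)[:s], np.sqrt(design.tau2_2(s)))
    return stage1, outcome, subpop_from_partitions(x2, design, 2, s=s)


def vector_select(x1: np.ndarray, design: TrialDesign) -> np.ndarray:
    """Vectorized selection decision (0 = stop, else s) for stage-1 mean rows."""
    w = design.partition_weights
    ybar = np.cumsum(w * x1, axis=1) / design.p
    above = ybar >= design.futility_b
    dec = np.where(above.any(axis=1), design.K - np.argmax(above[:, ::-1], axis=1), 0)
    return dec.astype(int)


def _vector_limits(x1: np.ndarray, s: int, design: TrialDesign):
    """Vectorized truncation limits (u, v, w) for rows all selecting S_s."""
    K = design.K
    p = design.p
    wts = design.partition_weights
    b = design.futility_b
    head = wts[:s] * x1[:, :s]
    head_sum = head.sum(axis=1)
    if s == K:
        u = np.full(x1.shape[0], np.inf)
        w_lim = np.full((x1.shape[0], s), np.inf)
    else:
        tail_cums = np.cumsum(wts[s:] * x1[:, s:], axis=1)
        u = ((p[s:] * b)[None, :] - tail_cums).min(axis=1) / p[s - 1]
        w_lim = (
            ((p[s:] * b)[None, :] - tail_cums)[:, None, :]
            - (head_sum[:, None] - head)[:, :, None]
        ).min(axis=2) / wts[:s][None, :]
    v_lim = (p[s - 1] * b - (head_sum[:, None] - head)) / wts[:s][None, :]
    return u, v_lim, w_lim


def vector_estimates(
    x1: np.ndarray,
    x2: np.ndarray,
    s: int,
    design: TrialDesign,
    which: Sequence[str] = FAST_ESTIMATORS,
    config: ShrinkageConfig | None = None,
) -> dict[str, np.ndarray]:
    """Closed-form estimators evaluated on arrays of replicate means.

    ``x1``: (n, K) stage-1 partition means of replicates that selected S_s;
    ``x2``: (n, s) stage-2 partition means.  The quadrature-based SI/MI
    estimators are not vectorizable this way and are excluded here.
    """
    config = config or ShrinkageConfig()
    wts = design.partition_weights
    p_s = design.p[s - 1]
    y1s = (wts[:s] * x1[:, :s]).sum(axis=1) / p_s
    y2s = (wts[:s] * x2).sum(axis=1) / p_s
    m1s = design.m1[s - 1]
    m2s = design.m2(s)[s - 1]
    t_s = m1s / (m1s + m2s)
    out: dict[str, np.ndarray] = {}
    naive = t_s * y1s + (1 - t_s) * y2s
    if "naive" in which:
        out["naive"] = naive
    need_limits = {"umvcue", "unbiased"} & set(which)
    if need_limits:
        u, v_lim, w_lim = _vector_limits(x1, s, design)
    if "umvcue" in which:
        s1v = design.sigma2_1[s - 1]
        s2v = design.sigma2_2(s)[s - 1]
        root = np.sqrt(s1v + s2v)
        f_b = root / s1v * (naive - design.futility_b)
        f_u = root / s1v * (naive - u)
        out["umvcue"] = naive - s2v / root * trunc_phi_ratio(f_b, f_u)
    if "unbiased" in which:
        n1 = np.asarray(design.n1, dtype=float)[:s]
        n2 = design.stage2_sizes(s)
        d_naive = (n1 * x1[:, :s] + n2 * x2) / (n1 + n2)
        t1 = design.tau2_1[:s]
        t2 = design.tau2_2(s)
        root = np.sqrt(t1 + t2)
        f_v = root / t1 * (d_naive - v_lim)
        f_w = root / t1 * (d_naive - w_lim)
        d_umv = d_naive - t2 / root * trunc_phi_ratio(f_v, f_w)
        out["unbiased"] = (wts[:s] * d_umv).sum(axis=1) / p_s
    if "l1" in which or "l2" in which:
        n1 = np.asarray(design.n1, dtype=float)[:s]
        n2 = design.stage2_sizes(s)
        t_i = n1 / (n1 + n2)
        target = (
            x1 @ wts if config.target == "prevalence" else x1.mean(axis=1)
        )
    if "l1" in which:
        K = design.K
        if config.c_variant == "k_minus_3" or (config.c_variant == "auto" and K >= 4):
            df = 2.0 * (K - 3)
        else:
            df = 2.0 * (K - 1)
        n_arm = float(np.exp(np.mean(np.log(np.asarray(design.n1) / 2.0))))
        spread = ((x1 - target[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore"):
            c = 1.0 - df * design.sigma**2 / (n_arm * spread)
        c_plus = np.clip(c, 0.0, 1.0 if config.clip_upper else np.inf)
        shrunk = c_plus[:, None] * x1[:, :s] + (1 - c_plus[:, None]) * target[:, None]
        d_l = t_i * shrunk + (1 - t_i) * x2
        out["l1"] = (wts[:s] * d_l).sum(axis=1) / p_s
    if "l2" in which:
        tau2 = design.tau2_1
        K = design.K
        nu2 = np.maximum(np.var(x1, axis=1, ddof=1) - tau2.mean(), 0.0)
        for _ in range(config.l2_max_iter):
            wgt = 1.0 / (tau2 + nu2[:, None])
            mu = (wgt * x1).sum(axis=1) / wgt.sum(axis=1)
            q = (wgt * ((K / (K - 1.0)) * (x1 - mu[:, None]) ** 2 - tau2)).sum(
                axis=1
            ) / wgt.sum(axis=1)
            step = nu2 + config.l2_damping * (np.maximum(q, 0.0) - nu2)
            if np.max(np.abs(step - nu2)) <= config.l2_tol * (1.0 + np.max(nu2)):
                nu2 = step
                break
            nu2 = step
        post = (nu2[:, None] * x1 + tau2 * mu[:, None]) / (nu2[:, None] + tau2)
        d_l2 = t_i * post[:, :s] + (1 - t_i) * x2
        out["l2"] = (wts[:s] * d_l2).sum(axis=1) / p_s
    return out


@dataclass(frozen=True)
class ConditionalCell:
    """Bias/MSE of one estimator conditional on one selection decision."""

    estimator: str
    s: int
    n_hits: int
    bias: float
    mse: float
    bias_mc_se: float
    approx_se: float  # sqrt(4 sigma^2 / (m_1s + m_2s))

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.mse))


@dataclass(frozen=True)
class SimulationResult:
    """Decision frequencies and conditional bias/MSE for one configuration."""

    scenario: Scenario
    design: TrialDesign
    n_replicates: int
    seed: int
    frequencies: dict[str, float]
    cells: tuple[ConditionalCell, ...] = field(default=())

    def frequency(self, decision: str) -> float:
        return self.frequencies.get(decision, 0.0)

    def cell(self, estimator: str, s: int) -> ConditionalCell | None:
        for c in self.cells:
            if c.estimator == estimator and c.s == s:
                return c
        return None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scenario": self.scenario.label,
                    "estimator": c.estimator,
                    "s": c.s,
                    "n_hits": c.n_hits,
                    "bias": c.bias,
                    "mse": c.mse,
                    "rmse": c.rmse,
                    "bias_mc_se": c.bias_mc_se,
                    "bias_over_se": c.bias / c.approx_se,
                    "rmse_over_se": c.rmse / c.approx_se,
                }
                for c in self.cells
            ]
        )


def _estimates_for_group(
    x1, x2, s, design, which, config, mi_tol, seed_estimates_slow
):
    est = vector_estimates(x1, x2, s, design, [w for w in which if w in FAST_ESTIMATORS], config)
    slow = [w for w in which if w in SLOW_ESTIMATORS]
    if slow:
        from .estimators import multiple_iteration_adjusted, single_iteration_adjusted

        si_vals = np.empty(x1.shape[0])
        mi_vals = np.empty(x1.shape[0])
        for r in range(x1.shape[0]):
            stage1 = subpop_from_partitions(x1[r], design, 1)
            outcome = select(stage1, design)
            stage2 = subpop_from_partitions(x2[r], design, 2, s=s)
            if "si" in slow:
                si_vals[r], _ = single_iteration_adjusted(stage1, stage2, outcome, design)
            if "mi" in slow:
                mi_vals[r] = multiple_iteration_adjusted(
                    stage1, stage2, outcome, design, tol=mi_tol
                ).estimate
        if "si" in slow:
            est["si"] = si_vals
        if "mi" in slow:
            est["mi"] = mi_vals
    return est


def run_study(
    scenarios: Sequence[Scenario] | None = None,
    designs: Sequence[TrialDesign] | None = None,
    n_replicates: int = 100_000,
    seed: int = 0,
    estimators: Sequence[str] = FAST_ESTIMATORS,
    config: ShrinkageConfig | None = None,
    mi_tol: float = 0.001,
) -> list[SimulationResult]:
    """Simulate the operating characteristics over scenarios x designs.

    Stage-1 means are drawn at the exact sample-mean level; every replicate
    that continues gets stage-2 means under the design's enrichment plan.
    Conditional bias and MSE are tabulated per (estimator, selected s) cell;
    cells with no hits are simply absent.  The quadrature-based ``si``/``mi``
    estimators run one replicate at a time and should only be requested at
    small replicate counts.
    """
    scenarios = tuple(scenarios if scenarios is not None else TABLE_SCENARIOS)
    designs = tuple(designs if designs is not None else (study_design(200),))
    results = []
    for design in designs:
        for sc_idx, sc in enumerate(scenarios):
            rng = np.random.default_rng([seed, sc_idx, int(sum(design.n1))])
            x1 = simulate_stage1_means(sc.delta, design, rng, n_replicates)
            dec = vector_select(x1, design)
            freqs = {"stop": float(np.mean(dec == 0))}
            for s in range(1, design.K + 1):
                key = "F" if s == design.K else f"S_{s}"
                freqs[key] = float(np.mean(dec == s))
            cells = []
            theta = theta_from_delta(sc.delta, design).theta_arr
            for s in range(1, design.K + 1):
                rows = np.nonzero(dec == s)[0]
                if rows.size == 0:
                    continue
                rng_s = np.random.default_rng([seed, sc_idx, s, 7919])
                x2 = rng_s.normal(
                    np.asarray(sc.delta)[:s],
                    np.sqrt(design.tau2_2(s)),
                    size=(rows.size, s),
                )
                est = _estimates_for_group(
                    x1[rows], x2, s, design, estimators, config, mi_tol, seed
                )
                m_tot = design.m1[s - 1] + design.m2(s)[s - 1]
                approx_se = float(np.sqrt(4 * design.sigma**2 / m_tot))
                for name, vals in est.items():
                    err = vals - theta[s - 1]
                    cells.append(
                        ConditionalCell(
                            estimator=name,
                            s=s,
                            n_hits=rows.size,
                            bias=float(err.mean()),
                            mse=float((err**2).mean()),
                            bias_mc_se=float(err.std(ddof=1) / np.sqrt(rows.size)),
                            approx_se=approx_se,
                        )
                    )
            results.append(
                SimulationResult(
                    scenario=sc,
                    design=design,
                    n_replicates=n_replicates,
                    seed=seed,
                    frequencies=freqs,
                    cells=tuple(cells),
                )
            )
    return results
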