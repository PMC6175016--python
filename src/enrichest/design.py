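"""Trial design data model and partition/subpopulation bookkeeping.

A two-stage adaptive threshold enrichment trial partitions the full
population ``F`` into ``K`` biomarker-defined partitions with cumulative
prevalences ``0 < p_1 < ... < p_K = 1``.  Candidate subpopulations are the
nested unions ``S_i`` = partitions ``1..i`` (so ``S_K = F``).  Outcomes are
normal with known standard deviation ``sigma``; within each partition,
patients are split between experimental and control arms, so the sample
mean difference in partition ``i`` at stage 1 has variance
``tau2_1i = 4 sigma^2 / n_1i`` under 1:1 allocation (the general form
``sigma^2 (1/n_A + 1/n_B)`` is used for other allocation ratios).

Partition effects ``delta_i`` and subpopulation effects ``theta_i`` are
linked by the prevalence-weighted linear map

    theta_i = sum_{i' <= i} (p_i' - p_{i'-1}) delta_i' / p_i,

which also links the observed sample means (``ybar`` from ``xbar``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TrialDesign",
    "Stage2Plan",
    "StageSummary",
    "EffectVector",
    "build_design",
    "subpop_from_partitions",
    "theta_from_delta",
    "delta_from_theta",
]


class DesignError(ValueError):
    """Raised when trial design inputs violate an invariant."""


@dataclass(frozen=True)
class Stage2Plan:
    """Stage-2 allocation plan.

    ``kind="fixed"``: per-partition stage-2 totals ``n2`` are prespecified
    for every partition; when ``S_s`` is selected, partitions ``1..s`` use
    ``n2[0..s-1]`` (the "no enrichment" convention).

    ``kind="equal_split"``: a fixed stage-2 total is split equally among the
    selected partitions and arms (the enrichment convention); the total must
    be divisible by ``2 s`` for every possible ``s``.
    """

    kind: Literal["fixed", "equal_split"]
    n2: tuple[int, ...] | None = None
    total: int | None = None

    def sizes_for(self, s: int, K: int) -> np.ndarray:
        """Per-partition stage-2 totals for partitions 1..s."""
        if self.kind == "fixed":
            assert self.n2 is not None
            if len(self.n2) < s:
                raise DesignError(
                    f"stage-2 plan covers {len(self.n2)} partitions, "
                    f"selection requires {s}"
                )
            return np.asarray(self.n2[:s], dtype=float)
        assert self.total is not None
        if self.total % (2 * s) != 0:
            raise DesignError(
                f"stage-2 total {self.total} not divisible by 2*s = {2 * s}"
            )
        return np.full(s, self.total / s)


@dataclass(frozen=True)
class TrialDesign:
    """Immutable description of a two-stage threshold enrichment design."""

    prevalences: tuple[float, ...]
    sigma: float
    futility_b: float
    n1: tuple[int, ...]
    stage2: Stage2Plan
    thresholds: tuple[float, ...] | None = None
    allocation_ratio: float = 1.0
    higher_biomarker_smaller_effect: bool = True

    @property
    def K(self) -> int:
        return len(self.prevalences)

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.prevalences, dtype=float)

    @property
    def partition_weights(self) -> np.ndarray:
        """Per-partition prevalences ``p_i - p_{i-1}`` (``p_0 = 0``)."""
        return np.diff(np.concatenate(([0.0], self.p)))

    def _mean_diff_var(self, n: np.ndarray) -> np.ndarray:
        """Variance of a mean difference from ``n`` patients per partition.

        With allocation ratio r (experimental:control), n splits as
        n_E = n r/(1+r), n_C = n/(1+r); variance is sigma^2 (1/n_E + 1/n_C),
        which reduces to 4 sigma^2 / n at 1:1.
        """
        r = self.allocation_ratio
        n = np.asarray(n, dtype=float)
        n_e = n * r / (1.0 + r)
        n_c = n / (1.0 + r)
        return self.sigma**2 * (1.0 / n_e + 1.0 / n_c)

    @property
    def m1(self) -> np.ndarray:
        """Cumulative stage-1 subpopulation sizes ``m_1i``."""
        return np.cumsum(np.asarray(self.n1, dtype=float))

    @property
    def tau2_1(self) -> np.ndarray:
        """Stage-1 partition mean-difference variances ``tau^2_1i``."""
        return self._mean_diff_var(np.asarray(self.n1, dtype=float))

    @property
    def sigma2_1(self) -> np.ndarray:
        """Stage-1 subpopulation mean-difference variances ``sigma^2_1i``.

        The subpopulation mean is the prevalence-weighted combination of
        partition means, so its variance is ``sum_{i'<=i} w_i'^2 tau^2_1i' /
        p_i^2``.  When per-partition sample sizes are proportional to the
        partition prevalences (as in equal-prevalence designs with equal
        sizes) this reduces to the familiar pooled form ``4 sigma^2 / m_1i``.
        """
        w = self.partition_weights
        return np.cumsum(w**2 * self.tau2_1) / self.p**2

    def stage2_sizes(self, s: int) -> np.ndarray:
        """Stage-2 per-partition totals ``n_2i`` for partitions 1..s."""
        return self.stage2.sizes_for(s, self.K)

    def tau2_2(self, s: int) -> np.ndarray:
        return self._mean_diff_var(self.stage2_sizes(s))

    def m2(self, s: int) -> np.ndarray:
        return np.cumsum(self.stage2_sizes(s))

    def sigma2_2(self, s: int) -> np.ndarray:
        w = self.partition_weights[:s]
        return np.cumsum(w**2 * self.tau2_2(s)) / self.p[:s] ** 2

    def t_fraction(self, s: int) -> float:
        """Stage-1 information fraction ``t_s = m_1s / (m_1s + m_2s)``."""
        m1s = self.m1[s - 1]
        m2s = self.m2(s)[s - 1]
        return float(m1s / (m1s + m2s))

    def partition_t(self, s: int) -> np.ndarray:
        """Per-partition stage-1 fractions ``n_1i / (n_1i + n_2i)``, i<=s."""
        n1 = np.asarray(self.n1, dtype=float)[:s]
        n2 = self.stage2_sizes(s)
        return n1 / (n1 + n2)


def build_design(
    prevalences: Sequence[float],
    sigma: float,
    futility_b: float,
    n1: Sequence[int],
    n2_plan: Sequence[int] | int | Stage2Plan,
    *,
    thresholds: Sequence[float] | None = None,
    allocation_ratio: float = 1.0,
    higher_biomarker_smaller_effect: bool = True,
) -> TrialDesign:
    """Validate inputs and return an immutable :class:`TrialDesign`.

    ``n2_plan`` may be an explicit per-partition size sequence (fixed,
    no-enrichment plan), an integer stage-2 total (equal-split enrichment
    plan), or a prepared :class:`Stage2Plan`.
    """
    p = np.asarray(prevalences, dtype=float)
    K = p.size
    if K < 2:
        raise DesignError("prevalences: need at least 2 partitions")
    if np.any(np.diff(p) <= 0) or p[0] <= 0:
        raise DesignError("prevalences: must be strictly increasing and positive")
    if not np.isclose(p[-1], 1.0):
        raise DesignError("prevalences: p_K must equal 1")
    if sigma <= 0:
        raise DesignError("sigma: must be positive")
    n1_arr = np.asarray(n1)
    if n1_arr.size != K:
        raise DesignError(f"n1: expected {K} sizes, got {n1_arr.size}")
    if np.any(n1_arr <= 0) or not np.all(n1_arr == n1_arr.astype(int)):
        raise DesignError("n1: sample sizes must be positive integers")
    if allocation_ratio <= 0:
        raise DesignError("allocation_ratio: must be positive")

    if isinstance(n2_plan, Stage2Plan):
        plan = n2_plan
    elif isinstance(n2_plan, (int, np.integer)):
        if n2_plan <= 0:
            raise DesignError("n2_plan: stage-2 total must be positive")
        plan = Stage2Plan(kind="equal_split", total=int(n2_plan))
    else:
        n2_arr = np.asarray(n2_plan)
        if np.any(n2_arr <= 0) or not np.all(n2_arr == n2_arr.astype(int)):
            raise DesignError("n2_plan: sample sizes must be positive integers")
        plan = Stage2Plan(kind="fixed", n2=tuple(int(x) for x in n2_arr))

    if thresholds is not None and len(thresholds) != K:
        raise DesignError(f"thresholds: expected {K} values")

    return TrialDesign(
        prevalences=tuple(float(x) for x in p),
        sigma=float(sigma),
        futility_b=float(futility_b),
        n1=tuple(int(x) for x in n1_arr),
        stage2=plan,
        thresholds=None if thresholds is None else tuple(map(float, thresholds)),
        allocation_ratio=float(allocation_ratio),
        higher_biomarker_smaller_effect=bool(higher_biomarker_smaller_effect),
    )


@dataclass(frozen=True)
class StageSummary:
    """Per-partition and derived per-subpopulation summaries for one stage.

    For stage 2 only the selected partitions ``1..s`` are present.
    """

    stage: int
    partition_means: tuple[float, ...]  # xbar
    partition_vars: tuple[float, ...]  # tau^2
    subpop_means: tuple[float, ...]  # ybar
    subpop_vars: tuple[float, ...]  # sigma^2
    n: tuple[float, ...]
    m: tuple[float, ...]

    @property
    def xbar(self) -> np.ndarray:
        return np.asarray(self.partition_means)

    @property
    def ybar(self) -> np.ndarray:
        return np.asarray(self.subpop_means)


def subpop_from_partitions(
    partition_means: Sequence[float], design: TrialDesign, stage: int, *, s: int | None = None
) -> StageSummary:
    """Derive subpopulation summaries from partition sample mean differences.

    ``ybar_i`` is the prevalence-weighted average of ``xbar_1..xbar_i``.  For
    stage 2, means must cover exactly the selected partitions ``1..s``.
    """
    xbar = np.asarray(partition_means, dtype=float)
    if stage not in (1, 2):
        raise DesignError("stage must be 1 or 2")
    if stage == 1:
        if xbar.size != design.K:
            raise DesignError(
                f"stage 1 requires {design.K} partition means, got {xbar.size}"
            )
        n = np.asarray(design.n1, dtype=float)
        tau2 = design.tau2_1
        m = design.m1
        sigma2 = design.sigma2_1
        w = design.partition_weights
        p = design.p
    else:
        s_eff = xbar.size if s is None else s
        if xbar.size != s_eff:
            raise DesignError(f"stage 2 requires {s_eff} partition means, got {xbar.size}")
        n = design.stage2_sizes(s_eff)
        tau2 = design.tau2_2(s_eff)
        m = design.m2(s_eff)
        sigma2 = design.sigma2_2(s_eff)
        w = design.partition_weights[:s_eff]
        p = design.p[:s_eff]
    ybar = np.cumsum(w * xbar) / p
    return StageSummary(
        stage=stage,
        partition_means=tuple(xbar),
        partition_vars=tuple(tau2),
        subpop_means=tuple(ybar),
        subpop_vars=tuple(sigma2),
        n=tuple(n),
        m=tuple(m),
    )


@dataclass(frozen=True)
class EffectVector:
    """True or plug-in partition effects with induced subpopulation effects."""

    delta: tuple[float, ...]
    theta: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if not self.theta:
            object.__setattr__(self, "theta", self.delta)

    @property
    def delta_arr(self) -> np.ndarray:
        return np.asarray(self.delta)

    @property
    def theta_arr(self) -> np.ndarray:
        return np.asarray(self.theta)


def theta_from_delta(delta: Sequence[float], design: TrialDesign) -> EffectVector:
    """Map partition effects to subpopulation effects (prevalence weighting)."""
    d = np.asarray(delta, dtype=float)
    if d.size != design.K:
        raise DesignError(f"delta: expected {design.K} effects, got {d.size}")
    theta = np.cumsum(design.partition_weights * d) / design.p
    return EffectVector(delta=tuple(d), theta=tuple(theta))


def delta_from_theta(theta: Sequence[float], design: TrialDesign) -> EffectVector:
    """Inverse map: recover partition effects from subpopulation effects."""
    th = np.asarray(theta, dtype=float)
    if th.size != design.K:
        raise DesignError(f"theta: expected {design.K} effects, got {th.size}")
    z = design.p * th  # cumulative weighted sums
    w = design.partition_weights
    d = np.diff(np.concatenate(([0.0], z))) / w
    return EffectVector(delta=tuple(d), theta=tuple(th))
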