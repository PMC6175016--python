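"""Futility-based subpopulation selection rule and its truncation limits.

The largest subpopulation whose observed stage-1 mean difference is at least
the futility boundary ``b`` continues to stage 2; if none reaches ``b`` the
trial stops.  Selecting ``S_s`` with ``s < K`` is equivalent to the event
``b <= ybar_1s < u`` on the subpopulation scale, and to the box
``v_i <= xbar_1i < w_i`` for every ``i <= s`` on the partition scale, where
``u``, ``v_i`` and ``w_i`` are functions of the non-selected partition means.
These limits define the conditioning event used by every corrected estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StageSummary, TrialDesign

__all__ = ["SelectionOutcome", "select", "upper_limit_u", "partition_limits", "STOP"]

STOP = 0  # decision sentinel: trial stops at stage 1


@dataclass(frozen=True)
class SelectionOutcome:
    """Selection decision with the truncation limits of the conditioning event."""

    decision: int  # STOP (0) or selected index s in 1..K
    u: float
    v: tuple[float, ...]  # lower limits for xbar_1i, i <= s
    w: tuple[float, ...]  # upper limits for xbar_1i, i <= s
    stage1: StageSummary

    @property
    def stopped(self) -> bool:
        return self.decision == STOP

    @property
    def s(self) -> int:
        if self.stopped:
            raise ValueError("trial stopped at stage 1: no selected subpopulation")
        return self.decision


def upper_limit_u(partition_means, s: int, design: TrialDesign) -> float:
    """Upper truncation limit ``u`` for ``ybar_1s`` given selection of ``S_s``.

    u = min over j in {s+1..K} of
        [ p_j b - sum_{i=s+1}^{j} (p_i - p_{i-1}) xbar_1i ] / p_s.

    For ``s = K`` there is no upper limit and ``+inf`` is returned.
    """
    if s == design.K:
        return np.inf
    xbar = np.asarray(partition_means, dtype=float)
    p = design.p
    w = design.partition_weights
    b = design.futility_b
    tail_cums = np.cumsum(w[s:] * xbar[s:])  # partial sums over i = s+1..j
    candidates = (p[s:] * b - tail_cums) / p[s - 1]
    return float(np.min(candidates))


def partition_limits(
    partition_means, s: int, design: TrialDesign, i_prime: int
) -> tuple[float, float]:
    """Truncation limits ``(v_i', w_i')`` for ``xbar_1i'`` given selection of ``S_s``.

    v_i' = [ p_s b - sum_{i<=s, i != i'} (p_i - p_{i-1}) xbar_1i ] / (p_i' - p_{i'-1})
    w_i' = min over j in {s+1..K} of
           [ p_j b - sum_{i<=j, i != i'} (p_i - p_{i-1}) xbar_1i ] / (p_i' - p_{i'-1});
    ``w_i' = +inf`` when ``s = K``.
    """
    if not 1 <= i_prime <= s:
        raise ValueError(f"partition index i'={i_prime} outside 1..s={s}")
    xbar = np.asarray(partition_means, dtype=float)
    p = design.p
    wts = design.partition_weights
    b = design.futility_b
    wi = wts[i_prime - 1]
    head = wts[:s] * xbar[:s]
    head_sum_excl = head.sum() - head[i_prime - 1]
    v = (p[s - 1] * b - head_sum_excl) / wi
    if s == design.K:
        return float(v), np.inf
    tail_cums = np.cumsum(wts[s:] * xbar[s:])
    candidates = (p[s:] * b - (head_sum_excl + tail_cums)) / wi
    w = float(np.min(candidates))
    return float(v), w


def select(stage1: StageSummary, design: TrialDesign) -> SelectionOutcome:
    """Apply the futility selection rule to a complete stage-1 summary.

    Decision is the largest ``i`` with ``ybar_1i >= b`` (boundary equality
    continues), or STOP if every subpopulation mean is below ``b``.
    """
    ybar = stage1.ybar
    if ybar.size != design.K:
        raise ValueError(f"stage-1 summary has {ybar.size} subpopulations, expected {design.K}")
    b = design.futility_b
    above = np.nonzero(ybar >= b)[0]
    if above.size == 0:
        return SelectionOutcome(decision=STOP, u=np.nan, v=(), w=(), stage1=stage1)
    s = int(above[-1]) + 1
    u = upper_limit_u(stage1.xbar, s, design)
    vw = [partition_limits(stage1.xbar, s, design, i) for i in range(1, s + 1)]
    return SelectionOutcome(
        decision=s,
        u=u,
        v=tuple(x[0] for x in vw),
        w=tuple(x[1] for x in vw),
        stage1=stage1,
    )
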