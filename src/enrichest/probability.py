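"""Selection probabilities, truncated expectations and naive-estimator bias.

Selection events are rectangles in the cumulative statistic
``Z_j = sum_{i<=j} (p_i - p_{i-1}) xbar_1i = p_j ybar_1j``:

* ``S_s`` selected (s < K):  ``Z_s >= p_s b`` and ``Z_j < p_j b`` for j > s;
* ``F = S_K`` selected:      ``Z_K >= b``;
* stop at stage 1:           ``Z_j < p_j b`` for all j.

Because the increments ``D_j = Z_j - Z_{j-1}`` are independent normals, the
``Z`` chain is Markov and every region probability (and truncated moment)
reduces to a nested sequence of one-dimensional integrals.  These are
evaluated by a Gauss-Legendre transfer-matrix recursion: each level's
integrand is represented on quadrature nodes and pushed through the normal
transition kernel of the next increment.  The conditional bias of the naive
estimator follows as

    Bias(theta_hat_{s,N}) = t_s * ( E[Z_s 1[S_s]] / (p_s Prob(S_s)) - theta_s ),

which vanishes when the truncation event has probability one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import gauss_legendre_nodes, ncdf
from .design import EffectVector, TrialDesign
from .selection import STOP

__all__ = [
    "ZLaw",
    "DecisionProbabilities",
    "z_law",
    "z_from_xbar",
    "decision_probability",
    "decision_probabilities",
    "prob_full_closed_form",
    "truncated_weighted_mean",
    "naive_bias",
    "conditional_partition_means",
    "partition_bias",
]

PROB_FLOOR = 1e-12
_SQRT2PI = np.sqrt(2.0 * np.pi)


class IntegrationError(RuntimeError):
    """Raised when the region quadrature cannot produce a reliable value."""


@dataclass(frozen=True)
class ZLaw:
    """Gaussian law of the cumulative vector Z under given effects.

    Follows the conventional scaling in which the first component is the
    raw first-partition mean, ``Z_1 = Xbar_11`` (identical to ``Ybar_11``),
    while ``Z_j = sum_{i<=j} (p_i - p_{i-1}) Xbar_1i = p_j Ybar_1j`` for
    ``j >= 2``.  Internally all computations use the uniform scaling
    ``p_j Ybar_1j`` for every j, which only rescales the first coordinate
    and leaves every region probability unchanged.
    """

    mean: np.ndarray
    cov: np.ndarray


def _increments(effects: EffectVector, design: TrialDesign):
    """Means/variances of the independent increments of p_j Ybar_1j.

    Returns (inc_mean, inc_var, cum_mean, cum_var) for the uniformly scaled
    chain Z_j = sum_{i<=j} w_i Xbar_1i.
    """
    w = design.partition_weights
    mu = w * effects.delta_arr
    s2 = w**2 * design.tau2_1
    return mu, s2, np.cumsum(mu), np.cumsum(s2)


def z_law(effects: EffectVector, design: TrialDesign) -> ZLaw:
    """Mean vector and covariance of Z = (Z_1, ..., Z_K).

    Z is a linear transform of the independent partition means, hence
    multivariate normal; with the first coordinate unscaled
    (``Z_1 = Xbar_11``) and ``Z_j = sum_{i<=j} w_i Xbar_1i`` otherwise,
    ``Cov(Z_j, Z_k) = sum_{i <= min(j,k)} w_i^2 tau^2_1i`` up to the
    first-row/column rescaling by ``1 / w_1``.
    """
    _, _, cum_mean, cum_var = _increments(effects, design)
    idx = np.arange(design.K)
    cov = cum_var[np.minimum.outer(idx, idx)]
    mean = cum_mean.copy()
    w1 = design.partition_weights[0]
    mean[0] /= w1
    cov[0, :] /= w1
    cov[:, 0] /= w1
    return ZLaw(mean=mean, cov=cov)


def z_from_xbar(partition_means, design: TrialDesign) -> np.ndarray:
    """Realized z vector from observed stage-1 partition means."""
    x = np.asarray(partition_means, dtype=float)
    z = np.cumsum(design.partition_weights * x)
    z[0] = x[0]
    return z


def _region_moments(
    effects: EffectVector,
    design: TrialDesign,
    decision: int,
    *,
    n_nodes: int = 200,
    window: float = 8.5,
    want_increments: bool = False,
):
    """Probability and truncated moments of the Z region for one decision.

    Returns ``(prob, ez0, einc)`` where ``ez0 = E[Z_{j0} 1[region]]`` with
    ``j0 = s`` (or 1 for STOP) and ``einc[j] = E[D_j 1[region]]`` for the
    constrained levels ``j > j0`` (only if ``want_increments``).
    """
    K = design.K
    mu, s2, m, V = _increments(effects, design)
    b = design.futility_b

    # Degenerate boundaries: no truncation at all (moments are closed-form).
    if b == -np.inf:
        return (1.0, float(m[K - 1]), {}) if decision == K else (0.0, 0.0, {})
    if b == np.inf:
        return (1.0, float(m[0]), {}) if decision == STOP else (0.0, 0.0, {})

    a = design.p * b  # thresholds p_j * b
    if decision == STOP:
        j0 = 1
        lo0, hi0 = -np.inf, a[0]
    else:
        j0 = decision
        lo0, hi0 = a[j0 - 1], np.inf

    sd0 = np.sqrt(V[j0 - 1])
    lo = max(lo0, m[j0 - 1] - window * sd0)
    hi = min(hi0, m[j0 - 1] + window * sd0)
    if hi <= lo:
        return 0.0, 0.0, {}

    nodes, wq = gauss_legendre_nodes(lo, hi, n_nodes)
    flow = np.exp(-0.5 * ((nodes - m[j0 - 1]) / sd0) ** 2) / (sd0 * _SQRT2PI)
    payloads: dict[object, np.ndarray] = {"ez0": nodes * flow}

    for j in range(j0 + 1, K + 1):
        sdj = np.sqrt(s2[j - 1])
        sdV = np.sqrt(V[j - 1])
        lo_j = m[j - 1] - window * sdV
        hi_j = min(a[j - 1], m[j - 1] + window * sdV)
        if hi_j <= lo_j:
            return 0.0, 0.0, {}
        # resolve the transition kernel: when this increment's sd is much
        # smaller than the window of Z_j, a fixed grid under-integrates the
        # narrow Gaussian, so scale the node count to ~5 nodes per kernel sd
        n_j = int(min(max(n_nodes, np.ceil(5.0 * (hi_j - lo_j) / sdj)), 3000))
        t, wt = gauss_legendre_nodes(lo_j, hi_j, n_j)
        kern = np.exp(-0.5 * ((t[None, :] - nodes[:, None] - mu[j - 1]) / sdj) ** 2) / (
            sdj * _SQRT2PI
        )
        fw = flow * wq
        new_flow = fw @ kern
        new_payloads = {name: (vec * wq) @ kern for name, vec in payloads.items()}
        if want_increments:
            # E[D_j 1]: weight the transition by the increment t - z
            new_payloads[("inc", j)] = new_flow * t - (fw * nodes) @ kern
        payloads = new_payloads
        flow = new_flow
        nodes, wq = t, wt

    prob = float(flow @ wq)
    ez0 = float(payloads["ez0"] @ wq)
    einc = {
        name[1]: float(vec @ wq)
        for name, vec in payloads.items()
        if isinstance(name, tuple) and name[0] == "inc"
    }
    return prob, ez0, einc


def decision_probability(
    effects: EffectVector,
    design: TrialDesign,
    decision: int,
    *,
    n_nodes: int = 200,
    window: float = 8.5,
) -> float:
    """Probability of a decision (STOP = 0 or selected index 1..K).

    Computed by the nested-quadrature recursion over the Z region; for the
    full population the result agrees with the closed form
    ``Phi((theta_K - b) / sigma_1K)`` (see :func:`prob_full_closed_form`).
    """
    if decision != STOP and not 1 <= decision <= design.K:
        raise ValueError(f"decision must be 0 (stop) or 1..{design.K}")
    prob, _, _ = _region_moments(effects, design, decision, n_nodes=n_nodes, window=window)
    if not np.isfinite(prob) or prob < -1e-9 or prob > 1 + 1e-9:
        raise IntegrationError(f"quadrature returned invalid probability {prob}")
    return float(min(max(prob, 0.0), 1.0))


@dataclass(frozen=True)
class DecisionProbabilities:
    """Probability of each decision for a given effect vector and design."""

    stop: float
    select: tuple[float, ...]  # index i-1 -> Prob(S_i)

    @property
    def total(self) -> float:
        return self.stop + sum(self.select)

    def as_dict(self) -> dict[str, float]:
        d = {f"S_{i+1}": p for i, p in enumerate(self.select)}
        d["stop"] = self.stop
        return d


def decision_probabilities(
    effects: EffectVector, design: TrialDesign, *, n_nodes: int = 200, window: float = 8.5
) -> DecisionProbabilities:
    """All decision probabilities; they sum to one within quadrature tolerance."""
    sel = tuple(
        decision_probability(effects, design, s, n_nodes=n_nodes, window=window)
        for s in range(1, design.K + 1)
    )
    stop = decision_probability(effects, design, STOP, n_nodes=n_nodes, window=window)
    return DecisionProbabilities(stop=stop, select=sel)


def prob_full_closed_form(effects: EffectVector, design: TrialDesign) -> float:
    """Closed form Prob(F selected) = Phi((theta_K - b) / sigma_1K)."""
    theta_K = effects.theta_arr[-1]
    sd = np.sqrt(design.sigma2_1[-1])
    return float(ncdf((theta_K - design.futility_b) / sd))


def truncated_weighted_mean(
    effects: EffectVector, design: TrialDesign, s: int, *, n_nodes: int = 200, window: float = 8.5
) -> float:
    """E[Z_s 1[S_s]] = sum_{i<=s} (p_i - p_{i-1}) E[Xbar_1i 1[S_s]]."""
    _, ez, _ = _region_moments(effects, design, s, n_nodes=n_nodes, window=window)
    return float(ez)


def naive_bias(
    effects: EffectVector,
    design: TrialDesign,
    s: int,
    t_s: float,
    *,
    n_nodes: int = 200,
    window: float = 8.5,
) -> float:
    """Conditional bias of the naive estimator given selection of S_s.

    ``t_s * ( E[Z_s 1[S_s]] / (p_s Prob(S_s)) - theta_s )``; the stage-2
    component is conditionally unbiased so only the stage-1 fraction ``t_s``
    carries selection bias, and the bias vanishes when truncation does.
    """
    prob, ez, _ = _region_moments(effects, design, s, n_nodes=n_nodes, window=window)
    if prob < PROB_FLOOR:
        raise IntegrationError(
            f"selection event S_{s} has negligible probability ({prob:.3e})"
        )
    theta_s = effects.theta_arr[s - 1]
    return float(t_s * (ez / (design.p[s - 1] * prob) - theta_s))


def conditional_partition_means(
    effects: EffectVector, design: TrialDesign, s: int, *, n_nodes: int = 200, window: float = 8.5
) -> np.ndarray:
    """E[Xbar_1i | S_s] for every partition i = 1..K.

    For i <= s the event constrains Xbar_1i only through Z_s, so the
    conditional mean follows from the joint normality of (D_i, Z_s); for
    i > s the increment expectations come from the region quadrature.
    """
    prob, ez, einc = _region_moments(
        effects, design, s, n_nodes=n_nodes, window=window, want_increments=True
    )
    if prob < PROB_FLOOR:
        raise IntegrationError(
            f"selection event S_{s} has negligible probability ({prob:.3e})"
        )
    _, _, cum_mean, cum_var = _increments(effects, design)
    w = design.partition_weights
    V_s = cum_var[s - 1]
    m_s = cum_mean[s - 1]
    shift = ez / prob - m_s
    out = np.array(effects.delta_arr, dtype=float, copy=True)
    out[:s] += w[:s] * design.tau2_1[:s] * shift / V_s
    for j in range(s + 1, design.K + 1):
        out[j - 1] = einc[j] / (w[j - 1] * prob)
    return out


def partition_bias(
    effects: EffectVector,
    design: TrialDesign,
    s: int,
    *,
    n_nodes: int = 200,
    window: float = 8.5,
) -> np.ndarray:
    """Conditional bias of the per-partition naive estimators given S_s.

    For selected partitions (i <= s) the naive estimator mixes stage-1 and
    stage-2 data with stage-1 fraction t_i, so bias_i = t_i (E[Xbar_1i|S_s]
    - delta_i); dropped partitions (i > s) have stage-1-only estimates.
    """
    cond = conditional_partition_means(effects, design, s, n_nodes=n_nodes, window=window)
    bias = cond - effects.delta_arr
    t_i = design.partition_t(s)
    bias[:s] *= t_i
    return bias
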