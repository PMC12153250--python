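"""Consistency-constrained rejection rules and the closed-testing layer.

The intersection hypothesis H0s ∩ H0o is rejected when either path holds
(all inequalities strict):

subgroup path (a)
    ``T_s > t_{alpha_s}``  and  ``T_c > b sqrt((1-p)/p) T_s``
    (equivalently ``theta_hat_c > b theta_hat_s``);

overall path (b)
    ``sqrt(p) T_s + sqrt(1-p) T_c > t_{alpha_o}``  and the two retention
    conditions, the T-scale form of ``theta_hat_s > k theta_hat_o`` and
    ``theta_hat_c > k theta_hat_o``:

    ``k T_c < ((1-k) sqrt(p/(1-p)) + sqrt((1-p)/p)) T_s``
    ``(sqrt(p/(1-p)) + (1-k) sqrt((1-p)/p)) T_c > k T_s``.

The T-scale and effect-scale forms are algebraically identical for every
sign of ``k`` (only positive factors are multiplied through), which
:func:`effect_scale_decision` exposes as a cross-check.

Rejection of the intersection opens the second closed-testing layer: each
individual hypothesis is then retested at the full family level, so at least
one elementary claim always accompanies an intersection rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .design import DesignSpec
from .sampling import SufficientStats, TestStats, compute_test_statistics

__all__ = [
    "DecisionOutcome",
    "condition_a",
    "condition_b",
    "intersection_test",
    "effect_scale_decision",
    "closed_test",
]


@dataclass(frozen=True)
class DecisionOutcome:
    """Intersection-test result plus per-hypothesis claims.

    Flags are booleans or boolean arrays (batched trials).  Invariants:
    ``intersection_rejected == via_condition_a | via_condition_b`` and,
    for the consistency procedure, ``intersection_rejected`` holds iff at
    least one of ``claim_s``/``claim_o`` holds.
    """

    intersection_rejected: bool | np.ndarray
    via_condition_a: bool | np.ndarray
    via_condition_b: bool | np.ndarray
    claim_s: bool | np.ndarray
    claim_o: bool | np.ndarray
    critical_values: Mapping[str, float]

    @property
    def any_claim(self) -> bool | np.ndarray:
        return self.claim_s | self.claim_o

    def replace(self, **kw) -> "DecisionOutcome":
        return replace(self, **kw)


def _ratio_coefficients(design: DesignSpec) -> tuple[float, float]:
    """Coefficients of the two k-retention half-planes on the T scale.

    Returns ``(c_s, c_c)`` with the conditions ``k T_c < c_s T_s`` and
    ``c_c T_c > k T_s``; ``c_s = (1 - k p)/sqrt(p(1-p))``,
    ``c_c = (1 - k(1-p))/sqrt(p(1-p))``.
    """
    p = design.p
    k = design.require_k()
    root = np.sqrt(p * (1.0 - p))
    return (1.0 - k * p) / root, (1.0 - k * (1.0 - p)) / root


def condition_a(T: TestStats, design: DesignSpec) -> bool | np.ndarray:
    """Subgroup path: significant in S and the complement retains fraction b."""
    return (T.t_s > design.t_alpha_s) & (T.t_c > design.consistency_slope * T.t_s)


def condition_b(T: TestStats, design: DesignSpec) -> bool | np.ndarray:
    """Overall path: significant overall and each subgroup retains fraction k."""
    p = design.p
    k = design.require_k()
    c_s, c_c = _ratio_coefficients(design)
    combined = np.sqrt(p) * T.t_s + np.sqrt(1.0 - p) * T.t_c
    return (combined > design.t_alpha_o) & (k * T.t_c < c_s * T.t_s) & (c_c * T.t_c > k * T.t_s)


def intersection_test(T: TestStats, design: DesignSpec) -> bool | np.ndarray:
    """Reject H0s ∩ H0o iff either path fires; this also defines study success."""
    return condition_a(T, design) | condition_b(T, design)


def effect_scale_decision(
    stats: SufficientStats, design: DesignSpec
) -> tuple[bool | np.ndarray, bool | np.ndarray]:
    """Evaluate both paths directly on the effect scale.

    Uses ``theta_hat_c > b theta_hat_s`` and ``theta_hat_{s,c} > k theta_hat_o``
    verbatim (significance parts still via the t statistics).  Must agree with
    ``(condition_a, condition_b)`` on every input; kept as the module's central
    equivalence check rather than the production path to avoid ratios with
    ``theta_hat_o`` near zero.
    """
    T = compute_test_statistics(stats, design)
    p = design.p
    k = design.require_k()
    th_s = np.asarray(stats.theta_hat_s)
    th_c = np.asarray(stats.theta_hat_c)
    th_o = p * th_s + (1.0 - p) * th_c
    path_a = (T.t_s > design.t_alpha_s) & (th_c > design.b * th_s)
    path_b = (T.t_o > design.t_alpha_o) & (th_s > k * th_o) & (th_c > k * th_o)
    return path_a, path_b


def closed_test(
    T: TestStats,
    design: DesignSpec,
    family_alpha: float | None = None,
    constrained: bool = False,
) -> DecisionOutcome:
    """Intersection test plus second-layer claims for H0s and H0o.

    If the intersection is rejected each hypothesis is retested at the full
    family level ``family_alpha`` (default ``max(alpha_s, alpha_o)``, the
    family-wise target in all the designs considered here).  A population can
    therefore claim significance even when its own intersection path failed —
    e.g. an overall p-value of 0.023 under ``alpha_o = 0.0125`` fails the
    intersection's overall path, but once the subgroup path rejects the
    intersection, H0o is retested at 0.025 and passes.

    ``constrained=True`` carries the consistency restrictions into the second
    layer as well: the subgroup claim additionally needs
    ``T_c > b sqrt((1-p)/p) T_s`` and the overall claim the two k-retention
    conditions.  This does not change the intersection decision, only which
    elementary claims are made.
    """
    if family_alpha is None:
        family_alpha = max(design.alpha_s, design.alpha_o)
    if not 0.0 < family_alpha <= 0.5:
        raise ValueError(f"family_alpha must lie in (0, 0.5], got {family_alpha}")
    via_a = condition_a(T, design)
    via_b = condition_b(T, design)
    rejected = via_a | via_b
    q_fam = design.critical_value(family_alpha)
    claim_s = rejected & (T.t_s > q_fam)
    claim_o = rejected & (T.t_o > q_fam)
    if constrained:
        c_s, c_c = _ratio_coefficients(design)
        k = design.require_k()
        claim_s = claim_s & (T.t_c > design.consistency_slope * T.t_s)
        claim_o = claim_o & (k * T.t_c < c_s * T.t_s) & (c_c * T.t_c > k * T.t_s)
    return DecisionOutcome(
        intersection_rejected=rejected,
        via_condition_a=via_a,
        via_condition_b=via_b,
        claim_s=claim_s,
        claim_o=claim_o,
        critical_values={
            "t_alpha_s": design.t_alpha_s,
            "t_alpha_o": design.t_alpha_o,
            "t_family": q_fam,
        },
    )
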