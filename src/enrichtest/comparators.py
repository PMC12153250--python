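"""Benchmark multiplicity procedures: Bonferroni, Dunnett-style, fixed sequence.

All comparators act on the same (T_s, T_o) pair as the consistency method and
return :class:`~enrichtest.rules.DecisionOutcome`, so power simulations can
swap procedures freely.

The Dunnett-style test exploits the positive correlation
``corr(T_s, T_o) = sqrt(p)`` implied by ``T_o = sqrt(p) T_s + sqrt(1-p) T_c``
(T_s and T_c share only the pooled variance estimate, so they are
conditionally independent given sigma_hat).  Its equicoordinate critical
value ``c`` solves ``P(T_s <= c, T_o <= c) = 1 - alpha`` under the bivariate
Student-t with the design's degrees of freedom, computed by integrating the
closed-form equicoordinate bivariate-normal CDF (via Owen's T function) over
the pooled-SD scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, special, stats

from .design import DesignSpec
from .rules import DecisionOutcome, _ratio_coefficients, closed_test
from .sampling import TestStats

__all__ = [
    "MethodSpec",
    "METHOD_NAMES",
    "bonferroni_decision",
    "holm_decision",
    "dunnett_critical_value",
    "dunnett_decision",
    "fixed_sequence_decision",
    "constrain",
    "decide",
]

METHOD_NAMES = (
    "consistency",
    "bonferroni",
    "dunnett",
    "fixed_sequence_s_first",
    "fixed_sequence_o_first",
)


@dataclass(frozen=True)
class MethodSpec:
    """A named testing procedure with its family-wise level.

    ``constrained`` applies the consistency restrictions of the design's
    (b, k) pair to the elementary claims (so a DesignSpec with both fractions
    set is required).
    """

    name: str
    alpha: float = 0.025
    constrained: bool = False

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.name!r}; expected one of {METHOD_NAMES}")
        if not 0.0 < self.alpha <= 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5], got {self.alpha}")

    @property
    def label(self) -> str:
        return ("constrained " if self.constrained else "") + self.name.replace("_", "-")


def _outcome(claim_s, claim_o, crit: dict) -> DecisionOutcome:
    return DecisionOutcome(
        intersection_rejected=claim_s | claim_o,
        via_condition_a=claim_s,
        via_condition_b=claim_o,
        claim_s=claim_s,
        claim_o=claim_o,
        critical_values=crit,
    )


def _crit(design: DesignSpec, alpha: float) -> float:
    return design.critical_value(alpha)


def bonferroni_decision(T: TestStats, design: DesignSpec, alpha: float = 0.025) -> DecisionOutcome:
    """Equal alpha/2 split, no step-down escalation.

    The plain split (each test always at alpha/2) is what the reference power
    table reports — its subgroup power is flat in theta_c, which a Holm-type
    escalation would not be.  See :func:`holm_decision` for the step-down
    variant.
    """
    q = _crit(design, alpha / 2.0)
    return _outcome(T.t_s > q, T.t_o > q, {"t_half_alpha": q})


def holm_decision(T: TestStats, design: DesignSpec, alpha: float = 0.025) -> DecisionOutcome:
    """Holm step-down variant of the Bonferroni split (not used by default)."""
    q_half = _crit(design, alpha / 2.0)
    q_full = _crit(design, alpha)
    first_s = T.t_s > q_half
    first_o = T.t_o > q_half
    claim_s = first_s | (first_o & (T.t_s > q_full))
    claim_o = first_o | (first_s & (T.t_o > q_full))
    return _outcome(claim_s, claim_o, {"t_half_alpha": q_half, "t_alpha": q_full})


def _equicoordinate_bvn_cdf(x: float, rho: float) -> float:
    """P(Z1 <= x, Z2 <= x) for standard bivariate normal with correlation rho.

    Closed form via Owen's T: Phi2(x, x; rho) = Phi(x) - 2 T(x, a) - delta,
    a = sqrt((1-rho)/(1+rho)), delta = 1/2 when x < 0 else 0.
    """
    a = np.sqrt((1.0 - rho) / (1.0 + rho))
    delta = 0.5 if x < 0 else 0.0
    return float(stats.norm.cdf(x) - 2.0 * special.owens_t(x, a) - delta)


@lru_cache(maxsize=128)
def dunnett_critical_value(alpha: float, rho: float, df: int, tol: float = 1e-6) -> float:
    """Equicoordinate upper-alpha critical value of the correlated bivariate t.

    Solves ``P(max(T1, T2) > c) = alpha`` where (T1, T2) = (Z1, Z2)/W with
    (Z1, Z2) standard bivariate normal with correlation ``rho`` and
    ``W = sqrt(ChiSq(df)/df)`` shared by both coordinates.  The joint CDF is
    the chi-scale mixture of the closed-form bivariate-normal CDF.  The root
    lies strictly between the per-test and the alpha/2 t-quantiles for
    ``rho`` in (0, 1).
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    chi = stats.chi(df, scale=1.0 / np.sqrt(df))
    w_lo, w_hi = chi.ppf(1e-12), chi.ppf(1.0 - 1e-12)

    def joint_cdf(c: float) -> float:
        val, _ = integrate.quad(
            lambda w: _equicoordinate_bvn_cdf(c * w, rho) * chi.pdf(w),
            w_lo, w_hi, epsabs=1e-11, epsrel=1e-11, limit=200,
        )
        return val

    lo = stats.t.ppf(1.0 - alpha, df) - 0.01
    hi = stats.t.ppf(1.0 - alpha / 2.0, df) + 0.01
    f = lambda c: joint_cdf(c) - (1.0 - alpha)
    try:
        return float(optimize.brentq(f, lo, hi, xtol=tol))
    except ValueError as exc:  # bracket failure: report diagnostics
        raise RuntimeError(
            f"equicoordinate critical-value solve failed for alpha={alpha}, rho={rho}, "
            f"df={df}: f({lo:.4f})={f(lo):.3e}, f({hi:.4f})={f(hi):.3e}"
        ) from exc


def dunnett_decision(T: TestStats, design: DesignSpec, alpha: float = 0.025) -> DecisionOutcome:
    """Single-step test of S and O at the shared equicoordinate critical value."""
    c = dunnett_critical_value(alpha, float(np.sqrt(design.p)), design.df)
    return _outcome(T.t_s > c, T.t_o > c, {"c_equicoordinate": c})


def fixed_sequence_decision(
    T: TestStats, design: DesignSpec, alpha: float = 0.025, order: str = "s_first"
) -> DecisionOutcome:
    """Hierarchical test: first hypothesis at full alpha gatekeeps the second."""
    q = _crit(design, alpha)
    if order == "s_first":
        claim_s = T.t_s > q
        claim_o = claim_s & (T.t_o > q)
    elif order == "o_first":
        claim_o = T.t_o > q
        claim_s = claim_o & (T.t_s > q)
    else:
        raise ValueError("order must be 's_first' or 'o_first'")
    return _outcome(claim_s, claim_o, {"t_alpha": q})


def constrain(
    outcome: DecisionOutcome,
    T: TestStats,
    design: DesignSpec,
    overall_rule: str = "k_ratio",
) -> DecisionOutcome:
    """Filter a procedure's claims through the consistency restrictions.

    The subgroup claim additionally requires the complement to retain the
    fraction b (``T_c > b sqrt((1-p)/p) T_s``).  For the overall claim,
    ``overall_rule="k_ratio"`` requires both k-retention conditions
    (``theta_hat_s > k theta_hat_o`` and ``theta_hat_c > k theta_hat_o`` on
    the T scale); ``"no_harm"`` requires only an observed non-negative
    complement effect, ``T_c > 0``.  Constrained claims are a subset of the
    unconstrained ones, and the disjunctive success flag is recomputed.
    """
    cons_s = T.t_c > design.consistency_slope * T.t_s
    if overall_rule == "k_ratio":
        k = design.require_k()
        c_s, c_c = _ratio_coefficients(design)
        cons_o = (k * T.t_c < c_s * T.t_s) & (c_c * T.t_c > k * T.t_s)
    elif overall_rule == "no_harm":
        cons_o = T.t_c > 0.0
    else:
        raise ValueError("overall_rule must be 'k_ratio' or 'no_harm'")
    claim_s = outcome.claim_s & cons_s
    claim_o = outcome.claim_o & cons_o
    return outcome.replace(
        claim_s=claim_s, claim_o=claim_o, intersection_rejected=claim_s | claim_o
    )


def decide(T: TestStats, design: DesignSpec, method: MethodSpec) -> DecisionOutcome:
    """Run one procedure on one (batch of) trial(s)."""
    if method.name == "consistency":
        out = closed_test(T, design, family_alpha=method.alpha, constrained=method.constrained)
        return out
    if method.name == "bonferroni":
        out = bonferroni_decision(T, design, method.alpha)
    elif method.name == "dunnett":
        out = dunnett_decision(T, design, method.alpha)
    elif method.name == "fixed_sequence_s_first":
        out = fixed_sequence_decision(T, design, method.alpha, "s_first")
    else:
        out = fixed_sequence_decision(T, design, method.alpha, "o_first")
    if method.constrained:
        out = constrain(out, T, design)
    return out
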