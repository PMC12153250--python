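"""Design and scenario parameterization for two-population enrichment trials.

An enrichment trial enrolls ``n_s`` patients per arm from the biomarker-positive
subgroup (S) and ``n_c`` per arm from its marker-negative complement (C), each
randomized 1:1 to control (0) or treatment (1).  Two one-sided hypotheses are
tested jointly: efficacy in S and efficacy in the overall population O.  The
rejection rule couples the two tests through consistency fractions:

``b``
    minimum fraction of the subgroup's estimated effect that the complement
    must retain for the subgroup claim (``theta_hat_c > b * theta_hat_s``);
``k``
    minimum fraction of the overall estimated effect that *each* subgroup must
    retain for the overall claim (``theta_hat_s > k * theta_hat_o`` and
    ``theta_hat_c > k * theta_hat_o``).

``k`` is usually not chosen freely but calibrated by Monte Carlo so that the
intersection test keeps a target family-wise one-sided level (see
:mod:`enrichtest.calibration`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["DesignSpec", "EffectScenario"]


@dataclass(frozen=True)
class DesignSpec:
    """Full parameterization of one enrichment design.

    Parameters
    ----------
    n_s, n_c
        Per-arm sample sizes in the marker-positive subgroup and its
        complement.  Both arms within a subgroup are equal-sized.
    alpha_s, alpha_o
        One-sided significance levels for the subgroup and overall tests
        inside the intersection rule.
    b
        Consistency fraction for the subgroup claim, ``-1 < b < 1``.
    k
        Consistency fraction for the overall claim, ``-1 < k < 1``.  ``None``
        marks a design whose ``k`` has not been calibrated yet; decision rules
        refuse to run until it is set (e.g. via :meth:`with_k`).
        Negative values are legal: calibrated tables reach k ~ -0.15 for
        large ``b``.
    critical_scale
        ``"t"`` uses exact Student-t quantiles at ``df`` degrees of freedom
        (the proper finite-sample choice); ``"normal"`` uses large-sample
        normal quantiles (1.96-style critical values, the convention of the
        reference calibration tables this package reproduces).  At df ~ 600
        the two differ by ~0.004, which is negligible for a single trial
        decision but shifts calibrated ``k`` noticeably because the attained
        level is extremely flat in ``k``.
    """

    n_s: int
    n_c: int
    alpha_s: float = 0.025
    alpha_o: float = 0.025
    b: float = 0.0
    k: float | None = None
    critical_scale: str = "t"

    def __post_init__(self) -> None:
        if int(self.n_s) != self.n_s or int(self.n_c) != self.n_c:
            raise ValueError("per-arm sample sizes must be integers")
        if self.n_s < 2 or self.n_c < 2:
            raise ValueError("need n_s >= 2 and n_c >= 2 for estimable group variances")
        for name in ("alpha_s", "alpha_o"):
            a = getattr(self, name)
            if not 0.0 < a <= 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5], got {a}")
        if not -1.0 < self.b < 1.0:
            raise ValueError(f"consistency fraction b must lie in (-1, 1), got {self.b}")
        if self.k is not None and not -1.0 < self.k < 1.0:
            raise ValueError(f"consistency fraction k must lie in (-1, 1), got {self.k}")
        if self.critical_scale not in ("t", "normal"):
            raise ValueError("critical_scale must be 't' or 'normal'")

    # -- derived quantities (never stored independently) --

    @property
    def p(self) -> float:
        """Prevalence of the marker-positive subgroup in the trial."""
        return self.n_s / (self.n_s + self.n_c)

    @property
    def df(self) -> int:
        """Degrees of freedom of the pooled variance estimate, 2*n_s + 2*n_c - 4."""
        return 2 * self.n_s + 2 * self.n_c - 4

    def critical_value(self, alpha: float) -> float:
        """Upper-``alpha`` critical value on the configured scale."""
        if self.critical_scale == "normal":
            return float(stats.norm.ppf(1.0 - alpha))
        return float(stats.t.ppf(1.0 - alpha, self.df))

    @property
    def t_alpha_s(self) -> float:
        return self.critical_value(self.alpha_s)

    @property
    def t_alpha_o(self) -> float:
        return self.critical_value(self.alpha_o)

    @property
    def consistency_slope(self) -> float:
        """Slope of the subgroup-claim constraint on the T scale.

        ``theta_hat_c > b * theta_hat_s`` is equivalent to
        ``T_c > b * sqrt((1-p)/p) * T_s``.
        """
        p = self.p
        return self.b * math.sqrt((1.0 - p) / p)

    def require_k(self) -> float:
        if self.k is None:
            raise ValueError(
                "design has no consistency fraction k; calibrate it first "
                "(enrichtest.calibration.solve_k) or set it via with_k()"
            )
        return self.k

    # -- functional updates --

    def with_k(self, k: float) -> "DesignSpec":
        return dataclasses.replace(self, k=k)

    def with_b(self, b: float) -> "DesignSpec":
        return dataclasses.replace(self, b=b)


@dataclass(frozen=True)
class EffectScenario:
    """A simulation truth: true effects and the common within-group SD.

    ``theta_s`` and ``theta_c`` are the true treatment-minus-control mean
    differences in the two subgroups, in outcome units; ``sigma`` is the
    common within-group standard deviation.  The overall effect is the
    prevalence-weighted mixture and is always derived, never set.
    """

    theta_s: float
    theta_c: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def theta_o(self, design: DesignSpec) -> float:
        """Overall effect p*theta_s + (1-p)*theta_c for the given design."""
        p = design.p
        return p * self.theta_s + (1.0 - p) * self.theta_c
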