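"""Distributional model of the trial and trial generation.

Four normal outcome groups with a common variance:

    X_{s,0,i} ~ N(theta_{s,0}, sigma^2),  X_{s,1,i} ~ N(theta_{s,1}, sigma^2)
    X_{c,0,i} ~ N(theta_{c,0}, sigma^2),  X_{c,1,i} ~ N(theta_{c,1}, sigma^2)

The sufficient statistics of a realized trial are the two estimated
differences and the pooled variance; with equal arms per subgroup they are
mutually independent with

    theta_hat_s ~ N(theta_s, 2 sigma^2 / n_s)
    theta_hat_c ~ N(theta_c, 2 sigma^2 / n_c)
    sigma_hat^2 ~ sigma^2 * ChiSq(df) / df,     df = 2 n_s + 2 n_c - 4

so trials can be simulated either at patient level or directly at the
sufficient-statistic level; the two routes are distributionally identical.

Array convention: statistic containers hold scalars or equal-length 1-D
arrays.  A batch of 10^6 simulated trials is a single ``SufficientStats``
whose fields are arrays; it also behaves as a sequence of per-draw scalar
``SufficientStats``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._random import rng_for
from .design import DesignSpec, EffectScenario

__all__ = [
    "DegenerateVarianceError",
    "PatientData",
    "SufficientStats",
    "TestStats",
    "simulate_patients",
    "summarize_patients",
    "sample_sufficient_stats",
    "compute_test_statistics",
]


class DegenerateVarianceError(ValueError):
    """Raised when a pooled variance of zero would make t-statistics undefined."""


@dataclass(frozen=True)
class PatientData:
    """Per-patient outcomes for the four groups (subgroup x arm)."""

    x_s0: np.ndarray
    x_s1: np.ndarray
    x_c0: np.ndarray
    x_c1: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x_s0", "x_s1", "x_c0", "x_c1"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D outcome vector")
            object.__setattr__(self, name, arr)

    @property
    def n_all(self) -> int:
        return self.x_s0.size + self.x_s1.size + self.x_c0.size + self.x_c1.size


@dataclass(frozen=True)
class SufficientStats:
    """One trial (or a batch of trials) summarized as (theta_hat_s, theta_hat_c, sigma_hat^2, df).

    ``sigma_hat_sq == 0`` is representable (a degenerate all-constant sample)
    but raises :class:`DegenerateVarianceError` as soon as t-statistics are
    requested.
    """

    theta_hat_s: float | np.ndarray
    theta_hat_c: float | np.ndarray
    sigma_hat_sq: float | np.ndarray
    df: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma_hat_sq) < 0):
            raise ValueError("sigma_hat_sq must be non-negative")
        if self.df <= 0:
            raise ValueError("df must be positive")

    @property
    def sigma_hat(self) -> float | np.ndarray:
        return np.sqrt(self.sigma_hat_sq)

    @property
    def is_degenerate(self) -> bool | np.ndarray:
        return np.asarray(self.sigma_hat_sq) == 0

    def __len__(self) -> int:
        return np.broadcast(
            np.asarray(self.theta_hat_s), np.asarray(self.theta_hat_c), np.asarray(self.sigma_hat_sq)
        ).size

    def __getitem__(self, i) -> "SufficientStats":
        ths = np.broadcast_arrays(
            np.asarray(self.theta_hat_s), np.asarray(self.theta_hat_c), np.asarray(self.sigma_hat_sq)
        )
        return SufficientStats(float(ths[0].flat[i]), float(ths[1].flat[i]), float(ths[2].flat[i]), self.df)


@dataclass(frozen=True)
class TestStats:
    """The (T_s, T_c, T_o) triple on the t-statistic scale.

    ``t_o`` is a deterministic function of the other two:
    ``t_o = sqrt(p) t_s + sqrt(1-p) t_c``; :meth:`from_subgroup` enforces the
    identity at construction.
    """

    t_s: float | np.ndarray
    t_c: float | np.ndarray
    t_o: float | np.ndarray
    df: int

    @classmethod
    def from_subgroup(cls, t_s, t_c, design: DesignSpec) -> "TestStats":
        p = design.p
        t_s = np.asarray(t_s, dtype=float)
        t_c = np.asarray(t_c, dtype=float)
        t_o = np.sqrt(p) * t_s + np.sqrt(1.0 - p) * t_c
        if t_s.ndim == 0:
            return cls(float(t_s), float(t_c), float(t_o), design.df)
        return cls(t_s, t_c, t_o, design.df)

    def __len__(self) -> int:
        return np.broadcast(np.asarray(self.t_s), np.asarray(self.t_c)).size


def simulate_patients(
    design: DesignSpec,
    scenario: EffectScenario,
    seed: int | np.random.Generator | None = None,
) -> PatientData:
    """Draw one trial at patient level (control means set to zero WLOG)."""
    rng = rng_for(seed, "patients")
    s = scenario.sigma
    return PatientData(
        x_s0=rng.normal(0.0, s, design.n_s),
        x_s1=rng.normal(scenario.theta_s, s, design.n_s),
        x_c0=rng.normal(0.0, s, design.n_c),
        x_c1=rng.normal(scenario.theta_c, s, design.n_c),
    )


def summarize_patients(data: PatientData, design: DesignSpec) -> SufficientStats:
    """Reduce patient-level outcomes to the sufficient statistics.

    The pooled variance divides the within-group sum of squares by
    ``n_all - 4`` (four estimated group means).
    """
    sizes = (data.x_s0.size, data.x_s1.size, data.x_c0.size, data.x_c1.size)
    expected = (design.n_s, design.n_s, design.n_c, design.n_c)
    if sizes != expected:
        raise ValueError(f"outcome vector lengths {sizes} do not match design arms {expected}")
    groups = (data.x_s0, data.x_s1, data.x_c0, data.x_c1)
    n_all = data.n_all
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df = n_all - 4
    return SufficientStats(
        theta_hat_s=float(data.x_s1.mean() - data.x_s0.mean()),
        theta_hat_c=float(data.x_c1.mean() - data.x_c0.mean()),
        sigma_hat_sq=ss / df,
        df=df,
    )


def sample_sufficient_stats(
    design: DesignSpec,
    scenario: EffectScenario,
    n_draws: int,
    seed: int | np.random.Generator | None = None,
) -> SufficientStats:
    """Draw ``n_draws`` trials directly at the sufficient-statistic level.

    Returns a batched :class:`SufficientStats` (array fields of length
    ``n_draws``).  Same seed, same call: identical output.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = rng_for(seed, "sufficient-stats")
    s2 = scenario.sigma**2
    df = design.df
    return SufficientStats(
        theta_hat_s=rng.normal(scenario.theta_s, np.sqrt(2.0 * s2 / design.n_s), n_draws),
        theta_hat_c=rng.normal(scenario.theta_c, np.sqrt(2.0 * s2 / design.n_c), n_draws),
        sigma_hat_sq=s2 * rng.chisquare(df, n_draws) / df,
        df=df,
    )


def compute_test_statistics(stats: SufficientStats, design: DesignSpec) -> TestStats:
    """Form (T_s, T_c, T_o) from sufficient statistics.

    ``T_s = sqrt(n_s/2) theta_hat_s / sigma_hat`` and analogously for C; the
    overall statistic follows from the identity
    ``T_o = sqrt(p) T_s + sqrt(1-p) T_c``.
    """
    if np.any(np.asarray(stats.sigma_hat_sq) <= 0):
        raise DegenerateVarianceError(
            "pooled variance estimate is zero (all residuals equal); t-statistics are undefined"
        )
    sig = stats.sigma_hat
    t_s = np.sqrt(design.n_s / 2.0) * stats.theta_hat_s / sig
    t_c = np.sqrt(design.n_c / 2.0) * stats.theta_hat_c / sig
    return TestStats.from_subgroup(t_s, t_c, design)


def to_frame(stats: SufficientStats, design: DesignSpec):
    """Export a batch of simulated trials as a tidy DataFrame (one row per draw)."""
    import pandas as pd

    t = compute_test_statistics(stats, design)
    return pd.DataFrame(
        {
            "draw": np.arange(len(stats)),
            "theta_hat_s": np.atleast_1d(stats.theta_hat_s),
            "theta_hat_c": np.atleast_1d(stats.theta_hat_c),
            "sigma_hat_sq": np.atleast_1d(stats.sigma_hat_sq),
            "T_s": np.atleast_1d(t.t_s),
            "T_c": np.atleast_1d(t.t_c),
            "T_o": np.atleast_1d(t.t_o),
        }
    )
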