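"""Benchmark designs and reference calibration pairs.

Six enrichment design options for a phase-III program targeting a
standardized effect of 0.3 in the marker-positive subgroup with a total of
~300 patients per arm, used throughout the package's power comparisons:

======== ===== ===== ======== ========
design    n_s   n_c  alpha_s  alpha_o
======== ===== ===== ======== ========
design1   150   150   0.025    0.025
design2   200   100   0.025    0.025
design3   100   200   0.025    0.025
design4   100   100   0.025    0.025
design5   150   150   0.0125   0.025
design6   150   150   0.025    0.0125
======== ===== ===== ======== ========

Designs 1-3, 5 and 6 carry b = -0.25 with the k calibrated for a 0.025
family-wise level; design6 (the preferred option) uses (b, k) = (-0.25, 0.26).
All presets use the large-sample ("normal") critical-value convention under
which the reference calibration tables were produced; see
:class:`~enrichtest.design.DesignSpec.critical_scale`.
"""

from __future__ import annotations

from .design import DesignSpec

__all__ = ["reference_designs", "consistency_pairs_half_prevalence"]


def reference_designs(critical_scale: str = "normal") -> dict[str, DesignSpec]:
    """The six benchmark designs, keyed 'design1' ... 'design6'."""
    mk = lambda ns, nc, a_s, a_o, b=None, k=None: DesignSpec(
        ns, nc, alpha_s=a_s, alpha_o=a_o, b=0.0 if b is None else b, k=k,
        critical_scale=critical_scale,
    )
    return {
        "design1": mk(150, 150, 0.025, 0.025, b=-0.25, k=0.82),
        "design2": mk(200, 100, 0.025, 0.025, b=-0.25, k=0.73),
        "design3": mk(100, 200, 0.025, 0.025, b=-0.25, k=0.89),
        "design4": mk(100, 100, 0.025, 0.025),
        "design5": mk(150, 150, 0.0125, 0.025, b=-0.25, k=0.54),
        "design6": mk(150, 150, 0.025, 0.0125, b=-0.25, k=0.26),
    }


def consistency_pairs_half_prevalence() -> list[tuple[float, float]]:
    """Reference (b, k) pairs at p = 0.5, alpha_s = alpha_o = 0.025, FWER 0.025.

    Each pair holds the intersection-test level at 0.025 (to Monte-Carlo
    accuracy) for n_s = n_c = 150 under the normal critical-value convention.
    """
    return [(-0.9, 0.99), (-0.5, 0.93), (0.0, 0.59), (0.08, 0.43), (0.2, 0.15), (0.5, -0.15)]
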