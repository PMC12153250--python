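"""Rejection-region grids, figures and tabular output.

Regions are rendered from exported grids, not pixels: a RegionGrid carries
per-cell membership flags for each rule on either the T-statistic scale or
the one-sided p-value scale (the monotone transform p = 1 - F_t(T; df)), so
figures are regression-testable through their underlying data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .comparators import dunnett_critical_value
from .design import DesignSpec
from .rules import condition_a, condition_b
from .sampling import TestStats

logger = logging.getLogger(__name__)

__all__ = ["RegionGrid", "region_grid", "write_tables", "plot_region", "plot_power_curves", "plot_bk_contour"]


@dataclass(frozen=True)
class RegionGrid:
    """Membership masks for the rejection rules on a 2-D grid.

    ``x``/``y`` are the subgroup/complement axes (T or p-value scale
    depending on ``scale``); masks are indexed [y, x] like images.
    """

    design: DesignSpec
    scale: str
    x: np.ndarray
    y: np.ndarray
    masks: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        data = {"x": xx.ravel(), "y": yy.ravel()}
        for name, mask in self.masks.items():
            data[name] = mask.ravel()
        return pd.DataFrame(data)

    def mass_under_null(self, n_draws: int = 10**5, seed: int | None = 0):
        """MC probability of each mask's region under the global null.

        Membership is re-evaluated on joint null draws of (T_s, T_c) — the
        p-scale margins are uniform but not independent, so the region mass
        is not the region's area even on that scale.
        """
        from .calibration import _null_test_stats
        from ._random import rng_for

        T = _null_test_stats(self.design, n_draws, rng_for(seed, "region-mass"))
        out = {}
        d = self.design
        out["condition_a"] = float(np.mean(condition_a(T, d)))
        out["condition_b"] = float(np.mean(condition_b(T, d)))
        out["consistency"] = float(np.mean(condition_a(T, d) | condition_b(T, d)))
        return out


def region_grid(
    design: DesignSpec,
    scale: str = "t",
    resolution: int = 200,
    t_range: tuple[float, float] = (-3.0, 5.0),
    fwer_alpha: float = 0.025,
    include_comparators: bool = True,
) -> RegionGrid:
    """Evaluate the rejection rules on a (T_s, T_c) or (p_s, p_c) grid."""
    if resolution < 50:
        raise ValueError("resolution must be >= 50 per axis")
    if scale not in ("t", "pvalue"):
        raise ValueError("scale must be 't' or 'pvalue'")
    if scale == "t":
        xs = np.linspace(*t_range, resolution)
        ys = xs.copy()
        ts_x, ts_y = xs, ys
    else:
        eps = 1.0 / (4 * resolution)
        xs = np.linspace(eps, 1.0 - eps, resolution)
        ys = xs.copy()
        # one-to-one monotone-decreasing transform back to the t scale
        ts_x = sps.t.ppf(1.0 - xs, design.df)
        ts_y = sps.t.ppf(1.0 - ys, design.df)
    tss, tcs = np.meshgrid(ts_x, ts_y)
    T = TestStats.from_subgroup(tss, tcs, design)
    masks = {
        "condition_a": condition_a(T, design),
        "condition_b": condition_b(T, design),
    }
    masks["consistency"] = masks["condition_a"] | masks["condition_b"]
    if include_comparators:
        q_half = design.critical_value(fwer_alpha / 2.0)
        masks["bonferroni"] = (T.t_s > q_half) | (T.t_o > q_half)
        c = dunnett_critical_value(fwer_alpha, float(np.sqrt(design.p)), design.df)
        masks["dunnett"] = (T.t_s > c) | (T.t_o > c)
    return RegionGrid(design=design, scale=scale, x=xs, y=ys, masks=masks)


def write_tables(results: pd.DataFrame, path, paper_style: bool = True) -> list:
    """Write a results table as full-precision CSV (+ optional 2-decimal view).

    Returns the list of files written.  An empty table yields a header-only
    file and a warning.
    """
    import pathlib

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if results.empty:
        logger.warning("writing empty results table to %s", path)
    written = [path]
    try:
        results.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed to write results table to {path}: {exc}") from exc
    if paper_style and not results.empty:
        rounded = results.copy()
        for col in rounded.select_dtypes(include=[float]).columns:
            rounded[col] = rounded[col].round(2)
        p2 = path.with_name(path.stem + "_2dp" + path.suffix)
        rounded.to_csv(p2, index=False)
        written.append(p2)
    return written


def _agg():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_region(grid: RegionGrid, path, rules=("consistency", "bonferroni")) -> None:
    """Shaded rejection-region plot from a RegionGrid (deterministic render)."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 5))
    extent = (grid.x[0], grid.x[-1], grid.y[0], grid.y[-1])
    colors = {"consistency": "tab:blue", "condition_a": "tab:green",
              "condition_b": "tab:orange", "bonferroni": "tab:red", "dunnett": "tab:purple"}
    for name in rules:
        if name not in grid.masks:
            continue
        ax.contourf(grid.x, grid.y, grid.masks[name].astype(float), levels=[0.5, 1.5],
                    colors=[colors.get(name, "gray")], alpha=0.35)
        ax.contour(grid.x, grid.y, grid.masks[name].astype(float), levels=[0.5],
                   colors=[colors.get(name, "gray")], linewidths=1.2)
    lab = ("T" if grid.scale == "t" else "p-value")
    ax.set_xlabel(f"{lab} (marker-positive)")
    ax.set_ylabel(f"{lab} (marker-negative)")
    d = grid.design
    ax.set_title(f"p={d.p:.2f}, b={d.b:.2f}, k={d.k if d.k is None else round(d.k, 2)}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_power_curves(sweep: pd.DataFrame, path, x: str = "b", y: str = "disjunctive",
                      group: str = "theta_c") -> None:
    """Power curves from a design_sweep table (one line per group value)."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(6, 4))
    for key, sub in sweep.sort_values(x).groupby(group):
        ax.plot(sub[x], sub[y], marker="o", ms=3, label=f"{group}={key}")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bk_contour(contour: pd.DataFrame, path) -> None:
    """Calibrated k against b, one line per target alpha."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(6, 4))
    for alpha, sub in contour.sort_values("b").groupby("alpha"):
        ok = sub[sub["feasible"]]
        ax.plot(ok["b"], ok["k"], marker="o", ms=3, label=f"alpha={alpha}")
    ax.set_xlabel("b (complement retention for the subgroup claim)")
    ax.set_ylabel("calibrated k")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
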