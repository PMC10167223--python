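"""Matplotlib views of nutrient arrays and stability simulations.

Every plotting function also exposes its plotted numbers (via the returned
objects' underlying data or the companion ``*_table`` helpers) so rendering
can be tested without pixel comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt

from .io import IntakeDataset
from .geometry import parse_rail

__all__ = [
    "plot_array",
    "plot_deviations",
    "plot_stability",
    "array_plot_table",
    "deviation_plot_table",
]


def _species_list(results, species):
    return [species] if species else sorted(results.records["species"].unique())


def array_plot_table(results, species: str) -> pd.DataFrame:
    """Per-rail mean intake coordinates drawn by :func:`plot_array`."""
    data: IntakeDataset = results.model.data
    df = data.rail_rows(species)
    return (
        df.groupby("rail")[["nutrient_a", "nutrient_b"]].mean().reset_index()
    )


def deviation_plot_table(results, species: str) -> pd.DataFrame:
    est = results.estimates
    return est[est["species"] == species].reset_index(drop=True)


def plot_array(results, species: str | None = None, ax=None):
    """Nutrient-space panel: rails, individual intakes, per-rail mean intake,
    the intake target (cross) and the Thales circle whose diameter is the
    origin–target segment."""
    sps = _species_list(results, species)
    if ax is None:
        _, axes = plt.subplots(1, len(sps), figsize=(5 * len(sps), 4.5), squeeze=False)
        axes = axes[0]
    else:
        axes = [ax]
        if len(sps) > 1:
            raise ValueError("pass species= when plotting a single axis")
    for sp, axis in zip(sps, axes):
        data = results.model.data
        rail_df = data.rail_rows(sp)
        target = results.targets[sp]
        circle = results.circle(sp)
        lim = 1.1 * max(
            rail_df["nutrient_a"].max(), rail_df["nutrient_b"].max(), target.norm
        )
        for label in sorted(rail_df["rail"].unique()):
            d = parse_rail(label).direction
            axis.plot([0, d[0] * lim], [0, d[1] * lim], color="0.8", lw=0.8, zorder=1)
            axis.annotate(label, xy=(d[0] * lim, d[1] * lim), fontsize=7, color="0.4")
        axis.scatter(
            rail_df["nutrient_a"], rail_df["nutrient_b"], s=8, alpha=0.35, label="intake"
        )
        means = array_plot_table(results, sp)
        axis.scatter(
            means["nutrient_a"], means["nutrient_b"], s=40, marker="D",
            color="k", zorder=3, label="rail mean",
        )
        theta = np.linspace(0, 2 * np.pi, 256)
        axis.plot(
            circle.center[0] + circle.radius * np.cos(theta),
            circle.center[1] + circle.radius * np.sin(theta),
            color="crimson", lw=1.2, label="Thales circle",
        )
        axis.scatter([target.nutrient_a], [target.nutrient_b], marker="X", s=90,
                     color="crimson", zorder=4, label="intake target")
        axis.set_xlim(0, lim)
        axis.set_ylim(0, lim)
        axis.set_xlabel("nutrient A intake")
        axis.set_ylabel("nutrient B intake")
        axis.set_title(sp)
        axis.legend(fontsize=7, loc="upper right")
    return axes[0].figure


def plot_deviations(results, species: str | None = None, ax=None, raw_beta: bool = False):
    """Per-rail deviation (or raw beta) with CI bars and the CDO reference."""
    sps = _species_list(results, species)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    offset = 90.0 if raw_beta else 0.0
    lo = next(c for c in results.estimates.columns if c.startswith("lwr"))
    hi = next(c for c in results.estimates.columns if c.startswith("upr"))
    for i, sp in enumerate(sps):
        est = deviation_plot_table(results, sp)
        est = est.sort_values("ratio", key=lambda s: s.map(_ratio_share))
        x = np.arange(len(est)) + 0.08 * i
        y = est["mean_beta_dev"] + offset
        yerr = np.vstack([y - (est[lo] + offset), (est[hi] + offset) - y])
        ax.errorbar(x, y, yerr=yerr, fmt="o", capsize=3, label=sp)
        ax.set_xticks(np.arange(len(est)))
        ax.set_xticklabels(est["ratio"])
    ax.axhline(offset, color="crimson", lw=1, ls="--")
    ax.set_xlabel("P:C ratio of the nutritional rail")
    ax.set_ylabel("angle beta (deg)" if raw_beta else "deviation beta - 90 (deg)")
    ax.legend(fontsize=8)
    return ax.figure


def _ratio_share(label: str) -> float:
    r = parse_rail(label)
    return r.ratio_a / (r.ratio_a + r.ratio_b)


def plot_stability(result, ax=None):
    """Mean estimated beta vs. noise proportion with CI ribbons, one curve
    per error family."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6.5, 4))
    for family, sub in result.grid.groupby("family"):
        sub = sub.sort_values("noise_proportion")
        ax.plot(sub["noise_proportion"], sub["mean_beta"], label=family, lw=1.2)
        ax.fill_between(
            sub["noise_proportion"], sub["lwr95"], sub["upr95"], alpha=0.25
        )
    ax.axhline(90.0, color="0.3", lw=0.8, ls=":")
    ax.set_xscale("log")
    ax.set_xlabel("noise proportion (scale / |intake target|)")
    ax.set_ylabel("estimated angle beta (deg)")
    ax.legend()
    return ax.figure
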