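"""Plotting helpers: annual effect bars and spatial-effect profiles.

Requires matplotlib (optional dependency)."""

from __future__ import annotations

import numpy as np

from .discontinuity import SpatialEffectProfile
from .effects import TemporalSeries, percent_effect


def plot_temporal_series(series: TemporalSeries, ax=None):
    """Bar chart of annual baselines with the tenure effect stacked on top,
    annotated with the percent effect; significant years in full colour."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    years = series.years
    b0 = [e.b0 for e in series.estimates]
    b1 = [e.b1 for e in series.estimates]
    sig = [e.significant for e in series.estimates]
    ax.bar(years, b0, color="0.7", label="other lands (baseline)")
    colors = ["tab:orange" if s else "0.85" for s in sig]
    ax.bar(years, b1, bottom=b0, color=colors, label=f"{series.tenure_class} effect")
    for e in series.estimates:
        if e.significant and e.b0 > 0:
            ax.annotate(
                f"{percent_effect(e):.0f}%",
                (e.year, e.b0 + max(e.b1, 0)),
                ha="center", va="bottom", fontsize=7,
            )
    ax.set_xlabel("year")
    ax.set_ylabel("carbon density (t C/ha)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_spatial_profile(profile: SpatialEffectProfile, ax=None):
    """Point-line profile of spatial effects vs buffer depth, one line per
    year; open markers for the first year, filled for the last."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    years = sorted({y for _, y in profile.estimates})
    for i, year in enumerate(years):
        pts = profile.b1_series(year)
        bounds = [b for b, _ in pts]
        b1 = [v for _, v in pts]
        err = [
            profile.effect(b, year).se_b1 * 1.96 for b in bounds
        ]
        filled = i == len(years) - 1
        ax.errorbar(
            bounds, b1, yerr=err,
            marker="o", mfc=None if filled else "white",
            linestyle="-" if filled else "--",
            label=str(year), capsize=2,
        )
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel("buffer depth (km)")
    ax.set_ylabel(f"spatial effect of {profile.tenure_class} (t C/ha)")
    ax.legend(frameon=False, fontsize=8)
    return ax
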