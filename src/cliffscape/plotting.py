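"""Scatter plots of SAS and DAD maps."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dad import DADMap
from .landscape import SASMap

#: green → red, low SALI to high SALI
SALI_CMAP = "RdYlGn_r"


def plot_sas_map(
    sas: SASMap,
    target: str,
    scheme: str,
    path: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """SAS scatter: similarity (X) vs activity difference (Y), colored by SALI.

    Pairs whose SALI is the infinity sentinel (identical structures with
    differing activity) are drawn at the top of the color scale; threshold
    lines show the four-region split.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    sims = np.array([p.similarity[scheme] for p in sas.pairs])
    dacts = np.array([p.activity_difference[target] for p in sas.pairs])
    salis = np.array([p.sali[(scheme, target)] for p in sas.pairs])
    finite = np.isfinite(salis)
    vmax = salis[finite].max() if finite.any() else 1.0
    colors = np.where(finite, salis, vmax)
    sc = ax.scatter(sims, dacts, c=colors, cmap=SALI_CMAP, vmin=0, vmax=vmax,
                    s=18, edgecolors="none", alpha=0.85)
    ax.axvline(sas.thresholds.t_sim[scheme], color="0.3", lw=0.8, ls="--")
    ax.axhline(sas.thresholds.t_act, color="0.3", lw=0.8, ls="--")
    ax.set_xlabel(f"Tanimoto similarity ({scheme})")
    ax.set_ylabel(f"|ΔpIC50| {target} (log units)")
    ax.set_title(f"SAS map — {target}")
    ax.set_xlim(0, 1)
    plt.colorbar(sc, ax=ax, label="SALI")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_dad_map(
    dad: DADMap,
    path: str | Path | None = None,
    signed: bool = False,
    sali_colors: list[float] | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """DAD scatter with threshold lines; optionally signed axes or SALI colors."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    if signed:
        xs = [p.signed_dx for p in dad.points]
        ys = [p.signed_dy for p in dad.points]
    else:
        xs = [p.dx for p in dad.points]
        ys = [p.dy for p in dad.points]
    if sali_colors is not None:
        finite = [c for c in sali_colors if math.isfinite(c)]
        vmax = max(finite) if finite else 1.0
        colors = [c if math.isfinite(c) else vmax for c in sali_colors]
        sc = ax.scatter(xs, ys, c=colors, cmap=SALI_CMAP, vmin=0, vmax=vmax,
                        s=18, edgecolors="none", alpha=0.85)
        plt.colorbar(sc, ax=ax, label="SALI")
    else:
        ax.scatter(xs, ys, s=18, color="tab:blue", edgecolors="none", alpha=0.7)
    for v in ([dad.t_act, -dad.t_act] if signed else [dad.t_act]):
        ax.axvline(v, color="0.3", lw=0.8, ls="--")
        ax.axhline(v, color="0.3", lw=0.8, ls="--")
    prefix = "ΔpIC50" if signed else "|ΔpIC50|"
    ax.set_xlabel(f"{prefix} {dad.target_x} (log units)")
    ax.set_ylabel(f"{prefix} {dad.target_y} (log units)")
    ax.set_title(f"DAD map — {dad.target_x} vs {dad.target_y}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
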