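"""Plot helpers: area profiles, rater agreement, association scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cordbold.morphometry import AreaProfile, CompressionRegion

__all__ = ["plot_area_profile", "plot_rater_agreement", "plot_association"]


def plot_area_profile(
    profile: AreaProfile, regions: list[CompressionRegion] | None = None, path: str | None = None
):
    """Per-slice area line plot with detected regions shaded."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    z = np.arange(len(profile))
    ax.plot(z, profile.areas, lw=1, color="0.5", label="area")
    if profile.smoothed_areas is not None:
        ax.plot(z, profile.smoothed_areas, lw=1.5, color="C0", label="smoothed")
    for r in regions or []:
        ax.axvspan(r.z_lo, r.z_hi, color="C3", alpha=0.25)
    ax.set_xlabel("axial slice (inferior → superior)")
    ax.set_ylabel("cross-sectional area (mm²)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_rater_agreement(table: pd.DataFrame, path: str | None = None):
    """Dot plot of each rater's repeated measurements per subject."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    subjects = sorted(table["subject_id"].unique())
    xpos = {s: i for i, s in enumerate(subjects)}
    for j, (rater, grp) in enumerate(table.groupby("rater_id")):
        ax.scatter(
            [xpos[s] + 0.12 * j for s in grp["subject_id"]],
            grp["value_mm3"],
            s=14,
            label=str(rater),
            alpha=0.8,
        )
    ax.set_xticks(range(len(subjects)), subjects, rotation=90, fontsize=6)
    ax.set_ylabel("compression volume (mm³)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_association(cohort: pd.DataFrame, x: str, y: str, path: str | None = None):
    """Scatter of two cohort variables with the least-squares line."""
    fig, ax = plt.subplots(figsize=(4, 3.4))
    xv = cohort[x].to_numpy(dtype=float)
    yv = cohort[y].to_numpy(dtype=float)
    ax.scatter(xv, yv, s=18, color="C0")
    b, a = np.polyfit(xv, yv, 1)
    xs = np.linspace(xv.min(), xv.max(), 2)
    ax.plot(xs, a + b * xs, color="C3", lw=1)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
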