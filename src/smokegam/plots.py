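"""Optional figures: dot-and-interval rate-ratio grid and percent surface."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .inference import SurfaceGrid

__all__ = ["plot_rate_ratio_grid", "plot_surface"]


def plot_rate_ratio_grid(report: pd.DataFrame, path=None):
    """Rate ratios with/without smoke per model, with 95% intervals."""
    fig, ax = plt.subplots(figsize=(7, 0.6 * max(len(report), 4) + 1.5))
    ypos = np.arange(len(report))[::-1]
    for y, row in zip(ypos, report.itertuples()):
        ax.errorbar(
            row.rr_nonwf, y + 0.15,
            xerr=[[row.rr_nonwf - row.rr_nonwf_lo], [row.rr_nonwf_hi - row.rr_nonwf]],
            fmt="o", color="tab:blue", capsize=2,
        )
        ax.errorbar(
            row.rr_wf, y - 0.15,
            xerr=[[row.rr_wf - row.rr_wf_lo], [row.rr_wf_hi - row.rr_wf]],
            fmt="s", color="tab:orange", capsize=2,
        )
        ax.annotate(f"x{row.factor:.3f}", (max(row.rr_wf_hi, row.rr_nonwf_hi), y),
                    fontsize=8, va="center", xytext=(4, 0), textcoords="offset points")
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels([f"{r.fraction} lag {r.lag_set}" for r in report.itertuples()])
    ax.set_xlabel("rate ratio per 5 µg/m³")
    ax.legend(["no smoke", "smoke"], loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_surface(surface: SurfaceGrid, path=None):
    """Shaded percent-increase surface with the significant region hatched."""
    fig, ax = plt.subplots(figsize=(6.5, 5))
    mesh = ax.pcolormesh(
        surface.pm25, surface.pmc, surface.percent, shading="auto", cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label="% increase in visits due to smoke")
    sig = np.where(surface.significant, 1.0, np.nan)
    ax.contourf(surface.pm25, surface.pmc, sig, levels=[0.5, 1.5],
                hatches=["//"], colors="none")
    ax.set_xlabel("PM2.5 (µg/m³)")
    ax.set_ylabel("PM10-2.5 (µg/m³)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
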