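"""Plotting for the estimate workflow (fitted MF line, level boundaries, LF)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fatigue import SMFDR, FatigueEstimate, LinearFit, level_boundaries
from .spectral import MFSeries


def plot_estimate(
    series: MFSeries,
    fit: LinearFit,
    smfdr: SMFDR,
    estimates: list[FatigueEstimate],
    N: int,
    path: str | Path,
) -> None:
    """Write the fatigue-staging figure: MF points, fitted line, dashed
    level boundaries, and the LF step curve on a twin axis."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(series.times, series.mf, "o", ms=3, color="0.4", label="window MF")
    yfit = fit.slope_A * series.times + fit.intercept_b
    ax.plot(series.times, yfit, color="tab:blue", lw=2, label="fitted MF line")
    for lo, hi, k in level_boundaries(smfdr, N):
        ax.axhline(hi, ls="--", lw=0.8, color="0.6")
        if k == N - 1:
            ax.axhline(lo, ls="--", lw=0.8, color="0.6")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("median frequency (Hz)")

    ax2 = ax.twinx()
    lf = np.array([e.LF for e in estimates])
    ax2.step(series.times, lf, where="post", color="tab:red", lw=2, label="fatigue level")
    ax2.set_ylabel("fatigue level LF")
    ax2.set_ylim(-0.05, 1.05)

    lines, labels = ax.get_legend_handles_labels()
    lines2, labels2 = ax2.get_legend_handles_labels()
    ax.legend(lines + lines2, labels + labels2, loc="center left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
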