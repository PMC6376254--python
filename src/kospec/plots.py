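"""Diagnostic figures: lane-profile plots and the index bar chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .pipeline import AntibodyBlotAnalysis
from .specificity import RankEntry


def profile_figure(analysis: AntibodyBlotAnalysis, path: str | Path) -> None:
    """Profile + baseline per lane, with the peak of interest shaded."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, lane in zip(axes, (analysis.control, analysis.ko)):
        q = lane.quantification
        rows = range(len(lane.profile))
        ax.plot(rows, lane.profile.values, lw=1, color="k", label="profile")
        ax.plot(rows, lane.baseline.values, lw=1, color="r", ls="--", label="baseline")
        for p in q.peaks:
            shade = "tab:blue" if p == q.peak_of_interest else "0.7"
            ax.fill_between(
                range(p.start, p.end),
                lane.baseline.values[p.start:p.end],
                lane.profile.values[p.start:p.end],
                color=shade, alpha=0.6,
            )
        ax.set_title(f"{q.lane_id} ({q.condition})", fontsize=9)
        ax.set_xlabel("row (top → bottom)")
    axes[0].set_ylabel("mean intensity (a.u.)")
    axes[0].legend(fontsize=8)
    fig.suptitle(analysis.antibody_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ranking_figure(entries: list[RankEntry], path: str | Path) -> None:
    """Bar chart of specificity indices, best antibody first."""
    defined = [e for e in entries if e.result.index is not None]
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ids = [e.result.antibody_id for e in defined]
    vals = [e.result.index for e in defined]
    ax.bar(range(len(ids)), vals, color="tab:blue")
    ax.set_xticks(range(len(ids)), ids, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("specificity index")
    ax.set_ylim(-1, 1)
    ax.axhline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
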