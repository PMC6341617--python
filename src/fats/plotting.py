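"""Per-well score-histogram figures.

One figure per well: lipid score on x, nucleus count on y, a vertical
line at the mean lipid score, and the adipogenic score annotated in the
upper right.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .scoring import WellResult


def plot_well_histogram(result: WellResult, ax=None):
    """Draw one well's lipid-score histogram onto ``ax`` (created if None)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    edges = result.histogram_edges
    counts = result.histogram_counts
    ax.bar(
        edges[:-1],
        counts,
        width=(edges[1:] - edges[:-1]),
        align="edge",
        color="#4878a8",
        edgecolor="none",
    )
    if result.mean_lipid_score is not None:
        ax.axvline(result.mean_lipid_score, color="grey", lw=1.5)
    if result.gate_threshold is not None:
        ax.axvline(result.gate_threshold, color="green", lw=1.0, ls="--")
    score = (
        "n/a"
        if result.adipogenic_score is None
        else f"{result.adipogenic_score:.2f}%"
    )
    ax.text(
        0.98,
        0.95,
        f"adipogenic score: {score}",
        transform=ax.transAxes,
        ha="right",
        va="top",
    )
    ax.set_xlabel("lipid score")
    ax.set_ylabel("nuclei")
    ax.set_title(result.well_id)
    return ax


def save_well_histograms(results: list[WellResult], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    for result in results:
        ax = plot_well_histogram(result)
        fig = ax.figure
        fig.tight_layout()
        fig.savefig(out_dir / f"histogram_{result.well_id}.png", dpi=120)
        plt.close(fig)
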