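"""Quadrant plot of segments in the awareness-want unit square."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless rendering

import matplotlib.pyplot as plt

from .classification import ClassificationBands, DEFAULT_BANDS
from .survey_data import SegmentSummary


def plot_segment_matrix(
    summaries: Sequence[SegmentSummary],
    bands: ClassificationBands = DEFAULT_BANDS,
    path: str | None = None,
    want_on_x: bool = True,
    title: str | None = None,
) -> plt.Figure:
    """Scatter segments with grid lines at the band cuts.

    Convention (configurable): want on x, awareness on y, origin bottom
    left, so the high-awareness/low-want corner — the improvement
    direction's "top left" — is up-left.  The two 45° reference diagonals
    mark awareness = want and awareness + want = 1.
    """
    fig, ax = plt.subplots(figsize=(6.5, 6.5))
    for cut in bands.cuts:
        ax.axvline(cut, color="0.6", lw=0.8, ls="--" if cut != 0.5 else "-")
        ax.axhline(cut, color="0.6", lw=0.8, ls="--" if cut != 0.5 else "-")
    ax.plot([0, 1], [0, 1], color="0.8", lw=0.8)
    ax.plot([0, 1], [1, 0], color="0.8", lw=0.8)
    for s in summaries:
        if s.aware_rate is None or s.want_rate is None:
            continue
        x, y = (
            (s.want_rate, s.aware_rate) if want_on_x else (s.aware_rate, s.want_rate)
        )
        ax.plot(x, y, "o", ms=4, color="tab:blue")
        ax.annotate(s.item_id, (x, y), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("want rate" if want_on_x else "awareness rate")
    ax.set_ylabel("awareness rate" if want_on_x else "want rate")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
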