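"""Per-gene dot plot of sgRNA dropout scores with the segment overlay."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .io import CKHSRegion, REMOVED, TilingProfile
from .segmentation import Segmentation


def plot_profile(
    profile: TilingProfile,
    segmentation: Segmentation | None = None,
    regions: Sequence[CKHSRegion] = (),
    ax=None,
):
    """Dropout Z-score per sgRNA cut site: filtered points greyed out,
    kept points in blue, the piecewise-constant segment fit as a red line
    and called CKHS regions shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    removed = profile.flags == REMOVED
    ax.scatter(
        profile.aa_pos[removed], profile.score[removed],
        s=12, color="0.7", label="filtered sgRNA",
    )
    ax.scatter(
        profile.aa_pos[~removed], profile.score[~removed],
        s=12, color="tab:blue", label="sgRNA",
    )
    if segmentation is not None:
        for seg in segmentation.segments:
            ax.plot([seg.aa_start, seg.aa_end], [seg.s, seg.s],
                    color="tab:red", lw=2)
    for r in regions:
        ax.axvspan(r.start_aa, r.end_aa, color="tab:red", alpha=0.15)
    ax.axhline(0.0, color="0.5", lw=0.5)
    ax.set_xlabel("amino-acid position")
    ax.set_ylabel("dropout Z-score")
    ax.set_title(profile.gene)
    ax.legend(loc="lower right", fontsize=8)
    return ax
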