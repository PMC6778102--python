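"""CKHS region calling: the k-mean-like (k = 2) iterative assignment rule.

Segments are sorted in ascending order of their mean viability score s_i
(most negative = strongest dropout = most CRISPR-knockout sensitive
first).  The most sensitive segment is always assigned to the CKHS class;
then, walking down the sorted list, segment i joins the CKHS class while

    s_i < (m_assigned + m_unassigned) / 2,

where m_assigned and m_unassigned summarize the already-assigned and the
still-unassigned segments; the walk stops at the first failure.  Finally,
CKHS segments that are adjacent in protein coordinates are merged into a
single CKHS region and scored by the mean of their member points.

Two definitions of the class summaries are provided.  The ``weighted``
mode (default) uses per-data-point class means sum(s_j k_j)/sum(k_j).
The ``printed`` mode divides the same k-weighted sums by segment *counts*:

    m_assigned   = (1/(i-1)) * sum_{j<i} s_j k_j
    m_unassigned = (1/(n-i)) * sum_{j>i} s_j k_j

which is not a weighted mean, is not shift-equivariant when the k_j
differ, and at realistic segment sizes stops the walk after one segment;
it coincides with the weighted mode when every k_j = 1 and is retained
for comparison.  Because m_unassigned averages over the n-i segments
strictly after i, the walk runs only to i = n-1 and the weakest segment
can never be assigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .denoise import DenoiseParams, denoise
from .io import CKHSRegion, TilingProfile
from .segmentation import Segment, Segmentation, TGUHParams, tguh_segment


@dataclass
class CallingParams:
    """mean_mode: 'weighted' (k-weighted means, default) or 'printed'
    (verbatim count-normalized formulas); min_segments guards against
    labeling a segmentation-free protein wholly CKHS.

    The verbatim formulas divide the k-weighted score sums by segment
    counts, so with realistic segment sizes (k in the tens to hundreds)
    the class summaries are tens of times larger in magnitude than any
    segment mean and the walk always stops after one segment — multi-
    region proteins become uncallable.  The weighted mode divides by
    sum(k_j), i.e. uses per-data-point class means, which reproduces the
    intended k-mean-like behavior at every segment size and reduces to
    the verbatim formulas when all k_j = 1.  Weighted is therefore the
    default; printed mode is kept for fidelity studies.
    """

    mean_mode: str = "weighted"
    min_segments: int = 2
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.mean_mode not in ("printed", "weighted"):
            raise ValueError(f"unknown mean_mode {self.mean_mode!r}")


def _sort_key(seg: Segment):
    # ties among equal s: larger k first, then left position
    return (seg.s, -seg.k, seg.aa_start)


def assign_ckhs_segments(
    segments: Sequence[Segment], params: CallingParams | None = None
) -> list[Segment]:
    """Return the segments assigned to the CKHS class (unsorted in protein)."""
    params = params or CallingParams()
    n = len(segments)
    if n < params.min_segments:
        return []
    order = sorted(segments, key=_sort_key)
    s = np.array([seg.s for seg in order])
    k = np.array([seg.k for seg in order], dtype=float)
    sk = s * k
    assigned = [order[0]]
    for i in range(2, n):  # 1-based i in 2..n-1; m_unassigned needs n-i > 0
        if params.mean_mode == "printed":
            m_assigned = sk[: i - 1].sum() / (i - 1)
            m_unassigned = sk[i:].sum() / (n - i)
        else:
            m_assigned = sk[: i - 1].sum() / k[: i - 1].sum()
            m_unassigned = sk[i:].sum() / k[i:].sum()
        if s[i - 1] < (m_assigned + m_unassigned) / 2.0:
            assigned.append(order[i - 1])
        else:
            break
    return assigned


def merge_regions(
    regions: Sequence[CKHSRegion], max_gap: int = 0
) -> list[CKHSRegion]:
    """Transitively merge regions separated by at most ``max_gap`` AAs.

    The gap between consecutive regions is start_{i+1} - end_i - 1; with
    the default max_gap 0 only AA-adjacent regions merge, while the
    region-prediction post-processing uses max_gap 2 ("closer than 3 AA").
    Merged scores are n_points-weighted means.
    """
    if not regions:
        return []
    regs = sorted(regions, key=lambda r: (r.gene, r.start_aa, r.end_aa))
    for a, b in zip(regs[:-1], regs[1:]):
        if a.gene == b.gene and b.start_aa <= a.end_aa:
            raise ValueError(
                f"overlapping regions {a.gene}:{a.start_aa}-{a.end_aa} and "
                f"{b.start_aa}-{b.end_aa}"
            )
    out: list[CKHSRegion] = []
    cur = regs[0]
    for r in regs[1:]:
        gap = r.start_aa - cur.end_aa - 1
        if r.gene == cur.gene and gap <= max_gap:
            total = cur.n_points + r.n_points
            score = (
                (cur.score * cur.n_points + r.score * r.n_points) / total
                if total > 0
                else 0.5 * (cur.score + r.score)
            )
            cur = CKHSRegion(
                gene=cur.gene,
                start_aa=cur.start_aa,
                end_aa=r.end_aa,
                score=score,
                n_points=total,
            )
        else:
            out.append(cur)
            cur = r
    out.append(cur)
    return out


def call_ckhs(
    segmentation: Segmentation,
    gene: str = "",
    params: CallingParams | None = None,
    values: np.ndarray | None = None,
) -> list[CKHSRegion]:
    """Classify segments into CKHS regions.

    After the iterative assignment, CKHS segments adjacent in the protein
    are merged; each merged region's score is recomputed as the mean of
    its member points (``values`` are the segmented scores; if omitted the
    k-weighted mean of segment scores is used, which is identical).
    """
    params = params or CallingParams()
    chosen = assign_ckhs_segments(segmentation.segments, params)
    if not chosen:
        return []
    regions = []
    for seg in sorted(chosen, key=lambda g: g.aa_start):
        if values is not None:
            member = np.asarray(values, float)[seg.first_idx: seg.last_idx + 1]
            score = float(member.mean())
        else:
            score = seg.s
        regions.append(
            CKHSRegion(
                gene=gene,
                start_aa=seg.aa_start,
                end_aa=seg.aa_end,
                score=score,
                n_points=seg.k,
            )
        )
    return merge_regions(regions, max_gap=params.merge_gap)


def call_regions(
    profile: TilingProfile,
    denoise_params: DenoiseParams | None = None,
    tguh_params: TGUHParams | None = None,
    calling_params: CallingParams | None = None,
) -> list[CKHSRegion]:
    """Full three-step pipeline on one tiling profile.

    (1) weak-signal removal and outlier clamping, (2) TGUH segmentation of
    the kept points, (3) iterative CKHS assignment and adjacent-segment
    merging.  Returns the called regions (possibly empty).
    """
    if len(profile) == 0:
        return []
    clean = denoise(profile, denoise_params)
    values = clean.kept_scores
    if values.size == 0:
        return []
    seg = tguh_segment(values, tguh_params, aa_pos=clean.kept_aa)
    return call_ckhs(seg, gene=profile.gene, params=calling_params, values=values)
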