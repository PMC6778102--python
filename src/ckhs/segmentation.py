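"""Tail-greedy unbalanced Haar (TGUH) changepoint segmentation.

The denoised per-protein signal is modeled as piecewise constant plus
noise.  TGUH builds a merge tree bottom-up: starting from singleton
regions, each pass computes for every adjacent region pair (a, b) the
unbalanced Haar detail coefficient

    d = sqrt(n_a * n_b / (n_a + n_b)) * (mean_a - mean_b),

then merges a fixed fraction rho of the pairs with smallest |d| (the
"tail" of the detail distribution), skipping pairs that share a region
with a pair already merged in the same pass.  The bottom-up strategy makes
the method markedly better at recognizing small segments than top-down
binary segmentation.

Changepoints are the child boundaries of merge nodes whose |detail|
exceeds the universal-style threshold lambda = C * sigma * sqrt(2 ln n),
with sigma estimated robustly from first differences.  Because the tree is
built independently of the threshold, raising C can only remove
changepoints, never add them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class TGUHParams:
    """Tuning constants for the TGUH transform.

    rho
        Fraction of adjacent pairs merged per pass (at least one merge per
        pass is always performed).
    thresh_const
        The constant C in the detail threshold lambda = C*sigma*sqrt(2 ln n).
    """

    rho: float = 0.01
    thresh_const: float = math.sqrt(3.0)

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if self.thresh_const < 0:
            raise ValueError("thresh_const must be >= 0")


@dataclass(frozen=True)
class MergeNode:
    """One bottom-up merge: the boundary between two adjacent regions.

    ``support_first``/``support_last`` delimit the merged region; the
    unbalanced Haar wavelet attached to this node is constant-positive on
    the left child, constant-negative on the right child and zero outside
    the support, so a reconstruction that uses this coefficient jumps at
    the internal boundary *and* at the support edges.
    """

    boundary: int  # last point index of the left child region
    n_left: int
    n_right: int
    detail: float
    order: int  # merge timestamp
    support_first: int = 0
    support_last: int = 0


@dataclass(frozen=True)
class Segment:
    """A maximal constant piece: point count, mean score and AA extent."""

    k: int
    s: float
    aa_start: int
    aa_end: int
    first_idx: int
    last_idx: int


@dataclass
class Segmentation:
    """A changepoint set over the kept points of one profile.

    ``boundaries`` lists the last point index of every segment but the
    final one; ``segments`` carries per-segment point counts k_i, exact
    mean scores s_i and amino-acid extents.
    """

    boundaries: list[int]
    segments: list[Segment]
    tree: list[MergeNode] = field(default_factory=list)
    sigma: float = 0.0
    threshold: float = 0.0

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def diff_mad_sigma(values: np.ndarray) -> float:
    """Gaussian-consistent sigma from first differences.

    median(|diff|) / (0.6745 * sqrt(2)): the 0.6745 factor calibrates the
    MAD to a normal sigma and sqrt(2) undoes the variance inflation of
    differencing.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    d = np.diff(values)
    return float(np.median(np.abs(d))) / (0.6745 * math.sqrt(2.0))


def _haar_detail(n_a: int, sum_a: float, n_b: int, sum_b: float) -> float:
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    return math.sqrt(n_a * n_b / (n_a + n_b)) * (mean_a - mean_b)


def build_merge_tree(values: np.ndarray, rho: float) -> list[MergeNode]:
    """Full bottom-up unary-binary merge tree of an input vector.

    Each pass ranks adjacent-pair details by (|d|, left position) and
    greedily merges the ceil(rho * #pairs) smallest, skipping any pair that
    shares a region with a merge already taken in the pass.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    # region bookkeeping: contiguous blocks with cached count and sum
    counts = [1] * n
    sums = [float(v) for v in values]
    first_idx = list(range(n))  # first point index of each region
    last_idx = list(range(n))  # last point index of each region
    nodes: list[MergeNode] = []
    order = 0
    while len(counts) > 1:
        m = len(counts) - 1  # adjacent pairs
        details = [
            _haar_detail(counts[i], sums[i], counts[i + 1], sums[i + 1])
            for i in range(m)
        ]
        ranked = sorted(range(m), key=lambda i: (abs(details[i]), i))
        budget = max(1, math.ceil(rho * m))
        used = [False] * (m + 1)  # region participation this pass
        merged_pairs: list[int] = []
        for i in ranked:
            if len(merged_pairs) >= budget:
                break
            if used[i] or used[i + 1]:
                continue
            used[i] = used[i + 1] = True
            merged_pairs.append(i)
        for i in sorted(merged_pairs):
            nodes.append(
                MergeNode(
                    boundary=last_idx[i],
                    n_left=counts[i],
                    n_right=counts[i + 1],
                    detail=details[i],
                    order=order,
                    support_first=first_idx[i],
                    support_last=last_idx[i + 1],
                )
            )
            order += 1
        # apply merges right-to-left so indices stay valid
        for i in sorted(merged_pairs, reverse=True):
            counts[i] += counts[i + 1]
            sums[i] += sums[i + 1]
            last_idx[i] = last_idx[i + 1]
            del counts[i + 1], sums[i + 1], first_idx[i + 1], last_idx[i + 1]
    return nodes


def segment_viability(
    values: np.ndarray, boundaries: list[int]
) -> list[tuple[int, float]]:
    """Exact per-segment (point count, mean score) for given boundaries."""
    values = np.asarray(values, dtype=float)
    n = values.size
    for b in boundaries:
        if not (0 <= b < n - 1):
            raise ValueError(f"boundary {b} out of range for n={n}")
    edges = [-1] + sorted(boundaries) + [n - 1]
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = values[lo + 1: hi + 1]
        out.append((int(seg.size), float(seg.mean())))
    return out


def tguh_segment(
    values: np.ndarray,
    params: TGUHParams | None = None,
    aa_pos: np.ndarray | None = None,
    sigma: float | None = None,
) -> Segmentation:
    """Segment a 1-D signal into piecewise-constant pieces.

    Builds the full merge tree, hard-thresholds details at
    lambda = C * sigma * sqrt(2 ln n), cuts the signal at every surviving
    boundary and refits each final segment with the exact mean of its
    members.  ``aa_pos`` (optional, same length) attaches amino-acid
    extents to the segments: interior boundaries between segments are
    placed at the midpoint between the flanking member points, so adjacent
    segments receive adjacent AA intervals.
    """
    params = params or TGUHParams()
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return Segmentation(boundaries=[], segments=[])
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    if aa_pos is None:
        aa_pos = np.arange(1, n + 1)
    aa_pos = np.asarray(aa_pos, dtype=int)

    if sigma is None:
        sigma = diff_mad_sigma(values)
    lam = params.thresh_const * sigma * math.sqrt(2.0 * math.log(n)) if n > 1 else 0.0

    tree = build_merge_tree(values, params.rho)
    cuts: set[int] = set()
    for nd in tree:
        if abs(nd.detail) > lam:
            # jumps of the thresholded reconstruction: the internal child
            # boundary plus the node's support edges (region boundaries
            # forced by ancestor merges), excluding the global ends
            cuts.add(nd.boundary)
            if nd.support_first > 0:
                cuts.add(nd.support_first - 1)
            if nd.support_last < n - 1:
                cuts.add(nd.support_last)
    boundaries = sorted(cuts)

    kvals = segment_viability(values, boundaries)
    edges = [-1] + boundaries + [n - 1]
    segments = []
    for (lo, hi), (k, s) in zip(zip(edges[:-1], edges[1:]), kvals):
        first, last = lo + 1, hi
        segments.append(
            Segment(
                k=k,
                s=s,
                aa_start=int(aa_pos[first]),
                aa_end=int(aa_pos[last]),
                first_idx=first,
                last_idx=last,
            )
        )
    # midpoint rule: assign inter-point AA gaps to the nearer segment
    segments = _midpoint_extents(segments, aa_pos)
    return Segmentation(
        boundaries=boundaries,
        segments=segments,
        tree=tree,
        sigma=sigma,
        threshold=lam,
    )


def _midpoint_extents(segments: list[Segment], aa_pos: np.ndarray) -> list[Segment]:
    if len(segments) <= 1:
        return segments
    out = list(segments)
    for i in range(len(out) - 1):
        left, right = out[i], out[i + 1]
        cut = int(aa_pos[left.last_idx] + aa_pos[right.first_idx]) // 2
        # degenerate guards: tied positions across the boundary
        cut = max(cut, left.aa_start)
        cut = min(cut, right.aa_end - 1)
        out[i] = Segment(left.k, left.s, left.aa_start, cut,
                         left.first_idx, left.last_idx)
        out[i + 1] = Segment(right.k, right.s, cut + 1,
                             right.aa_end, right.first_idx, right.last_idx)
    return out


def reconstruct(values: np.ndarray, segmentation: Segmentation) -> np.ndarray:
    """Piecewise-constant fit: each point replaced by its segment mean."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for seg in segmentation.segments:
        out[seg.first_idx: seg.last_idx + 1] = seg.s
    return out
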