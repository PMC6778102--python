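"""Two-step denoising of a tiling profile before segmentation.

Roughly one third of PAM-appended tiling sgRNAs are inactive and carry a
weak dropout signal regardless of where they cut.  Step one removes points
that are weaker than the bulk of their flanking neighbors.  Step two clamps
the surviving outliers (non-Gaussian variation, additive off-target hits)
toward the local median, using a robust noise scale estimated from
consecutive-signal differences.

Both steps are single-pass: every decision is made against the original,
unmodified profile, so results do not depend on processing order and no
removal can cascade into further removals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ADJUSTED, KEPT, REMOVED, TilingProfile


@dataclass
class DenoiseParams:
    """Tuning constants for weak-signal removal and outlier clamping.

    k_neighbors
        Number of flanking points compared on each side; 5 corresponds to
        an average window span of roughly 30 AA at typical tiling density,
        the size of the smallest domain module.
    weak_fraction
        A point is dropped when it is weaker (higher score) than at least
        this fraction of its available neighbors on *both* sides.
    window
        Sliding-window size (in kept points, odd) for the outlier median.
    clamp_mult
        Outliers are clamped to median +/- clamp_mult * MAD.
    mad_scaled
        If True, scale the MAD by 1/(0.6745*sqrt(2)) so it estimates the
        Gaussian sigma of the underlying noise; the default keeps the
        literal unscaled MAD of the differences.
    cascade
        If True, re-evaluate weak-signal removal against already-filtered
        data until a fixed point (off by default; single pass).
    """

    k_neighbors: int = 5
    weak_fraction: float = 2.0 / 3.0
    window: int = 11
    clamp_mult: float = 2.0
    mad_scaled: bool = False
    cascade: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0 < self.weak_fraction <= 1):
            raise ValueError("weak_fraction must be in (0, 1]")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.clamp_mult <= 0:
            raise ValueError("clamp_mult must be > 0")


def _weak_mask(scores: np.ndarray, k: int, frac: float) -> np.ndarray:
    """Mask of points weaker than ``frac`` of both neighbor sets."""
    n = scores.size
    removed = np.zeros(n, dtype=bool)
    for i in range(n):
        left = scores[max(0, i - k): i]
        right = scores[i + 1: i + 1 + k]
        # terminal guard: too few neighbors on either side -> never removed
        if left.size < 2 or right.size < 2:
            continue
        need_left = math.ceil(frac * left.size)
        need_right = math.ceil(frac * right.size)
        if (
            np.sum(scores[i] > left) >= need_left
            and np.sum(scores[i] > right) >= need_right
        ):
            removed[i] = True
    return removed


def remove_weak_signals(
    profile: TilingProfile, params: DenoiseParams | None = None
) -> TilingProfile:
    """Flag likely-inactive sgRNA points as removed.

    A point is removed iff its score is strictly greater (weaker dropout)
    than at least ceil(weak_fraction * L) of its L available left neighbors
    AND ceil(weak_fraction * R) of its R available right neighbors, with
    L = min(k, points to the left) and likewise R.  Points with fewer than
    two available neighbors on either side are never removed.
    """
    params = params or DenoiseParams()
    flags = profile.flags.copy()
    keep_idx = np.flatnonzero(flags != REMOVED)
    while True:
        scores = profile.score[keep_idx]
        removed = _weak_mask(scores, params.k_neighbors, params.weak_fraction)
        flags[keep_idx[removed]] = REMOVED
        keep_idx = keep_idx[~removed]
        if not params.cascade or not removed.any():
            break
    return profile.with_updates(flags=flags)


def noise_mad(profile: TilingProfile, scaled: bool = False) -> float:
    """Robust noise scale from consecutive-signal differences.

    Computes the median absolute deviation of the first differences of the
    kept scores in position order.  Unscaled by default; ``scaled=True``
    divides by 0.6745*sqrt(2) for a Gaussian-consistent sigma estimate
    (differencing inflates the noise by sqrt(2)).
    """
    kept = profile.kept_scores
    if kept.size < 3:
        raise ValueError(
            f"{profile.gene}: need >= 3 kept points to estimate noise, "
            f"have {kept.size}"
        )
    d = np.diff(kept)
    mad = float(np.median(np.abs(d - np.median(d))))
    if scaled:
        mad /= 0.6745 * math.sqrt(2.0)
    return mad


def adjust_outliers(
    profile: TilingProfile,
    params: DenoiseParams | None = None,
    sigma: float | None = None,
) -> TilingProfile:
    """Clamp outliers toward the local median of a sliding window.

    For every kept point x the window holds up to (window-1)/2 kept points
    on each side, excluding x itself; with m the window median and sigma
    the profile's MAD noise scale, x is clamped into
    [m - clamp_mult*sigma, m + clamp_mult*sigma].  All medians are taken
    on the original values (single pass).
    """
    params = params or DenoiseParams()
    if sigma is None:
        sigma = noise_mad(profile, scaled=params.mad_scaled)
    half = (params.window - 1) // 2
    keep_idx = np.flatnonzero(profile.kept_mask)
    scores = profile.score[keep_idx]
    new_score = profile.score.copy()
    flags = profile.flags.copy()
    for j in range(keep_idx.size):
        neigh = np.concatenate(
            [scores[max(0, j - half): j], scores[j + 1: j + 1 + half]]
        )
        if neigh.size == 0:
            continue
        m = float(np.median(neigh))
        hi = m + params.clamp_mult * sigma
        lo = m - params.clamp_mult * sigma
        x = scores[j]
        if x > hi:
            new_score[keep_idx[j]] = hi
            flags[keep_idx[j]] = ADJUSTED
        elif x < lo:
            new_score[keep_idx[j]] = lo
            flags[keep_idx[j]] = ADJUSTED
    return profile.with_updates(score=new_score, flags=flags)


def denoise(
    profile: TilingProfile, params: DenoiseParams | None = None
) -> TilingProfile:
    """Weak-signal removal followed by outlier adjustment."""
    params = params or DenoiseParams()
    filtered = remove_weak_signals(profile, params)
    if filtered.kept_scores.size < 3:
        return filtered
    return adjust_outliers(filtered, params)
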