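import numpy as np
import pytest

from ckhs import TilingProfile


@pytest.fixture
def make_profile():
    """Build a TilingProfile from a score list (positions 1..n by default)."""

    def _make(scores, aa_pos=None, gene="GENE", protein_length=None):
        scores = np.asarray(scores, dtype=float)
        if aa_pos is None:
            aa_pos = np.arange(1, scores.size + 1)
        aa_pos = np.asarray(aa_pos, dtype=int)
        if protein_length is None:
            protein_length = int(aa_pos.max()) if aa_pos.size else 1
        return TilingProfile(
            gene=gene, protein_length=protein_length, aa_pos=aa_pos, score=scores
        )

    return _make


def ls_changepoints(values, n_changepoints):
    """Exhaustive least-squares changepoint oracle (0, 1 or 2 cuts).

    Independent of the segmentation code: minimizes the residual sum of
    squares over all placements by brute force using cumulative sums.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    c = np.concatenate([[0.0], np.cumsum(values)])
    c2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(i, j):
        s = c[j + 1] - c[i]
        return (c2[j + 1] - c2[i]) - s * s / (j - i + 1)

    if n_changepoints == 0:
        return ()
    if n_changepoints == 1:
        return (min(range(n - 1), key=lambda b: sse(0, b) + sse(b + 1, n - 1)),)
    if n_changepoints == 2:
        best = None
        for b1 in range(n - 2):
            left = sse(0, b1)
            for b2 in range(b1 + 1, n - 1):
                tot = left + sse(b1 + 1, b2) + sse(b2 + 1, n - 1)
                if best is None or tot < best[0]:
                    best = (tot, b1, b2)
        return best[1:]
    raise ValueError("oracle supports at most 2 changepoints")


def piecewise_signal(rng, n, n_jumps, jump_lo=5.0, jump_hi=8.0, min_seg=8):
    """Random piecewise-constant signal with given jump count and minimum
    segment length; jumps of magnitude in [jump_lo, jump_hi]."""
    while True:
        bs = np.sort(rng.integers(min_seg, n - min_seg, size=n_jumps))
        if n_jumps < 2 or np.all(np.diff(bs) >= min_seg):
            break
    levels = [0.0]
    for _ in range(n_jumps):
        levels.append(levels[-1] + rng.choice([-1, 1]) * rng.uniform(jump_lo, jump_hi))
    sig = np.zeros(n)
    edges = [-1] + list(bs) + [n - 1]
    for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sig[lo + 1: hi + 1] = levels[k]
    return sig, tuple(int(b) for b in bs)
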