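"""Synthetic tiling-screen and feature-set generators with known truth.

The screen generator emulates the data model the region-calling pipeline
assumes: sgRNA cut sites scattered uniformly across the protein at a
configurable density, a piecewise-constant dropout mean (baseline plus a
negative effect inside planted hyper-sensitive regions), Gaussian noise,
a fraction of inactive sgRNAs whose dropout signal collapses toward zero
regardless of where they cut, and sparse strong outliers.  Everything is
driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CKHSRegion, DomainAnnotation, TilingProfile
from .prediction import PTM_TYPES, encode_features, labels_from_regions


@dataclass
class SyntheticSpec:
    """Generative parameters for one simulated tiling profile.

    planted_regions are (start_aa, end_aa, effect) with effect < 0 added
    to the baseline inside the region.  inactive_shift is the score added
    to inactive sgRNAs (toward 0); None means full signal loss, i.e. the
    point's mean is reset to 0.  outlier displacement is
    +/- outlier_scale * noise_sd with random sign.
    """

    protein_length: int = 600
    planted_regions: list[tuple[int, int, float]] = field(default_factory=list)
    baseline: float = -0.2
    noise_sd: float = 0.4
    sgrna_density: float = 0.5
    inactive_frac: float = 1.0 / 3.0
    inactive_shift: float | None = None
    outlier_frac: float = 0.02
    outlier_scale: float = 5.0
    seed: int = 0
    gene: str = "SIM"

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for frac, name in (
            (self.inactive_frac, "inactive_frac"),
            (self.outlier_frac, "outlier_frac"),
        ):
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sgrna_density <= 0:
            raise ValueError("sgrna_density must be > 0")
        last = 0
        for start, end, effect in sorted(self.planted_regions):
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(f"planted region {start}-{end} outside protein")
            if start <= last:
                raise ValueError("planted regions must be disjoint")
            last = end


def simulate_screen(spec: SyntheticSpec) -> tuple[TilingProfile, list[CKHSRegion]]:
    """Generate one tiling profile plus its ground-truth regions."""
    rng = np.random.default_rng(spec.seed)
    n = max(2, int(round(spec.sgrna_density * spec.protein_length)))
    aa = np.sort(rng.integers(1, spec.protein_length + 1, size=n))

    mean = np.full(n, spec.baseline)
    for start, end, effect in spec.planted_regions:
        mean[(aa >= start) & (aa <= end)] += effect

    inactive = rng.random(n) < spec.inactive_frac
    if spec.inactive_shift is None:
        mean[inactive] = 0.0  # full signal loss
    else:
        # shift toward zero, never past it
        mean[inactive] = np.minimum(mean[inactive] + abs(spec.inactive_shift), 0.0)

    score = mean + rng.normal(0.0, spec.noise_sd, size=n)

    outlier = rng.random(n) < spec.outlier_frac
    signs = rng.choice([-1.0, 1.0], size=n)
    score[outlier] += signs[outlier] * spec.outlier_scale * spec.noise_sd

    profile = TilingProfile(
        gene=spec.gene,
        protein_length=spec.protein_length,
        aa_pos=aa,
        score=score,
    )
    truth = [
        CKHSRegion(
            gene=spec.gene,
            start_aa=start,
            end_aa=end,
            score=spec.baseline + effect,
            n_points=int(((aa >= start) & (aa <= end)).sum()),
        )
        for start, end, effect in sorted(spec.planted_regions)
    ]
    return profile, truth


def screen_table(
    profiles: Sequence[TilingProfile], lines: Sequence[str] = ("A",)
) -> pd.DataFrame:
    """Render simulated profiles as a tiling-screen table (one Z-score
    column per cell line; all lines share the simulated scores)."""
    rows = []
    for prof in profiles:
        for i, (pos, score) in enumerate(zip(prof.aa_pos, prof.score)):
            row = {
                "gene": prof.gene,
                "sgrna_id": f"{prof.gene}_{i}",
                "aa_pos": int(pos),
            }
            for line in lines:
                row[f"zscore_{line}"] = float(score)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FeatureEffectSpec:
    """Label-feature association strengths for the feature simulator.

    domain_match_rate: probability that an AA's domain flag equals its
    CKHS label (0.5 = no association).  conservation_shift: amount
    subtracted from the conservation track inside CKHS regions (0 = no
    association).  ptm_ratio: PTM site density inside CKHS relative to
    outside (1 = no association; the screens show depletion, ratio < 1).
    ss_helix_boost: excess helix probability inside CKHS regions.
    """

    domain_match_rate: float = 0.5
    conservation_shift: float = 0.0
    conservation_sd: float = 1.0
    ptm_ratio: float = 1.0
    ptm_base_density: float = 0.05
    ss_helix_boost: float = 0.0


def simulate_feature_set(
    n_genes: int,
    length_range: tuple[int, int] = (200, 500),
    effect: FeatureEffectSpec | None = None,
    seed: int = 0,
    region_frac: float = 0.3,
) -> tuple[pd.DataFrame, list[CKHSRegion], dict[str, int]]:
    """Simulate labeled per-AA feature matrices for several genes.

    Each gene gets one or two planted CKHS regions covering roughly
    ``region_frac`` of its length; feature tracks are generated with the
    configured label association and run through the same encoding
    (smoothing, centering, two-bit secondary structure) as real inputs.
    Returns the stacked feature matrix, the truth regions and the protein
    lengths.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    effect = effect or FeatureEffectSpec()
    rng = np.random.default_rng(seed)
    frames = []
    truth: list[CKHSRegion] = []
    lengths: dict[str, int] = {}
    for g in range(n_genes):
        gene = f"G{g:03d}"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        lengths[gene] = L
        n_regions = int(rng.integers(1, 3))
        total = max(10, int(region_frac * L))
        sizes = [total // n_regions] * n_regions
        regions = []
        cursor = 1
        for size in sizes:
            room = L - cursor - size
            if room < 1:
                break
            start = int(rng.integers(cursor, cursor + room // max(1, n_regions) + 1))
            regions.append((start, min(start + size - 1, L)))
            cursor = regions[-1][1] + max(10, size // 2)
        label = np.zeros(L, dtype=int)
        for start, end in regions:
            label[start - 1: end] = 1
            truth.append(CKHSRegion(gene, start, end, -1.0, end - start + 1))

        match = rng.random(L) < effect.domain_match_rate
        flag = np.where(match, label, 1 - label)
        # express domain flag as interval annotations for the encoder
        domains = _runs_to_domains(gene, flag)

        cons = rng.normal(0.0, effect.conservation_sd, size=L)
        cons -= effect.conservation_shift * label

        p_helix = np.clip(0.3 + effect.ss_helix_boost * label, 0, 1)
        draw = rng.random(L)
        ss = np.where(draw < p_helix, "H", np.where(draw < p_helix + 0.2, "E", "C"))

        ptm_sites: dict[str, list[int]] = {}
        dens_in = effect.ptm_base_density * effect.ptm_ratio
        dens_out = effect.ptm_base_density
        for ptype in PTM_TYPES:
            density = np.where(label == 1, dens_in, dens_out)
            hit = rng.random(L) < density
            ptm_sites[ptype] = list(np.flatnonzero(hit) + 1)

        frames.append(
            encode_features(
                protein=gene,
                protein_length=L,
                domains=domains,
                conservation=cons,
                ss_labels=list(ss),
                ptm_sites=ptm_sites,
                labels=label,
            )
        )
    return pd.concat(frames, ignore_index=True), truth, lengths


def _runs_to_domains(gene: str, flag: np.ndarray) -> list[DomainAnnotation]:
    out = []
    start = None
    for i, f in enumerate(flag):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append(DomainAnnotation(gene, f"dom{len(out)}", start + 1, i))
            start = None
    if start is not None:
        out.append(DomainAnnotation(gene, f"dom{len(out)}", start + 1, flag.size))
    return out


def region_jaccard(a: CKHSRegion, b: CKHSRegion) -> float:
    """Jaccard index of two AA intervals (0 when on different genes)."""
    if a.gene != b.gene:
        return 0.0
    inter = max(0, min(a.end_aa, b.end_aa) - max(a.start_aa, b.start_aa) + 1)
    union = a.length + b.length - inter
    return inter / union if union else 0.0
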