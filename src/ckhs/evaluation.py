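"""Scoring CKHS calls against domain annotations.

Amino-acid level precision/recall/F1, region-level overlap percentages,
border-distance resolution statistics with a Fisher enrichment test, a
permutation null for the F1 score, a hypergeometric test for PTM density
inside vs outside called regions, and a LOESS-threshold baseline caller
used for method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .calling import merge_regions
from .io import CKHSRegion, DomainAnnotation, TilingProfile


@dataclass
class EvalReport:
    n_identified_aas: int
    precision: float
    recall: float
    f1: float
    n_regions: int
    pct_regions_overlapping_domains: float
    pct_domains_identified: float
    pct_left_borders_within_20aa: float
    pct_right_borders_within_20aa: float

    def to_dict(self) -> dict:
        return asdict(self)


def _region_aas(regions: Sequence[CKHSRegion]) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for r in regions:
        out.setdefault(r.gene, set()).update(range(r.start_aa, r.end_aa + 1))
    return out


def _domain_aas(domains: Sequence[DomainAnnotation]) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for d in domains:
        out.setdefault(d.protein, set()).update(range(d.start_aa, d.end_aa + 1))
    return out


def f1_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def aa_metrics(
    regions: Sequence[CKHSRegion],
    domains: Sequence[DomainAnnotation],
    protein_lengths: Mapping[str, int],
) -> tuple[float, float, float]:
    """AA-level precision, recall and F1 over the pooled protein set.

    Precision is the proportion of amino acids inside called regions that
    lie within annotated domains; recall is the proportion of annotated
    domain amino acids recovered by the calls.  Undefined ratios (no
    called AAs / no domain AAs) are 0 by convention, as is F1 when both
    sides vanish.
    """
    for r in regions:
        length = protein_lengths.get(r.gene)
        if length is not None and r.end_aa > length:
            raise ValueError(
                f"region {r.gene}:{r.start_aa}-{r.end_aa} exceeds protein "
                f"length {length}"
            )
    reg = _region_aas(regions)
    dom = _domain_aas(domains)
    n_reg = sum(len(v) for v in reg.values())
    n_dom = sum(len(v) for v in dom.values())
    n_both = sum(len(reg[g] & dom.get(g, set())) for g in reg)
    precision = n_both / n_reg if n_reg else 0.0
    recall = n_both / n_dom if n_dom else 0.0
    return precision, recall, f1_score(precision, recall)


def _overlaps(r: CKHSRegion, d: DomainAnnotation) -> bool:
    return r.gene == d.protein and r.start_aa <= d.end_aa and d.start_aa <= r.end_aa


def region_domain_overlap(
    regions: Sequence[CKHSRegion], domains: Sequence[DomainAnnotation]
) -> dict:
    """Region-level specificity and sensitivity percentages.

    Returns the percentage of called regions overlapping (sharing >= 1 AA
    with) any annotated domain, and the percentage of annotated domains
    touched by any called region, with explicit numerators/denominators.
    """
    n_regions = len(regions)
    n_domains = len(domains)
    n_reg_overlap = sum(any(_overlaps(r, d) for d in domains) for r in regions)
    n_dom_identified = sum(any(_overlaps(r, d) for r in regions) for d in domains)
    return {
        "n_regions": n_regions,
        "n_regions_overlapping": n_reg_overlap,
        "pct_regions_overlapping": 100.0 * n_reg_overlap / n_regions if n_regions else 0.0,
        "n_domains": n_domains,
        "n_domains_identified": n_dom_identified,
        "pct_domains_identified": 100.0 * n_dom_identified / n_domains if n_domains else 0.0,
    }


def border_distances(
    regions: Sequence[CKHSRegion], domains: Sequence[DomainAnnotation]
) -> tuple[list[float], list[float], list[str]]:
    """Signed distance from each region border to the nearest same-side
    domain boundary; negative values are inside the domain.

    Left border: domain_start - region_start (positive when the region
    starts outside, 5'-ward of the domain).  Right border:
    region_end - domain_end (positive when the region ends outside).
    Proteins without any domain are excluded and reported.
    """
    dom_by_prot: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        dom_by_prot.setdefault(d.protein, []).append(d)
    left, right, skipped = [], [], []
    for r in regions:
        doms = dom_by_prot.get(r.gene)
        if not doms:
            skipped.append(r.gene)
            continue
        left.append(min((d.start_aa - r.start_aa for d in doms), key=abs))
        right.append(min((r.end_aa - d.end_aa for d in doms), key=abs))
    return left, right, skipped


def border_distance_enrichment(
    regions: Sequence[CKHSRegion],
    domains: Sequence[DomainAnnotation],
    protein_lengths: Mapping[str, int],
    window: int = 20,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Fisher's exact enrichment of region borders near domain boundaries.

    The observed within-``window`` counts are compared, per side, against
    borders of position-matched random regions (same count and lengths per
    protein, placed uniformly without overlap) in a 2x2 table, one-sided
    toward enrichment.
    """
    obs_left, obs_right, skipped = border_distances(regions, domains)
    rng = np.random.default_rng(seed)
    null_left: list[float] = []
    null_right: list[float] = []
    for _ in range(n_perm):
        placed = _random_placement(regions, protein_lengths, rng)
        l, r, _ = border_distances(placed, domains)
        null_left.extend(l)
        null_right.extend(r)

    def fisher(obs: list[float], null: list[float]) -> float:
        if not obs or not null:
            return 1.0
        a = sum(abs(x) <= window for x in obs)
        b = len(obs) - a
        c = sum(abs(x) <= window for x in null)
        d = len(null) - c
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])

    return {
        "left_distances": obs_left,
        "right_distances": obs_right,
        "p_left": fisher(obs_left, null_left),
        "p_right": fisher(obs_right, null_right),
        "pct_left_within": 100.0 * np.mean([abs(x) <= window for x in obs_left]) if obs_left else 0.0,
        "pct_right_within": 100.0 * np.mean([abs(x) <= window for x in obs_right]) if obs_right else 0.0,
        "skipped_proteins": sorted(set(skipped)),
    }


def _random_placement(
    regions: Sequence[CKHSRegion],
    protein_lengths: Mapping[str, int],
    rng: np.random.Generator,
) -> list[CKHSRegion]:
    """Uniform non-overlapping re-placement preserving per-protein region
    count and lengths (stars-and-bars sampling of the gap composition)."""
    by_gene: dict[str, list[CKHSRegion]] = {}
    for r in regions:
        by_gene.setdefault(r.gene, []).append(r)
    out: list[CKHSRegion] = []
    for gene, regs in by_gene.items():
        length = protein_lengths[gene]
        lens = [r.length for r in regs]
        total = sum(lens)
        if total > length:
            raise ValueError(f"{gene}: regions longer than protein")
        m = len(lens)
        free = length - total
        # uniform over gap compositions: m distinct draws from {0..free+m-1}
        marks = np.sort(rng.choice(free + m, size=m, replace=False))
        lensum = 0
        for j, (mark, ln) in enumerate(zip(marks, lens)):
            cumgap = int(mark) - j  # cumulative free space before region j
            start = cumgap + lensum + 1
            out.append(
                CKHSRegion(
                    gene=gene,
                    start_aa=start,
                    end_aa=start + ln - 1,
                    score=regs[j].score,
                    n_points=regs[j].n_points,
                )
            )
            lensum += ln
    return out


def permute_regions(
    regions: Sequence[CKHSRegion],
    domains: Sequence[DomainAnnotation],
    protein_lengths: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Permutation null for the AA-level F1 score.

    Each permutation re-places every region uniformly at random within its
    protein (count and lengths preserved, non-overlapping) and recomputes
    F1; the empirical p-value is (1 + #{null F1 >= observed})/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    _, _, observed = aa_metrics(regions, domains, protein_lengths)
    null = np.empty(n_perm)
    for i in range(n_perm):
        placed = _random_placement(regions, protein_lengths, rng)
        null[i] = aa_metrics(placed, domains, protein_lengths)[2]
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return null, float(p)


@dataclass
class PTMDensityResult:
    density_in: float
    density_out: float
    p_value: float
    direction: str  # 'depletion' or 'enrichment'
    p_depletion: float
    p_enrichment: float
    n_in: int
    n_out: int
    aa_in: int
    aa_out: int


def ptm_density(
    regions: Sequence[CKHSRegion],
    ptm_positions: Mapping[str, Sequence[int]],
    protein_lengths: Mapping[str, int],
) -> PTMDensityResult:
    """PTM site density inside vs outside CKHS regions, hypergeometric p.

    Population: all AAs of the evaluated proteins.  Successes: AAs bearing
    at least one PTM site of the chosen type.  Draws: AAs inside CKHS
    regions.  The headline p-value is the one-sided tail in the direction
    of the observed effect (labeled); both fixed-direction tails are also
    returned.
    """
    reg = _region_aas(regions)
    N = int(sum(protein_lengths.values()))
    draws = sum(len(reg.get(g, set()) & set(range(1, L + 1)))
                for g, L in protein_lengths.items())
    ptm_aas = 0
    ptm_in = 0
    for gene, length in protein_lengths.items():
        sites = {p for p in ptm_positions.get(gene, []) if 1 <= p <= length}
        ptm_aas += len(sites)
        ptm_in += len(sites & reg.get(gene, set()))
    aa_in = draws
    aa_out = N - draws
    density_in = ptm_in / aa_in if aa_in else 0.0
    density_out = (ptm_aas - ptm_in) / aa_out if aa_out else 0.0
    if ptm_aas == 0:
        return PTMDensityResult(0.0, 0.0, 1.0, "depletion", 1.0, 1.0,
                                0, 0, aa_in, aa_out)
    hg = stats.hypergeom(N, ptm_aas, aa_in)
    p_depl = float(hg.cdf(ptm_in))
    p_enr = float(hg.sf(ptm_in - 1))
    if density_in < density_out:
        direction, p = "depletion", p_depl
    else:
        direction, p = "enrichment", p_enr
    return PTMDensityResult(
        density_in=density_in,
        density_out=density_out,
        p_value=min(p, 1.0),
        direction=direction,
        p_depletion=p_depl,
        p_enrichment=p_enr,
        n_in=ptm_in,
        n_out=ptm_aas - ptm_in,
        aa_in=aa_in,
        aa_out=aa_out,
    )


def loess_baseline_call(
    profile: TilingProfile,
    aa_budget: int,
    span: float = 0.1,
    merge_gap: int = 2,
) -> list[CKHSRegion]:
    """LOESS-threshold baseline: smooth, take the ``aa_budget`` most
    negative amino acids, merge runs closer than ``merge_gap``+1 AA.

    The smoothed score is a local-linear LOESS fit of the kept points,
    evaluated on the full 1..protein_length grid with span a fraction of
    the protein length.  Exactly ``aa_budget`` AAs are flagged; ties are
    broken by more negative smoothed score, then left position, so the
    flagged count is exact (budget-matched comparisons need this).
    """
    if aa_budget <= 0:
        raise ValueError("aa_budget must be > 0")
    if aa_budget > profile.protein_length:
        raise ValueError("aa_budget exceeds protein length")
    grid = np.arange(1, profile.protein_length + 1, dtype=float)
    x = profile.kept_aa.astype(float)
    y = profile.kept_scores
    if np.unique(x).size < 3:
        smoothed = np.full(grid.shape, float(np.mean(y)))
    else:
        fitted = lowess(
            y, x, frac=min(1.0, max(span, 3.0 / np.unique(x).size)),
            return_sorted=True,
        )
        # collapse duplicate positions, then interpolate onto the AA grid
        # (np.interp holds the terminal fitted values beyond the data)
        xs, inverse = np.unique(fitted[:, 0], return_inverse=True)
        fit = np.bincount(inverse, weights=fitted[:, 1]) / np.bincount(inverse)
        smoothed = np.interp(grid, xs, fit)
    # quantize before ordering so exact ties (e.g. constant profiles) break
    # by position instead of floating-point jitter
    order = np.lexsort((grid, np.round(smoothed, 9)))  # score asc, then position
    chosen = np.sort(order[:aa_budget]) + 1  # back to 1-based AAs
    runs: list[CKHSRegion] = []
    start = prev = int(chosen[0])
    for pos in chosen[1:]:
        pos = int(pos)
        if pos == prev + 1:
            prev = pos
            continue
        runs.append(_run_region(profile, start, prev, smoothed))
        start = prev = pos
    runs.append(_run_region(profile, start, prev, smoothed))
    return merge_regions(runs, max_gap=merge_gap)


def _run_region(profile: TilingProfile, start: int, end: int,
                smoothed: np.ndarray) -> CKHSRegion:
    mask = (profile.kept_aa >= start) & (profile.kept_aa <= end)
    return CKHSRegion(
        gene=profile.gene,
        start_aa=start,
        end_aa=end,
        score=float(np.mean(smoothed[start - 1: end])),
        n_points=int(mask.sum()),
    )


def evaluate(
    regions: Sequence[CKHSRegion],
    domains: Sequence[DomainAnnotation],
    protein_lengths: Mapping[str, int],
    border_window: int = 20,
) -> EvalReport:
    """Full evaluation report of a region set against domain annotation."""
    precision, recall, f1 = aa_metrics(regions, domains, protein_lengths)
    ov = region_domain_overlap(regions, domains)
    left, right, _ = border_distances(regions, domains)
    n_aas = sum(len(v) for v in _region_aas(regions).values())
    pct_l = 100.0 * np.mean([abs(x) <= border_window for x in left]) if left else 0.0
    pct_r = 100.0 * np.mean([abs(x) <= border_window for x in right]) if right else 0.0
    return EvalReport(
        n_identified_aas=n_aas,
        precision=precision,
        recall=recall,
        f1=f1,
        n_regions=len(regions),
        pct_regions_overlapping_domains=ov["pct_regions_overlapping"],
        pct_domains_identified=ov["pct_domains_identified"],
        pct_left_borders_within_20aa=pct_l,
        pct_right_borders_within_20aa=pct_r,
    )
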