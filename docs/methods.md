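# Methods

## Signal model

A tiling screen delivers, per gene, an ordered series of (amino-acid
position, dropout Z-score) points — one per sgRNA, the position being the
codon containing the Cas9 cut site (a CDS nucleotide coordinate c maps to
codon ⌈c/3⌉). The working model is piecewise-constant-plus-noise: protein
regions have a constant underlying viability level, more negative inside
essential domains, with three contaminations on top of Gaussian noise:

* **inactive sgRNAs** (~1/3 of a PAM-appended library) whose dropout
  signal collapses toward zero regardless of cut position;
* **sparse outliers** from off-target cutting or non-Gaussian variation;
* uneven sgRNA spacing, since only PAM-adjacent sites are targetable.

Coordinates are 1-based and inclusive. Genes enter the analysis when
their mean sgRNA Z-score is ≤ −0.4 (inclusive) in at least one cell line;
per-sgRNA scores are then averaged over exactly the lines in which the
gene passes, which raises signal-to-noise without diluting a line-specific
essentiality.

## Denoising

**Weak-signal removal.** Point i is removed iff its score is strictly
greater than the scores of at least ⌈f·L⌉ of its L available left
neighbors and ⌈f·R⌉ of its R available right neighbors, with
L = min(k, #left), R = min(k, #right), k = 5 and f = 2/3. k = 5 spans
roughly 30 AA at typical density — the size of the smallest domain
module — so a genuinely sensitive point is compared against peers likely
to share its level. Ceiling keeps the rule conservative when fewer than k
neighbors exist; points with fewer than two neighbors on either side are
never removed, preventing mass deletion at protein termini. Decisions are
made on the original profile in a single pass (no cascade), so the result
is order-deterministic; a cascade variant exists behind a flag.

**Outlier clamping.** The noise scale is the *unscaled* median absolute
deviation of consecutive-score differences — unscaled because the clamp
is defined literally as `median ± 2·MAD`; a Gaussian-consistent variant
(÷0.6745√2) is available as `mad_scaled`. Each kept point is compared to
the median of up to 5 kept points on each side (window 11, defined over
point indices, not AA distance), excluding itself, and clamped into
`median ± 2·MAD`. Single pass, original values throughout.

A worked fixture: for scores [0,1,0,1,0,8,0,1,0,1,0] the consecutive
differences are [1,−1,1,−1,8,−8,1,−1,1,−1], their median is 0 and the MAD
is 1; the window of the spike holds six 0s and four 1s, so its median is
0 and the spike is clamped to 0 + 2·1 = 2.

## Segmentation (tail-greedy unbalanced Haar)

Starting from singleton regions, each pass computes the unbalanced Haar
detail `d = √(n_a n_b/(n_a+n_b))·(x̄_a − x̄_b)` for every adjacent region
pair and merges the ⌈ρ·#pairs⌉ pairs of smallest |d| (ρ = 0.01, at least
one merge per pass), in ascending |d| with ties broken leftmost,
skipping pairs that share a region with a merge already taken in the
pass. This bottom-up order protects small segments that top-down binary
splitting misses. Details are hard-thresholded at
`λ = C·σ̂·√(2 ln n)` with C = √3 and
`σ̂ = median(|Δx|)/(0.6745·√2)` — here the Gaussian-consistent,
differencing-corrected estimate, because the threshold theory assumes a
calibrated σ. The changepoints are the jumps of the thresholded
reconstruction: each surviving coefficient's wavelet is constant on its
two child regions and zero outside, so it contributes jumps at the
internal child boundary *and* at its support edges (the boundaries its
ancestor merges forced). Keeping the support edges matters in practice:
when a flank merges into a strong region before the opposite flank does,
the root-level detail is diluted below λ, and the missing boundary is
recovered only through the support edge of the surviving mid-level
coefficient. Final segment values are refit as exact means, so
Σ kᵢ·sᵢ equals the input sum to machine precision, and raising C can
only remove changepoints (the tree does not depend on λ).

Segments carry AA extents via a midpoint rule: the cut between adjacent
segments falls halfway between their flanking member points, so segment
intervals tile the profile span and adjacent CKHS segments merge cleanly.

## Region calling

Segments sorted ascending by mean score (ties: larger point count first,
then left position); the first is CKHS; segment i (2 ≤ i ≤ n−1) joins
while `s_i < (m_assigned + m_unassigned)/2`, else the walk stops. The
summaries are per-data-point class means `Σ s_j k_j / Σ k_j`
(`mean_mode="weighted"`, the default). A verbatim `printed` mode dividing
the same sums by segment *counts* is retained for comparison; it is not a
weighted mean, is not shift-equivariant when segment sizes differ, and
with realistic kᵢ (tens to hundreds) its summaries are an order of
magnitude larger than any segment mean, so the walk always stops after
one segment and multi-region proteins become uncallable — the weighted
mode, which coincides with it when every kᵢ = 1, is therefore the
default. Because m_unassigned averages the segments strictly after i,
the weakest segment can never be assigned. Proteins with fewer than two
segments return no regions (a single-segment protein would otherwise be
labeled wholly CKHS). Adjacent CKHS segments merge into regions scored by
the mean of their member points; a general merge utility joins regions
whose gap is ≤ max_gap AAs (0 for calling; 2 — i.e. distance < 3 AA — in
prediction post-processing).

## Evaluation

* AA-level precision (called ∩ domain / called), recall (called ∩ domain
  / domain) and F1 = 2PR/(P+R), all 0 by convention on empty
  denominators, pooled over proteins.
* Region-level percentages: regions overlapping ≥1 domain AA; domains
  touched by ≥1 region.
* Border distances: signed distance from each region border to the
  nearest same-side domain boundary (negative = inside the domain).
  Enrichment within ±20 AA is tested per side by Fisher's exact test of
  observed borders against borders of position-matched random regions —
  the 2×2 construction is this package's choice; the null placement
  preserves per-protein region count and lengths and samples
  non-overlapping arrangements uniformly (stars-and-bars over the gap
  composition).
* Permutation F1 null: regions re-placed per protein as above,
  p = (1 + #{F1_null ≥ F1_obs})/(n_perm + 1). Integer-valued overlaps tie
  occasionally, making the p-value mildly conservative.
* PTM density: population = all AAs, successes = PTM-bearing AAs, draws =
  CKHS AAs; the headline p is the hypergeometric tail in the direction of
  the observed effect (labeled), and both fixed-direction tails are
  returned — calibration must use a fixed tail, since a
  direction-of-effect p is non-uniform under the null by construction.
* LOESS baseline: local-linear LOESS (span 0.1 of the protein length by
  default; the comparison recipe fixes no span) fitted at the data points
  and interpolated onto the AA grid, then exactly `aa_budget` most
  negative AAs flagged (ties quantized at 1e-9 and broken by position) and
  merged at gap ≤ 2 — budget matching makes the comparison with the
  segment-based caller fair.

## Feature-based prediction

Per-residue features: domain flag (0/1); conservation smoothed with a
Gaussian kernel (σ = bandwidth = 10 AA, truncated at ±3σ, edge-
renormalized so constants are preserved and interior impulses keep unit
mass) then mean-centered per protein; secondary structure as [1,0] helix,
[0,1] sheet, [0,0] unstructured; four PTM tracks (phosphorylation,
acetylation, methylation, ubiquitination) as smoothed site indicators
(log1p reference counts optionally). The classifier is a bag of 100 SVMs
(RBF kernel by default — the underlying recipe names no kernel — with
standard scaling fit on the training set only); each member trains on
⌈0.05·N_CKHS⌉ positives sampled with replacement plus an equal-size
negative sample, and the prediction score is the mean of member decision
values. Evaluation is leave-one-gene-out: all residues of one gene form
the held-out fold (no within-gene leakage; per-protein centering uses
only the protein's own track), AUC pooled over held-out residues
(macro-average available). Predicted regions are score runs ≥ cutoff
(default: the cutoff maximizing training-set F1), merged at gap < 3 AA;
regions shorter than 10 AA are discarded.

## Synthetic data

`simulate_screen` draws sgRNA positions uniformly (density default
0.5/AA — PAM-realistic spacing is irrelevant to the algorithm under
test), sets the mean to baseline (−0.2) plus the planted effect inside
regions, adds Gaussian noise (default σ = 0.4 on the Z-score scale),
collapses an inactive fraction (default 1/3) to zero mean — full signal
loss, matching the observed behavior of weak guides — and displaces a
small outlier fraction (default 2%) by ±5σ. `simulate_feature_set`
generates labeled per-residue features with configurable label
association (domain-flag match rate, conservation shift, PTM depletion
ratio, helix excess) and runs them through the same encoder as real
inputs. What the generator does *not* emulate: sequence-dependent sgRNA
activity, off-target structure correlated along the genome, isoform
mixtures, and copy-number artifacts — so passing recovery tests
demonstrates correctness of the algorithmic chain under the stated noise
model, not performance on any particular published screen.

## Test and acceptance conditions

The planted-recovery suite uses a single 120-AA region at AAs 241–360 of
a 600-AA protein (a typical domain-to-protein proportion), effect −1.2
with σ = 0.4 (jump/σ = 3), density 0.5 sgRNA/AA, generator defaults
otherwise, over 400 seeded replicates; null profiles use the same
geometry without a planted region. Remaining recovery failures at these
settings are boundary shrinkage that the exhaustive least-squares
optimum shares — the clamped surviving inactive sgRNAs form a ramp at
region edges, a data-identifiability limit rather than an estimator
artifact. The changepoint oracle suite compares 200 seeded signals
(60–120 points, ≤2 jumps of 5–8σ, segments ≥8 points) against an
exhaustive least-squares search. Statistical calibration uses 150
permutation-test replicates (n_perm = 99) and 300 hypergeometric
replicates in which PTM sites are redrawn iid against fixed regions —
conditioning on the realized site count makes the overlap exactly
hypergeometric, which is the test's null model.

## Known limitations

* Boundary resolution is limited to roughly the inter-sgRNA spacing plus
  the denoiser's edge ramp (±5–15 AA at default conditions).
* The verbatim `printed` calling mode is unusable on realistic segment
  sizes (see above); it exists for fidelity comparisons only.
* The permutation and Fisher nulls preserve per-protein region count and
  lengths; pooled-genome nulls would change the marginal structure and
  are deliberately not offered.
* Isoform choice is the caller's responsibility: each sgRNA must arrive
  with a single AA or CDS coordinate.
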