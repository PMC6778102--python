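"""Proteome-wide CKHS region prediction from protein features.

Tiling screens cover only a limited panel of proteins, so hyper-sensitive
regions are predicted for arbitrary proteins from sequence-independent
per-residue features: domain membership, conservation, secondary
structure and PTM annotation.  The classifier is a bagging ensemble of
100 support-vector machines; each member is trained on a small
with-replacement sample (5% of the CKHS amino acids, matched by an
equal-size sample of non-CKHS amino acids) and the prediction score is
the mean of the member decision values.  Evaluation uses
leave-one-gene-out cross-validation, which keeps all residues of a
protein in the same fold and so prevents within-gene leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .calling import merge_regions
from .io import CKHSRegion, DomainAnnotation

PTM_TYPES = ("phosphorylation", "acetylation", "methylation", "ubiquitination")
FEATURE_COLUMNS = (
    "domain_flag",
    "conservation",
    "ss_a",
    "ss_b",
    "ptm_phosphorylation",
    "ptm_acetylation",
    "ptm_methylation",
    "ptm_ubiquitination",
)
SS_CODES = {"H": (1, 0), "E": (0, 1), "C": (0, 0)}  # helix, sheet, unstructured

DEFAULT_BANDWIDTH = 10.0
DEFAULT_N_MEMBERS = 100
DEFAULT_SAMPLE_FRAC = 0.05
MIN_REGION_LENGTH = 10
PREDICT_MERGE_GAP = 2  # merge predicted regions closer than 3 AA


def gaussian_smooth(track: np.ndarray, bandwidth: float = DEFAULT_BANDWIDTH) -> np.ndarray:
    """Mass-preserving Gaussian kernel smoothing of a per-AA track.

    The kernel standard deviation is ``bandwidth`` (in AA), truncated at
    +/- 3 bandwidths and renormalized to unit sum; at sequence edges the
    kernel is renormalized over the in-range positions, so constant
    tracks stay constant and the mass of any impulse at least 3
    bandwidths from the edges is conserved exactly.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    track = np.asarray(track, dtype=float)
    n = track.size
    if n == 0:
        return track.copy()
    radius = int(math.ceil(3 * bandwidth))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / bandwidth) ** 2)
    kernel /= kernel.sum()

    def conv_centered(x: np.ndarray) -> np.ndarray:
        # full convolution sliced to the centered window; robust when the
        # kernel is longer than the track
        return np.convolve(x, kernel, mode="full")[radius: radius + n]

    # edge renormalization: divide by the kernel mass falling in range
    return conv_centered(track) / conv_centered(np.ones(n))


def encode_features(
    protein: str,
    protein_length: int,
    domains: Sequence[DomainAnnotation] = (),
    conservation: np.ndarray | None = None,
    ss_labels: Sequence[str] | None = None,
    ptm_sites: Mapping[str, Sequence[int]] | None = None,
    ptm_counts: Mapping[str, Mapping[int, int]] | None = None,
    labels: np.ndarray | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> pd.DataFrame:
    """Encode one protein's per-AA feature matrix.

    domain_flag is 1 within any annotated domain; conservation is smoothed
    (bandwidth 10 AA) then mean-centered per protein; secondary structure
    is two-bit ([1,0] helix, [0,1] sheet, [0,0] unstructured); each PTM
    type becomes a smoothed site-indicator track (or log1p reference
    counts when ``ptm_counts`` is given).
    """
    L = int(protein_length)
    idx = np.arange(1, L + 1)
    flag = np.zeros(L, dtype=int)
    for d in domains:
        if d.protein == protein:
            flag[d.start_aa - 1: d.end_aa] = 1
    if conservation is None:
        conservation = np.zeros(L)
    conservation = np.asarray(conservation, dtype=float)
    if conservation.size != L:
        raise ValueError("conservation track length mismatch")
    cons = gaussian_smooth(conservation, bandwidth)
    cons = cons - cons.mean()
    if ss_labels is None:
        ss_labels = ["C"] * L
    ss = []
    for lab in ss_labels:
        if lab not in SS_CODES:
            raise ValueError(f"unknown secondary-structure label {lab!r}")
        ss.append(SS_CODES[lab])
    ss = np.asarray(ss, dtype=float)
    if ss.shape[0] != L:
        raise ValueError("secondary-structure track length mismatch")
    data = {
        "gene": protein,
        "pos": idx,
        "domain_flag": flag,
        "conservation": cons,
        "ss_a": ss[:, 0],
        "ss_b": ss[:, 1],
    }
    ptm_sites = ptm_sites or {}
    ptm_counts = ptm_counts or {}
    for ptype in PTM_TYPES:
        track = np.zeros(L)
        if ptype in ptm_counts:
            for pos, nref in ptm_counts[ptype].items():
                if 1 <= pos <= L:
                    track[pos - 1] = math.log1p(nref)
        else:
            for pos in ptm_sites.get(ptype, ()):
                if 1 <= pos <= L:
                    track[pos - 1] = 1.0
        data[f"ptm_{ptype}"] = gaussian_smooth(track, bandwidth)
    df = pd.DataFrame(data)
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if labels.size != L:
            raise ValueError("label track length mismatch")
        df["label"] = labels
    return df


def labels_from_regions(regions: Sequence[CKHSRegion], protein: str,
                        protein_length: int) -> np.ndarray:
    """Per-AA 0/1 CKHS labels for one protein."""
    lab = np.zeros(protein_length, dtype=int)
    for r in regions:
        if r.gene == protein:
            lab[r.start_aa - 1: r.end_aa] = 1
    return lab


@dataclass
class BaggingSVM:
    """Bagging ensemble of SVM decision functions.

    Defaults: 100 RBF-kernel members, each trained on a with-replacement
    sample of ceil(sample_frac * N_CKHS) positive amino acids plus an
    equal-size with-replacement sample of negatives; features are
    standardized with a scaler fit on the full training set only.  The
    prediction score is the arithmetic mean of the member decision values
    (higher = more CKHS-like).
    """

    n_members: int = DEFAULT_N_MEMBERS
    sample_frac: float = DEFAULT_SAMPLE_FRAC
    kernel: str = "rbf"
    seed: int = 0
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS
    members: list = field(default_factory=list, repr=False)
    scaler: StandardScaler | None = field(default=None, repr=False)

    def fit(self, features: pd.DataFrame) -> "BaggingSVM":
        cols = list(self.feature_columns)
        X = features[cols].to_numpy(dtype=float)
        y = features["label"].to_numpy(dtype=int)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        if pos_idx.size == 0 or neg_idx.size == 0:
            raise ValueError("training data must contain both classes")
        self.scaler = StandardScaler().fit(X)
        Xs = self.scaler.transform(X)
        rng = np.random.default_rng(self.seed)
        m = max(1, math.ceil(self.sample_frac * pos_idx.size))
        self.members = []
        for _ in range(self.n_members):
            take_pos = rng.choice(pos_idx, size=m, replace=True)
            take_neg = rng.choice(neg_idx, size=m, replace=True)
            take = np.concatenate([take_pos, take_neg])
            clf = SVC(kernel=self.kernel, random_state=0)
            clf.fit(Xs[take], y[take])
            self.members.append(clf)
        return self

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        if not self.members:
            raise ValueError("model is not fitted")
        cols = list(self.feature_columns)
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        Xs = self.scaler.transform(features[cols].to_numpy(dtype=float))
        return np.mean([clf.decision_function(Xs) for clf in self.members], axis=0)


def train_bagging(
    features: pd.DataFrame,
    seed: int = 0,
    n_members: int = DEFAULT_N_MEMBERS,
    sample_frac: float = DEFAULT_SAMPLE_FRAC,
    kernel: str = "rbf",
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> BaggingSVM:
    """Train the bagging SVM on a labeled feature matrix."""
    model = BaggingSVM(
        n_members=n_members,
        sample_frac=sample_frac,
        kernel=kernel,
        seed=seed,
        feature_columns=tuple(feature_columns),
    )
    return model.fit(features)


def predict_scores(model: BaggingSVM, features: pd.DataFrame) -> np.ndarray:
    """Per-AA CKHS score: the mean of the member decision values."""
    return model.decision_scores(features)


def loo_cv_auc(
    features: pd.DataFrame,
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
    seed: int = 0,
    n_members: int = DEFAULT_N_MEMBERS,
    sample_frac: float = DEFAULT_SAMPLE_FRAC,
    kernel: str = "rbf",
    pooled: bool = True,
) -> dict:
    """Leave-one-gene-out cross-validated ROC-AUC.

    For each gene, a model is trained on all other genes and scores the
    held-out gene's amino acids.  The default AUC pools all held-out
    scores; ``pooled=False`` macro-averages per-gene AUCs over genes with
    both classes.  Folds whose training set is single-class are skipped
    and reported.
    """
    genes = list(pd.unique(features["gene"]))
    if len(genes) < 2:
        raise ValueError("need at least two genes for leave-one-gene-out CV")
    scores = np.full(len(features), np.nan)
    skipped: list[str] = []
    rng = np.random.default_rng(seed)
    for gene in genes:
        held = features["gene"] == gene
        train = features.loc[~held]
        if train["label"].nunique() < 2:
            skipped.append(gene)
            continue
        model = train_bagging(
            train,
            seed=int(rng.integers(2**31 - 1)),
            n_members=n_members,
            sample_frac=sample_frac,
            kernel=kernel,
            feature_columns=feature_columns,
        )
        scores[held.to_numpy()] = model.decision_scores(features.loc[held])
    valid = ~np.isnan(scores)
    y = features["label"].to_numpy(dtype=int)[valid]
    s = scores[valid]
    if pooled:
        auc = float(roc_auc_score(y, s)) if np.unique(y).size == 2 else float("nan")
    else:
        per_gene = []
        for gene in genes:
            mask = (features["gene"] == gene).to_numpy() & valid
            yy = features["label"].to_numpy(dtype=int)[mask]
            if np.unique(yy).size == 2:
                per_gene.append(roc_auc_score(yy, scores[mask]))
        auc = float(np.mean(per_gene)) if per_gene else float("nan")
    return {"auc": auc, "scores": scores, "skipped_genes": skipped}


def choose_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cutoff maximizing F1 on the supplied (training) labels."""
    order = np.argsort(scores)[::-1]
    y = np.asarray(labels, int)[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    fn = y.sum() - tp
    f1 = 2 * tp / np.maximum(2 * tp + fp + fn, 1)
    best = int(np.argmax(f1))
    return float(np.sort(scores)[::-1][best])


def postprocess_predicted(
    scores: np.ndarray,
    cutoff: float,
    gene: str = "",
    merge_gap: int = PREDICT_MERGE_GAP,
    min_length: int = MIN_REGION_LENGTH,
) -> list[CKHSRegion]:
    """Turn per-AA scores into predicted regions.

    AAs scoring at or above ``cutoff`` form runs; runs closer than
    ``merge_gap``+1 AA are merged; merged regions shorter than
    ``min_length`` AA are discarded to reduce false positives.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return []
    above = scores >= cutoff
    runs: list[CKHSRegion] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append(_score_region(gene, start, i - 1, scores))
            start = None
    if start is not None:
        runs.append(_score_region(gene, start, scores.size - 1, scores))
    merged = merge_regions(runs, max_gap=merge_gap)
    return [r for r in merged if r.length >= min_length]


def _score_region(gene: str, i0: int, i1: int, scores: np.ndarray) -> CKHSRegion:
    return CKHSRegion(
        gene=gene,
        start_aa=i0 + 1,
        end_aa=i1 + 1,
        score=float(scores[i0: i1 + 1].mean()),
        n_points=i1 - i0 + 1,
    )
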