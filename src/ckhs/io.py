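"""Reading and writing tiling-screen tables, annotations and region calls.

A tiling-sgRNA screen table has one row per sgRNA: the gene symbol, the
amino-acid position of the Cas9 cut site (or, alternatively, a 1-based CDS
nucleotide coordinate), and one dropout Z-score column per screened cell
line.  More negative Z-scores mean stronger dropout, i.e. a larger fitness
cost of the knockout.

Coordinates are 1-based and inclusive on both ends, in amino acids.
Genomic-to-CDS arithmetic (strand, exons, isoform choice) is deliberately
left to the caller; this module only converts a CDS nucleotide to an
amino-acid index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ckhs")

KEPT = "kept"
REMOVED = "removed"
ADJUSTED = "adjusted"

#: default threshold on the per-gene mean sgRNA Z-score below (<=) which a
#: gene is considered essential in a cell line.
DEFAULT_ESSENTIAL_THRESHOLD = -0.4


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass
class SgRNARecord:
    """One sgRNA with its dropout Z-score in each screened cell line."""

    gene: str
    scores: dict[str, float]
    aa_pos: int | None = None
    cds_pos: int | None = None
    sgrna_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not self.scores:
            raise ValueError("at least one cell-line score is required")
        if self.aa_pos is None and self.cds_pos is None:
            raise ValueError("either aa_pos or cds_pos must be given")
        if self.aa_pos is not None and self.aa_pos < 1:
            raise ValueError(f"aa_pos must be >= 1, got {self.aa_pos}")

    def resolved_aa(self) -> int:
        """Amino-acid index of the cut site (converting from CDS if needed)."""
        if self.aa_pos is not None:
            return self.aa_pos
        return map_cut_to_aa(self.cds_pos)


@dataclass
class TilingProfile:
    """Per-gene ordered series of (amino-acid position, dropout score).

    Every point carries a provenance flag: ``kept`` (in play), ``removed``
    (filtered as a likely-inactive sgRNA) or ``adjusted`` (outlier clamped;
    still in play).  Downstream computations use only non-removed points.
    """

    gene: str
    protein_length: int
    aa_pos: np.ndarray
    score: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.aa_pos = np.asarray(self.aa_pos, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.aa_pos.shape, KEPT, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if self.aa_pos.shape != self.score.shape or self.aa_pos.shape != self.flags.shape:
            raise ValueError("aa_pos, score and flags must have equal length")
        if self.aa_pos.size and np.any(np.diff(self.aa_pos) < 0):
            order = np.argsort(self.aa_pos, kind="stable")
            self.aa_pos = self.aa_pos[order]
            self.score = self.score[order]
            self.flags = self.flags[order]
        if self.aa_pos.size and self.aa_pos.max() > self.protein_length:
            raise ValueError(
                f"{self.gene}: aa_pos {self.aa_pos.max()} exceeds protein length "
                f"{self.protein_length}"
            )

    @property
    def kept_mask(self) -> np.ndarray:
        return self.flags != REMOVED

    @property
    def kept_aa(self) -> np.ndarray:
        return self.aa_pos[self.kept_mask]

    @property
    def kept_scores(self) -> np.ndarray:
        return self.score[self.kept_mask]

    def __len__(self) -> int:
        return int(self.aa_pos.size)

    def with_updates(self, score=None, flags=None) -> "TilingProfile":
        return TilingProfile(
            gene=self.gene,
            protein_length=self.protein_length,
            aa_pos=self.aa_pos.copy(),
            score=self.score.copy() if score is None else np.asarray(score, float),
            flags=self.flags.copy() if flags is None else np.asarray(flags, object),
        )


@dataclass(frozen=True)
class DomainAnnotation:
    """A Pfam-style domain interval on a protein (1-based, inclusive)."""

    protein: str
    domain_name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"invalid domain interval {self.start_aa}-{self.end_aa}"
            )

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass(frozen=True)
class CKHSRegion:
    """A called CRISPR-knockout hyper-sensitive interval (1-based, inclusive)."""

    gene: str
    start_aa: int
    end_aa: int
    score: float
    n_points: int

    def __post_init__(self) -> None:
        if self.start_aa > self.end_aa:
            raise ValueError(f"region start {self.start_aa} > end {self.end_aa}")

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


# ---------------------------------------------------------------------------
# Table dialects and readers
# ---------------------------------------------------------------------------

@dataclass
class TableDialect:
    """Column-name configuration for the tiling-screen table."""

    gene: str = "gene"
    aa_pos: str = "aa_pos"
    cds_pos: str = "cds_pos"
    sgrna_id: str = "sgrna_id"
    score_prefix: str = "zscore_"


def _read_delimited(path) -> pd.DataFrame:
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise FormatError(f"{path}: empty or malformed file ({exc})") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no columns found")
    return df


def read_tiling_table(path, dialect: TableDialect | None = None) -> list[SgRNARecord]:
    """Read a tiling-screen table into sgRNA records.

    Rows whose position or any score fails to parse as a number are dropped
    and reported (with 1-based data-row numbers) through the package logger.
    """
    dialect = dialect or TableDialect()
    df = _read_delimited(path)
    if dialect.gene not in df.columns:
        raise FormatError(f"{path}: missing mandatory column '{dialect.gene}'")
    has_aa = dialect.aa_pos in df.columns
    has_cds = dialect.cds_pos in df.columns
    if not has_aa and not has_cds:
        raise FormatError(
            f"{path}: missing position column "
            f"('{dialect.aa_pos}' or '{dialect.cds_pos}')"
        )
    score_cols = [c for c in df.columns if str(c).startswith(dialect.score_prefix)]
    if not score_cols:
        raise FormatError(
            f"{path}: no score columns with prefix '{dialect.score_prefix}'"
        )

    records: list[SgRNARecord] = []
    dropped: list[int] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        pos_col = dialect.aa_pos if has_aa else dialect.cds_pos
        pos = pd.to_numeric(pd.Series([row_d[pos_col]]), errors="coerce").iloc[0]
        scores_raw = pd.to_numeric(
            pd.Series([row_d[c] for c in score_cols]), errors="coerce"
        )
        if pd.isna(pos) or scores_raw.isna().any() or float(pos) < 1:
            dropped.append(row_no)
            continue
        scores = {
            c[len(dialect.score_prefix):]: float(v)
            for c, v in zip(score_cols, scores_raw)
        }
        kwargs = {"aa_pos": int(pos)} if has_aa else {"cds_pos": int(pos)}
        records.append(
            SgRNARecord(
                gene=str(row_d[dialect.gene]),
                scores=scores,
                sgrna_id=str(row_d.get(dialect.sgrna_id, "")) if dialect.sgrna_id in df.columns else "",
                **kwargs,
            )
        )
    if dropped:
        logger.warning(
            "%s: dropped %d unparsable row(s): %s", path, len(dropped), dropped
        )
    return records


def map_cut_to_aa(cds_pos: int) -> int:
    """Convert a 1-based CDS nucleotide position to its 1-based codon index."""
    if cds_pos is None or cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return -(-int(cds_pos) // 3)


def select_essential_genes(
    records: Iterable[SgRNARecord],
    threshold: float = DEFAULT_ESSENTIAL_THRESHOLD,
    protein_lengths: Mapping[str, int] | None = None,
) -> dict[str, TilingProfile]:
    """Select essential genes and build their averaged tiling profiles.

    A gene is essential in a cell line iff the mean Z-score of its sgRNAs in
    that line is <= ``threshold``; the returned genes are the union over
    lines.  When a gene is essential in several lines, each sgRNA's score is
    the mean over exactly those lines, which boosts the signal-to-noise
    ratio of the profile.
    """
    by_gene: dict[str, list[SgRNARecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)

    profiles: dict[str, TilingProfile] = {}
    for gene, recs in by_gene.items():
        lines = sorted({line for r in recs for line in r.scores})
        essential_lines = [
            line
            for line in lines
            if np.mean([r.scores[line] for r in recs if line in r.scores])
            <= threshold
        ]
        if not essential_lines:
            continue
        aa = np.array([r.resolved_aa() for r in recs], dtype=int)
        score = np.array(
            [
                np.mean([r.scores[line] for line in essential_lines if line in r.scores])
                for r in recs
            ],
            dtype=float,
        )
        length = None if protein_lengths is None else protein_lengths.get(gene)
        if length is None:
            length = int(aa.max())
        profiles[gene] = TilingProfile(
            gene=gene, protein_length=length, aa_pos=aa, score=score
        )
    return profiles


# ---------------------------------------------------------------------------
# Annotation tables and region output
# ---------------------------------------------------------------------------

def read_domain_table(path) -> list[DomainAnnotation]:
    """Read a domain table with columns protein, domain, start, end."""
    df = _read_delimited(path)
    required = {"protein", "domain", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        DomainAnnotation(
            protein=str(r.protein),
            domain_name=str(r.domain),
            start_aa=int(r.start),
            end_aa=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


def read_ptm_table(path) -> pd.DataFrame:
    """Read a PTM site table with columns protein, pos, type, nrefs."""
    df = _read_delimited(path)
    required = {"protein", "pos", "type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if "nrefs" not in df.columns:
        df = df.assign(nrefs=1)
    df["pos"] = df["pos"].astype(int)
    df["nrefs"] = df["nrefs"].astype(int)
    return df


REGION_COLUMNS = ["gene", "start_aa", "end_aa", "score", "n_points"]


def write_regions(regions: Sequence[CKHSRegion], path, bed: bool = False) -> None:
    """Write region calls as TSV; ``bed=True`` exports 0-based half-open."""
    rows = []
    for r in regions:
        if bed:
            rows.append((r.gene, r.start_aa - 1, r.end_aa, r.score, r.n_points))
        else:
            rows.append((r.gene, r.start_aa, r.end_aa, r.score, r.n_points))
    cols = ["chrom", "start", "end", "score", "n_points"] if bed else REGION_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[CKHSRegion]:
    df = _read_delimited(path)
    missing = set(REGION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        CKHSRegion(
            gene=str(r.gene),
            start_aa=int(r.start_aa),
            end_aa=int(r.end_aa),
            score=float(r.score),
            n_points=int(r.n_points),
        )
        for r in df.itertuples(index=False)
    ]
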