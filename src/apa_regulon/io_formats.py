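"""Readers, writers and domain containers for the tabular formats the pipeline touches.

Coordinate convention is BED throughout: 0-based, half-open intervals. A
poly(A) site (PAS) is a short genomic interval inside a terminal exon; within
each exon PAS are ranked 1..k in transcript 5'->3' orientation (ascending
genomic coordinate on the + strand, descending on -). The 3'-most site is the
distal PAS (dPAS); all others are proximal (pPAS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PasAnnotation",
    "PasCountMatrix",
    "read_pas_atlas",
    "read_matrix",
    "write_matrix",
    "read_bed6",
    "annotations_to_frame",
    "validate_clinical_table",
    "validate_clip_table",
    "validate_design_table",
]


@dataclass(frozen=True)
class PasAnnotation:
    """A poly(A) site placed in a terminal exon, with strand-aware rank.

    ``rank_from_5p`` counts PAS within the host exon in transcript
    orientation (1 = most 5'); ``is_distal`` marks the single 3'-most site.
    Coordinates are 0-based half-open.
    """

    pas_id: str
    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank_from_5p: int
    is_distal: bool

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"PAS {self.pas_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"PAS {self.pas_id}: strand must be '+' or '-'")
        if self.rank_from_5p < 1:
            raise ValueError(f"PAS {self.pas_id}: rank_from_5p must be >= 1")

    def to_one_based(self) -> tuple[int, int]:
        """1-based inclusive coordinates; inverse of ``from_one_based``."""
        return self.start + 1, self.end

    @staticmethod
    def from_one_based(start: int, end: int) -> tuple[int, int]:
        """Convert 1-based inclusive coordinates back to BED half-open."""
        return start - 1, end


@dataclass
class PasCountMatrix:
    """Raw read counts supporting each PAS across samples.

    ``counts`` is indexed by pas_id with sample ids as columns.
    ``library_size`` defaults to the per-sample column sum: the pipeline only
    sees the PAS count matrix, not full alignments, so total supporting reads
    are the available proxy for sequencing depth.
    """

    annotations: list[PasAnnotation]
    counts: pd.DataFrame
    library_size: pd.Series = None

    def __post_init__(self):
        ann_ids = [a.pas_id for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise ValueError("duplicate pas_id in annotations")
        if list(self.counts.index) != ann_ids:
            raise ValueError("counts rows must match annotations (same pas_id order)")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0).astype(float)
        else:
            self.library_size = pd.Series(self.library_size, dtype=float).reindex(
                self.counts.columns
            )
            if self.library_size.isna().any() or (self.library_size <= 0).any():
                raise ValueError("library_size must be positive for every sample")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def pas_ids(self) -> list[str]:
        return list(self.counts.index)

    def exon_groups(self) -> dict[str, list[PasAnnotation]]:
        """PAS annotations grouped by host exon, ordered by rank_from_5p."""
        groups: dict[str, list[PasAnnotation]] = {}
        for ann in self.annotations:
            groups.setdefault(ann.exon_id, []).append(ann)
        for anns in groups.values():
            anns.sort(key=lambda a: a.rank_from_5p)
        return groups


def annotations_to_frame(annotations: Iterable[PasAnnotation]) -> pd.DataFrame:
    """Flatten annotations into a DataFrame indexed by pas_id."""
    rows = [
        {
            "pas_id": a.pas_id,
            "exon_id": a.exon_id,
            "gene_id": a.gene_id,
            "chrom": a.chrom,
            "start": a.start,
            "end": a.end,
            "strand": a.strand,
            "rank_from_5p": a.rank_from_5p,
            "is_distal": a.is_distal,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows).set_index("pas_id")


def read_bed6(path) -> pd.DataFrame:
    """Parse a BED file with at least 6 columns into a DataFrame.

    Raises ValueError naming the offending line on malformed input.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 tab-separated BED columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-'")
            records.append(
                {"chrom": chrom, "start": start_i, "end": end_i, "name": name,
                 "score": score, "strand": strand}
            )
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def read_pas_atlas(path, exon_table: pd.DataFrame) -> list[PasAnnotation]:
    """Load a PAS atlas (BED6) and place each site into a terminal exon.

    ``exon_table`` needs columns exon_id, gene_id, chrom, start, end, strand
    (BED coordinates). Each PAS is assigned to the same-strand overlapping
    exon; on multiple hits the exon with the greatest overlap wins, ties are
    dropped with a warning. Sites overlapping no exon are dropped (counted in
    the log). Within each exon, ranks run 5'->3' in transcript orientation and
    the 3'-most PAS is flagged distal.
    """
    bed = read_bed6(path)
    required = {"exon_id", "gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(exon_table.columns)
    if missing:
        raise ValueError(f"exon_table missing columns: {sorted(missing)}")

    exons_by_key: dict[tuple[str, str], pd.DataFrame] = {
        key: grp for key, grp in exon_table.groupby(["chrom", "strand"])
    }

    n_unassigned = 0
    n_tied = 0
    assigned: list[tuple[pd.Series, pd.Series]] = []
    for _, pas in bed.iterrows():
        candidates = exons_by_key.get((pas["chrom"], pas["strand"]))
        if candidates is None:
            n_unassigned += 1
            continue
        ovl = np.minimum(candidates["end"], pas["end"]) - np.maximum(
            candidates["start"], pas["start"]
        )
        hits = candidates[ovl > 0]
        if hits.empty:
            n_unassigned += 1
            continue
        best = ovl[ovl > 0]
        top = best.max()
        winners = hits[best == top]
        if len(winners) > 1:
            n_tied += 1
            logger.warning(
                "PAS %s overlaps %d exons equally; dropped", pas["name"], len(winners)
            )
            continue
        assigned.append((pas, winners.iloc[0]))

    if n_unassigned:
        logger.info("%d PAS overlapped no terminal exon and were dropped", n_unassigned)

    # rank within exon in transcript orientation
    by_exon: dict[str, list[tuple[pd.Series, pd.Series]]] = {}
    for pas, exon in assigned:
        by_exon.setdefault(exon["exon_id"], []).append((pas, exon))

    annotations: list[PasAnnotation] = []
    for exon_id, items in by_exon.items():
        strand = items[0][1]["strand"]
        items.sort(key=lambda t: t[0]["start"], reverse=(strand == "-"))
        k = len(items)
        for rank, (pas, exon) in enumerate(items, start=1):
            annotations.append(
                PasAnnotation(
                    pas_id=str(pas["name"]),
                    exon_id=exon_id,
                    gene_id=str(exon["gene_id"]),
                    chrom=str(pas["chrom"]),
                    start=int(pas["start"]),
                    end=int(pas["end"]),
                    strand=strand,
                    rank_from_5p=rank,
                    is_distal=(rank == k),
                )
            )
    return annotations


def read_matrix(path, counts: bool = False) -> pd.DataFrame:
    """Read a TSV matrix: first column row ids, header row sample ids.

    With ``counts=True`` the cells must be non-negative integers. Duplicate
    row or column ids and non-numeric cells raise ValueError with location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no rows")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dups}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate column ids")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = converted
    if counts:
        arr = df.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"{path}: negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: count matrix contains non-integer values")
        df = df.astype(np.int64)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix TSV that round-trips bit-identically for integer counts."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table: sample_id, time >= 0, event in {0,1}, purity in [0,1]."""
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("clinical table has duplicate sample_id")
    if (df["time"] < 0).any():
        raise ValueError("clinical table has negative time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("clinical event must be 0 or 1")
    if "purity" in df.columns:
        purity = df["purity"].dropna()
        if ((purity < 0) | (purity > 1)).any():
            raise ValueError("purity must lie in [0, 1]")
    return df


def validate_clip_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a CLIP binding table: unique (rbp_id, exon_id) rows."""
    required = {"rbp_id", "exon_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clip table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["rbp_id", "exon_id"]).any():
        raise ValueError("clip table has duplicate (rbp_id, exon_id) rows")
    return df


def validate_design_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a perturbation design: each experiment has both arms and one target RBP."""
    required = {"experiment_id", "cell_line", "target_rbp", "sample_id", "arm",
                "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if not df["arm"].isin(["control", "depleted"]).all():
        raise ValueError("arm must be 'control' or 'depleted'")
    for exp_id, grp in df.groupby("experiment_id"):
        arms = set(grp["arm"])
        if arms != {"control", "depleted"}:
            raise ValueError(f"experiment {exp_id}: needs both control and depleted samples")
        if grp["target_rbp"].nunique() != 1:
            raise ValueError(f"experiment {exp_id}: more than one target_rbp")
    return df
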