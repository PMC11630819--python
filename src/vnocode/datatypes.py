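"""Core containers shared by every analysis module.

The pipeline works on raw integer count matrices (genes x cells) together
with a gene annotation table that assigns each gene to one of the
chemoreceptor families of the vomeronasal organ (V1R, V2R, OR, Fpr) or to
one of the curated panels (transcription factors, axon-guidance molecules).
Cell-level metadata (type, age, spatial position, label-transfer prediction
score) rides along in :class:`CellRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class GeneClass(str, Enum):
    """Gene families and panels recognized by the pipeline."""

    V1R = "V1R"
    V2R = "V2R"
    OR = "OR"
    FPR = "Fpr"
    TF = "TF"
    AG = "AG"
    OTHER = "other"


#: Chemoreceptor families (the substrates of co-expression calling).
RECEPTOR_CLASSES = (GeneClass.V1R, GeneClass.V2R, GeneClass.OR, GeneClass.FPR)


@dataclass
class GeneRecord:
    """One annotated gene: family membership, locus, pseudogene status.

    Coordinates are 1-based inclusive (GFF / circos convention).
    """

    gene_id: str
    gene_class: GeneClass
    chromosome: str
    start_bp: int
    end_bp: int
    symbol: Optional[str] = None
    pseudogene: bool = False
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(f"{self.gene_id}: start_bp must be >= 1, got {self.start_bp}")
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"{self.gene_id}: start_bp ({self.start_bp}) > end_bp ({self.end_bp})"
            )

    @property
    def midpoint_bp(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0


@dataclass
class CountMatrix:
    """Raw integer counts, rows = genes, columns = cells."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"{n_genes} count rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_barcodes):
            raise ValueError(
                f"{n_cells} count columns but {len(self.cell_barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in count matrix")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValueError("duplicate cell barcodes in count matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(as_int != self.counts)[0]
                raise ValueError(
                    f"non-integer count at gene row {bad[0]}, cell column {bad[1]}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Row indices for the given genes (raises KeyError on absent ids)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in count matrix") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(gene_ids)
        return CountMatrix(self.counts[idx], list(gene_ids), list(self.cell_barcodes))


class AgeGroup(str, Enum):
    P14 = "P14"
    P56 = "P56"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    M = "M"
    F = "F"
    UNKNOWN = "unknown"


@dataclass
class CellRecord:
    """Per-cell metadata; spatial fields are optional."""

    barcode: str
    cell_type: str = "unknown"
    age_group: AgeGroup = AgeGroup.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    sample_id: str = ""
    x_px: Optional[float] = None
    y_px: Optional[float] = None
    prediction_score: Optional[float] = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.prediction_score is not None and not (
            0.0 <= self.prediction_score <= 1.0
        ):
            raise ValueError(
                f"{self.barcode}: prediction_score {self.prediction_score} not in [0,1]"
            )


@dataclass
class PairTestResult:
    """One receptor pair's contingency table and Fisher enrichment test.

    ``n11`` counts cells where both receptors pass the presence threshold;
    ``n10``/``n01`` one-only cells; ``n00`` neither. ``odds_ratio`` is
    (n11*n00)/(n10*n01), infinite when the denominator vanishes with n11 > 0.
    """

    gene_a: str
    gene_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p_value: float
    p_adjusted: float = math.nan
    same_chromosome: Optional[bool] = None
    genomic_distance_bp: Optional[float] = None

    @property
    def n_total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def annotation_by_id(annotation: Sequence[GeneRecord]) -> dict[str, GeneRecord]:
    index = {}
    for rec in annotation:
        if rec.gene_id in index:
            raise ValueError(f"duplicate gene_id in annotation: {rec.gene_id}")
        index[rec.gene_id] = rec
    return index


def genes_of_class(
    annotation: Sequence[GeneRecord],
    classes: Sequence[GeneClass | str],
    include_pseudogenes: bool = True,
) -> list[GeneRecord]:
    wanted = {GeneClass(c) for c in classes}
    out = [
        r
        for r in annotation
        if r.gene_class in wanted and (include_pseudogenes or not r.pseudogene)
    ]
    return out
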