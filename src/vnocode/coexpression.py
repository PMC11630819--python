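"""Receptor co-expression calling.

A receptor counts as *present* in a cell at >= 10 raw counts, and only
receptors present in >= 5 cells are retained for testing — the stringent
criterion that rejects ambient contamination. Co-expression of every
retained receptor pair is then tested with a one-sided (enrichment) Fisher
exact test on the 2x2 presence table, Benjamini-Hochberg corrected across
all pairs; significant pairs are summarized for genomic co-localization
(same-chromosome fraction, midpoint distances). Per-cell receptor diversity
uses the Shannon index over raw counts of the chemoreceptor families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_enrichment_p, fisher_two_sided_p, odds_ratio
from .datatypes import (
    CellRecord,
    CountMatrix,
    GeneClass,
    GeneRecord,
    PairTestResult,
    RECEPTOR_CLASSES,
    annotation_by_id,
    genes_of_class,
)


class ConfigError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """Thresholded receptor-by-cell presence; substrate of all pair tests."""

    presence: np.ndarray  # bool, receptors x cells
    receptor_ids: list[str]
    cell_barcodes: list[str]
    count_threshold: int
    min_cells: int
    retained_receptors: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.presence.shape[1]

    def retained_matrix(self) -> tuple[np.ndarray, list[str]]:
        idx = [self.receptor_ids.index(r) for r in self.retained_receptors]
        return self.presence[idx], list(self.retained_receptors)


def binarize_presence(
    counts: CountMatrix,
    annotation: Sequence[GeneRecord],
    classes: Sequence[GeneClass | str] = RECEPTOR_CLASSES,
    count_threshold: int = 10,
    min_cells: int = 5,
) -> PresenceMatrix:
    """Boolean receptor x cell presence at >= count_threshold raw counts.

    Receptors present in fewer than ``min_cells`` cells stay in the matrix
    but are dropped from ``retained_receptors`` (and hence from testing).
    """
    if not classes:
        raise ConfigError("classes must be nonempty")
    if count_threshold < 1:
        raise ConfigError("count_threshold must be >= 1")
    genes = genes_of_class(annotation, classes)
    in_matrix = [g.gene_id for g in genes if g.gene_id in set(counts.gene_ids)]
    idx = counts.gene_index(in_matrix)
    presence = counts.counts[idx] >= count_threshold
    n_present = presence.sum(axis=1)
    retained = [g for g, n in zip(in_matrix, n_present) if n >= min_cells]
    return PresenceMatrix(
        presence=presence,
        receptor_ids=in_matrix,
        cell_barcodes=list(counts.cell_barcodes),
        count_threshold=count_threshold,
        min_cells=min_cells,
        retained_receptors=retained,
    )


def shannon_per_cell(
    counts: CountMatrix,
    annotation: Sequence[GeneRecord],
    classes: Sequence[GeneClass | str] = RECEPTOR_CLASSES,
) -> pd.DataFrame:
    """Per-cell Shannon diversity of raw receptor counts (natural log).

    H = -sum_i p_i ln p_i over the cell's counts restricted to the listed
    receptor families; H = 0 means a single receptor species. Cells with no
    receptor counts are flagged ``h_undefined`` and should be excluded from
    comparisons. Also reports the share of the cell's receptor counts on its
    1st-3rd most expressed receptors and the receptor fraction of the cell's
    total counts.
    """
    genes = genes_of_class(annotation, classes)
    ids = [g.gene_id for g in genes if g.gene_id in set(counts.gene_ids)]
    if not ids:
        raise ValueError("no genes of the requested classes in the count matrix")
    sub = counts.counts[counts.gene_index(ids)].astype(float)
    class_total = sub.sum(axis=0)
    grand_total = counts.counts.sum(axis=0).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        p = sub / class_total
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0)
    undefined = class_total == 0
    h[undefined] = np.nan

    sorted_counts = np.sort(sub, axis=0)[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        top = sorted_counts[:3] / class_total

    frame = pd.DataFrame(
        {
            "barcode": counts.cell_barcodes,
            "shannon_H": h,
            "h_undefined": undefined,
            "n_receptors_present": (sub > 0).sum(axis=0).astype(int),
            "top1_share": np.where(undefined, np.nan, top[0]),
            "top2_share": np.where(undefined, np.nan, top[1] if len(ids) > 1 else 0.0),
            "top3_share": np.where(undefined, np.nan, top[2] if len(ids) > 2 else 0.0),
            "class_fraction_of_total": np.divide(
                class_total,
                grand_total,
                out=np.full_like(class_total, np.nan),
                where=grand_total > 0,
            ),
        }
    )
    return frame


def multiplicity_table(
    presence: PresenceMatrix,
    cells: Sequence[CellRecord],
    group_by: Sequence[str] = ("cell_type",),
) -> pd.DataFrame:
    """Fractions of cells with 0, 1, 2, 3+ present receptors per group."""
    allowed = {"cell_type", "age_group"}
    for key in group_by:
        if key not in allowed:
            raise ValueError(f"unknown group key {key!r}; allowed: {sorted(allowed)}")
    by_barcode = {c.barcode: c for c in cells}
    mat, _ = presence.retained_matrix()
    n_per_cell = mat.sum(axis=0) if mat.size else np.zeros(presence.n_cells, int)

    rows = []
    for barcode, n in zip(presence.cell_barcodes, n_per_cell):
        cell = by_barcode.get(barcode)
        key = tuple(
            getattr(cell, k).value if k == "age_group" else getattr(cell, k)
            for k in group_by
        ) if cell is not None else tuple("unknown" for _ in group_by)
        rows.append(key + (int(n),))
    frame = pd.DataFrame(rows, columns=list(group_by) + ["n_receptors"])

    def fractions(sub: pd.DataFrame) -> pd.Series:
        n = len(sub)
        if n == 0:
            return pd.Series(
                {"frac_0": np.nan, "frac_1": np.nan, "frac_2": np.nan,
                 "frac_3plus": np.nan, "n_cells": 0, "empty_group": True}
            )
        k = sub["n_receptors"]
        return pd.Series(
            {
                "frac_0": float((k == 0).mean()),
                "frac_1": float((k == 1).mean()),
                "frac_2": float((k == 2).mean()),
                "frac_3plus": float((k >= 3).mean()),
                "n_cells": n,
                "empty_group": False,
            }
        )

    out = (
        frame.groupby(list(group_by), sort=True)
        .apply(fractions, include_groups=False)
        .reset_index()
    )
    return out


def pairwise_fisher(
    presence: PresenceMatrix,
    annotation: Optional[Sequence[GeneRecord]] = None,
    two_sided: bool = False,
) -> list[PairTestResult]:
    """Fisher exact test for every unordered pair of retained receptors.

    The universe N is every cell in the presence matrix; the default test is
    one-sided for enrichment (co-expression), with BH correction applied
    jointly across all tested pairs. Pairs with zero overlap are still
    tested (their one-sided p is 1 whenever overlap cannot be exceeded).
    """
    mat, ids = presence.retained_matrix()
    if len(ids) < 2:
        raise ConfigError("need >= 2 retained receptors for pair testing")
    n = presence.n_cells
    k = mat.sum(axis=1).astype(np.int64)
    overlap = (mat.astype(np.int64) @ mat.T.astype(np.int64))

    pairs = list(itertools.combinations(range(len(ids)), 2))
    ai = np.array([a for a, _ in pairs])
    bi = np.array([b for _, b in pairs])
    n11 = overlap[ai, bi]
    ka, kb = k[ai], k[bi]
    if two_sided:
        p = np.array(
            [
                fisher_two_sided_p(
                    int(n11[i]),
                    int(ka[i] - n11[i]),
                    int(kb[i] - n11[i]),
                    int(n - ka[i] - kb[i] + n11[i]),
                )
                for i in range(len(pairs))
            ]
        )
    else:
        p = fisher_enrichment_p(n11, ka, kb, n)
    padj = bh_adjust(p)

    index = annotation_by_id(annotation) if annotation is not None else None
    results = []
    for i, (a, b) in enumerate(pairs):
        t11 = int(n11[i])
        t10 = int(ka[i] - t11)
        t01 = int(kb[i] - t11)
        t00 = int(n - t11 - t10 - t01)
        same_chrom = None
        dist = None
        if index is not None:
            ga, gb = index.get(ids[a]), index.get(ids[b])
            if ga is not None and gb is not None:
                same_chrom = ga.chromosome == gb.chromosome
                if same_chrom:
                    dist = abs(ga.midpoint_bp - gb.midpoint_bp)
        results.append(
            PairTestResult(
                gene_a=ids[a],
                gene_b=ids[b],
                n11=t11,
                n10=t10,
                n01=t01,
                n00=t00,
                odds_ratio=odds_ratio(t11, t10, t01, t00),
                p_value=float(p[i]),
                p_adjusted=float(padj[i]),
                same_chromosome=same_chrom,
                genomic_distance_bp=dist,
            )
        )
    return results


@dataclass
class ColocalizationSummary:
    """Genomic co-localization of significantly co-expressed pairs."""

    n_significant: int
    n_same_chromosome: int
    fraction_same_chromosome: float  # NaN (flagged) when no significant pair
    fraction_defined: bool
    gene_level_fraction: float
    distances_bp: dict[tuple[str, str], float]


def genomic_colocalization(
    results: Sequence[PairTestResult],
    annotation: Sequence[GeneRecord],
    alpha: float = 0.05,
) -> ColocalizationSummary:
    """Fraction of significant pairs (padj <= alpha) on the same chromosome.

    Distances are between interval midpoints, reported only for
    same-chromosome pairs. The gene-level fraction counts receptor genes
    that share a chromosome with at least one significant partner, among
    all genes in significant pairs.
    """
    index = annotation_by_id(annotation)
    significant = [r for r in results if r.p_adjusted <= alpha]
    n_same = 0
    distances: dict[tuple[str, str], float] = {}
    colocal_genes: set[str] = set()
    all_genes: set[str] = set()
    for r in significant:
        for gene in (r.gene_a, r.gene_b):
            if gene not in index:
                raise KeyError(f"gene {gene!r} absent from annotation")
        ga, gb = index[r.gene_a], index[r.gene_b]
        all_genes.update([r.gene_a, r.gene_b])
        if ga.chromosome == gb.chromosome:
            n_same += 1
            distances[(r.gene_a, r.gene_b)] = abs(ga.midpoint_bp - gb.midpoint_bp)
            colocal_genes.update([r.gene_a, r.gene_b])
    n_sig = len(significant)
    return ColocalizationSummary(
        n_significant=n_sig,
        n_same_chromosome=n_same,
        fraction_same_chromosome=(n_same / n_sig) if n_sig else float("nan"),
        fraction_defined=n_sig > 0,
        gene_level_fraction=(len(colocal_genes) / len(all_genes)) if all_genes else float("nan"),
        distances_bp=distances,
    )
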