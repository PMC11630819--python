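"""The receptor <-> transcription-factor / axon-guidance association code.

For every receptor (present at >= 10 raw counts) and every panel gene
(transcription factor or axon-guidance molecule, present at >= 3 raw
counts), co-expression is scored with a one-sided Fisher test over cell
barcodes, BH-corrected across the whole receptor x panel table. On top of
the association tables sit the derived similarity structures: Pearson
correlation of receptors' panel-expression profiles, pairwise protein
percent identity, the expression-similarity vs sequence-similarity
relation, and per-receptor TF x AG Jaccard grids (do the TF and the AG
occupy the same cells of that receptor's population?).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, fisher_enrichment_p
from .datatypes import CountMatrix, GeneClass, GeneRecord, genes_of_class

logger = logging.getLogger("vnocode")


@dataclass
class AssociationTable:
    """Receptor x panel-gene association: means, p, padj, presence sets."""

    panel: GeneClass
    receptor_ids: list[str]
    panel_ids: list[str]
    mean_expression: pd.DataFrame  # receptors x panel genes
    p_value: pd.DataFrame
    p_adjusted: pd.DataFrame
    receptor_threshold: int
    panel_threshold: int
    cell_barcodes: list[str]
    receptor_presence: np.ndarray  # bool receptors x cells
    panel_presence: np.ndarray  # bool panel genes x cells
    flagged_receptors: list[str] = field(default_factory=list)

    def significant_partners(self, receptor: str, alpha: float = 0.05) -> list[str]:
        row = self.p_adjusted.loc[receptor]
        return [g for g in self.panel_ids if row[g] <= alpha]


@dataclass
class SimilarityMatrix:
    """Square symmetric receptor similarity; kind fixes the diagonal."""

    kind: str  # tf_profile | ag_profile | sequence | combined
    values: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


@dataclass
class JaccardGrid:
    """TF x AG co-occupancy within one receptor's cells."""

    receptor: str
    tf_ids: list[str]
    ag_ids: list[str]
    jaccard: pd.DataFrame  # TF x AG
    empty: bool = False


@dataclass
class SimilarityRelation:
    """Binned relation between two receptor similarity matrices."""

    spearman_rho: float
    spearman_p: float
    n_pairs: int
    by_second_bin: pd.DataFrame  # bins on the second matrix; stats of the first
    by_first_bin: pd.DataFrame


def _normalized_log_expression(counts: CountMatrix) -> np.ndarray:
    """log1p of counts scaled to the median cell total (heatmap means)."""
    totals = counts.counts.sum(axis=0).astype(float)
    median_total = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(totals > 0, median_total / totals, 0.0)
    return np.log1p(counts.counts * scale)


def build_association(
    counts: CountMatrix,
    annotation: Sequence[GeneRecord],
    receptor_classes: Sequence[GeneClass | str],
    panel: GeneClass | str,
    receptor_threshold: int = 10,
    panel_threshold: int = 3,
) -> AssociationTable:
    """Receptor x panel Fisher association table with BH across all cells.

    Receptors with zero presence cells are flagged and their tests skipped
    (p = NaN); mean expression is the mean log1p-normalized count of the
    panel gene over the receptor's presence cells.
    """
    panel = GeneClass(panel)
    receptor_genes = genes_of_class(annotation, receptor_classes)
    panel_genes = genes_of_class(annotation, [panel])
    if not panel_genes:
        raise ValueError(f"no {panel.value} genes in annotation")
    in_matrix = set(counts.gene_ids)
    receptor_ids = [g.gene_id for g in receptor_genes if g.gene_id in in_matrix]
    panel_ids = [g.gene_id for g in panel_genes if g.gene_id in in_matrix]
    if not receptor_ids:
        raise ValueError("no receptor genes of the requested classes in the matrix")

    r_counts = counts.counts[counts.gene_index(receptor_ids)]
    g_counts = counts.counts[counts.gene_index(panel_ids)]
    r_presence = r_counts >= receptor_threshold
    g_presence = g_counts >= panel_threshold

    n = counts.n_cells
    kr = r_presence.sum(axis=1).astype(np.int64)
    kg = g_presence.sum(axis=1).astype(np.int64)
    overlap = r_presence.astype(np.int64) @ g_presence.T.astype(np.int64)

    p = fisher_enrichment_p(
        overlap, kr[:, None] * np.ones_like(kg)[None, :],
        np.broadcast_to(kg, overlap.shape), n
    )
    flagged = [r for r, k in zip(receptor_ids, kr) if k == 0]
    flag_mask = kr == 0
    p = np.asarray(p, dtype=float)
    p[flag_mask, :] = np.nan

    padj = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        padj[valid] = bh_adjust(p[valid])

    norm = _normalized_log_expression(counts)
    g_norm = norm[counts.gene_index(panel_ids)]
    mean_expr = np.zeros((len(receptor_ids), len(panel_ids)))
    for i in range(len(receptor_ids)):
        cells = r_presence[i]
        if cells.any():
            mean_expr[i] = g_norm[:, cells].mean(axis=1)
        else:
            mean_expr[i] = np.nan

    def frame(values: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(values, index=receptor_ids, columns=panel_ids)

    return AssociationTable(
        panel=panel,
        receptor_ids=receptor_ids,
        panel_ids=panel_ids,
        mean_expression=frame(mean_expr),
        p_value=frame(p),
        p_adjusted=frame(padj),
        receptor_threshold=receptor_threshold,
        panel_threshold=panel_threshold,
        cell_barcodes=list(counts.cell_barcodes),
        receptor_presence=r_presence,
        panel_presence=g_presence,
        flagged_receptors=flagged,
    )


def _row_correlation(profiles: pd.DataFrame, kind: str) -> SimilarityMatrix:
    values = profiles.to_numpy(dtype=float)
    finite = np.isfinite(values).all(axis=1)
    variable = np.nanstd(values, axis=1) > 0
    keep = finite & variable
    excluded = [r for r, k in zip(profiles.index, keep) if not k]
    if keep.sum() < 2:
        raise ValueError("fewer than 2 receptors with variable finite profiles")
    kept = profiles.index[keep]
    corr = np.corrcoef(values[keep])
    frame = pd.DataFrame(corr, index=kept, columns=kept)
    return SimilarityMatrix(kind=kind, values=frame, excluded=excluded)


def profile_correlation(assoc: AssociationTable) -> SimilarityMatrix:
    """Pearson correlation between receptors' panel mean-expression profiles."""
    kind = "tf_profile" if assoc.panel == GeneClass.TF else "ag_profile"
    return _row_correlation(assoc.mean_expression, kind)


def sequence_similarity(sequences: dict[str, str]) -> SimilarityMatrix:
    """Global pairwise percent identity between receptor proteins.

    Needleman-Wunsch with BLOSUM62 scoring and affine gaps (open 11,
    extend 1); identity = identities / alignment length x 100.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    for name, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {name}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0

    ids = list(sequences)
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            alignment = aligner.align(sequences[ids[i]], sequences[ids[j]])[0]
            counts = alignment.counts()
            ident = 100.0 * counts.identities / alignment.length
            mat[i, j] = mat[j, i] = ident
    return SimilarityMatrix(
        kind="sequence", values=pd.DataFrame(mat, index=ids, columns=ids)
    )


def _offdiag_pairs(sim: SimilarityMatrix, order: list[str]) -> np.ndarray:
    values = sim.values.loc[order, order].to_numpy(dtype=float)
    iu = np.triu_indices(len(order), k=1)
    return values[iu]


def similarity_relation(
    seq: SimilarityMatrix, ag: SimilarityMatrix, n_bins: int = 20
) -> SimilarityRelation:
    """How panel-expression similarity tracks receptor sequence similarity.

    Off-diagonal receptor pairs are pooled; the first matrix is summarized
    (mean/median) in equal-width bins of the second and vice versa, and a
    Spearman correlation over all pairs is reported.
    """
    if set(seq.values.index) != set(ag.values.index):
        raise ValueError("similarity matrices cover different receptor sets")
    order = list(seq.values.index)
    x = _offdiag_pairs(seq, order)
    y = _offdiag_pairs(ag, order)

    def binned(by: np.ndarray, of: np.ndarray) -> pd.DataFrame:
        lo, hi = float(np.min(by)), float(np.max(by))
        if hi <= lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, n_bins + 1)
        which = np.clip(np.digitize(by, edges, right=False) - 1, 0, n_bins - 1)
        rows = []
        for b in range(n_bins):
            sel = which == b
            rows.append(
                {
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "n_pairs": int(sel.sum()),
                    "mean": float(np.mean(of[sel])) if sel.any() else np.nan,
                    "median": float(np.median(of[sel])) if sel.any() else np.nan,
                }
            )
        return pd.DataFrame(rows)

    rho, pval = stats.spearmanr(x, y)
    return SimilarityRelation(
        spearman_rho=float(rho),
        spearman_p=float(pval),
        n_pairs=len(x),
        by_second_bin=binned(y, x),  # bins on AG similarity, stats of sequence
        by_first_bin=binned(x, y),  # bins on sequence similarity, stats of AG
    )


def tf_ag_jaccard(
    assoc_tf: AssociationTable,
    assoc_ag: AssociationTable,
    receptor: str,
    alpha: float = 0.05,
    tf_ids: Optional[Sequence[str]] = None,
    ag_ids: Optional[Sequence[str]] = None,
) -> JaccardGrid:
    """TF x AG Jaccard grid within one receptor's presence cells.

    By default only panel genes significantly co-expressed with the
    receptor (padj <= alpha) enter the grid; explicit gene lists override
    the selection. J(t, a) = |T n A| / |T u A| where T and A are the
    barcode sets (within the receptor's cells) where the gene passes the
    panel presence threshold.
    """
    if assoc_tf.cell_barcodes != assoc_ag.cell_barcodes:
        raise ValueError("association tables built over different cells")
    tfs = list(tf_ids) if tf_ids is not None else assoc_tf.significant_partners(receptor, alpha)
    ags = list(ag_ids) if ag_ids is not None else assoc_ag.significant_partners(receptor, alpha)
    if not tfs or not ags:
        return JaccardGrid(
            receptor=receptor, tf_ids=tfs, ag_ids=ags,
            jaccard=pd.DataFrame(index=tfs, columns=ags, dtype=float), empty=True,
        )
    r_row = assoc_tf.receptor_ids.index(receptor)
    cells = assoc_tf.receptor_presence[r_row]

    def presence_in_cells(assoc: AssociationTable, gene: str) -> np.ndarray:
        g_row = assoc.panel_ids.index(gene)
        return assoc.panel_presence[g_row] & cells

    grid = np.zeros((len(tfs), len(ags)))
    t_sets = [presence_in_cells(assoc_tf, t) for t in tfs]
    a_sets = [presence_in_cells(assoc_ag, a) for a in ags]
    for i, t in enumerate(t_sets):
        for j, a in enumerate(a_sets):
            union = (t | a).sum()
            grid[i, j] = (t & a).sum() / union if union else 0.0
    return JaccardGrid(
        receptor=receptor,
        tf_ids=tfs,
        ag_ids=ags,
        jaccard=pd.DataFrame(grid, index=tfs, columns=ags),
        empty=False,
    )


def receptor_type_correlation(
    assoc_tf: Optional[AssociationTable], assoc_ag: Optional[AssociationTable]
) -> SimilarityMatrix:
    """Receptor-type similarity from concatenated TF + AG expression profiles."""
    frames = []
    for assoc in (assoc_tf, assoc_ag):
        if assoc is not None and assoc.panel_ids:
            frames.append(assoc.mean_expression)
    if not frames:
        raise ValueError("both panels empty: no profiles to correlate")
    if len(frames) == 1:
        logger.warning("one panel empty; receptor-type correlation uses the other alone")
        combined = frames[0]
    else:
        if list(frames[0].index) != list(frames[1].index):
            raise ValueError("association tables cover different receptors")
        combined = pd.concat(frames, axis=1)
    sim = _row_correlation(combined, "combined")
    return sim
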