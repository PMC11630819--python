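"""Per-receptor expression summaries and the rank-probability power law.

Within each chemoreceptor family, the probability that a cell expresses a
given receptor falls off with the receptor's rank approximately as
p_r ~ r^(-alpha); the low-rank tail deviates downward (technical dropout of
weakly expressed genes) and is excluded from the fit by a detected-cell
floor rather than a rank cutoff. "Expressing" here means any nonzero raw
count — the presence threshold (>= 10 counts) belongs to co-expression
calling, not to these summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, GeneClass, GeneRecord, genes_of_class


@dataclass
class PowerLawFit:
    """Least-squares fit of log expression probability on log rank."""

    alpha_hat: float
    intercept: float
    r_squared: float
    fit_range: tuple[int, int]
    n_fitted: int


class FitError(ValueError):
    """Too few usable receptors for a power-law fit."""


def summarize_receptors(
    counts: CountMatrix,
    annotation: Sequence[GeneRecord],
    gene_class: GeneClass | str,
    include_pseudogenes: bool = True,
) -> pd.DataFrame:
    """One row per receptor of the class: totals, expressing cells, mean.

    Receptors never detected are retained with zeros (``mean_undefined``
    flags them); ranks (1..K, by mean expression per expressing cell,
    descending) break ties by gene id for determinism.
    """
    gene_class = GeneClass(gene_class)
    genes = genes_of_class(annotation, [gene_class], include_pseudogenes)
    if not genes:
        raise ValueError(f"no genes of class {gene_class.value} in annotation")
    present = [g for g in genes if g.gene_id in set(counts.gene_ids)]
    absent = [g for g in genes if g.gene_id not in set(counts.gene_ids)]

    rows = []
    if present:
        idx = counts.gene_index([g.gene_id for g in present])
        sub = counts.counts[idx]
        totals = sub.sum(axis=1)
        n_cells = (sub > 0).sum(axis=1)
        for g, tot, n in zip(present, totals, n_cells):
            rows.append((g.gene_id, int(tot), int(n), g.pseudogene))
    for g in absent:
        rows.append((g.gene_id, 0, 0, g.pseudogene))

    frame = pd.DataFrame(
        rows, columns=["gene_id", "total_counts", "n_cells_expressing", "pseudogene"]
    )
    with np.errstate(invalid="ignore"):
        mean = frame["total_counts"] / frame["n_cells_expressing"]
    frame["mean_undefined"] = frame["n_cells_expressing"] == 0
    frame["mean_counts_per_expressing_cell"] = mean.where(~frame["mean_undefined"], 0.0)
    frame["gene_class"] = gene_class.value
    frame = frame.sort_values(
        ["mean_counts_per_expressing_cell", "gene_id"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame["rank_by_mean"] = np.arange(1, len(frame) + 1)
    return frame


def fit_power_law(summary: pd.DataFrame, min_cells_floor: int = 10) -> PowerLawFit:
    """Fit p_r ~ r^(-alpha) by OLS on (log rank, log p).

    p_r is the receptor's share of expressing cells,
    n_cells_expressing_r / sum_r n_cells_expressing, ranked descending;
    receptors below ``min_cells_floor`` detected cells (the dropout tail)
    are excluded from the regression.
    """
    n_cells = summary["n_cells_expressing"].to_numpy(dtype=float)
    total = n_cells.sum()
    if total <= 0:
        raise FitError("no expressing cells in summary")
    order = np.argsort(-n_cells, kind="mergesort")
    sorted_cells = n_cells[order]
    ranks = np.arange(1, len(sorted_cells) + 1, dtype=float)
    usable = sorted_cells >= min_cells_floor
    if usable.sum() < 5:
        raise FitError(
            f"only {int(usable.sum())} receptors at or above the {min_cells_floor}-cell floor; need >= 5"
        )
    p = sorted_cells[usable] / total
    x = np.log(ranks[usable])
    y = np.log(p)
    res = stats.linregress(x, y)
    return PowerLawFit(
        alpha_hat=float(-res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_range=(int(ranks[usable][0]), int(ranks[usable][-1])),
        n_fitted=int(usable.sum()),
    )


def expression_cells_relation(summary: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of total counts on expressing-cell number, plus Pearson r.

    A tight relation (r near 1) means receptors reach similar per-cell
    levels; a weak one means per-cell expression varies between receptors.
    """
    sub = summary[summary["total_counts"] > 0]
    if len(sub) < 3:
        raise ValueError("need >= 3 receptors with nonzero totals")
    x = sub["n_cells_expressing"].to_numpy(dtype=float)
    y = sub["total_counts"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in expressing-cell numbers: correlation undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def bin_mean_expression(
    summary: pd.DataFrame, bin_edges: Sequence[float] = (0.0, 10.0, 100.0, np.inf)
) -> np.ndarray:
    """Histogram receptors by mean counts per expressing cell.

    Bins are half-open [lo, hi); default edges split at the decade
    boundaries 10 and 100.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    means = summary.loc[
        ~summary["mean_undefined"], "mean_counts_per_expressing_cell"
    ].to_numpy(dtype=float)
    if means.size == 0:
        return np.zeros(len(edges) - 1, dtype=int)
    which = np.digitize(means, edges, right=False) - 1
    valid = (which >= 0) & (which < len(edges) - 1)
    return np.bincount(which[valid], minlength=len(edges) - 1).astype(int)
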