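"""Standard recovery experiments on synthetic data with planted truth.

Each experiment generates data under the study conditions of the package's
validation suite, runs the corresponding pipeline stage, and measures how
well the planted parameters are recovered. The problem sizes (cells, seeds,
planted-pair counts) are the package's reference conditions and are shared
between the test suite and the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._stats import bh_adjust, fisher_enrichment_p
from .coexpression import binarize_presence, genomic_colocalization, pairwise_fisher
from .code import build_association, profile_correlation, tf_ag_jaccard
from .quantify import fit_power_law, summarize_receptors
from .synthetic import (
    SyntheticTruth,
    block_code_truth,
    coexpression_truth,
    simulate_counts,
    simulate_spatial,
)
from .zones import assign_zones, zone_enrichment

#: Field of view and neural/non-neuronal boundary used by spatial experiments.
GEOMETRY = (6000.0, 4000.0)
LANDMARKS = np.array([[0.0, y] for y in np.linspace(0.0, 4000.0, 9)])


def _seeds(base_seed: int, n: int) -> list[int]:
    # keep derived seeds well below 2**31
    return [(base_seed * 1000 + i) % (2**31 - 1) for i in range(n)]


# ---------------------------------------------------------------------------
# Fisher oracle sweep
# ---------------------------------------------------------------------------

def brute_force_enrichment_p(n11: int, k_a: int, k_b: int, n: int) -> float:
    """Hypergeometric upper-tail by direct enumeration (independent oracle)."""
    denom = math.comb(n, k_b)
    total = 0
    for k in range(n11, min(k_a, k_b) + 1):
        if k_b - k <= n - k_a:
            total += math.comb(k_a, k) * math.comb(n - k_a, k_b - k)
    return total / denom


def fisher_oracle_sweep(max_n: int = 25) -> tuple[float, int]:
    """Max |pipeline p - enumeration p| over every 2x2 table with N <= max_n."""
    worst = 0.0
    n_tables = 0
    for n in range(1, max_n + 1):
        for k_a in range(n + 1):
            for k_b in range(n + 1):
                lo = max(0, k_a + k_b - n)
                hi = min(k_a, k_b)
                n11s = np.arange(lo, hi + 1)
                p_impl = fisher_enrichment_p(
                    n11s, np.full_like(n11s, k_a), np.full_like(n11s, k_b), n
                )
                for n11, p in zip(n11s, p_impl):
                    worst = max(
                        worst, abs(p - brute_force_enrichment_p(int(n11), k_a, k_b, n))
                    )
                    n_tables += 1
    return worst, n_tables


# ---------------------------------------------------------------------------
# co-expression recovery
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionRecovery:
    sensitivity: float
    fdr: float
    same_chromosome_fraction: float
    n_seeds: int


def coexpression_recovery(
    base_seed: int,
    n_seeds: int = 20,
    n_cells: int = 3000,
    alpha: float = 0.05,
) -> CoexpressionRecovery:
    """Planted-pair recovery: 60 receptors, 12 pairs (co_prob 0.8, 8 intra-
    chromosomal) per seed; sensitivity, empirical FDR, and the recovered
    same-chromosome fraction among significant pairs."""
    tps, fps, fns, fracs = 0, 0, 0, []
    for seed in _seeds(base_seed, n_seeds):
        truth = coexpression_truth(seed=seed)
        sim = simulate_counts(truth, n_cells)
        presence = binarize_presence(sim.counts, sim.annotation, ["V1R"])
        results = pairwise_fisher(presence, annotation=sim.annotation)
        called = {
            frozenset((r.gene_a, r.gene_b)) for r in results if r.p_adjusted <= alpha
        }
        planted = {
            frozenset((p.receptor_a, p.receptor_b)) for p in truth.planted_pairs
        }
        tps += len(called & planted)
        fps += len(called - planted)
        fns += len(planted - called)
        summary = genomic_colocalization(results, sim.annotation, alpha=alpha)
        if summary.fraction_defined:
            fracs.append(summary.fraction_same_chromosome)
    return CoexpressionRecovery(
        sensitivity=tps / (tps + fns) if tps + fns else float("nan"),
        fdr=fps / (tps + fps) if tps + fps else 0.0,
        same_chromosome_fraction=float(np.mean(fracs)) if fracs else float("nan"),
        n_seeds=n_seeds,
    )


# ---------------------------------------------------------------------------
# power-law recovery
# ---------------------------------------------------------------------------

def power_law_recovery(
    base_seed: int,
    n_seeds: int = 10,
    n_cells: int = 20000,
    alpha_true: float = 1.2,
) -> float:
    """Mean fitted exponent over seeds for a planted rank-choice exponent.

    Uses ambient-free data: the rank-probability summaries correspond to
    ambient-cleaned input (contamination removal is upstream of these
    analyses), and detection there is any-nonzero rather than thresholded.
    """
    alphas = []
    for seed in _seeds(base_seed, n_seeds):
        truth = SyntheticTruth(seed=seed, alpha=alpha_true, ambient_rate=0.0)
        sim = simulate_counts(truth, n_cells)
        summary = summarize_receptors(sim.counts, sim.annotation, "V1R")
        alphas.append(fit_power_law(summary).alpha_hat)
    return float(np.mean(alphas))


# ---------------------------------------------------------------------------
# TF/AG code recovery
# ---------------------------------------------------------------------------

@dataclass
class CodeRecovery:
    top1_tf_recovery: float
    jaccard_separation_wins: int
    block_correlation_wins: int
    n_seeds: int


def code_recovery(
    base_seed: int, n_seeds: int = 20, n_cells: int = 3000
) -> CodeRecovery:
    """Recovery of the planted receptor -> TF/AG wiring.

    Per seed: fraction of receptors whose strongest TF association (min p)
    is a planted TF; whether planted TF-AG pairs out-Jaccard unplanted ones
    on average; and whether within-block profile correlation exceeds
    between-block.
    """
    top1_rates = []
    jaccard_wins = 0
    corr_wins = 0
    for seed in _seeds(base_seed, n_seeds):
        truth = block_code_truth(seed=seed)
        sim = simulate_counts(truth, n_cells)
        assoc_tf = build_association(sim.counts, sim.annotation, ["V1R"], "TF")
        assoc_ag = build_association(sim.counts, sim.annotation, ["V1R"], "AG")

        hits, total = 0, 0
        planted_js, unplanted_js = [], []
        for rid, entry in truth.code_map.items():
            if rid not in assoc_tf.p_value.index or rid in assoc_tf.flagged_receptors:
                continue
            total += 1
            if assoc_tf.p_value.loc[rid].idxmin() in entry.tf_ids:
                hits += 1
            other_tfs = [t for t in truth.tf_ids() if t not in entry.tf_ids][:2]
            other_ags = [a for a in truth.ag_ids() if a not in entry.ag_ids][:3]
            grid = tf_ag_jaccard(
                assoc_tf, assoc_ag, rid,
                tf_ids=list(entry.tf_ids) + other_tfs,
                ag_ids=list(entry.ag_ids) + other_ags,
            )
            for t in grid.tf_ids:
                for a in grid.ag_ids:
                    value = float(grid.jaccard.loc[t, a])
                    if t in entry.tf_ids and a in entry.ag_ids:
                        planted_js.append(value)
                    else:
                        unplanted_js.append(value)
        top1_rates.append(hits / total if total else float("nan"))
        if planted_js and np.mean(planted_js) > np.mean(unplanted_js):
            jaccard_wins += 1

        sim_tf = profile_correlation(assoc_tf)
        ids = list(sim_tf.values.index)
        receptor_order = truth.receptor_ids("V1R")
        block = {r: i * 6 // len(receptor_order) for i, r in enumerate(receptor_order)}
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                bucket = within if block[ids[i]] == block[ids[j]] else between
                bucket.append(sim_tf.values.iloc[i, j])
        if within and between and np.mean(within) > np.mean(between):
            corr_wins += 1
    return CodeRecovery(
        top1_tf_recovery=float(np.mean(top1_rates)),
        jaccard_separation_wins=jaccard_wins,
        block_correlation_wins=corr_wins,
        n_seeds=n_seeds,
    )


# ---------------------------------------------------------------------------
# zone enrichment: type-I control and power
# ---------------------------------------------------------------------------

@dataclass
class ZoneExperiment:
    max_null_significant: int
    mean_null_significant: float
    power: float
    n_seeds: int


def zone_experiment(
    base_seed: int, n_seeds: int = 20, n_cells: int = 2000
) -> ZoneExperiment:
    """Null calibration (10 types, no enrichment) and power at a planted
    3x marginal enrichment of GBCs."""
    null_types = [f"T{i}" for i in range(10)]
    null_counts = []
    power_hits = 0
    for seed in _seeds(base_seed, n_seeds):
        null_truth = SyntheticTruth(
            seed=seed,
            composition={t: 0.1 for t in null_types},
            progenitor_types=tuple(null_types),
        )
        sim = simulate_counts(null_truth, n_cells)
        cells = simulate_spatial(null_truth, sim.cells, GEOMETRY, LANDMARKS)
        table = zone_enrichment(assign_zones(cells, LANDMARKS), cells, null_types)
        null_counts.append(int((table["p_adjusted"] <= 0.05).sum()))

        power_truth = SyntheticTruth(
            seed=seed + 500_000,
            progenitor_types=("GBC", "INP", "iVSN", "mVSN", "sVSN"),
            zone_enrichment={"GBC": 3.0},
        )
        sim2 = simulate_counts(power_truth, n_cells)
        cells2 = simulate_spatial(power_truth, sim2.cells, GEOMETRY, LANDMARKS)
        table2 = zone_enrichment(
            assign_zones(cells2, LANDMARKS), cells2, ["GBC", "INP", "iVSN"]
        )
        padj = float(table2.loc[table2["cell_type"] == "GBC", "p_adjusted"].iloc[0])
        if padj <= 0.05:
            power_hits += 1
    return ZoneExperiment(
        max_null_significant=max(null_counts),
        mean_null_significant=float(np.mean(null_counts)),
        power=power_hits / n_seeds,
        n_seeds=n_seeds,
    )
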