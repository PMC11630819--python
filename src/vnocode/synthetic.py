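"""Synthetic vomeronasal single-cell data with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a power-law rank-abundance of receptor choice, predominantly
one-receptor-per-cell expression with planted co-expressed pairs (enriched
on the same chromosome), receptor-linked transcription-factor / axon-guidance
programs, ambient contamination and capture dropout, and marginal-zone
enrichment of progenitor cell types. Every generator is a pure function of
a :class:`SyntheticTruth` (including its seed), so recovery experiments can
compare pipeline output against the planted parameters exactly.

Count model
-----------
Each receptor-expressing cell draws one *primary* receptor within its class
with probability proportional to rank^(-alpha). Primary (and, for planted
pairs, partner) transcript numbers are drawn as ``floor + NB(mean - floor)``
with ``floor`` equal to the presence count threshold, so in the noise-free
limit (ambient 0, capture 1) a mature cell always carries exactly one
receptor at or above threshold. Ambient contamination adds Poisson counts on
off-target receptors; the whole matrix is binomially thinned by the capture
rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import (
    AgeGroup,
    CellRecord,
    CountMatrix,
    GeneClass,
    GeneRecord,
    Sex,
)


class ConfigurationError(ValueError):
    """A SyntheticTruth is internally inconsistent."""


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedPair:
    """A receptor pair planted to co-express."""

    receptor_a: str
    receptor_b: str
    co_prob: float
    same_chromosome: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_prob <= 1.0:
            raise ConfigurationError(f"co_prob {self.co_prob} not in [0,1]")


@dataclass(frozen=True)
class CodeEntry:
    """The TF/AG program wired to one receptor."""

    tf_ids: tuple[str, ...]
    ag_ids: tuple[str, ...]
    mean: float = 8.0


@dataclass
class SyntheticTruth:
    """Planted generative parameters; the oracle for recovery tests."""

    alpha: float = 1.2
    n_receptors_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"V1R": 60}
    )
    planted_pairs: tuple[PlantedPair, ...] = ()
    code_map: Mapping[str, CodeEntry] = field(default_factory=dict)
    n_tf: int = 30
    n_ag: int = 45
    n_other: int = 10
    background_mean: float = 0.3
    other_mean: float = 1.0
    ambient_rate: float = 0.5
    capture_rate: float = 0.8
    primary_mean: float = 60.0
    partner_mean: float = 40.0
    nb_size: float = 5.0
    count_floor: int = 10
    n_chromosomes: int = 5
    composition: Mapping[str, float] = field(
        default_factory=lambda: {
            "GBC": 0.05,
            "INP": 0.10,
            "iVSN": 0.20,
            "mVSN": 0.60,
            "sVSN": 0.05,
        }
    )
    progenitor_types: tuple[str, ...] = ("GBC", "INP")
    immature_types: tuple[str, ...] = ("iVSN",)
    immature_multiplier: float = 2.0
    p14_multiplier: float = 1.5
    p14_fraction: float = 0.5
    zone_enrichment: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if not 0.0 < self.capture_rate <= 1.0:
            raise ConfigurationError("capture_rate must be in (0, 1]")
        if self.ambient_rate < 0:
            raise ConfigurationError("ambient_rate must be >= 0")
        if any(n <= 0 for n in self.n_receptors_per_class.values()):
            raise ConfigurationError("n_receptors_per_class entries must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(
                f"composition probabilities sum to {total}, expected 1"
            )
        if self.primary_mean <= self.count_floor:
            raise ConfigurationError("primary_mean must exceed count_floor")
        if self.partner_mean <= self.count_floor:
            raise ConfigurationError("partner_mean must exceed count_floor")
        for mult in self.zone_enrichment.values():
            if mult < 1.0:
                raise ConfigurationError("zone_enrichment multipliers must be >= 1")

    def receptor_ids(self, gene_class: str) -> list[str]:
        """Receptor ids of one class in rank order (rank 1 first)."""
        n = self.n_receptors_per_class[gene_class]
        return [f"{gene_class}_{i:03d}" for i in range(1, n + 1)]

    def all_receptor_ids(self) -> list[str]:
        out: list[str] = []
        for cls in self.n_receptors_per_class:
            out.extend(self.receptor_ids(cls))
        return out

    def tf_ids(self) -> list[str]:
        return [f"TF_{i:03d}" for i in range(1, self.n_tf + 1)]

    def ag_ids(self) -> list[str]:
        return [f"AG_{i:03d}" for i in range(1, self.n_ag + 1)]


@dataclass
class SimulatedDataset:
    """Counts + cells plus the per-cell bookkeeping recovery tests need."""

    counts: CountMatrix
    cells: list[CellRecord]
    annotation: list[GeneRecord]
    truth: SyntheticTruth
    primary_receptor: list[Optional[str]]
    partner_receptor: list[Optional[str]]

    def __iter__(self):
        return iter((self.counts, self.cells))


def power_law_probabilities(n_ranks: int, alpha: float) -> np.ndarray:
    """Normalized choice probabilities p_r proportional to r^(-alpha)."""
    ranks = np.arange(1, n_ranks + 1, dtype=float)
    weights = ranks ** (-alpha)
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# annotation layout
# ---------------------------------------------------------------------------

#: Gene spacing within a chromosome; planted same-chromosome partners are
#: adjacent, hence one spacing (< 1 Mb) apart.
_GENE_SPACING_BP = 200_000
_GENE_LENGTH_BP = 1_000
_PANEL_OFFSET_BP = 100_000_000
_PANEL_SPACING_BP = 50_000


def generate_annotation(truth: SyntheticTruth) -> list[GeneRecord]:
    """Deterministic genome layout honoring the planted pair topology.

    Receptors are clustered on ``n_chromosomes`` chromosomes so that planted
    same-chromosome pairs sit adjacently (< 1 Mb apart) while cross-chromosome
    pairs land on distinct chromosomes; TF/AG/other genes are spread
    round-robin in a separate coordinate region.
    """
    receptor_set = set(truth.all_receptor_ids())
    for pair in truth.planted_pairs:
        for rid in (pair.receptor_a, pair.receptor_b):
            if rid not in receptor_set:
                raise ConfigurationError(
                    f"planted pair references unknown receptor {rid!r}"
                )
        if pair.receptor_a == pair.receptor_b:
            raise ConfigurationError("planted pair must involve two receptors")

    chroms = [f"chr{i + 1}" for i in range(truth.n_chromosomes)]
    chrom_of: dict[str, str] = {}
    cursor = 0

    def next_chrom(exclude: Optional[str] = None) -> str:
        nonlocal cursor
        for _ in range(len(chroms)):
            c = chroms[cursor % len(chroms)]
            cursor += 1
            if c != exclude:
                return c
        raise ConfigurationError(
            "cannot place a cross-chromosome pair with a single chromosome"
        )

    for pair in truth.planted_pairs:
        a, b = pair.receptor_a, pair.receptor_b
        if pair.same_chromosome:
            c = chrom_of.get(a) or chrom_of.get(b) or next_chrom()
            if chrom_of.get(a, c) != c or chrom_of.get(b, c) != c:
                raise ConfigurationError(
                    f"conflicting chromosome constraints for pair ({a}, {b})"
                )
            chrom_of[a] = chrom_of[b] = c
        else:
            if len(chroms) < 2:
                raise ConfigurationError(
                    "cannot place a cross-chromosome pair with a single chromosome"
                )
            ca = chrom_of.get(a) or next_chrom()
            cb = chrom_of.get(b)
            if cb is None:
                cb = next_chrom(exclude=ca)
            if ca == cb:
                raise ConfigurationError(
                    f"conflicting chromosome constraints for pair ({a}, {b})"
                )
            chrom_of[a], chrom_of[b] = ca, cb

    for rid in truth.all_receptor_ids():
        if rid not in chrom_of:
            chrom_of[rid] = next_chrom()

    # per-chromosome gene order: same-chromosome partners first, adjacently
    order: dict[str, list[str]] = {c: [] for c in chroms}
    placed: set[str] = set()
    for pair in truth.planted_pairs:
        if pair.same_chromosome:
            c = chrom_of[pair.receptor_a]
            for rid in (pair.receptor_a, pair.receptor_b):
                if rid not in placed:
                    order[c].append(rid)
                    placed.add(rid)
    for rid in truth.all_receptor_ids():
        if rid not in placed:
            order[chrom_of[rid]].append(rid)
            placed.add(rid)

    class_of = {
        rid: GeneClass(cls)
        for cls in truth.n_receptors_per_class
        for rid in truth.receptor_ids(cls)
    }
    records: list[GeneRecord] = []
    for c in chroms:
        for k, rid in enumerate(order[c]):
            start = 1 + k * _GENE_SPACING_BP
            records.append(
                GeneRecord(
                    gene_id=rid,
                    gene_class=class_of[rid],
                    chromosome=c,
                    start_bp=start,
                    end_bp=start + _GENE_LENGTH_BP - 1,
                )
            )
    # receptors keep rank order in the returned list
    rank_order = {rid: i for i, rid in enumerate(truth.all_receptor_ids())}
    records.sort(key=lambda r: rank_order[r.gene_id])

    panel_genes = (
        [(g, GeneClass.TF) for g in truth.tf_ids()]
        + [(g, GeneClass.AG) for g in truth.ag_ids()]
        + [(f"OTH_{i:03d}", GeneClass.OTHER) for i in range(1, truth.n_other + 1)]
    )
    per_chrom_panel = {c: 0 for c in chroms}
    for i, (gid, gcls) in enumerate(panel_genes):
        c = chroms[i % len(chroms)]
        start = _PANEL_OFFSET_BP + per_chrom_panel[c] * _PANEL_SPACING_BP
        per_chrom_panel[c] += 1
        records.append(
            GeneRecord(
                gene_id=gid,
                gene_class=gcls,
                chromosome=c,
                start_bp=start,
                end_bp=start + _GENE_LENGTH_BP - 1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _draw_signal(
    rng: np.random.Generator, n: int, mean: float, size: float, floor: int
) -> np.ndarray:
    """floor + NB(mean - floor): transcript numbers guaranteed >= floor."""
    excess = mean - floor
    p = size / (size + excess)
    return floor + rng.negative_binomial(size, p, size=n)


def simulate_counts(
    truth: SyntheticTruth,
    n_cells: int,
    annotation: Optional[list[GeneRecord]] = None,
) -> SimulatedDataset:
    """Simulate a raw genes x cells count matrix plus cell metadata.

    Deterministic given ``truth`` (including its seed).
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if annotation is None:
        annotation = generate_annotation(truth)
    gene_ids = [r.gene_id for r in annotation]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for entry in truth.code_map.values():
        for gid in list(entry.tf_ids) + list(entry.ag_ids):
            if gid not in gene_pos:
                raise ConfigurationError(f"code_map references unknown gene {gid!r}")

    rng = np.random.default_rng([truth.seed, 2])

    types = list(truth.composition)
    probs = np.array([truth.composition[t] for t in types])
    cell_types = rng.choice(types, size=n_cells, p=probs)
    ages = np.where(
        rng.random(n_cells) < truth.p14_fraction, AgeGroup.P14.value, AgeGroup.P56.value
    )
    sexes = rng.choice([Sex.M.value, Sex.F.value], size=n_cells)

    classes = list(truth.n_receptors_per_class)
    class_sizes = np.array([truth.n_receptors_per_class[c] for c in classes], float)
    class_probs = class_sizes / class_sizes.sum()
    rank_probs = {c: power_law_probabilities(int(truth.n_receptors_per_class[c]), truth.alpha) for c in classes}

    pair_partner: dict[str, tuple[str, float]] = {}
    for pair in truth.planted_pairs:
        pair_partner[pair.receptor_a] = (pair.receptor_b, pair.co_prob)
        pair_partner[pair.receptor_b] = (pair.receptor_a, pair.co_prob)

    n_genes = len(gene_ids)
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)

    # ambient contamination on receptors
    receptor_rows = np.array(
        [gene_pos[r] for r in truth.all_receptor_ids()], dtype=int
    )
    if truth.ambient_rate > 0 and receptor_rows.size:
        counts[receptor_rows, :] = rng.poisson(
            truth.ambient_rate, size=(receptor_rows.size, n_cells)
        )

    # panel background
    tf_rows = np.array([gene_pos[g] for g in truth.tf_ids()], dtype=int)
    ag_rows = np.array([gene_pos[g] for g in truth.ag_ids()], dtype=int)
    panel_rows = np.concatenate([tf_rows, ag_rows]).astype(int)
    if truth.background_mean > 0 and panel_rows.size:
        counts[panel_rows, :] = rng.poisson(
            truth.background_mean, size=(panel_rows.size, n_cells)
        )
    other_rows = np.array(
        [gene_pos[g] for g in gene_ids if g.startswith("OTH_")], dtype=int
    )
    if truth.other_mean > 0 and other_rows.size:
        counts[other_rows, :] = rng.poisson(
            truth.other_mean, size=(other_rows.size, n_cells)
        )

    primary: list[Optional[str]] = [None] * n_cells
    partner: list[Optional[str]] = [None] * n_cells
    expressing = ~np.isin(cell_types, truth.progenitor_types)

    for i in np.where(expressing)[0]:
        cls = classes[rng.choice(len(classes), p=class_probs)] if len(classes) > 1 else classes[0]
        ids = truth.receptor_ids(cls)
        r_idx = rng.choice(len(ids), p=rank_probs[cls])
        rid = ids[r_idx]
        primary[i] = rid
        row = gene_pos[rid]
        counts[row, i] = _draw_signal(
            rng, 1, truth.primary_mean, truth.nb_size, truth.count_floor
        )[0]
        if rid in pair_partner:
            partner_id, co_prob = pair_partner[rid]
            eff = co_prob
            if cell_types[i] in truth.immature_types:
                eff *= truth.immature_multiplier
            if ages[i] == AgeGroup.P14.value:
                eff *= truth.p14_multiplier
            eff = min(1.0, eff)
            if rng.random() < eff:
                partner[i] = partner_id
                prow = gene_pos[partner_id]
                counts[prow, i] = _draw_signal(
                    rng, 1, truth.partner_mean, truth.nb_size, truth.count_floor
                )[0]
        entry = truth.code_map.get(rid)
        if entry is not None:
            for gid in list(entry.tf_ids) + list(entry.ag_ids):
                counts[gene_pos[gid], i] = rng.poisson(entry.mean)

    if truth.capture_rate < 1.0:
        counts = rng.binomial(counts, truth.capture_rate)

    cells = [
        CellRecord(
            barcode=f"cell{i:05d}",
            cell_type=str(cell_types[i]),
            age_group=AgeGroup(str(ages[i])),
            sex=Sex(str(sexes[i])),
            sample_id=f"{ages[i]}_{sexes[i]}",
            prediction_score=None,
        )
        for i in range(n_cells)
    ]
    matrix = CountMatrix(counts, gene_ids, [c.barcode for c in cells])
    return SimulatedDataset(matrix, cells, annotation, truth, primary, partner)


# ---------------------------------------------------------------------------
# spatial simulation
# ---------------------------------------------------------------------------

def marginal_area_fraction(
    geometry: tuple[float, float],
    landmarks: np.ndarray,
    radius: float,
    grid: int = 400,
) -> float:
    """Fraction of the field of view within ``radius`` of a landmark.

    Deterministic grid estimate (grid x grid evaluation points).
    """
    w, h = geometry
    tree = cKDTree(np.asarray(landmarks, dtype=float))
    xs = (np.arange(grid) + 0.5) * (w / grid)
    ys = (np.arange(grid) + 0.5) * (h / grid)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    d, _ = tree.query(pts)
    return float(np.mean(d <= radius))


def simulate_spatial(
    truth: SyntheticTruth,
    cells: Sequence[CellRecord],
    geometry: tuple[float, float],
    landmarks: np.ndarray,
    r1: float = 750.0,
    r2: float = 1500.0,
    score_range: tuple[float, float] = (0.4, 1.0),
) -> list[CellRecord]:
    """Place cells in the field of view with planted marginal-zone enrichment.

    Positions are uniform; cell types with ``zone_enrichment`` multiplier
    m > 1 are resampled into the marginal zone (within r1 of the nearest
    landmark) with the move probability that multiplies their marginal
    density by exactly m: a cell landing outside the zone moves in with
    probability f(m-1)/(1-f), f being the marginal area fraction.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.ndim != 2 or landmarks.shape[0] < 1:
        raise ConfigurationError("at least one landmark is required")
    w, h = geometry
    if w < 2 * r2 or h < 2 * r2:
        raise ConfigurationError(
            f"geometry {geometry} smaller than 2*r2={2 * r2}: zones degenerate"
        )
    rng = np.random.default_rng([truth.seed, 3])
    tree = cKDTree(landmarks)
    f = marginal_area_fraction(geometry, landmarks, r1)
    if any(m > 1 for m in truth.zone_enrichment.values()) and f <= 0:
        raise ConfigurationError("no marginal area under the given landmarks")

    n = len(cells)
    xs = rng.uniform(0, w, size=n)
    ys = rng.uniform(0, h, size=n)
    dists, _ = tree.query(np.column_stack([xs, ys]))

    def sample_in_marginal() -> tuple[float, float]:
        for _ in range(100_000):
            x, y = rng.uniform(0, w), rng.uniform(0, h)
            if tree.query([[x, y]])[0][0] <= r1:
                return x, y
        raise ConfigurationError("marginal zone too small to sample")

    out: list[CellRecord] = []
    for i, cell in enumerate(cells):
        x, y, d = xs[i], ys[i], dists[i]
        mult = truth.zone_enrichment.get(cell.cell_type, 1.0)
        if mult > 1.0 and d > r1:
            p_move = min(1.0, f * (mult - 1.0) / (1.0 - f))
            if rng.random() < p_move:
                x, y = sample_in_marginal()
        score = cell.prediction_score
        if score is None:
            score = float(rng.uniform(*score_range))
        out.append(replace(cell, x_px=float(x), y_px=float(y), prediction_score=score))
    return out


# ---------------------------------------------------------------------------
# receptor protein sequences
# ---------------------------------------------------------------------------

def generate_receptor_sequences(
    receptor_ids: Sequence[str],
    groups: Mapping[str, int],
    seed: int,
    length: int = 120,
    within_divergence: float = 0.05,
) -> dict[str, str]:
    """Synthetic receptor proteins with cluster structure.

    Receptors sharing a group index descend from one random ancestor with
    per-site substitution probability ``within_divergence``; distinct groups
    are unrelated random sequences.
    """
    rng = np.random.default_rng([seed, 4])
    aa = np.array(list(AMINO_ACIDS))
    bases: dict[int, np.ndarray] = {}
    for g in sorted(set(groups.values())):
        bases[g] = rng.choice(aa, size=length)
    seqs: dict[str, str] = {}
    for rid in receptor_ids:
        base = bases[groups[rid]].copy()
        mutate = rng.random(length) < within_divergence
        base[mutate] = rng.choice(aa, size=int(mutate.sum()))
        seqs[rid] = "".join(base)
    return seqs


# ---------------------------------------------------------------------------
# canned truth builders for the standard recovery experiments
# ---------------------------------------------------------------------------

def coexpression_truth(
    seed: int,
    n_receptors: int = 60,
    n_pairs: int = 12,
    n_same_chromosome: int = 8,
    co_prob: float = 0.8,
    first_paired_rank: int = 5,
    **overrides,
) -> SyntheticTruth:
    """Truth for the planted-pair recovery experiment.

    Pairs are planted on consecutive mid-ranked receptors (ranks
    ``first_paired_rank`` onward) so every planted receptor is detected in
    comfortably more cells than the ``min_cells`` retention floor.
    """
    ids = [f"V1R_{i:03d}" for i in range(1, n_receptors + 1)]
    pairs = []
    r = first_paired_rank - 1
    for k in range(n_pairs):
        pairs.append(
            PlantedPair(ids[r], ids[r + 1], co_prob, same_chromosome=k < n_same_chromosome)
        )
        r += 2
    return SyntheticTruth(
        n_receptors_per_class={"V1R": n_receptors},
        planted_pairs=tuple(pairs),
        seed=seed,
        **overrides,
    )


def block_code_truth(
    seed: int,
    n_receptors: int = 30,
    n_blocks: int = 6,
    tfs_per_receptor: int = 2,
    ags_per_receptor: int = 3,
    code_mean: float = 8.0,
    receptor_class: str = "V1R",
    **overrides,
) -> SyntheticTruth:
    """Truth for the TF/AG code-recovery experiment.

    Receptors are grouped into ``n_blocks`` blocks; every receptor in a block
    shares the same disjoint TF and AG sets, wired at ``code_mean`` expected
    counts against a low background — the planted "code".
    """
    truth = SyntheticTruth(
        n_receptors_per_class={receptor_class: n_receptors},
        seed=seed,
        **overrides,
    )
    ids = truth.receptor_ids(receptor_class)
    tfs, ags = truth.tf_ids(), truth.ag_ids()
    if n_blocks * tfs_per_receptor > len(tfs) or n_blocks * ags_per_receptor > len(ags):
        raise ConfigurationError("not enough panel genes for the requested blocks")
    code_map = {}
    for i, rid in enumerate(ids):
        b = i * n_blocks // n_receptors
        code_map[rid] = CodeEntry(
            tf_ids=tuple(tfs[b * tfs_per_receptor : (b + 1) * tfs_per_receptor]),
            ag_ids=tuple(ags[b * ags_per_receptor : (b + 1) * ags_per_receptor]),
            mean=code_mean,
        )
    return dataclasses.replace(truth, code_map=code_map)


def code_block_of(truth: SyntheticTruth) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Map receptor -> (tf_ids, ag_ids) of its planted code block."""
    return {
        rid: (entry.tf_ids, entry.ag_ids) for rid, entry in truth.code_map.items()
    }
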