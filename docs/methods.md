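# Methods

## Scope and model

`vnocode` analyzes raw (unnormalized) genes × cells count matrices of
vomeronasal-organ single-cell RNA-seq. It deliberately sits *downstream*
of read quantification, droplet QC, ambient-RNA and doublet removal,
normalization/clustering, and label transfer: those steps are assumed done
by standard tooling, and their outputs (raw counts, cell-type labels,
prediction scores, spatial coordinates) are this package's inputs. The
package's own substance is the receptor logic: presence calling, pair
tests, the TF/AG association code, rank-abundance fits, and zone
enrichment.

Statistical core, shared by all modules: co-occurrence of two boolean
presence patterns over N cells is tested one-sided for enrichment with a
Fisher exact test, equivalently the hypergeometric upper tail
P(X ≥ n11) with X ~ Hypergeom(N, K_a, K_b). Depletion is not interpreted;
a two-sided variant is available by flag. Multiple testing uses
Benjamini–Hochberg, applied once across all tests of a scan (all receptor
pairs; the full receptor × panel table; the focus cell types). BH is a
monotone step-up map — note it is *not* idempotent as a function on
p-vectors, so the tests assert boundedness, rank monotonicity, agreement
with the textbook definition, and that re-application never decreases
values, rather than strict idempotence.

## Thresholds (defaults, all configurable)

| parameter | default | meaning |
|---|---|---|
| receptor presence | ≥ 10 raw counts | a receptor counts as expressed in a cell |
| receptor retention | ≥ 5 cells | minimum presence cells for a receptor to be tested |
| panel-gene presence | ≥ 3 raw counts | TF/AG genes are detected at lower levels |
| significance | padj ≤ 0.05 | BH-adjusted, all scans |
| marginal / intermediate radius | 750 / 1500 px | distance to the nearest boundary landmark, inclusive |
| prediction-score floor | ≥ 0.3 | cells below are zoned `unknown` |
| power-law fit floor | ≥ 10 detected cells | excludes the technical-dropout tail |

All boundaries are inclusive ("at least"): a count of exactly 10 (or 3)
is present; a score of exactly 0.3 is retained; a distance of exactly
750 px is marginal.

## Definitions and numerical choices

- **Expression probability** (rank-abundance): share of cells with *any*
  nonzero count, not thresholded presence. The raw-detection view and the
  thresholded view answer different questions (how often is a receptor
  chosen vs. is it reliably co-expressed), and the 10-count bar belongs
  only to the latter.
- **Power-law fit**: ordinary least squares of log p_r on log rank;
  α̂ = −slope. A detected-cell floor, not a rank cutoff, trims the dropout
  tail, so the excluded set adapts to sequencing depth.
- **Shannon diversity**: natural-log units over raw counts of the
  receptor families (V1R, V2R, OR, Fpr); cells with zero receptor counts
  are flagged undefined and excluded from comparisons.
- **Odds ratio**: (n11·n00)/(n10·n01), ∞ when the denominator vanishes
  with n11 > 0, NaN when uninformative.
- **Genomic co-localization**: chromosome identity plus midpoint distance
  (1-based inclusive coordinates throughout). Both a pair-level fraction
  (significant pairs sharing a chromosome) and a gene-level fraction are
  reported, since "fraction of co-expressed receptors on the same
  chromosome" is ambiguous between the two.
- **Association heatmap means**: log1p of counts scaled to the median
  cell total. Only the ordering of means matters downstream; the scaling
  is recorded in output metadata.
- **Sequence similarity**: global alignment percent identity
  (identities / alignment length × 100) under BLOSUM62 with affine gaps
  (open 11, extend 1).
- **Jaccard grids**: within one receptor's presence cells, J(t, a) over
  the barcode sets where each panel gene passes its threshold. Genes
  enter the grid if significantly associated with the receptor
  (padj ≤ 0.05) — the "stringent criterion" — or by explicit list.
- **Tie-breaks**: receptor ranks break ties lexicographically by gene id;
  all generators and scans are deterministic given their seed.
- **Zone partition** is exhaustive and exclusive; cells lacking
  coordinates produce per-cell error records instead of aborting; the
  test universe for enrichment is marginal + main cells, with the
  intermediate zone reported descriptively.
- **Fisher universe**: all cells of the supplied matrix. Restricting to a
  lineage subset is the caller's job via the cell table, since the right
  universe is a scientific choice, not a computational one.

## The synthetic generator

`SyntheticTruth` fixes every generative parameter, and all generators are
pure functions of it (seeded `numpy` Generator streams), so recovery
experiments can compare pipeline output to planted values exactly.

Per cell: a type from a configurable composition (default GBC 5%,
INP 10%, iVSN 20%, mVSN 60%, sVSN 5%); progenitor types express no
receptor. Receptor-expressing cells draw one primary receptor with
probability ∝ rank^(−α) (default α = 1.2, 60 receptors). Primary and
partner transcript numbers are `floor + NegBin(mean − floor, size 5)`
with floor = 10 (the presence threshold) and means 60/40 — the shift
guarantees a chosen receptor is detectable in the noise-free limit, which
pins down the generator's boundary behavior exactly; the means are
otherwise "well above threshold", as observed for dominant receptors. If
the primary belongs to a planted pair, the partner is co-expressed with
probability `co_prob` (default experiments: 0.8), multiplied for immature
cells and younger (P14) animals — co-expression is a property of
immature, still-specifying neurons. Receptors wired to a TF/AG program
express those genes at Poisson(8) against a Poisson(0.3) background.
Ambient contamination adds Poisson(0.5) stray counts per off-target
receptor per cell — individually far below the 10-count bar, so the
threshold, not the noise magnitude, drives outcomes — and the whole
matrix is thinned binomially at capture rate 0.8.

Annotation layout is deterministic: receptors are clustered on 5
chromosomes with planted same-chromosome partners adjacent (200 kb apart)
and cross-chromosome pairs forced onto distinct chromosomes; panel genes
occupy a separate coordinate region.

Spatial placement is uniform over the field of view; a cell type with
zone-enrichment multiplier m > 1 is moved into the marginal zone (within
750 px of the nearest landmark) with probability f(m−1)/(1−f) when it
lands outside, where f is the marginal area fraction (deterministic grid
estimate). This multiplies the type's marginal density by exactly m,
giving closed-form expected zone fractions for power calculations.

What the generator does **not** emulate: UMI/read-level noise, transcript
length bias, batch effects, doublets, the broad V2R co-receptor
(Vmn2r1–7) hierarchy, or realistic cell-type transcriptomes beyond the
receptor/TF/AG structure. Passing recovery tests therefore demonstrates
that the pipeline's inference is correct *under its stated model*, not
that real VNO data satisfy that model.

## Reference experiment conditions

Chosen once as the package's standard validation settings:

- **Fisher oracle**: every 2×2 table with N ≤ 25 (23,750 tables) against
  brute-force tail enumeration; max |Δp| < 1e−10 expected at machine
  precision.
- **Co-expression recovery**: 3,000 cells, 60 receptors, 12 planted pairs
  (co_prob 0.8, 8 intra-chromosomal), 20 seeds; sensitivity ≥ 0.9,
  empirical FDR ≤ 0.1 at padj ≤ 0.05, same-chromosome fraction within
  ±0.15 of 2/3. Planted pairs sit on consecutive mid-ranks (from rank 5)
  so every planted receptor clears the 5-cell retention floor.
- **Power-law recovery**: α = 1.2, 20,000 cells, 10 seeds, ambient rate 0
  (rank-probability summaries correspond to ambient-cleaned input; under
  flat per-receptor ambient, any-nonzero detection is
  contamination-dominated and carries no rank signal for any generator);
  mean α̂ within ±0.15.
- **Code recovery**: 30 receptors in 6 blocks, 2 TFs + 3 AGs per receptor
  at mean 8 vs background 0.3, 3,000 cells, 20 seeds; top-1 TF planted for
  ≥ 90% of receptors; planted TF–AG pairs out-Jaccard unplanted and
  within-block profile correlation beats between-block in ≥ 19/20 seeds.
  The Jaccard contrast evaluates explicit planted + unwired gene lists,
  since unwired genes rarely pass the significance prefilter at all.
- **Zones**: 2,000 cells on a 6,000 × 4,000 px field with 9 boundary
  landmarks along one edge; null calibration with 10 unenriched types
  (≤ 1 false call per run), power at a planted 3× GBC enrichment
  (detected in ≥ 95% of 20 seeds).

These sizes keep the full suite and the reproduction script to a few
minutes on one CPU while leaving comfortable statistical margins.

## Known limitations

- Association-table means use a simple median-total scaling, not a
  variance-stabilizing transform; comparisons of means across cells with
  very different depths inherit log1p's compression.
- Percent identity is computed from a single optimal global alignment;
  co-optimal alignments with different identity counts are not averaged.
- The marginal-area fraction is a grid estimate (400×400); with extremely
  sparse landmarks relative to the field, the resampling-based enrichment
  factor inherits its small bias.
- `pairwise_fisher` materializes the receptor × receptor overlap matrix;
  fine for receptor panels (hundreds), not designed for genome-wide
  scans.
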