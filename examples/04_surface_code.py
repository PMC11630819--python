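"""The receptor <-> TF/AG association code and its Jaccard structure.

Receptors (>= 10 counts) are tested against transcription factors and
axon-guidance genes (>= 3 counts) with Fisher + BH; receptors sharing a
planted code block show correlated panel-expression profiles, and the
TF x AG Jaccard grid shows which planted gene pairs occupy the same cells.
"""

import numpy as np

from vnocode import (
    block_code_truth,
    build_association,
    profile_correlation,
    simulate_counts,
    tf_ag_jaccard,
)

truth = block_code_truth(seed=0)  # 30 receptors in 6 blocks, 2 TFs + 3 AGs each
sim = simulate_counts(truth, n_cells=3000)

assoc_tf = build_association(sim.counts, sim.annotation, ["V1R"], "TF")
assoc_ag = build_association(sim.counts, sim.annotation, ["V1R"], "AG")

hits = sum(
    assoc_tf.p_value.loc[rid].idxmin() in entry.tf_ids
    for rid, entry in truth.code_map.items()
)
print(f"top TF association is a planted TF for {hits}/{len(truth.code_map)} receptors")

sim_tf = profile_correlation(assoc_tf)
order = truth.receptor_ids("V1R")
block = {r: i * 6 // len(order) for i, r in enumerate(order)}
ids = list(sim_tf.values.index)
within = [sim_tf.values.iloc[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))
          if block[ids[i]] == block[ids[j]]]
between = [sim_tf.values.iloc[i, j] for i in range(len(ids)) for j in range(i + 1, len(ids))
           if block[ids[i]] != block[ids[j]]]
print(f"TF-profile correlation: within-block {np.mean(within):.3f}, "
      f"between-block {np.mean(between):.3f}")

rid = order[0]
grid = tf_ag_jaccard(assoc_tf, assoc_ag, rid)
print(f"{rid}: {len(grid.tf_ids)} significant TFs x {len(grid.ag_ids)} significant AGs, "
      f"mean Jaccard {grid.jaccard.to_numpy().mean():.3f}")
# high J: the TF and AG are present in the same cells of this receptor type
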