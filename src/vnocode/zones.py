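"""Marginal / intermediate / main zone assignment and cell-type enrichment.

Neurogenesis in the vomeronasal epithelium is concentrated at its margins.
Taking the neural / non-neuronal boundary landmarks as centers, cells
within 750 px of the nearest landmark fall in the marginal zone, within
1500 px in the intermediate zone, and beyond that in the main zone. Cells
whose label-transfer prediction score is below 0.3 are labeled unknown
before zoning; flagged non-neuronal cells are excluded. Enrichment of a
cell type in the marginal over the main zone is tested with a one-sided
Fisher exact test, BH-corrected across the focus types.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._stats import bh_adjust, fisher_enrichment_p, odds_ratio
from .datatypes import CellRecord


class Zone(str, Enum):
    MARGINAL = "marginal"
    INTERMEDIATE = "intermediate"
    MAIN = "main"
    UNKNOWN = "unknown"
    EXCLUDED = "excluded"


@dataclass
class ZoneAssignment:
    barcode: str
    zone: Zone
    distance_px: Optional[float]
    error: Optional[str] = None


def assign_zones(
    cells: Sequence[CellRecord],
    landmarks: np.ndarray,
    r1: float = 750.0,
    r2: float = 1500.0,
    score_min: float = 0.3,
) -> list[ZoneAssignment]:
    """Assign each cell a zone from its distance to the nearest landmark.

    Boundaries are inclusive: distance <= r1 is marginal, r1 < d <= r2
    intermediate, d > r2 main. The prediction-score filter (cells below
    ``score_min`` become unknown) applies before zoning; excluded cells
    stay excluded. Cells without coordinates get a per-cell error record
    rather than aborting the run.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.ndim != 2 or landmarks.shape[0] < 1:
        raise ValueError("at least one landmark is required")
    if not r1 < r2:
        raise ValueError(f"r1 ({r1}) must be < r2 ({r2})")
    tree = cKDTree(landmarks)

    out: list[ZoneAssignment] = []
    for cell in cells:
        if cell.excluded:
            out.append(ZoneAssignment(cell.barcode, Zone.EXCLUDED, None))
            continue
        if cell.x_px is None or cell.y_px is None:
            out.append(
                ZoneAssignment(cell.barcode, Zone.UNKNOWN, None, error="missing coordinates")
            )
            continue
        d = float(tree.query([[cell.x_px, cell.y_px]])[0][0])
        if cell.prediction_score is not None and cell.prediction_score < score_min:
            out.append(ZoneAssignment(cell.barcode, Zone.UNKNOWN, d))
            continue
        if d <= r1:
            zone = Zone.MARGINAL
        elif d <= r2:
            zone = Zone.INTERMEDIATE
        else:
            zone = Zone.MAIN
        out.append(ZoneAssignment(cell.barcode, zone, d))
    return out


def assignments_frame(assignments: Sequence[ZoneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": [a.barcode for a in assignments],
            "zone": [a.zone.value for a in assignments],
            "distance_px": [a.distance_px for a in assignments],
            "error": [a.error for a in assignments],
        }
    )


def zone_enrichment(
    assignments: Sequence[ZoneAssignment],
    cells: Sequence[CellRecord],
    focus_types: Sequence[str],
) -> pd.DataFrame:
    """Marginal-vs-main enrichment of each focus cell type.

    Per type, a one-sided Fisher test on the 2x2 table (type vs all other
    zoned cells) x (marginal vs main); the intermediate zone is reported
    descriptively. BH correction is applied across the focus types. Types
    untestable because the marginal or main zone is empty are flagged.
    """
    zone_by_barcode = {a.barcode: a.zone for a in assignments}
    rows = []
    for cell in cells:
        zone = zone_by_barcode.get(cell.barcode)
        if zone in (Zone.MARGINAL, Zone.INTERMEDIATE, Zone.MAIN):
            rows.append((cell.cell_type, zone))
    frame = pd.DataFrame(rows, columns=["cell_type", "zone"])
    populated = frame["zone"].nunique()
    if populated < 2:
        raise ValueError("need at least 2 populated zones for enrichment testing")

    n_marginal = int((frame["zone"] == Zone.MARGINAL).sum())
    n_main = int((frame["zone"] == Zone.MAIN).sum())
    testable = n_marginal > 0 and n_main > 0

    records = []
    pvals = []
    for ctype in focus_types:
        mine = frame["cell_type"] == ctype
        fracs = {
            f"fraction_{z.value}": float(
                (mine & (frame["zone"] == z)).sum() / max((frame["zone"] == z).sum(), 1)
            )
            for z in (Zone.MARGINAL, Zone.INTERMEDIATE, Zone.MAIN)
        }
        if testable:
            n11 = int((mine & (frame["zone"] == Zone.MARGINAL)).sum())
            n10 = n_marginal - n11
            n01 = int((mine & (frame["zone"] == Zone.MAIN)).sum())
            n00 = n_main - n01
            n = n11 + n10 + n01 + n00
            p = float(fisher_enrichment_p(np.array([n11]), np.array([n11 + n10]),
                                          np.array([n11 + n01]), n)[0])
            orr = odds_ratio(n11, n10, n01, n00)
            skipped = False
        else:
            p, orr, skipped = np.nan, np.nan, True
        pvals.append(p)
        records.append(
            {"cell_type": ctype, **fracs, "odds_ratio": orr, "p_value": p,
             "test_skipped": skipped}
        )
    result = pd.DataFrame(records)
    p_arr = np.array(pvals, dtype=float)
    padj = np.full_like(p_arr, np.nan)
    valid = ~np.isnan(p_arr)
    if valid.any():
        padj[valid] = bh_adjust(p_arr[valid])
    result["p_adjusted"] = padj
    return result
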