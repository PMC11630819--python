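"""Readers and writers for every external representation the pipeline uses.

Count matrices come in two dialects: 10x-style MatrixMarket triplets
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) and a dense TSV with
gene ids in the first column and barcodes in the header. Gene annotations,
cell metadata and boundary landmarks are plain TSV. Significant co-expressed
receptor pairs can be exported as a circos link file (1-based inclusive
genomic intervals).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .datatypes import (
    AgeGroup,
    CellRecord,
    CountMatrix,
    GeneClass,
    GeneRecord,
    PairTestResult,
    Sex,
    annotation_by_id,
)

logger = logging.getLogger("vnocode")

PathLike = Union[str, Path]


class FormatError(Exception):
    """A file is missing or structurally malformed."""


#: Case-insensitive aliases for gene-class labels found in annotations.
CLASS_ALIASES = {
    "v1r": GeneClass.V1R,
    "vmn1r": GeneClass.V1R,
    "v2r": GeneClass.V2R,
    "vmn2r": GeneClass.V2R,
    "or": GeneClass.OR,
    "olfr": GeneClass.OR,
    "odorant_receptor": GeneClass.OR,
    "fpr": GeneClass.FPR,
    "formyl_peptide_receptor": GeneClass.FPR,
    "tf": GeneClass.TF,
    "transcription_factor": GeneClass.TF,
    "ag": GeneClass.AG,
    "axon_guidance": GeneClass.AG,
    "axon-guidance": GeneClass.AG,
    "other": GeneClass.OTHER,
}


def resolve_gene_class(label: str) -> GeneClass:
    """Map a free-text class label to a GeneClass; unknowns demote to other."""
    key = str(label).strip().lower()
    if key in CLASS_ALIASES:
        return CLASS_ALIASES[key]
    logger.warning("unknown gene class %r mapped to 'other'", label)
    return GeneClass.OTHER


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _read_id_column(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing companion file: {path} ({what})")
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return frame.iloc[:, 0].tolist()


def read_count_matrix(
    path: PathLike, dialect: str = "mtx_triplet"
) -> CountMatrix:
    """Read a genes x cells raw count matrix.

    ``mtx_triplet``: *path* is a directory containing ``matrix.mtx``,
    ``features.tsv`` and ``barcodes.tsv`` (1-based MatrixMarket coordinates).
    ``dense_tsv``: *path* is a TSV file, first column gene ids, header row
    cell barcodes.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FormatError(f"missing companion file: {mtx} (MatrixMarket matrix)")
        gene_ids = _read_id_column(path / "features.tsv", "feature ids")
        barcodes = _read_id_column(path / "barcodes.tsv", "cell barcodes")
        if len(set(gene_ids)) != len(gene_ids):
            raise FormatError(f"duplicate feature ids in {path / 'features.tsv'}")
        mat = scipy_io.mmread(str(mtx))
        dense = np.asarray(sparse.coo_matrix(mat).todense())
        if not np.allclose(dense, np.round(dense)):
            bad = np.argwhere(dense != np.round(dense))[0]
            raise ValueError(
                f"non-integer entry at gene row {bad[0] + 1}, cell column {bad[1] + 1}"
            )
        return CountMatrix(dense.astype(np.int64), gene_ids, barcodes)
    if dialect == "dense_tsv":
        if not Path(path).exists():
            raise FormatError(f"missing file: {path}")
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy()
        if not np.allclose(values, np.round(values)):
            bad = np.argwhere(values != np.round(values))[0]
            raise ValueError(
                f"non-integer entry at gene row {bad[0] + 1}, cell column {bad[1] + 1}"
            )
        return CountMatrix(
            values.astype(np.int64),
            [str(g) for g in frame.index],
            [str(c) for c in frame.columns],
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_matrix(
    matrix: CountMatrix, path: PathLike, dialect: str = "mtx_triplet"
) -> None:
    """Write a CountMatrix in the given dialect (inverse of the reader)."""
    path = Path(path)
    if dialect == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        coo = sparse.coo_matrix(matrix.counts)
        scipy_io.mmwrite(str(path / "matrix.mtx"), coo, field="integer")
        pd.Series(matrix.gene_ids).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(matrix.cell_barcodes).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif dialect == "dense_tsv":
        frame = pd.DataFrame(
            matrix.counts, index=matrix.gene_ids, columns=matrix.cell_barcodes
        )
        frame.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

_TRUE_STRINGS = {"true", "1", "yes", "t"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip().lower() in _TRUE_STRINGS


def read_annotation(path: PathLike) -> list[GeneRecord]:
    """Read the gene annotation TSV into GeneRecords.

    Required columns: gene_id, gene_class, chromosome, start_bp, end_bp.
    Optional: symbol, pseudogene, protein_seq.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "gene_class", "chromosome", "start_bp", "end_bp"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    if frame["gene_id"].duplicated().any():
        dup = frame.loc[frame["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicated gene_id in annotation: {dup}")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            GeneRecord(
                gene_id=str(d["gene_id"]).strip(),
                gene_class=resolve_gene_class(d["gene_class"]),
                chromosome=str(d["chromosome"]).strip(),
                start_bp=int(d["start_bp"]),
                end_bp=int(d["end_bp"]),
                symbol=str(d["symbol"]).strip() if "symbol" in d and pd.notna(d["symbol"]) else None,
                pseudogene=_parse_bool(d.get("pseudogene")),
                protein_seq=str(d["protein_seq"]).strip()
                if "protein_seq" in d and pd.notna(d["protein_seq"])
                else None,
            )
        )
    return records


def write_annotation(annotation: Sequence[GeneRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in annotation],
            "symbol": [r.symbol or r.gene_id for r in annotation],
            "gene_class": [r.gene_class.value for r in annotation],
            "chromosome": [r.chromosome for r in annotation],
            "start_bp": [r.start_bp for r in annotation],
            "end_bp": [r.end_bp for r in annotation],
            "pseudogene": [r.pseudogene for r in annotation],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_protein_fasta(path: PathLike) -> dict[str, str]:
    """Receptor protein sequences keyed by record id."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_protein_fasta(seqs: dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# cell metadata and landmarks
# ---------------------------------------------------------------------------

def read_cells(path: PathLike) -> list[CellRecord]:
    """Read the per-cell metadata TSV (barcode column required)."""
    frame = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    if "barcode" not in frame.columns:
        raise FormatError("cell table missing 'barcode' column")

    def opt_float(d, key):
        if key in d and pd.notna(d[key]):
            return float(d[key])
        return None

    cells = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        cells.append(
            CellRecord(
                barcode=str(d["barcode"]),
                cell_type=str(d.get("cell_type", "unknown")),
                age_group=AgeGroup(str(d["age_group"]))
                if "age_group" in d and pd.notna(d["age_group"])
                else AgeGroup.UNKNOWN,
                sex=Sex(str(d["sex"])) if "sex" in d and pd.notna(d["sex"]) else Sex.UNKNOWN,
                sample_id=str(d.get("sample_id", "")),
                x_px=opt_float(d, "x_px"),
                y_px=opt_float(d, "y_px"),
                prediction_score=opt_float(d, "prediction_score"),
                excluded=_parse_bool(d.get("excluded")),
            )
        )
    return cells


def write_cells(cells: Sequence[CellRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "barcode": [c.barcode for c in cells],
            "cell_type": [c.cell_type for c in cells],
            "age_group": [c.age_group.value for c in cells],
            "sex": [c.sex.value for c in cells],
            "sample_id": [c.sample_id for c in cells],
            "x_px": [c.x_px for c in cells],
            "y_px": [c.y_px for c in cells],
            "prediction_score": [c.prediction_score for c in cells],
            "excluded": [c.excluded for c in cells],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_landmarks(path: PathLike) -> np.ndarray:
    """Boundary landmark coordinates as an (n, 2) array of pixels."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("x_px", "y_px"):
        if col not in frame.columns:
            raise FormatError(f"landmark table missing '{col}' column")
    return frame[["x_px", "y_px"]].to_numpy(dtype=float)


def write_landmarks(landmarks: np.ndarray, path: PathLike) -> None:
    pd.DataFrame(np.asarray(landmarks), columns=["x_px", "y_px"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# pair results and circos links
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "gene_a",
    "gene_b",
    "n11",
    "n10",
    "n01",
    "n00",
    "odds_ratio",
    "p_value",
    "p_adjusted",
    "same_chromosome",
    "genomic_distance_bp",
]


def pair_results_frame(results: Sequence[PairTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "n11": r.n11,
                "n10": r.n10,
                "n01": r.n01,
                "n00": r.n00,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "same_chromosome": r.same_chromosome,
                "genomic_distance_bp": r.genomic_distance_bp,
            }
            for r in results
        ],
        columns=_PAIR_COLUMNS,
    )


def write_pair_results(results: Sequence[PairTestResult], path: PathLike) -> None:
    pair_results_frame(results).to_csv(path, sep="\t", index=False)


def read_pair_results(path: PathLike) -> list[PairTestResult]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        same_chrom = d.get("same_chromosome")
        if pd.isna(same_chrom):
            same_chrom = None
        elif not isinstance(same_chrom, (bool, np.bool_)):
            same_chrom = _parse_bool(same_chrom)
        dist = d.get("genomic_distance_bp")
        out.append(
            PairTestResult(
                gene_a=str(d["gene_a"]),
                gene_b=str(d["gene_b"]),
                n11=int(d["n11"]),
                n10=int(d["n10"]),
                n01=int(d["n01"]),
                n00=int(d["n00"]),
                odds_ratio=float(d["odds_ratio"]),
                p_value=float(d["p_value"]),
                p_adjusted=float(d["p_adjusted"]),
                same_chromosome=bool(same_chrom) if same_chrom is not None else None,
                genomic_distance_bp=float(dist) if pd.notna(dist) else None,
            )
        )
    return out


def write_circos_links(
    results: Sequence[PairTestResult],
    annotation: Sequence[GeneRecord],
    path: PathLike,
    alpha: float = 0.05,
) -> int:
    """Write significant pairs (padj <= alpha) as a circos link file.

    One line per pair: chromA startA endA chromB startB endB n_cells, with
    coordinates copied verbatim from the annotation (1-based inclusive).
    Returns the number of links written.
    """
    index = annotation_by_id(annotation)
    lines = []
    for r in results:
        if not (r.p_adjusted <= alpha):
            continue
        for gene in (r.gene_a, r.gene_b):
            if gene not in index:
                raise KeyError(f"gene {gene!r} absent from annotation")
        a, b = index[r.gene_a], index[r.gene_b]
        lines.append(
            f"{a.chromosome}\t{a.start_bp}\t{a.end_bp}\t"
            f"{b.chromosome}\t{b.start_bp}\t{b.end_bp}\t{r.n11}"
        )
    with open(path, "w") as fh:
        fh.write("# chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\tn_cells\n")
        for line in lines:
            fh.write(line + "\n")
    return len(lines)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: PathLike,
    command: str,
    parameters: dict,
    inputs: Sequence[PathLike] = (),
    seed: Optional[int] = None,
) -> None:
    """Record the thresholds, seed and input checksums of a pipeline run."""
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.is_dir():
            for child in sorted(p.iterdir()):
                if child.is_file():
                    checksums[str(child)] = _sha256(child)
        elif p.exists():
            checksums[str(p)] = _sha256(p)
    manifest = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "input_sha256": checksums,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
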