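"""Readers and writers for the package's interchange formats.

Expression matrices travel as TSV (genes x samples) or MatrixMarket with
row/column index sidecars; gene annotation as 6-column TSV (1-based
inclusive coordinates); peaks as BED6 with the enrichment score in the
score column (0-based half-open); motifs as JASPAR count matrices;
segmentation masks as ``.npy`` arrays with a JSON sidecar carrying the
voxel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import DataError, ExpressionMatrix, GeneAnnotation, MitoSegmentation, PWM

# ---------------------------------------------------------------- expression


def write_expression_tsv(expr: ExpressionMatrix, path, meta_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    if meta_path is not None:
        expr.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_expression_tsv(path, meta_path=None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    else:
        meta = pd.DataFrame(index=values.columns)
    return ExpressionMatrix(values, meta)


def write_expression_mtx(expr: ExpressionMatrix, prefix) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.txt`` / ``.samples.txt``."""
    prefix = Path(prefix)
    sparse = scipy.sparse.csr_matrix(expr.values.to_numpy())
    scipy.io.mmwrite(str(prefix) + ".mtx", sparse)
    prefix.with_suffix(".genes.txt").write_text("\n".join(expr.gene_ids) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(expr.sample_ids) + "\n")


def read_expression_mtx(prefix) -> ExpressionMatrix:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    values = pd.DataFrame(mat, index=genes, columns=samples)
    return ExpressionMatrix(values, pd.DataFrame(index=samples))


# ---------------------------------------------------------------- annotation


def write_annotation_tsv(annot: GeneAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index_label="gene_id",
                       columns=["chrom", "start", "end", "strand", "tss"])


def read_annotation_tsv(path) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    return GeneAnnotation(table)


# ----------------------------------------------------------------------- BED


def write_bed(peaks, path) -> None:
    """Write a PeakSet as BED6 (strand written as '.')."""
    f = peaks.frame
    out = pd.DataFrame({
        "chrom": f["chrom"], "start": f["start"], "end": f["end"],
        "name": f["name"], "score": f["score"], "strand": ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path):
    from .containers import PeakSet

    cols = ["chrom", "start", "end", "name", "score", "strand"]
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 5:
        raise DataError("BED file needs at least 5 columns (score required)")
    frame = frame.iloc[:, :6]
    frame.columns = cols[: frame.shape[1]]
    return PeakSet(frame[["chrom", "start", "end", "name", "score"]])


# --------------------------------------------------------------------- FASTA


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------------------- PWM


def read_jaspar_pwm(path, background=None) -> PWM:
    """Load the first motif of a JASPAR-format file as a probability PWM."""
    with open(path) as handle:
        motif = next(iter(motifs.parse(handle, "jaspar")))
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float).T
    row_sums = counts.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise DataError("JASPAR matrix has an all-zero position")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(counts / row_sums, background=bg, name=motif.name or motif.matrix_id)


def write_jaspar_pwm(pwm: PWM, path, scale: int = 100) -> None:
    """Write a probability PWM as scaled JASPAR pseudo-counts."""
    lines = [f">{pwm.name} {pwm.name}"]
    for i, base in enumerate("ACGT"):
        vals = " ".join(f"{v * scale:8.2f}" for v in pwm.matrix[:, i])
        lines.append(f"{base}  [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------- masks


def write_mask(seg: MitoSegmentation, prefix) -> None:
    """Write ``<prefix>.npy`` plus ``<prefix>.json`` (voxel size, cell id)."""
    prefix = Path(prefix)
    np.save(str(prefix) + ".npy", seg.labels)
    sidecar = {"voxel_size": list(seg.voxel_size), "cell_id": seg.cell_id}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_mask(prefix) -> MitoSegmentation:
    prefix = Path(prefix)
    labels = np.load(str(prefix) + ".npy")
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return MitoSegmentation(labels, tuple(sidecar["voxel_size"]), sidecar["cell_id"])
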