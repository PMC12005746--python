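"""Multi-contrast DEG intersection, chromosome partitioning and escapee calls.

A DEG table is a DataFrame indexed by gene id with columns ``log2fc``,
``fdr``, ``direction`` (up/down, the sign of log2fc) and ``contrast``.
Tables computed by external DE machinery are first-class inputs via
:func:`read_deg_tsv`; :func:`call_deg_standin` provides a deliberately
simple in-package differential test (Welch's t on log2(TPM+1) with
Benjamini-Hochberg correction) for the synthetic pipeline — it makes no
attempt to model count dispersion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import DataError, EscapeeCatalog, ExpressionMatrix, GeneAnnotation

DEG_COLUMNS = ["log2fc", "fdr", "direction", "contrast"]


def read_deg_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"DEG table lacks columns: {missing}")
    return table


def write_deg_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", columns=DEG_COLUMNS)


def call_deg_standin(expr_case: ExpressionMatrix, expr_ctrl: ExpressionMatrix,
                     fc_thresh: float = 1.5, fdr_thresh: float = 0.05,
                     contrast_id: str = "case_vs_ctrl",
                     full_table: bool = False) -> pd.DataFrame:
    """Per-gene Welch's t-test on log2(TPM+1) with BH correction.

    Returns genes with linear fold change above ``fc_thresh`` in either
    direction and BH-adjusted FDR below ``fdr_thresh``; ``log2fc`` is
    case minus control in mean log2(TPM+1). Groups with all-zero
    variance and equal means get p = 1; unequal means with zero
    variance in both groups get p = 0 (a perfectly separated gene).
    With ``full_table`` the unfiltered per-gene table (all genes, with
    a ``pvalue`` column) is returned instead.
    """
    if expr_case.values.shape[1] < 2 or expr_ctrl.values.shape[1] < 2:
        raise DataError("each group needs at least 2 samples")
    genes = expr_case.gene_ids
    if not genes.equals(expr_ctrl.gene_ids):
        raise DataError("case and control matrices must share the gene set")

    a = np.log2(expr_case.values.to_numpy(dtype=float) + 1.0)
    b = np.log2(expr_ctrl.values.to_numpy(dtype=float) + 1.0)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = np.isnan(pvals)
    pvals = np.where(degenerate & (log2fc != 0), 0.0, pvals)
    pvals = np.where(degenerate & (log2fc == 0), 1.0, pvals)

    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "contrast": contrast_id,
        },
        index=genes,
    )
    if full_table:
        return table
    keep = (np.abs(table["log2fc"]) > np.log2(fc_thresh)) & (table["fdr"] < fdr_thresh)
    return table[keep].drop(columns="pvalue")


def intersect_contrasts(tables, require_direction: bool = True) -> pd.DataFrame:
    """Genes shared by every contrast table, with their direction.

    With ``require_direction`` (the default) a gene must move the same
    way in all contrasts to count as commonly dysregulated; otherwise
    direction conflicts are retained and flagged in the
    ``direction_consistent`` column (conflicting genes carry direction
    ``"mixed"``).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise DataError("need at least 2 DEG tables to intersect")
    shared = set(tables[0].index)
    for t in tables[1:]:
        shared &= set(t.index)
    rows = []
    for gene in sorted(shared):
        directions = {t.at[gene, "direction"] for t in tables}
        consistent = len(directions) == 1
        if require_direction and not consistent:
            continue
        rows.append((gene, directions.pop() if consistent else "mixed", consistent))
    return pd.DataFrame(
        rows, columns=["gene_id", "direction", "direction_consistent"]
    ).set_index("gene_id")


def partition_by_chromosome(genes: pd.DataFrame, annot: GeneAnnotation):
    """Per-chromosome up/down DEG counts and their ratio, plus X-vs-autosome totals.

    ``genes`` is indexed by gene id with a ``direction`` column. The
    up/down ratio is reported as ``inf`` when a chromosome has
    upregulated genes but none downregulated; chromosomes with no DEGs
    do not appear. Returns ``(per_chromosome_frame, totals_dict)``.
    """
    unannotated = [g for g in genes.index if g not in annot.gene_ids]
    if unannotated:
        raise DataError(f"unannotated genes: {unannotated[:10]}")
    chrom = annot.table.loc[genes.index, "chrom"]
    df = pd.DataFrame({"chrom": chrom, "direction": genes["direction"]})

    rows = []
    for c, grp in df.groupby("chrom", sort=True):
        n_up = int((grp["direction"] == "up").sum())
        n_down = int((grp["direction"] == "down").sum())
        ratio = np.inf if n_down == 0 else n_up / n_down
        rows.append((c, n_up, n_down, ratio))
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_up", "n_down", "up_down_ratio"])

    x_mask = df["chrom"].isin({"X", "chrX"})
    totals = {
        "x": {
            "n_up": int((df.loc[x_mask, "direction"] == "up").sum()),
            "n_down": int((df.loc[x_mask, "direction"] == "down").sum()),
        },
        "autosome": {
            "n_up": int((df.loc[~x_mask, "direction"] == "up").sum()),
            "n_down": int((df.loc[~x_mask, "direction"] == "down").sum()),
        },
    }
    return per_chrom, totals


def classify_escapees(x_up_genes, catalog: EscapeeCatalog,
                      annot: GeneAnnotation | None = None) -> dict:
    """Partition X-linked upregulated genes by escapee catalog membership.

    Genes found in the catalog's constitutive or variable sets keep that
    class; uncatalogued genes are the candidate novel (hPSC-related)
    escapees. The three sets are disjoint and cover the input. When an
    annotation is supplied, non-X genes in the input raise.
    """
    x_up = set(x_up_genes)
    if annot is not None:
        offenders = [
            g for g in sorted(x_up)
            if g not in annot.gene_ids
            or annot.chromosome_of(g) not in {"X", "chrX"}
        ]
        if offenders:
            raise DataError(f"input genes not X-linked: {offenders[:10]}")
    constitutive = x_up & catalog.constitutive
    variable = x_up & catalog.variable
    novel = x_up - constitutive - variable
    return {"constitutive": constitutive, "variable": variable, "novel": novel}
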