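"""X:A expression ratios with bootstrap nulls and chromosome tracks.

The X:A ratio is the median TPM of expressed X-linked genes (catalogued
escapees removed from the numerator set, since their biallelic
expression would inflate the X estimate regardless of XCI state)
divided by the median TPM of expressed autosomal genes. "Expressed"
means strictly above ``min_tpm`` (default 1 TPM).

Because the X chromosome carries far fewer genes than the autosomes
combined, significance is judged against a size-matched bootstrap null:
random autosomal gene sets of the same size as the filtered X set, each
scored as its median over the global autosomal median, replicated
``n_boot`` times (1000 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DataError, GeneAnnotation, RatioResult


def _filtered_values(expr_col: pd.Series, annot: GeneAnnotation,
                     escapees=(), min_tpm: float = 1.0):
    """(X values, autosomal values) above the TPM filter, escapees dropped from X."""
    escapees = set(escapees)
    x_genes = [g for g in annot.x_genes() if g not in escapees and g in expr_col.index]
    auto_genes = [g for g in annot.autosomal_genes() if g in expr_col.index]
    x_vals = expr_col.loc[x_genes].to_numpy(dtype=float)
    auto_vals = expr_col.loc[auto_genes].to_numpy(dtype=float)
    return x_vals[x_vals > min_tpm], auto_vals[auto_vals > min_tpm]


def compute_xa_ratio(expr_col: pd.Series, annot: GeneAnnotation,
                     escapees=(), min_tpm: float = 1.0) -> float:
    """Median-over-median X:A expression ratio for one sample."""
    x_vals, auto_vals = _filtered_values(expr_col, annot, escapees, min_tpm)
    if len(x_vals) == 0 or len(auto_vals) == 0:
        raise DataError(
            "insufficient genes after TPM filtering "
            f"(X: {len(x_vals)}, autosomal: {len(auto_vals)})"
        )
    return float(np.median(x_vals) / np.median(auto_vals))


def bootstrap_background(expr_col: pd.Series, annot: GeneAnnotation,
                         set_size: int | None = None, n_boot: int = 1000,
                         min_tpm: float = 1.0, escapees=(),
                         seed: int = 0) -> RatioResult:
    """Size-matched bootstrap null for the X:A ratio of one sample.

    Each replicate draws ``set_size`` autosomal genes without
    replacement (defaulting to the filtered X gene count) and scores
    their median over the global autosomal median. Returns the observed
    ratio, the null distribution, its central 95% interval and an
    add-one two-sided empirical p-value for the observed ratio's
    deviation from 1.
    """
    x_vals, auto_vals = _filtered_values(expr_col, annot, escapees, min_tpm)
    if len(x_vals) == 0 or len(auto_vals) == 0:
        raise DataError("insufficient genes after TPM filtering")
    if set_size is None:
        set_size = len(x_vals)
    if set_size > len(auto_vals):
        raise DataError(
            f"set_size {set_size} exceeds {len(auto_vals)} filtered autosomal genes"
        )
    if n_boot < 1:
        raise DataError("n_boot must be >= 1")

    observed = float(np.median(x_vals) / np.median(auto_vals))
    auto_median = np.median(auto_vals)

    rng = np.random.default_rng(seed)
    # vectorized without-replacement sampling: rank random keys per replicate
    keys = rng.random((n_boot, len(auto_vals)))
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    boot = np.median(auto_vals[idx], axis=1) / auto_median

    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    p = (1 + int(np.sum(np.abs(boot - 1.0) >= abs(observed - 1.0)))) / (n_boot + 1)
    return RatioResult(
        ratio=observed,
        boot_distribution=boot,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_empirical=float(p),
        n_genes_x=len(x_vals),
        n_genes_background=len(auto_vals),
    )


def chromosome_track(expr_col: pd.Series, annot: GeneAnnotation,
                     chromosome: str, window_bp: int, step_bp: int) -> pd.DataFrame:
    """Sliding-window mean TPM along one chromosome, genes placed by TSS.

    Windows are ``[start, start + window_bp)`` at ``step_bp`` intervals
    from position 0 to the last TSS. Windows containing no gene carry
    NaN (a missing marker, never zero). Returns a frame with columns
    ``window_start``, ``position`` (window centre), ``mean_tpm``,
    ``n_genes``.
    """
    if not (window_bp >= step_bp > 0):
        raise DataError("need window_bp >= step_bp > 0")
    genes = annot.genes_on(chromosome)
    if len(genes) == 0:
        raise DataError(f"no genes annotated on chromosome {chromosome!r}")
    genes = [g for g in genes if g in expr_col.index]
    tss = annot.table.loc[genes, "tss"].to_numpy(dtype=float)
    tpm = expr_col.loc[genes].to_numpy(dtype=float)

    max_tss = tss.max()
    starts = np.arange(0, max_tss + 1, step_bp)
    rows = []
    for s in starts:
        in_win = (tss >= s) & (tss < s + window_bp)
        n = int(in_win.sum())
        mean = float(tpm[in_win].mean()) if n else np.nan
        rows.append((int(s), int(s) + window_bp / 2.0, mean, n))
    return pd.DataFrame(rows, columns=["window_start", "position", "mean_tpm", "n_genes"])
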