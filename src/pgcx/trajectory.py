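"""Single-lineage pseudotime, temporal smoothing and mutual exclusivity.

Pseudotime is a deliberately simple single-lineage principal-curve
procedure: PCA on log-normalized (never variance-scaled) expression,
then alternating curve smoothing and orthogonal projection until the
cell orderings stabilise. Arc length along the fitted curve, rescaled
to [0, 1] and oriented so a user-designated root population sits early,
is the pseudotime. Temporal profiles are least-squares cubic B-spline
fits against pseudotime. The mutual-exclusivity statistic for a gene
pair compares the observed double-positive cell count with the
independence expectation and judges it by label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import BSpline

from .containers import DataError, ExclusivityResult, ExpressionMatrix


@dataclass
class PseudotimeAxis:
    """Per-cell pseudotime in [0, 1] plus the fitted curve in PC space."""

    t: pd.Series  # indexed by cell id
    curve: np.ndarray  # ordered curve points, grid x n_pcs
    n_pcs: int


# ------------------------------------------------------------ spline fitting


def _bspline_basis(t: np.ndarray, df: int, domain=None):
    """Cubic B-spline design matrix with df basis functions, knots at quantiles."""
    k = 3
    if df < k + 1:
        raise DataError(f"df must be >= {k + 1} for cubic splines")
    lo, hi = (t.min(), t.max()) if domain is None else domain
    if hi <= lo:
        raise DataError("degenerate pseudotime: all values equal")
    n_interior = df - k - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    x = np.clip(t, lo, hi)
    return np.asarray(BSpline.design_matrix(x, knots, k).todense()), knots


def smooth_temporal(gene_expr, t, df: int = 6, n_grid: int = 100):
    """Least-squares cubic B-spline fit of one gene along pseudotime.

    Returns ``(grid, fitted, residual_variance)`` with the fitted mean
    curve sampled at ``n_grid`` points across the pseudotime range. The
    spline space contains all cubics, so polynomial trends of degree
    <= 3 are reproduced exactly whenever ``df >= 6``.
    """
    y = np.asarray(gene_expr, dtype=float).ravel()
    t = np.asarray(t.t if isinstance(t, PseudotimeAxis) else t, dtype=float).ravel()
    if len(y) != len(t):
        raise DataError("expression and pseudotime lengths differ")
    if len(y) < df + 2:
        raise DataError(f"need at least df + 2 = {df + 2} cells")
    B, knots = _bspline_basis(t, df)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    fitted_at_cells = B @ coef
    resid = y - fitted_at_cells
    dof = max(len(y) - df, 1)
    grid = np.linspace(t.min(), t.max(), n_grid)
    Bg = np.asarray(BSpline.design_matrix(grid, knots, 3).todense())
    return grid, Bg @ coef, float(resid @ resid / dof)


# -------------------------------------------------------------- pseudotime


def _pca_scores(X: np.ndarray, n_pcs: int) -> np.ndarray:
    """PC scores with a rotation-invariant sign convention.

    Signs are fixed so the score of largest magnitude on each component
    is positive — a rule that depends only on the scores, hence is
    unchanged by any rigid rotation of the input feature space.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = (U * s)[:, :n_pcs]
    for j in range(scores.shape[1]):
        pivot = np.argmax(np.abs(scores[:, j]))
        if scores[pivot, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's nearest location on the polyline."""
    a, b = curve[:-1], curve[1:]  # segments
    seg = b - a
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    # alpha: cells x segments, clamped projection parameter
    diff = points[:, None, :] - a[None, :, :]
    alpha = np.clip(np.einsum("csd,sd->cs", diff, seg) / seg_len2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + alpha[:, :, None] * seg[None, :, :]
    d2 = np.sum((points[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    seg_len = np.sqrt(np.where(seg_len2 < 1e-299, 0.0, seg_len2))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    arc = cum[best] + alpha[np.arange(len(points)), best] * seg_len[best]
    total = cum[-1]
    if total == 0:
        raise DataError("degenerate curve: all cells identical")
    return arc / total


def fit_pseudotime(matrix: ExpressionMatrix, n_pcs: int = 10, root=None,
                   log_transform: bool = True, df: int = 6,
                   n_curve_grid: int = 100, max_iter: int = 50,
                   tol: float = 1e-4) -> PseudotimeAxis:
    """Principal-curve pseudotime for a single-lineage population.

    ``root`` designates the developmental origin and is required (the
    arc length itself cannot tell start from end): either an iterable
    of cell ids or a ``(metadata_column, value)`` pair. The axis is
    oriented so root cells have mean pseudotime < 0.5.
    """
    n_cells = matrix.values.shape[1]
    if n_cells < 10:
        raise DataError("need at least 10 cells for a trajectory")
    if root is None:
        raise DataError("orientation is ambiguous: supply root cells or a "
                        "(metadata_column, value) root label")
    if n_pcs >= n_cells:
        raise DataError("n_pcs must be smaller than the number of cells")

    X = matrix.values.to_numpy(dtype=float).T  # cells x genes
    if log_transform:
        X = np.log2(X + 1.0)
    n_pcs = min(n_pcs, X.shape[1], n_cells - 1)
    scores = _pca_scores(X, n_pcs)

    # initial ordering along PC1; average ranks keep duplicates identical
    t = scipy.stats.rankdata(scores[:, 0], method="average")
    t = (t - t.min()) / max(t.max() - t.min(), 1e-300)

    curve = None
    grid = np.linspace(0.0, 1.0, n_curve_grid)
    for _ in range(max_iter):
        B, knots = _bspline_basis(t, df, domain=(0.0, 1.0))
        Bg = np.asarray(BSpline.design_matrix(grid, knots, 3).todense())
        coef, *_ = np.linalg.lstsq(B, scores, rcond=None)
        curve = Bg @ coef  # grid x n_pcs
        t_new = _project_to_polyline(scores, curve)
        t_new = (t_new - t_new.min()) / max(t_new.max() - t_new.min(), 1e-300)
        delta = np.mean(np.abs(t_new - t))
        t = t_new
        if delta < tol:
            break

    if isinstance(root, tuple) and len(root) == 2 and isinstance(root[0], str):
        col, value = root
        if col not in matrix.sample_meta.columns:
            raise DataError(f"no metadata column {col!r}")
        mask = (matrix.sample_meta[col] == value).to_numpy()
    else:
        root_ids = set(root)
        mask = np.array([c in root_ids for c in matrix.sample_ids])
    if not mask.any():
        raise DataError("root selection matches no cells")
    if t[mask].mean() > 0.5:
        t = 1.0 - t
        curve = curve[::-1]

    return PseudotimeAxis(
        t=pd.Series(t, index=matrix.sample_ids, name="pseudotime"),
        curve=curve,
        n_pcs=n_pcs,
    )


# -------------------------------------------------------- mutual exclusivity


def exclusivity_test(a, b, on_threshold: float = 1.0, n_perm: int = 10_000,
                     seed: int = 0) -> ExclusivityResult:
    """Permutation test for mutual exclusivity of two genes.

    Cells are binarized at ``on_threshold``; the observed
    double-positive count is compared with the independence expectation
    n * p_a * p_b. The exclusivity score (expected - observed) /
    max(expected, 1), clipped to [-1, 1], is positive for avoidance and
    negative for co-occurrence. The one-sided permutation p (shuffling
    the second gene's labels, add-one corrected) asks whether so few
    double positives could arise by chance. If either gene has no
    positive cells the result is flagged ``undetermined`` (score 0,
    p 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DataError("gene vectors must have equal length")
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    A = a > on_threshold
    Bv = b > on_threshold
    n = len(a)
    observed = int(np.sum(A & Bv))
    expected = float(n * A.mean() * Bv.mean())
    if A.sum() == 0 or Bv.sum() == 0:
        return ExclusivityResult(observed, expected, 0.0, 1.0, n_perm,
                                 undetermined=True)

    score = float(np.clip((expected - observed) / max(expected, 1.0), -1.0, 1.0))
    rng = np.random.default_rng(seed)
    perm_counts = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        shuffled = rng.permuted(np.tile(Bv, (m, 1)), axis=1)
        perm_counts[start:start + m] = (shuffled & A).sum(axis=1)
    p = (1 + int(np.sum(perm_counts <= observed))) / (n_perm + 1)
    return ExclusivityResult(observed, expected, score, float(p), n_perm)
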