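"""Cell-identity scoring by simplex-constrained least squares.

Each cell's expression vector x is decomposed against K reference
lineage profiles (columns of S) by solving

    minimize  ||x - S w||^2   subject to  w >= 0,  sum(w) = 1,

the quadratic program classically used for transcriptome-based cell
fate scoring. The optimum is found exactly by enumerating active sets
of the equality-constrained KKT system — every face of the simplex is
solved in closed form and the feasible solution with the smallest
objective wins — so there is no iterative-solver tolerance to tune.
Ties between equally optimal faces resolve toward lower lineage index.

Inputs are taken as pre-harmonized: the references and queries must
share gene order and expression scale (conventionally log2(TPM+1)
restricted to the reference's informative genes); no transform is
applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import DataError, ExpressionMatrix

_MAX_EXACT_K = 12


@dataclass
class IdentityWeights:
    """Simplex weights for one cell plus the fit residual."""

    weights: pd.Series  # indexed by lineage name, >= 0, sums to 1
    residual_norm: float
    objective: float  # squared residual at the optimum


def _validate_refs(refs: pd.DataFrame) -> np.ndarray:
    S = np.asarray(refs, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise DataError("reference signature must be genes x K with K >= 2")
    if (S < 0).any():
        raise DataError("reference signature has negative entries")
    if (S.sum(axis=0) == 0).any():
        raise DataError("reference signature has an all-zero column")
    if S.shape[1] > _MAX_EXACT_K:
        raise DataError(f"active-set enumeration supports K <= {_MAX_EXACT_K}")
    return S


def fit_identity(cell, refs: pd.DataFrame) -> IdentityWeights:
    """Exact simplex-constrained least-squares fit of one cell.

    ``cell`` is a gene expression vector aligned to the rows of
    ``refs`` (genes x lineages). Returns the global optimum of
    ``min ||x - Sw||^2`` over the probability simplex.
    """
    S = _validate_refs(refs)
    x = np.asarray(cell, dtype=float).ravel()
    if x.shape[0] != S.shape[0]:
        raise DataError(
            f"cell has {x.shape[0]} genes but references have {S.shape[0]}"
        )
    K = S.shape[1]
    G = S.T @ S
    c = S.T @ x
    xx = float(x @ x)

    best_obj, best_w = np.inf, None
    for size in range(1, K + 1):
        for active in combinations(range(K), size):
            idx = list(active)
            # KKT system of min ||x - S_A w||^2 s.t. 1'w = 1 on the face
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = 2.0 * G[np.ix_(idx, idx)]
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([2.0 * c[idx], [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            w_face = sol[:size]
            if (w_face < -1e-9).any():
                continue
            w = np.zeros(K)
            w[idx] = np.clip(w_face, 0.0, None)
            w /= w.sum()
            obj = xx - 2.0 * (c @ w) + w @ G @ w
            if obj < best_obj - 1e-12:
                best_obj, best_w = obj, w
    if best_w is None:  # unreachable for a valid simplex problem; vertices always feasible
        raise DataError("no feasible face found")
    best_obj = max(best_obj, 0.0)
    names = list(refs.columns) if isinstance(refs, pd.DataFrame) else list(range(K))
    return IdentityWeights(
        weights=pd.Series(best_w, index=names),
        residual_norm=float(np.sqrt(best_obj)),
        objective=float(best_obj),
    )


def grid_search_objective(cell, refs: pd.DataFrame, step: float = 0.001) -> float:
    """Brute-force minimum of the identity objective on a simplex grid.

    Evaluates ``||x - Sw||^2`` at every grid point with coordinates in
    multiples of ``step`` summing to 1 (K = 3 only; ~0.5M points at the
    default step). A verification utility, deliberately independent of
    the active-set solver.
    """
    S = np.asarray(refs, dtype=float)
    if S.shape[1] != 3:
        raise DataError("grid search oracle implemented for K = 3")
    x = np.asarray(cell, dtype=float).ravel()
    n = int(round(1.0 / step))
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    keep = (i + j) <= n
    W = np.column_stack([i[keep], j[keep], n - i[keep] - j[keep]]) / n
    # ||x - Sw||^2 expanded through the Gram matrix to avoid a grid x genes array
    G = S.T @ S
    obj = x @ x - 2.0 * (W @ (S.T @ x)) + np.einsum("ij,ij->i", W @ G, W)
    return float(obj.min())


def score_population(matrix: ExpressionMatrix, refs: pd.DataFrame,
                     group_by: str | None = None, bin_width: float = 0.02):
    """Identity weights for every cell plus per-group summaries.

    Returns ``(weights, summary)``: ``weights`` is a cells x lineages
    frame with a ``residual`` column; ``summary`` maps each group (or
    ``"all"``) to its per-lineage mean weight and a histogram density
    with fixed ``bin_width`` bins on [0, 1].
    """
    if matrix.values.shape[1] < 1:
        raise DataError("need at least one cell")
    if not matrix.gene_ids.equals(refs.index):
        raise DataError("matrix and references must share gene order")
    rows = []
    for i, cell_id in enumerate(matrix.sample_ids):
        try:
            fit = fit_identity(matrix.values[cell_id].to_numpy(), refs)
        except DataError as err:
            raise DataError(f"cell {i} ({cell_id}): {err}") from err
        rows.append(list(fit.weights) + [fit.residual_norm])
    weights = pd.DataFrame(
        rows, index=matrix.sample_ids, columns=list(refs.columns) + ["residual"]
    )

    if group_by is None:
        groups = {"all": weights.index}
    else:
        groups = {
            str(g): idx.index
            for g, idx in matrix.sample_meta.groupby(group_by, sort=True)
        }
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    centres = (edges[:-1] + edges[1:]) / 2.0
    summary = {}
    for name, cells in groups.items():
        sub = weights.loc[cells, refs.columns]
        density = pd.DataFrame(
            {
                lin: np.histogram(sub[lin], bins=edges, density=True)[0]
                for lin in refs.columns
            },
            index=centres,
        )
        summary[name] = {"mean": sub.mean(), "density": density}
    return weights, summary
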