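"""Synthetic data generation for every analysis stage.

Each generator emulates the statistical structure the downstream method
assumes, with the ground truth returned alongside the data:

* bulk TPM matrices with genotype-dependent X dosage (XY baseline,
  XX/XXY with intact X inactivation where only escapees are biallelic,
  and eroded genotypes where the whole inactive X reactivates), plus a
  dedicated XIST gene whose level encodes XCI status;
* single-cell mixtures of hES / ectoderm / mesoendoderm reference
  profiles with Dirichlet lineage weights;
* DNA sequence sets with motif instances embedded at known positions;
* cells along a noisy one-dimensional differentiation path with known
  generative time;
* labeled 3D voxel masks of mitochondria with analytically known
  surface areas.

All generators take a single integer seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BASES,
    ConfigError,
    DataError,
    ExpressionMatrix,
    GeneAnnotation,
    MitoSegmentation,
    PeakSet,
    PWM,
)

GENOTYPES = ("XY", "XX_XCI", "XXY_XCI", "XXY_eroded", "XX_eroded")

# genotypes in which an inactive (XIST-coated) X chromosome exists
_HAS_INACTIVE_X = {"XX_XCI", "XXY_XCI"}
# genotypes in which non-escapee X genes are expressed from two X copies
_ERODED = {"XXY_eroded", "XX_eroded"}

_GENE_SPACING_BP = 100_000
_GENE_LENGTH_BP = 10_000
_XIST_ACTIVE_TPM = 50.0
_XIST_SILENT_TPM = 0.5


@dataclass
class DosageSimConfig:
    """Configuration for the bulk X-dosage simulator.

    ``escapee_multiplier`` is the fold-increase applied to escapee genes
    under intact XCI and to all X genes under erosion; biallelic
    expression doubles output under a simple additive-copy model, hence
    the default of 2.
    """

    n_genes_per_autosome: int = 100
    n_autosomes: int = 22
    n_x_genes: int = 80
    n_samples: int = 4
    genotype: str = "XY"
    escapee_fraction: float = 0.15
    base_mu: float = 2.0  # mean of log TPM
    base_sigma: float = 1.0  # sd of log TPM
    noise_sd: float = 0.1  # sd of per-sample log-TPM noise (~10% CV, clonal lines)
    escapee_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ConfigError(f"unknown genotype {self.genotype!r}; choose from {GENOTYPES}")
        if not 0 <= self.escapee_fraction <= 1:
            raise ConfigError("escapee_fraction must lie in [0, 1]")
        for name in ("n_genes_per_autosome", "n_autosomes", "n_x_genes", "n_samples"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.base_sigma < 0:
            raise ConfigError("scale parameters must be non-negative")


@dataclass
class LineageSimConfig:
    """Configuration for the lineage-mixture simulator."""

    n_cells: int = 200
    reference_profiles: pd.DataFrame = None  # genes x 3 (hES, ectoderm, mesoendoderm)
    weight_law: tuple = (1.0, 1.0, 1.0)  # Dirichlet concentrations
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.reference_profiles is None:
            raise ConfigError("reference_profiles is required")
        if (np.asarray(self.reference_profiles) < 0).any():
            raise ConfigError("reference profiles must be non-negative")
        if len(self.weight_law) != self.reference_profiles.shape[1]:
            raise ConfigError("one Dirichlet concentration per reference lineage")
        if any(a <= 0 for a in self.weight_law):
            raise ConfigError("Dirichlet concentrations must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def _build_annotation(cfg: DosageSimConfig) -> GeneAnnotation:
    records = []
    for c in range(1, cfg.n_autosomes + 1):
        for i in range(cfg.n_genes_per_autosome):
            start = 1 + i * _GENE_SPACING_BP
            strand = "+" if i % 2 == 0 else "-"
            records.append((f"A{c}_{i}", f"chr{c}", start, start + _GENE_LENGTH_BP, strand))
    for i in range(cfg.n_x_genes):
        start = 1 + i * _GENE_SPACING_BP
        strand = "+" if i % 2 == 0 else "-"
        records.append((f"X_{i}", "chrX", start, start + _GENE_LENGTH_BP, strand))
    xist_start = 1 + cfg.n_x_genes * _GENE_SPACING_BP
    records.append(("XIST", "chrX", xist_start, xist_start + _GENE_LENGTH_BP, "-"))
    return GeneAnnotation.from_records(records)


def simulate_dosage_expression(cfg: DosageSimConfig):
    """Generate a bulk TPM matrix with genotype-dependent X dosage.

    Returns ``(ExpressionMatrix, GeneAnnotation, escapee_gene_list)``.
    Per-gene baselines are log-normal and drawn identically for every
    genotype at a given seed, so genotypes differ only through the
    dosage multipliers (and XIST): with ``noise_sd=0`` an eroded X gene
    is exactly ``escapee_multiplier`` times its XY value.
    """
    annot = _build_annotation(cfg)
    gene_ids = list(annot.gene_ids)
    n_genes = len(gene_ids)
    rng = np.random.default_rng(cfg.seed)

    base = np.exp(rng.normal(cfg.base_mu, cfg.base_sigma, n_genes))

    x_regular = [g for g in gene_ids if g.startswith("X_")]
    n_escapees = int(round(cfg.escapee_fraction * cfg.n_x_genes))
    escapees = sorted(rng.choice(x_regular, size=n_escapees, replace=False).tolist())
    escapee_set = set(escapees)

    mult = np.ones(n_genes)
    for j, g in enumerate(gene_ids):
        if not g.startswith("X_"):
            continue
        if cfg.genotype in _ERODED:
            mult[j] = cfg.escapee_multiplier
        elif cfg.genotype in _HAS_INACTIVE_X and g in escapee_set:
            mult[j] = cfg.escapee_multiplier
    xist_idx = gene_ids.index("XIST")
    base[xist_idx] = (
        _XIST_ACTIVE_TPM if cfg.genotype in _HAS_INACTIVE_X else _XIST_SILENT_TPM
    )

    noise = np.exp(rng.normal(0.0, cfg.noise_sd, (n_genes, cfg.n_samples)))
    values = (base * mult)[:, None] * noise
    samples = [f"{cfg.genotype}_s{k}" for k in range(cfg.n_samples)]
    meta = pd.DataFrame({"genotype": cfg.genotype, "line": cfg.genotype}, index=samples)
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples), meta)
    return expr, annot, escapees


def make_reference_profiles(n_genes: int = 60, n_markers: int = 10,
                            marker_tpm: float = 100.0, base_tpm: float = 5.0,
                            seed: int = 0) -> pd.DataFrame:
    """Three distinguishable reference profiles (hES, ectoderm, mesoendoderm).

    Each lineage carries a disjoint block of ``n_markers`` marker genes
    at ``marker_tpm``; all remaining genes sit at a shared jittered
    baseline. Values are TPM.
    """
    if 3 * n_markers > n_genes:
        raise ConfigError("need n_genes >= 3 * n_markers")
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    profiles = pd.DataFrame(
        base_tpm * np.exp(rng.normal(0, 0.1, (n_genes, 3))),
        index=genes, columns=["hES", "ectoderm", "mesoendoderm"],
    )
    for k, lineage in enumerate(profiles.columns):
        profiles.iloc[k * n_markers:(k + 1) * n_markers, k] = marker_tpm
    return profiles


def simulate_lineage_cells(cfg: LineageSimConfig):
    """Mix reference profiles with Dirichlet weights plus log-normal noise.

    Returns ``(ExpressionMatrix, weights)`` where ``weights`` is the
    cells x lineages ground-truth mixing matrix. Cells are convex
    combinations of the references on the scale the references are given
    in, so with ``noise_sd=0`` every cell lies in their convex hull.
    """
    refs = cfg.reference_profiles
    rng = np.random.default_rng(cfg.seed)
    weights = rng.dirichlet(np.asarray(cfg.weight_law, float), size=cfg.n_cells)
    cells = weights @ refs.to_numpy().T  # n_cells x genes
    if cfg.noise_sd > 0:
        cells = cells * np.exp(rng.normal(0.0, cfg.noise_sd, cells.shape))
    cell_ids = [f"cell{i}" for i in range(cfg.n_cells)]
    values = pd.DataFrame(cells.T, index=refs.index, columns=cell_ids)
    meta = pd.DataFrame(index=cell_ids)
    w = pd.DataFrame(weights, index=cell_ids, columns=refs.columns)
    return ExpressionMatrix(values, meta), w


def simulate_motif_sequences(pwm: PWM, n_pos: int, n_neg: int, seq_len: int,
                             seed: int = 0, background=None):
    """Sequence set with one PWM-sampled instance embedded in each positive.

    Negatives are pure background; positives receive a single instance
    sampled position-wise from the PWM, at a uniform offset, on a
    uniform strand. Returns ``(sequences, PeakSet, labels)`` where
    ``sequences`` maps peak name -> DNA string and ``labels`` is a
    peak-name-indexed Series with 1 for motif-bearing sequences (the
    PeakSet is coordinate-sorted, so positional alignment would be
    unsafe).
    """
    if seq_len < len(pwm):
        raise ConfigError(f"seq_len {seq_len} shorter than motif length {len(pwm)}")
    if n_pos < 0 or n_neg < 0:
        raise ConfigError("sequence counts must be non-negative")
    bg = pwm.background if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    base_arr = np.array(list(BASES))
    comp = str.maketrans(BASES, "TGCA")

    sequences, records, labels = {}, [], []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        seq = rng.choice(base_arr, size=seq_len, p=bg)
        if positive:
            instance = "".join(
                rng.choice(base_arr, p=pwm.matrix[j]) for j in range(len(pwm))
            )
            if rng.random() < 0.5:
                instance = instance.translate(comp)[::-1]
            offset = int(rng.integers(0, seq_len - len(pwm) + 1))
            seq[offset:offset + len(pwm)] = list(instance)
        name = f"peak{i}"
        sequences[name] = "".join(seq)
        records.append((name, 0, seq_len, name, 30.0))
        labels.append(1 if positive else 0)
    peaks = PeakSet.from_records(records)
    label_series = pd.Series(labels, index=list(sequences), name="label")
    return sequences, peaks, label_series


def simulate_trajectory_cells(n_cells: int = 200, n_genes: int = 20,
                              noise_sd: float = 0.1, seed: int = 0,
                              root_fraction: float = 0.2):
    """Cells along a noisy one-dimensional differentiation path.

    The latent state traces a half-circle arc in a 2-D subspace as a
    function of generative time u ~ U(0, 1); gene space is a random
    linear embedding of that arc, expressed on the log2(TPM+1) scale and
    mapped back to TPM. Cells with u below ``root_fraction`` are tagged
    with stage label ``"root"``. Returns ``(ExpressionMatrix, u)``.
    """
    if n_cells < 10:
        raise ConfigError("need at least 10 cells")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 1, n_cells)
    latent = np.column_stack([np.cos(np.pi * u), np.sin(np.pi * u)])  # n_cells x 2
    loadings = rng.normal(0, 1.0, (n_genes, 2))
    log_expr = 4.0 + 2.0 * latent @ loadings.T  # n_cells x n_genes
    log_expr += rng.normal(0, noise_sd, log_expr.shape)
    tpm = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    cell_ids = [f"cell{i}" for i in range(n_cells)]
    genes = [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {"stage": np.where(u < root_fraction, "root", "late")}, index=cell_ids
    )
    expr = ExpressionMatrix(pd.DataFrame(tpm.T, index=genes, columns=cell_ids), meta)
    return expr, u


# ------------------------------------------------------------------ 3D masks


def _face_area(mask: np.ndarray, voxel_size) -> float:
    """Exposed-face area of a single boolean component (construction oracle)."""
    dz, dy, dx = voxel_size
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    total = 0.0
    for axis, area in face.items():
        m = np.moveaxis(mask, axis, 0)
        interior = m[:-1] != m[1:]
        total += area * (interior.sum() + m[0].sum() + m[-1].sum())
    return float(total)


def _box_voxels(size_um, voxel_size):
    if np.isscalar(size_um):
        size_um = (size_um,) * 3
    return tuple(max(1, int(round(s / v))) for s, v in zip(size_um, voxel_size))


def _box_area(extent_vox, voxel_size) -> float:
    nz, ny, nx = extent_vox
    dz, dy, dx = voxel_size
    return 2.0 * (ny * dy * nx * dx + nz * dz * nx * dx + nz * dz * ny * dy)


def _sphere_mask(diameter_um: float, voxel_size) -> np.ndarray:
    r = diameter_um / 2.0
    dz, dy, dx = voxel_size
    nz, ny, nx = (max(1, int(np.ceil(diameter_um / v)) + 1) for v in voxel_size)
    zc, yc, xc = ((n - 1) / 2.0 for n in (nz, ny, nx))
    z, y, x = np.ogrid[:nz, :ny, :nx]
    dist2 = ((z - zc) * dz) ** 2 + ((y - yc) * dy) ** 2 + ((x - xc) * dx) ** 2
    mask = dist2 <= r**2
    if not mask.any():  # sub-voxel sphere occupies its centre voxel
        mask[int(zc), int(yc), int(xc)] = True
    return mask


def simulate_mito_masks(n_cells: int, components_per_cell, voxel_size,
                        seed: int = 0, positions=None):
    """Labeled mitochondrial masks with analytically known surface areas.

    ``components_per_cell`` is either one list of ``(shape, size_um)``
    specs applied to every cell, or one such list per cell. ``shape`` is
    ``"box"`` (cube of the given edge, or a 3-tuple of edges) or
    ``"sphere"`` (diameter). Components are laid out disjointly along
    the x axis unless explicit corner ``positions`` are given, in which
    case any overlap raises. Box areas come from the closed-form face
    formula; sphere areas from an independent construction-time face
    count on the isolated occupancy mask.

    Returns a list of ``(MitoSegmentation, {label: area_um2})``.
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in voxel_size):
        raise ConfigError("voxel_size entries must be positive")
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")

    def _is_spec(item):
        return (isinstance(item, (tuple, list)) and len(item) == 2
                and isinstance(item[0], str))

    if not components_per_cell or all(_is_spec(it) for it in components_per_cell):
        components_per_cell = [list(components_per_cell)] * n_cells
    if len(components_per_cell) != n_cells:
        raise ConfigError("components_per_cell must match n_cells")

    out = []
    for ci, specs in enumerate(components_per_cell):
        masks, areas = [], {}
        for label, (shape, size_um) in enumerate(specs, start=1):
            if shape == "box":
                extent = _box_voxels(size_um, voxel_size)
                comp = np.ones(extent, dtype=bool)
                areas[label] = _box_area(extent, voxel_size)
            elif shape == "sphere":
                comp = _sphere_mask(float(size_um), voxel_size)
                areas[label] = _face_area(comp, voxel_size)
            else:
                raise ConfigError(f"unknown component shape {shape!r}")
            masks.append(comp)

        gap = 2
        if positions is None:
            # disjoint by construction: stack along x with a 2-voxel gap
            nz = max((m.shape[0] for m in masks), default=1)
            ny = max((m.shape[1] for m in masks), default=1)
            nx = sum(m.shape[2] + gap for m in masks) + gap
            labels = np.zeros((nz + 2, ny + 2, max(nx, 1)), dtype=np.int32)
            x0 = gap
            for label, comp in enumerate(masks, start=1):
                sz, sy, sx = comp.shape
                region = labels[1:1 + sz, 1:1 + sy, x0:x0 + sx]
                region[comp] = label
                x0 += sx + gap
        else:
            corners = positions[ci]
            extent = np.zeros(3, dtype=int)
            for corner, comp in zip(corners, masks):
                extent = np.maximum(extent, np.asarray(corner) + comp.shape)
            labels = np.zeros(tuple(extent), dtype=np.int32)
            for label, (corner, comp) in enumerate(zip(corners, masks), start=1):
                z0, y0, x0 = corner
                region = labels[z0:z0 + comp.shape[0], y0:y0 + comp.shape[1],
                                x0:x0 + comp.shape[2]]
                if (region[comp] != 0).any():
                    raise DataError(f"component {label} overlaps an earlier one")
                region[comp] = label
        out.append((MitoSegmentation(labels, voxel_size, cell_id=f"cell{ci}"), areas))
    return out
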