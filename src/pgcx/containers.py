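"""Core in-memory containers shared by every analysis stage.

Conventions used throughout the package:

* expression values are non-negative (TPM or counts), genes x samples;
* gene annotation coordinates are 1-based inclusive, as in GTF-derived
  tables, and are converted to BED's 0-based half-open convention only
  inside the cistrome interval routines;
* peak intervals follow the BED convention (0-based, half-open);
* DNA is over the alphabet ACGT with ``N`` treated as background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
X_CHROMOSOMES = {"X", "chrX"}


class PgcxError(Exception):
    """Base class for all package errors."""


class ConfigError(PgcxError):
    """Invalid configuration (bad enum value, non-positive size, ...)."""


class DataError(PgcxError):
    """Structurally invalid or insufficient input data."""


def is_x_chromosome(chrom: str) -> bool:
    return chrom in X_CHROMOSOMES


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample; ``sample_meta`` is indexed by sample id and may carry
    arbitrary labels (cell line, stage, genotype ...).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise DataError("gene ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise DataError("expression values must be non-negative")
        if len(self.sample_meta) != self.values.shape[1]:
            raise DataError(
                f"sample_meta has {len(self.sample_meta)} rows but the "
                f"matrix has {self.values.shape[1]} columns"
            )
        self.sample_meta = self.sample_meta.set_axis(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def column(self, sample: str) -> pd.Series:
        """Expression of one sample as a gene-indexed Series."""
        return self.values[sample]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.sample_meta.loc[list(samples)])


@dataclass
class GeneAnnotation:
    """Gene -> (chromosome, start, end, strand, TSS) map.

    Coordinates are 1-based inclusive; the TSS is ``start`` on the plus
    strand and ``end`` on the minus strand.
    """

    table: pd.DataFrame  # index gene_id; columns chrom, start, end, strand, tss

    REQUIRED = ("chrom", "start", "end", "strand", "tss")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataError(f"annotation lacks columns: {missing}")
        t = self.table
        if not t.index.is_unique:
            raise DataError("annotation gene ids must be unique")
        if (t["start"] > t["end"]).any():
            raise DataError("annotation has start > end")
        bad = ~t["strand"].isin(["+", "-"])
        if bad.any():
            raise DataError(f"bad strand for genes: {list(t.index[bad][:5])}")
        outside = (t["tss"] < t["start"]) | (t["tss"] > t["end"])
        if outside.any():
            raise DataError(f"TSS outside gene body for: {list(t.index[outside][:5])}")

    @classmethod
    def from_records(cls, records) -> "GeneAnnotation":
        """Build from (gene_id, chrom, start, end, strand) tuples; TSS derived."""
        df = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
        return cls(df.set_index("gene_id"))

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def chromosome_of(self, gene_id: str) -> str:
        return self.table.at[gene_id, "chrom"]

    def genes_on(self, chrom: str) -> pd.Index:
        return self.table.index[self.table["chrom"] == chrom]

    def x_genes(self) -> pd.Index:
        mask = self.table["chrom"].map(is_x_chromosome)
        return self.table.index[mask]

    def autosomal_genes(self) -> pd.Index:
        """Genes on autosomes (everything except X, Y and MT-like names)."""
        non_autosome = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}
        return self.table.index[~self.table["chrom"].isin(non_autosome)]


@dataclass
class PeakSet:
    """Scored genomic intervals in BED convention (0-based half-open).

    The underlying frame is sorted by (chrom, start) on construction and
    carries columns chrom, start, end, name, score.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "name", "score"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise DataError(f"peak frame lacks columns: {missing}")
        f = self.frame
        if (f["start"] >= f["end"]).any():
            raise DataError("peaks must have start < end")
        if (f["score"] < 0).any():
            raise DataError("peak scores must be non-negative")
        self.frame = f.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "PeakSet":
        return cls(pd.DataFrame(records, columns=["chrom", "start", "end", "name", "score"]))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.frame["start"].to_numpy() + self.frame["end"].to_numpy()) // 2


@dataclass
class PWM:
    """Position weight matrix over ACGT with a background model.

    ``matrix`` holds per-position base probabilities (rows sum to 1);
    log-odds scores are log2(p/background) in bits.
    """

    matrix: np.ndarray  # (length, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise DataError("PWM matrix must be positions x 4")
        if (m < 0).any():
            raise DataError("PWM entries must be non-negative")
        m = m + self.pseudocount
        self.matrix = m / m.sum(axis=1, keepdims=True)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-6 or (bg <= 0).any():
            raise DataError("background must be 4 positive probabilities summing to 1")
        self.background = bg

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/bg) in bits, shape (length, 4)."""
        return np.log2(self.matrix / self.background[None, :])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def max_score(self) -> float:
        """Score of the consensus sequence (sum of per-position maxima)."""
        return float(self.log_odds().max(axis=1).sum())


@dataclass
class MitoSegmentation:
    """Labeled 3D voxel array with anisotropic voxel size in micrometres.

    ``labels`` uses 0 for background and k > 0 for component k; each
    label is treated as one object whether or not it is connected.
    """

    labels: np.ndarray  # 3D int
    voxel_size: tuple  # (dz, dy, dx) in um
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise DataError("labels must be a 3D array")
        if not np.issubdtype(arr.dtype, np.integer):
            raise DataError("labels must be integer-typed")
        if (arr < 0).any():
            raise DataError("labels must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise DataError("voxel_size must be three positive lengths (dz, dy, dx)")
        self.labels = arr
        self.voxel_size = vs

    def component_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]


@dataclass
class EscapeeCatalog:
    """Catalogued X-inactivation escapees: constitutive vs variable."""

    constitutive: frozenset
    variable: frozenset

    def __post_init__(self) -> None:
        self.constitutive = frozenset(self.constitutive)
        self.variable = frozenset(self.variable)
        overlap = self.constitutive & self.variable
        if overlap:
            raise DataError(f"genes in both catalog classes: {sorted(overlap)[:5]}")

    @property
    def all_escapees(self) -> frozenset:
        return self.constitutive | self.variable


@dataclass
class RatioResult:
    """X:A ratio with its bootstrap null distribution."""

    ratio: float
    boot_distribution: np.ndarray
    ci_low: float
    ci_high: float
    p_empirical: float
    n_genes_x: int
    n_genes_background: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise DataError("ci_low > ci_high")
        if not 0 <= self.p_empirical <= 1:
            raise DataError("p_empirical outside [0, 1]")


@dataclass
class ExclusivityResult:
    """Mutual-exclusivity test summary for a gene pair."""

    observed_double_pos: int
    expected_double_pos: float
    exclusivity_score: float
    p_perm: float
    n_perm: int
    undetermined: bool = False


@dataclass
class MitoCellStats:
    """Per-cell mitochondrial morphology summary."""

    cell_id: str
    areas: np.ndarray  # per-component surface areas, um^2
    bin_counts: np.ndarray
    has_cluster: bool
    clustering_degree: float

    def __post_init__(self) -> None:
        if int(self.bin_counts.sum()) != len(self.areas):
            raise DataError("bin counts do not conserve component count")
        if not 0 <= self.clustering_degree <= 1:
            raise DataError("clustering_degree outside [0, 1]")
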