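"""End-to-end synthetic study: generation through every analysis stage.

Stages communicate only through declared files inside the run
directory; each stage reads the outputs of its upstream stage from
disk, so any stage can be re-run or swapped against externally
produced files of the same format. A manifest records the
configuration, derived seeds and a checksum per output file; reruns
with an identical configuration produce byte-identical outputs and
manifests (the timestamped log is excluded from checksumming).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cistrome, degsets, dosage, identity as identity_mod, io, mitomorph
from . import synthio, trajectory
from .containers import ConfigError, DataError, EscapeeCatalog, PWM

ALL_STAGES = ("synthio", "dosage", "degsets", "identity", "trajectory",
              "cistrome", "mito")

# a strongly informative SOX-family-like motif used by the synthetic study
_SOX_LIKE_CONSENSUS = [0, 1, 0, 0, 3, 2, 3, 3, 1]  # ACAATGTTC
_SOX_LIKE = np.full((9, 4), 0.01)
for _pos, _base in enumerate(_SOX_LIKE_CONSENSUS):
    _SOX_LIKE[_pos, _base] = 0.97


@dataclass
class RunConfig:
    """Declarative configuration for a full synthetic run.

    Thresholds default to the analysis conventions used throughout the
    package: 1 TPM expression filter, FDR < 0.05 with fold change >
    1.5 for DEGs, 1000 bootstrap replicates, a 125 kb TSS window,
    enrichment-score filter at 25, and the 500 um^2 cluster threshold.
    ``theta`` (the affinity split, in bits) may be left unset, in which
    case the synthetic study places it midway between the median
    motif-bearing and background scan scores.
    """

    seed: int = 0
    stages: tuple = ALL_STAGES
    # analysis thresholds
    min_tpm: float = 1.0
    fdr: float = 0.05
    fc: float = 1.5
    n_boot: int = 1000
    window_bp: int = 125_000
    min_score: float = 25.0
    cluster_threshold: float = 500.0
    bin_edges: tuple = (0.0, 5.0, 10.0, 50.0, float("inf"))
    theta: float | None = None
    n_perm: int = 10_000
    # synthetic-study sizes
    n_genes_per_autosome: int = 100
    n_autosomes: int = 22
    n_x_genes: int = 80
    n_samples: int = 4
    escapee_fraction: float = 0.15
    noise_sd: float = 0.1
    n_lineage_cells: int = 200
    lineage_noise_sd: float = 0.2
    n_traj_cells: int = 200
    n_motif_pos: int = 100
    n_motif_neg: int = 100
    seq_len: int = 60
    n_mito_cells: int = 20
    mito_cluster_fraction: float = 0.4

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)
        self.bin_edges = tuple(float(e) for e in self.bin_edges)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["bin_edges"] = [("inf" if np.isinf(e) else e) for e in d["bin_edges"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "bin_edges" in d:
            d["bin_edges"] = tuple(float(e) for e in d["bin_edges"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    digest = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _require(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise DataError(
            f"stage {stage!r} requires missing upstream output {path.name} "
            f"(enable/run the {upstream!r} stage first)"
        )
    return path


class _Log:
    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def __call__(self, stage: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp}\t{stage}\t{message}\n")


GENOTYPE_PANEL = ("XY", "XX_XCI", "XXY_XCI", "XXY_eroded", "XX_eroded")


def _stage_synthio(cfg: RunConfig, rundir: Path, log) -> None:
    seed = _stage_seed(cfg, "synthio")
    for genotype in GENOTYPE_PANEL:
        sim = synthio.DosageSimConfig(
            n_genes_per_autosome=cfg.n_genes_per_autosome,
            n_autosomes=cfg.n_autosomes, n_x_genes=cfg.n_x_genes,
            n_samples=cfg.n_samples, genotype=genotype,
            escapee_fraction=cfg.escapee_fraction, noise_sd=cfg.noise_sd,
            seed=seed,
        )
        expr, annot, escapees = synthio.simulate_dosage_expression(sim)
        io.write_expression_tsv(expr, rundir / f"expr_{genotype}.tsv",
                                rundir / f"meta_{genotype}.tsv")
        if genotype == "XY":
            io.write_annotation_tsv(annot, rundir / "annotation.tsv")
            (rundir / "escapees.txt").write_text("\n".join(escapees) + "\n")
    log("synthio", f"dosage panel written for {len(GENOTYPE_PANEL)} genotypes")

    refs = synthio.make_reference_profiles(seed=seed)
    refs.to_csv(rundir / "lineage_refs.tsv", sep="\t", index_label="gene_id")
    lin_cfg = synthio.LineageSimConfig(
        n_cells=cfg.n_lineage_cells, reference_profiles=refs,
        weight_law=(1.0, 1.0, 1.0), noise_sd=cfg.lineage_noise_sd, seed=seed,
    )
    cells, true_w = synthio.simulate_lineage_cells(lin_cfg)
    io.write_expression_tsv(cells, rundir / "lineage_cells.tsv")
    true_w.to_csv(rundir / "lineage_true_weights.tsv", sep="\t",
                  index_label="cell_id")

    traj, true_time = synthio.simulate_trajectory_cells(
        n_cells=cfg.n_traj_cells, seed=seed)
    io.write_expression_tsv(traj, rundir / "traj_cells.tsv",
                            rundir / "traj_meta.tsv")
    pd.Series(true_time, index=traj.sample_ids, name="true_time").to_csv(
        rundir / "traj_true_time.tsv", sep="\t", index_label="cell_id")

    pwm = PWM(_SOX_LIKE, name="SOX_like")
    io.write_jaspar_pwm(pwm, rundir / "motif.jaspar")
    seqs, peaks, labels = synthio.simulate_motif_sequences(
        pwm, cfg.n_motif_pos, cfg.n_motif_neg, cfg.seq_len, seed=seed)
    io.write_fasta(seqs, rundir / "motif_seqs.fa")
    io.write_bed(peaks, rundir / "motif_peaks.bed")
    labels.to_csv(rundir / "motif_labels.tsv", sep="\t", index_label="peak")

    n_clustered = int(round(cfg.mito_cluster_fraction * cfg.n_mito_cells))
    comps = []
    for i in range(cfg.n_mito_cells):
        cell = [("box", 1.0), ("box", 2.0), ("sphere", 3.0)]
        if i < n_clustered:
            cell.append(("box", 10.0))  # 600 um^2 cube, a cluster
        comps.append(cell)
    masks = synthio.simulate_mito_masks(
        cfg.n_mito_cells, comps, voxel_size=(1.0, 1.0, 1.0), seed=seed)
    mito_dir = rundir / "mito"
    mito_dir.mkdir(exist_ok=True)
    truth = {}
    for seg, areas in masks:
        io.write_mask(seg, mito_dir / seg.cell_id)
        truth[seg.cell_id] = areas
    (rundir / "mito_truth.json").write_text(json.dumps(truth, sort_keys=True))
    log("synthio", "lineage, trajectory, motif and mito fixtures written")


def _stage_dosage(cfg: RunConfig, rundir: Path, log) -> dict:
    seed = _stage_seed(cfg, "dosage")
    annot = io.read_annotation_tsv(
        _require(rundir / "annotation.tsv", "dosage", "synthio"))
    escapees = (rundir / "escapees.txt").read_text().split()
    results = {}
    boot_cols = {}
    for genotype in GENOTYPE_PANEL:
        expr = io.read_expression_tsv(
            _require(rundir / f"expr_{genotype}.tsv", "dosage", "synthio"))
        sample = expr.sample_ids[0]
        res = dosage.bootstrap_background(
            expr.column(sample), annot, n_boot=cfg.n_boot,
            min_tpm=cfg.min_tpm, escapees=escapees, seed=seed)
        results[genotype] = {
            "sample": sample, "ratio": res.ratio, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p_empirical": res.p_empirical,
            "null_p975": float(np.percentile(res.boot_distribution, 97.5)),
            "n_genes_x": res.n_genes_x,
            "n_genes_background": res.n_genes_background,
        }
        boot_cols[genotype] = res.boot_distribution
    (rundir / "xa_ratios.json").write_text(
        json.dumps(results, sort_keys=True, indent=1))
    pd.DataFrame(boot_cols).to_csv(rundir / "xa_boot.tsv", sep="\t", index=False)

    expr_xy = io.read_expression_tsv(rundir / "expr_XY.tsv")
    track = dosage.chromosome_track(
        expr_xy.column(expr_xy.sample_ids[0]), annot, "chrX",
        window_bp=1_000_000, step_bp=500_000)
    track.to_csv(rundir / "chrX_track_XY.tsv", sep="\t", index=False)
    log("dosage", f"X:A ratios computed for {len(results)} genotypes")
    return results


def _stage_degsets(cfg: RunConfig, rundir: Path, log) -> dict:
    annot = io.read_annotation_tsv(
        _require(rundir / "annotation.tsv", "degsets", "synthio"))
    ctrl = io.read_expression_tsv(
        _require(rundir / "expr_XY.tsv", "degsets", "synthio"))
    contrasts = ("XXY_XCI", "XXY_eroded", "XX_XCI", "XX_eroded")
    tables = []
    for genotype in contrasts:
        case = io.read_expression_tsv(
            _require(rundir / f"expr_{genotype}.tsv", "degsets", "synthio"))
        table = degsets.call_deg_standin(
            case, ctrl, fc_thresh=cfg.fc, fdr_thresh=cfg.fdr,
            contrast_id=f"{genotype}_vs_XY")
        degsets.write_deg_tsv(table, rundir / f"deg_{genotype}_vs_XY.tsv")
        tables.append(table)
    shared = degsets.intersect_contrasts(tables, require_direction=True)
    shared.to_csv(rundir / "shared_degs.tsv", sep="\t")
    per_chrom, totals = degsets.partition_by_chromosome(shared, annot)
    per_chrom.replace(np.inf, "inf").to_csv(
        rundir / "deg_by_chromosome.tsv", sep="\t", index=False)

    # catalog from the designated escapee truth: first 8 constitutive, next 3 variable
    escapees = (rundir / "escapees.txt").read_text().split()
    catalog = EscapeeCatalog(frozenset(escapees[:8]), frozenset(escapees[8:11]))
    x_up = [g for g in shared.index
            if annot.chromosome_of(g) in {"X", "chrX"}
            and shared.at[g, "direction"] == "up"]
    classes = degsets.classify_escapees(x_up, catalog, annot)
    out = {
        "n_shared": int(len(shared)),
        "totals": totals,
        "escapee_classes": {k: sorted(v) for k, v in classes.items()},
    }
    (rundir / "escapee_classes.json").write_text(
        json.dumps(out, sort_keys=True, indent=1))
    log("degsets", f"{len(shared)} shared DEGs; "
        f"{len(x_up)} X-linked upregulated classified")
    return out


def _stage_identity(cfg: RunConfig, rundir: Path, log) -> dict:
    refs = pd.read_csv(
        _require(rundir / "lineage_refs.tsv", "identity", "synthio"),
        sep="\t", index_col="gene_id")
    cells = io.read_expression_tsv(
        _require(rundir / "lineage_cells.tsv", "identity", "synthio"))
    weights, _summary = identity_mod.score_population(cells, refs)
    weights.to_csv(rundir / "identity_weights.tsv", sep="\t",
                   index_label="cell_id")
    true_w = pd.read_csv(rundir / "lineage_true_weights.tsv", sep="\t",
                         index_col="cell_id")
    corr = {
        lin: float(np.corrcoef(true_w[lin], weights[lin])[0, 1])
        for lin in refs.columns
    }
    mae = float((true_w - weights[refs.columns]).abs().mean().mean())
    out = {"recovery_correlation": corr, "mean_abs_weight_error": mae}
    (rundir / "identity_recovery.json").write_text(
        json.dumps(out, sort_keys=True, indent=1))
    log("identity", f"scored {len(weights)} cells; "
        f"ectoderm recovery r={corr['ectoderm']:.3f}")
    return out


def _stage_trajectory(cfg: RunConfig, rundir: Path, log) -> dict:
    seed = _stage_seed(cfg, "trajectory")
    cells = io.read_expression_tsv(
        _require(rundir / "traj_cells.tsv", "trajectory", "synthio"),
        _require(rundir / "traj_meta.tsv", "trajectory", "synthio"))
    axis = trajectory.fit_pseudotime(cells, n_pcs=10, root=("stage", "root"))
    axis.t.to_csv(rundir / "pseudotime.tsv", sep="\t", index_label="cell_id")
    true_time = pd.read_csv(rundir / "traj_true_time.tsv", sep="\t",
                            index_col="cell_id")["true_time"]
    import scipy.stats as st

    rho = float(st.spearmanr(axis.t, true_time.loc[axis.t.index]).statistic)

    grid, fitted, resid_var = trajectory.smooth_temporal(
        cells.values.iloc[0].to_numpy(), axis)
    pd.DataFrame({"t": grid, "fitted": fitted}).to_csv(
        rundir / "temporal_gene0.tsv", sep="\t", index=False)

    # a SOX2/SOX17-like switch pair along the true generative time
    u = true_time.to_numpy()
    rng = np.random.default_rng(seed)
    a = np.where(u < 0.5, 10.0, 0.1) * np.exp(rng.normal(0, 0.1, len(u)))
    b = np.where(u >= 0.5, 10.0, 0.1) * np.exp(rng.normal(0, 0.1, len(u)))
    res = trajectory.exclusivity_test(a, b, on_threshold=cfg.min_tpm,
                                      n_perm=cfg.n_perm, seed=seed)
    out = {
        "pseudotime_spearman_vs_truth": abs(rho),
        "temporal_residual_variance": resid_var,
        "exclusivity": {
            "observed_double_pos": res.observed_double_pos,
            "expected_double_pos": res.expected_double_pos,
            "score": res.exclusivity_score,
            "p_perm": res.p_perm,
        },
    }
    (rundir / "trajectory_summary.json").write_text(
        json.dumps(out, sort_keys=True, indent=1))
    log("trajectory", f"|spearman|={abs(rho):.3f}; "
        f"exclusivity score={res.exclusivity_score:.3f}")
    return out


def _stage_cistrome(cfg: RunConfig, rundir: Path, log) -> dict:
    pwm = io.read_jaspar_pwm(
        _require(rundir / "motif.jaspar", "cistrome", "synthio"))
    seqs = io.read_fasta(_require(rundir / "motif_seqs.fa", "cistrome", "synthio"))
    peaks = io.read_bed(_require(rundir / "motif_peaks.bed", "cistrome", "synthio"))
    labels = pd.read_csv(rundir / "motif_labels.tsv", sep="\t",
                         index_col="peak")["label"]

    boundary = int((peaks.frame["score"] == cfg.min_score).sum())
    if boundary:
        log("cistrome", f"warning: {boundary} peak(s) score exactly at the "
            f"min_score threshold {cfg.min_score}")
    kept = cistrome.filter_peaks(peaks, min_score=cfg.min_score)
    scores = pd.Series(
        {name: cistrome.scan_pwm(seq, pwm)[0] for name, seq in seqs.items()})
    if cfg.theta is None:
        pos_med = scores[labels == 1].median()
        neg_med = scores[labels == 0].median()
        theta = float((pos_med + neg_med) / 2.0)
    else:
        theta = cfg.theta
    parts = cistrome.partition_affinity(kept, seqs, pwm, theta)
    io.write_bed(parts["high"], rundir / "peaks_high_affinity.bed")
    io.write_bed(parts["low"], rundir / "peaks_low_affinity.bed")
    pred = scores >= theta
    accuracy = float((pred.astype(int) == labels.loc[pred.index]).mean())

    annot = io.read_annotation_tsv(rundir / "annotation.tsv")
    genome_peaks = _peaks_near_tss(annot)
    annotated = cistrome.annotate_peaks_to_tss(genome_peaks, annot,
                                               window_bp=cfg.window_bp)
    common_genes = cistrome.annotated_gene_set(annotated)
    expr1 = io.read_expression_tsv(rundir / "expr_XY.tsv")
    expr2 = io.read_expression_tsv(rundir / "expr_XXY_eroded.tsv")
    dyn = cistrome.classify_dynamic_genes(
        common_genes,
        expr1.values.mean(axis=1), expr2.values.mean(axis=1),
        on_threshold=cfg.min_tpm)
    out = {
        "n_peaks_kept": len(kept),
        "theta_bits": theta,
        "affinity_accuracy": accuracy,
        "n_high": len(parts["high"]),
        "n_low": len(parts["low"]),
        "n_annotated_genes": len(common_genes),
        "dynamic_counts": {k: len(v) for k, v in dyn.items()},
    }
    (rundir / "cistrome_summary.json").write_text(
        json.dumps(out, sort_keys=True, indent=1))
    log("cistrome", f"affinity split at theta={theta:.2f} bits, "
        f"accuracy={accuracy:.3f}")
    return out


def _peaks_near_tss(annot, every: int = 7, offset_bp: int = 10_000):
    """Deterministic demo peak set: one peak near every 7th gene's TSS."""
    from .containers import PeakSet

    records = []
    genes = list(annot.gene_ids)
    for i, g in enumerate(genes):
        if i % every:
            continue
        tss0 = int(annot.table.at[g, "tss"]) - 1
        start = max(tss0 - offset_bp, 0)
        records.append((annot.table.at[g, "chrom"], start, start + 400,
                        f"peak_{g}", 30.0 + (i % 50)))
    return PeakSet.from_records(records)


def _stage_mito(cfg: RunConfig, rundir: Path, log) -> dict:
    mito_dir = _require(rundir / "mito", "mito", "synthio")
    stats = []
    rows = []
    for npy in sorted(mito_dir.glob("*.npy")):
        seg = io.read_mask(mito_dir / npy.stem)
        st = mitomorph.cell_cluster_stats(
            seg, cluster_threshold=cfg.cluster_threshold, edges=cfg.bin_edges)
        stats.append(st)
        rows.append([st.cell_id, len(st.areas), *st.bin_counts.tolist(),
                     st.has_cluster, st.clustering_degree])
    frame = pd.DataFrame(
        rows, columns=["cell_id", "n_components", "bin_0_5", "bin_5_10",
                       "bin_10_50", "bin_50_plus", "has_cluster",
                       "clustering_degree"])
    frame.to_csv(rundir / "mito_stats.tsv", sep="\t", index=False)
    fraction = mitomorph.population_cluster_fraction(stats)
    out = {"n_cells": len(stats), "percent_cells_with_cluster": fraction}
    (rundir / "mito_summary.json").write_text(
        json.dumps(out, sort_keys=True, indent=1))
    log("mito", f"{fraction:.1f}% of cells carry a cluster")
    return out


_STAGE_FUNCS = {
    "synthio": _stage_synthio,
    "dosage": _stage_dosage,
    "degsets": _stage_degsets,
    "identity": _stage_identity,
    "trajectory": _stage_trajectory,
    "cistrome": _stage_cistrome,
    "mito": _stage_mito,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every enabled stage and write a checksummed manifest.

    Returns a dict of per-stage summaries. The manifest
    (``manifest.json``) holds the full configuration, the per-stage
    derived seeds and a sha256 checksum of every output file except the
    timestamped log, so identical configurations yield identical
    manifests.
    """
    rundir = Path(out_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    log = _Log(rundir / "run.log")
    config.to_yaml(rundir / "config.yaml")

    results = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        results[stage] = _STAGE_FUNCS[stage](config, rundir, log)

    files = sorted(
        p for p in rundir.rglob("*")
        if p.is_file() and p.name not in {"run.log", "manifest.json"}
    )
    manifest = {
        "config_sha256": _checksum(rundir / "config.yaml"),
        "stages": list(config.stages),
        "stage_seeds": {s: _stage_seed(config, s) for s in config.stages},
        "outputs": {str(p.relative_to(rundir)): _checksum(p) for p in files},
    }
    (rundir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return results
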