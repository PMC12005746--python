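"""ChIP-seq peak filtering, TSS annotation, motif scoring and set algebra.

Peaks are BED-convention intervals (0-based, half-open) with an
enrichment score; the default filters follow the conventions of
TF-binding reanalysis: peaks scoring under 25 are dropped, and peaks
are linked to every gene whose TSS lies within 125 kb of the peak
midpoint — the reported median enhancer-promoter distance in the human
genome. Motif matches are scored as PWM log-odds in bits (log2 of
motif over background probability summed over positions, maximised
over offsets and strands), and a log-odds threshold theta splits bound
regions into high- and low-affinity classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BASES, DataError, GeneAnnotation, PeakSet, PWM

_COMPLEMENT = str.maketrans(BASES, "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------------ filtering


def filter_peaks(peaks: PeakSet, min_score: float = 25.0) -> PeakSet:
    """Keep peaks with enrichment score >= min_score (scores under it drop)."""
    kept = peaks.frame[peaks.frame["score"] >= min_score]
    return PeakSet(kept.reset_index(drop=True))


# ----------------------------------------------------------------- annotation


@dataclass
class AnnotatedPeak:
    """One peak with every gene whose TSS lies within the window."""

    name: str
    chrom: str
    midpoint: int
    gene_ids: list
    distances: list  # signed bp, TSS minus peak midpoint


def annotate_peaks_to_tss(peaks: PeakSet, annot: GeneAnnotation,
                          window_bp: int = 125_000) -> list:
    """Link each peak to all genes with a TSS within ``window_bp``.

    The anchor is the peak midpoint, floor((start + end) / 2); the
    window is closed at both ends; distances are signed (TSS minus
    midpoint, both on the 0-based axis). Peaks with no gene in range
    keep an empty gene list.
    """
    # 1-based annotation TSS -> 0-based axis shared with BED coordinates
    by_chrom = {}
    for chrom, sub in annot.table.groupby("chrom", sort=False):
        tss0 = sub["tss"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(tss0, kind="stable")
        by_chrom[chrom] = (tss0[order], sub.index.to_numpy()[order])

    out = []
    f = peaks.frame
    mids = peaks.midpoints
    for i in range(len(f)):
        chrom, name = f.at[i, "chrom"], f.at[i, "name"]
        mid = int(mids[i])
        genes, dists = [], []
        if chrom in by_chrom:
            tss0, gene_ids = by_chrom[chrom]
            lo = np.searchsorted(tss0, mid - window_bp, side="left")
            hi = np.searchsorted(tss0, mid + window_bp, side="right")
            genes = list(gene_ids[lo:hi])
            dists = [int(t - mid) for t in tss0[lo:hi]]
        out.append(AnnotatedPeak(name, chrom, mid, genes, dists))
    return out


def annotated_gene_set(annotated) -> set:
    """Union of all genes linked to any peak."""
    return {g for ap in annotated for g in ap.gene_ids}


# -------------------------------------------------------------- PWM scanning


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -2, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    lut[ord("N")] = lut[ord("n")] = -1
    enc = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (enc == -2).any():
        raise DataError(
            f"non-ACGTN base in sequence at position {int(np.argmax(enc == -2))}"
        )
    return enc.astype(np.int64)


def scan_pwm(sequence: str, pwm: PWM):
    """Best log-odds match of a PWM in a sequence, over both strands.

    Returns ``(score_bits, offset, strand)`` where offset indexes the
    match start on the forward sequence. ``N`` bases contribute 0 bits
    (neutral under the background). Ties (within 1e-9 bits, so that
    summation order cannot flip them) resolve to the smaller offset,
    then to the forward strand.
    """
    L = len(pwm)
    if len(sequence) < L:
        raise DataError(f"sequence length {len(sequence)} < motif length {L}")
    enc = _encode(sequence)
    lo = pwm.log_odds()
    # column 4 absorbs N (index -1) with zero contribution
    lo5 = np.hstack([lo, np.zeros((L, 1))])
    lo5_rc = np.hstack([lo[::-1, [3, 2, 1, 0]], np.zeros((L, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)  # n_off x L
    pos = np.arange(L)
    fwd = lo5[pos[None, :], windows].sum(axis=1)
    rev = lo5_rc[pos[None, :], windows].sum(axis=1)
    best = max(fwd.max(), rev.max())
    fwd_hits = np.flatnonzero(fwd >= best - 1e-9)
    rev_hits = np.flatnonzero(rev >= best - 1e-9)
    best_fwd = fwd_hits[0] if len(fwd_hits) else np.inf
    best_rev = rev_hits[0] if len(rev_hits) else np.inf
    if best_fwd <= best_rev:
        return float(fwd[best_fwd]), int(best_fwd), "+"
    return float(rev[best_rev]), int(best_rev), "-"


def partition_affinity(peaks: PeakSet, sequences: dict, pwm: PWM,
                       theta: float):
    """Split peaks into high- and low-affinity sets by best log-odds score.

    ``sequences`` maps peak name -> DNA string. A peak is high-affinity
    iff its best match scores >= theta bits; the partition is exhaustive
    and disjoint. Returns ``{"high": PeakSet, "low": PeakSet,
    "scores": Series}``.
    """
    f = peaks.frame
    scores = {}
    high_rows, low_rows = [], []
    for i in range(len(f)):
        name = f.at[i, "name"]
        if name not in sequences:
            raise DataError(f"no sequence supplied for peak {name!r}")
        s, _, _ = scan_pwm(sequences[name], pwm)
        scores[name] = s
        (high_rows if s >= theta else low_rows).append(f.iloc[i])
    empty = f.iloc[0:0]
    high = PeakSet(pd.DataFrame(high_rows) if high_rows else empty.copy())
    low = PeakSet(pd.DataFrame(low_rows) if low_rows else empty.copy())
    return {"high": high, "low": low, "scores": pd.Series(scores, dtype=float)}


# ------------------------------------------------------------- intersection


def intersect_peaksets(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1,
                       min_fraction: float = 0.0) -> PeakSet:
    """Peaks of ``a`` overlapping any peak of ``b``.

    A peak qualifies when its best overlap with ``b`` spans at least
    ``min_overlap_bp`` bases and at least ``min_fraction`` of the
    a-peak's own length. Inputs are already (chrom, start)-sorted;
    candidates are found by a bounded sweep over b's sorted starts.
    """
    fa, fb = a.frame, b.frame
    kept = []
    for chrom, sub_a in fa.groupby("chrom", sort=False):
        sub_b = fb[fb["chrom"] == chrom]
        if sub_b.empty:
            continue
        b_start = sub_b["start"].to_numpy()
        b_end = sub_b["end"].to_numpy()
        max_b_len = int((b_end - b_start).max())
        for i in sub_a.index:
            a_start, a_end = fa.at[i, "start"], fa.at[i, "end"]
            lo = np.searchsorted(b_start, a_start - max_b_len, side="left")
            hi = np.searchsorted(b_start, a_end, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(a_end, b_end[lo:hi]) - np.maximum(a_start, b_start[lo:hi])
            best = ov.max() if len(ov) else 0
            if best >= min_overlap_bp and best >= min_fraction * (a_end - a_start):
                kept.append(i)
    return PeakSet(fa.loc[kept].reset_index(drop=True))


# ------------------------------------------------------- dynamic-gene classes


def classify_dynamic_genes(common_genes, expr_stage1: pd.Series,
                           expr_stage2: pd.Series,
                           on_threshold: float = 1.0) -> dict:
    """Partition genes by on/off transition between two stages.

    A gene above ``on_threshold`` in stage 1 but not stage 2 was
    activated then silenced (e.g. SOX2-driven in PSCs, shut in
    PGCLCs); the reverse pattern is silenced then activated; everything
    else is static. The three sets are disjoint and cover the input.
    """
    genes = sorted(set(common_genes))
    missing = [g for g in genes
               if g not in expr_stage1.index or g not in expr_stage2.index]
    if missing:
        raise DataError(f"genes missing from a stage: {missing[:10]}")
    result = {"activated_then_silenced": set(), "silenced_then_activated": set(),
              "static": set()}
    for g in genes:
        on1 = expr_stage1[g] > on_threshold
        on2 = expr_stage2[g] > on_threshold
        if on1 and not on2:
            result["activated_then_silenced"].add(g)
        elif on2 and not on1:
            result["silenced_then_activated"].add(g)
        else:
            result["static"].add(g)
    return result
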