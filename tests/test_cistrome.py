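"""Peak filtering/annotation, PWM scanning, affinity split, interval algebra."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_scan
from pgcx import cistrome, synthio
from pgcx.containers import DataError, GeneAnnotation, PeakSet, PWM


class TestFilterPeaks:
    def test_boundary_keeps_score_at_threshold(self, simple_peaks):
        kept = cistrome.filter_peaks(simple_peaks, 25.0)
        assert len(kept) == 2
        assert set(kept.frame["name"]) == {"p2", "p3"}

    def test_zero_threshold_is_identity(self, simple_peaks):
        assert len(cistrome.filter_peaks(simple_peaks, 0.0)) == 3

    def test_idempotent(self, simple_peaks):
        once = cistrome.filter_peaks(simple_peaks, 25.0)
        twice = cistrome.filter_peaks(once, 25.0)
        assert once.frame.equals(twice.frame)

    def test_random_scores_match_tally(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 50, 1000)
        records = [("chr1", 10 * i, 10 * i + 5, f"p{i}", s)
                   for i, s in enumerate(scores)]
        peaks = PeakSet.from_records(records)
        kept = cistrome.filter_peaks(peaks, 25.0)
        assert len(kept) == int((scores >= 25.0).sum())


class TestAnnotate:
    def test_exact_window_boundary_included(self):
        # TSS (1-based 125_101 -> 0-based 125_100) is exactly 125 kb
        # from the peak midpoint at 100
        annot = GeneAnnotation.from_records([("g", "chr1", 125_101, 126_000, "+")])
        peaks = PeakSet.from_records([("chr1", 50, 150, "p", 30.0)])
        ann = cistrome.annotate_peaks_to_tss(peaks, annot, window_bp=125_000)
        assert ann[0].gene_ids == ["g"]
        assert ann[0].distances == [125_000]

    def test_no_gene_in_window_gives_empty_list(self):
        annot = GeneAnnotation.from_records([("g", "chr1", 10**7, 10**7 + 99, "+")])
        peaks = PeakSet.from_records([("chr1", 0, 100, "p", 30.0)])
        ann = cistrome.annotate_peaks_to_tss(peaks, annot)
        assert ann[0].gene_ids == []

    def test_random_layout_matches_quadratic_scan(self):
        rng = np.random.default_rng(1)
        genes = []
        for i in range(100):
            start = int(rng.integers(1, 2_000_000))
            chrom = rng.choice(["chr1", "chr2"])
            genes.append((f"g{i}", chrom, start, start + 100,
                          rng.choice(["+", "-"])))
        annot = GeneAnnotation.from_records(genes)
        records = []
        for i in range(200):
            s = int(rng.integers(0, 2_000_000))
            records.append((rng.choice(["chr1", "chr2"]), s, s + 200,
                            f"p{i}", 30.0))
        peaks = PeakSet.from_records(records)
        window = 100_000
        ann = {a.name: a for a in
               cistrome.annotate_peaks_to_tss(peaks, annot, window)}
        f = peaks.frame
        for i in range(len(f)):
            mid = (f.at[i, "start"] + f.at[i, "end"]) // 2
            expected = {}
            for g, chrom, start, end, strand in genes:
                tss0 = (start if strand == "+" else end) - 1
                if chrom == f.at[i, "chrom"] and abs(tss0 - mid) <= window:
                    expected[g] = tss0 - mid
            got = ann[f.at[i, "name"]]
            assert dict(zip(got.gene_ids, got.distances)) == expected


class TestScanPWM:
    def test_consensus_scores_closed_form(self, sox_like_pwm):
        seq = "AAAA" + sox_like_pwm.consensus() + "CCCC"
        score, offset, strand = cistrome.scan_pwm(seq, sox_like_pwm)
        expected = float(np.sum(np.log2(
            sox_like_pwm.matrix.max(axis=1) / 0.25)))
        assert score == pytest.approx(expected, abs=1e-9)
        assert (offset, strand) == (4, "+")

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(np.full((5, 4), 0.25), name="flat")
        score, _, _ = cistrome.scan_pwm("ACGTACGTAC", pwm)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_n_bases_contribute_nothing(self, sox_like_pwm):
        full, off, _ = cistrome.scan_pwm(sox_like_pwm.consensus(), sox_like_pwm)
        lo = sox_like_pwm.log_odds()
        masked, _, _ = cistrome.scan_pwm("N" + sox_like_pwm.consensus()[1:],
                                         sox_like_pwm)
        assert masked == pytest.approx(full - lo[0].max(), abs=1e-9)

    def test_matches_brute_force_on_random_sequences(self, sox_like_pwm):
        rng = np.random.default_rng(2)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), 60))
            score, offset, strand = cistrome.scan_pwm(seq, sox_like_pwm)
            b_score, b_offset, b_strand = brute_force_scan(seq, sox_like_pwm)
            assert score == pytest.approx(b_score, abs=1e-9)
            assert (offset, strand) == (b_offset, b_strand)

    def test_strand_symmetry(self, sox_like_pwm):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 50))
            s1, _, _ = cistrome.scan_pwm(seq, sox_like_pwm)
            s2, _, _ = cistrome.scan_pwm(cistrome.reverse_complement(seq),
                                         sox_like_pwm)
            assert s1 == pytest.approx(s2, abs=1e-9)

    def test_short_sequence_rejected(self, sox_like_pwm):
        with pytest.raises(DataError):
            cistrome.scan_pwm("ACGT", sox_like_pwm)


class TestAffinityPartition:
    def test_extreme_thresholds(self, sox_like_pwm):
        seqs, peaks, _ = synthio.simulate_motif_sequences(
            sox_like_pwm, 10, 10, 40, seed=0)
        all_high = cistrome.partition_affinity(peaks, seqs, sox_like_pwm, -1e9)
        assert len(all_high["high"]) == 20 and len(all_high["low"]) == 0
        above_max = sox_like_pwm.max_score() + 1.0
        all_low = cistrome.partition_affinity(peaks, seqs, sox_like_pwm,
                                              above_max)
        assert len(all_low["high"]) == 0 and len(all_low["low"]) == 20

    def test_partition_is_exhaustive_and_disjoint(self, sox_like_pwm):
        seqs, peaks, _ = synthio.simulate_motif_sequences(
            sox_like_pwm, 15, 15, 40, seed=4)
        parts = cistrome.partition_affinity(peaks, seqs, sox_like_pwm, 5.0)
        names_high = set(parts["high"].frame["name"])
        names_low = set(parts["low"].frame["name"])
        assert names_high | names_low == set(peaks.frame["name"])
        assert not names_high & names_low

    def test_recovers_embedded_labels(self, sox_like_pwm):
        seqs, peaks, labels = synthio.simulate_motif_sequences(
            sox_like_pwm, 100, 100, 60, seed=7)
        scores = pd.Series(
            {n: cistrome.scan_pwm(s, sox_like_pwm)[0] for n, s in seqs.items()})
        theta = (scores[labels == 1].median() + scores[labels == 0].median()) / 2
        parts = cistrome.partition_affinity(peaks, seqs, sox_like_pwm, theta)
        predicted = pd.Series(0, index=labels.index)
        predicted[parts["high"].frame["name"]] = 1
        assert (predicted == labels).mean() >= 0.95

    def test_missing_sequence_names_the_peak(self, sox_like_pwm):
        seqs, peaks, _ = synthio.simulate_motif_sequences(
            sox_like_pwm, 2, 2, 40, seed=1)
        del seqs["peak1"]
        with pytest.raises(DataError, match="peak1"):
            cistrome.partition_affinity(peaks, seqs, sox_like_pwm, 0.0)


class TestIntersect:
    def test_one_bp_overlap_at_boundary(self):
        a = PeakSet.from_records([("chr1", 100, 200, "a", 30.0)])
        b = PeakSet.from_records([("chr1", 199, 300, "b", 30.0)])
        assert len(cistrome.intersect_peaksets(a, b, min_overlap_bp=1)) == 1
        b2 = PeakSet.from_records([("chr1", 200, 300, "b", 30.0)])
        assert len(cistrome.intersect_peaksets(a, b2, min_overlap_bp=1)) == 0

    def test_disjoint_sets_empty(self):
        a = PeakSet.from_records([("chr1", 0, 10, "a", 30.0)])
        b = PeakSet.from_records([("chr2", 0, 10, "b", 30.0)])
        assert len(cistrome.intersect_peaksets(a, b)) == 0

    def test_random_intervals_match_quadratic_oracle(self):
        rng = np.random.default_rng(8)

        def random_peaks(prefix, n):
            recs = []
            for i in range(n):
                s = int(rng.integers(0, 100_000))
                recs.append((rng.choice(["chr1", "chr2"]), s,
                             s + int(rng.integers(50, 2000)),
                             f"{prefix}{i}", 30.0))
            return PeakSet.from_records(recs)

        a, b = random_peaks("a", 500), random_peaks("b", 500)
        got = set(cistrome.intersect_peaksets(a, b, min_overlap_bp=100)
                  .frame["name"])
        expected = set()
        fa, fb = a.frame, b.frame
        for i in range(len(fa)):
            for j in range(len(fb)):
                if fa.at[i, "chrom"] != fb.at[j, "chrom"]:
                    continue
                ov = (min(fa.at[i, "end"], fb.at[j, "end"])
                      - max(fa.at[i, "start"], fb.at[j, "start"]))
                if ov >= 100:
                    expected.add(fa.at[i, "name"])
                    break
        assert got == expected

    def test_hit_structure_symmetric(self):
        rng = np.random.default_rng(9)
        recs_a = [("chr1", int(s), int(s) + 300, f"a{i}", 30.0)
                  for i, s in enumerate(rng.integers(0, 20_000, 50))]
        recs_b = [("chr1", int(s), int(s) + 300, f"b{i}", 30.0)
                  for i, s in enumerate(rng.integers(0, 20_000, 50))]
        a, b = PeakSet.from_records(recs_a), PeakSet.from_records(recs_b)
        assert (len(cistrome.intersect_peaksets(a, b)) > 0) == (
            len(cistrome.intersect_peaksets(b, a)) > 0)


class TestDynamicGenes:
    def test_on_off_transitions(self):
        s1 = pd.Series({"g1": 10.0, "g2": 0.5, "g3": 0.5, "g4": 3.0})
        s2 = pd.Series({"g1": 0.1, "g2": 0.8, "g3": 5.0, "g4": 3.0})
        res = cistrome.classify_dynamic_genes(["g1", "g2", "g3", "g4"], s1, s2)
        assert res["activated_then_silenced"] == {"g1"}
        assert res["silenced_then_activated"] == {"g3"}
        assert res["static"] == {"g2", "g4"}

    def test_random_genes_match_rule_application(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(100)]
        s1 = pd.Series(rng.uniform(0, 5, 100), index=genes)
        s2 = pd.Series(rng.uniform(0, 5, 100), index=genes)
        res = cistrome.classify_dynamic_genes(genes, s1, s2, on_threshold=1.0)
        for g in genes:
            on1, on2 = s1[g] > 1.0, s2[g] > 1.0
            if on1 and not on2:
                assert g in res["activated_then_silenced"]
            elif on2 and not on1:
                assert g in res["silenced_then_activated"]
            else:
                assert g in res["static"]
        total = sum(len(v) for v in res.values())
        assert total == 100

    def test_missing_gene_rejected(self):
        s = pd.Series({"g1": 1.0})
        with pytest.raises(DataError, match="g2"):
            cistrome.classify_dynamic_genes(["g1", "g2"], s, s)
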