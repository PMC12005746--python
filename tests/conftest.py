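import numpy as np
import pandas as pd
import pytest

from pgcx.containers import ExpressionMatrix, GeneAnnotation, PeakSet, PWM


@pytest.fixture
def toy_annot():
    """4 autosomal genes on chr1, 5 X genes, one gene on chr2."""
    records = []
    for i in range(4):
        start = 1000 + i * 10_000
        records.append((f"a{i}", "chr1", start, start + 500, "+"))
    for i in range(5):
        start = 1000 + i * 10_000
        records.append((f"x{i}", "chrX", start, start + 500, "+"))
    records.append(("b0", "chr2", 5000, 5500, "-"))
    return GeneAnnotation.from_records(records)


@pytest.fixture
def toy_expr(toy_annot):
    """Single-sample expression over the toy annotation: the hand example.

    X genes {2, 3, 4, 50, 60}; chr1 autosomes {2, 4, 6, 8}; the chr2
    gene sits below the 1 TPM filter.
    """
    vals = {"a0": 2, "a1": 4, "a2": 6, "a3": 8,
            "x0": 2, "x1": 3, "x2": 4, "x3": 50, "x4": 60, "b0": 0.5}
    frame = pd.DataFrame({"s1": pd.Series(vals, dtype=float)})
    return ExpressionMatrix(frame.loc[list(toy_annot.gene_ids)],
                            pd.DataFrame(index=["s1"]))


@pytest.fixture
def sox_like_pwm():
    """A strongly informative 9-position motif (0.97 dominant base)."""
    m = np.full((9, 4), 0.01)
    for pos, base in enumerate([0, 1, 0, 0, 3, 2, 3, 3, 1]):  # ACAATGTTC
        m[pos, base] = 0.97
    return PWM(m, name="SOX_like")


@pytest.fixture
def simple_peaks():
    return PeakSet.from_records([
        ("chr1", 100, 200, "p1", 24.9),
        ("chr1", 300, 400, "p2", 25.0),
        ("chr2", 50, 150, "p3", 25.1),
    ])


def brute_force_scan(seq, pwm):
    """Independent per-offset, per-strand PWM scan (python loops)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    lo = pwm.log_odds()
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score_at(s, off):
        total = 0.0
        for j in range(len(pwm)):
            b = s[off + j]
            total += 0.0 if b == "N" else lo[j, base_idx[b]]
        return total

    rc = "".join(comp[b] for b in reversed(seq))
    n, L = len(seq), len(pwm)
    best = (-np.inf, None, None)
    for off in range(n - L + 1):
        for strand, s, o in (("+", seq, off), ("-", rc, n - L - off)):
            sc = score_at(s, o)
            if sc > best[0] + 1e-9:  # same tie tolerance as the scanner
                best = (sc, off, strand)
    return best
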