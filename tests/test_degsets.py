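"""DEG stand-in, multi-contrast intersection, chromosome partition, escapees."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pgcx import degsets
from pgcx.containers import DataError, EscapeeCatalog, ExpressionMatrix, GeneAnnotation


def _matrix(arr, genes, prefix):
    arr = np.asarray(arr, dtype=float)
    cols = [f"{prefix}{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cols),
                            pd.DataFrame(index=cols))


def _table(genes_dirs, contrast="c"):
    genes = list(genes_dirs)
    return pd.DataFrame(
        {
            "log2fc": [1.0 if d == "up" else -1.0 for d in genes_dirs.values()],
            "fdr": 0.01,
            "direction": list(genes_dirs.values()),
            "contrast": contrast,
        },
        index=genes,
    )


class TestDEGStandin:
    def test_identical_groups_yield_empty_table(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, (30, 3))
        a = _matrix(vals, [f"g{i}" for i in range(30)], "a")
        b = _matrix(vals, [f"g{i}" for i in range(30)], "b")
        assert len(degsets.call_deg_standin(a, b)) == 0

    def test_single_separated_gene_detected_up(self):
        genes = [f"g{i}" for i in range(10)]
        base = np.full((10, 3), 10.0)
        case = base.copy()
        case[4] = 80.0  # 8x higher, zero variance everywhere
        table = degsets.call_deg_standin(_matrix(case, genes, "a"),
                                         _matrix(base, genes, "b"))
        assert list(table.index) == ["g4"]
        assert table.at["g4", "direction"] == "up"

    def test_bh_adjustment_matches_hand_computation(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        case = rng.uniform(1, 50, (20, 4))
        ctrl = rng.uniform(1, 50, (20, 4))
        full = degsets.call_deg_standin(_matrix(case, genes, "a"),
                                        _matrix(ctrl, genes, "b"),
                                        full_table=True)
        # independent oracle: recompute Welch p, then p(i)*n/i with
        # monotonicity enforced from the largest p downwards, capped at 1
        la, lb = np.log2(case + 1), np.log2(ctrl + 1)
        _, p = scipy.stats.ttest_ind(la, lb, axis=1, equal_var=False)
        order = np.argsort(p)
        n = len(p)
        adj = np.empty(n)
        running = 1.0
        for rank_from_top in range(n - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, p[i] * n / (rank_from_top + 1))
            adj[i] = running
        assert np.allclose(full["fdr"].to_numpy(), adj)
        # monotone non-decreasing in raw p-rank, capped at 1
        assert np.all(np.diff(full["fdr"].to_numpy()[order]) >= -1e-12)
        assert full["fdr"].max() <= 1.0

    def test_small_groups_rejected(self):
        a = _matrix(np.ones((5, 1)), [f"g{i}" for i in range(5)], "a")
        b = _matrix(np.ones((5, 3)), [f"g{i}" for i in range(5)], "b")
        with pytest.raises(DataError):
            degsets.call_deg_standin(a, b)


class TestIntersect:
    def test_four_identical_tables_keep_the_gene(self):
        tables = [_table({"gX": "up"}, f"c{i}") for i in range(4)]
        shared = degsets.intersect_contrasts(tables)
        assert list(shared.index) == ["gX"]
        assert shared.at["gX", "direction"] == "up"

    def test_direction_conflict_excluded_or_flagged(self):
        tables = [_table({"g": "up"}, f"c{i}") for i in range(3)]
        tables.append(_table({"g": "down"}, "c3"))
        assert len(degsets.intersect_contrasts(tables, True)) == 0
        flagged = degsets.intersect_contrasts(tables, False)
        assert flagged.at["g", "direction"] == "mixed"
        assert not flagged.at["g", "direction_consistent"]

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(100)]
        tables = []
        for c in range(3):
            chosen = rng.choice(genes, size=60, replace=False)
            dirs = rng.choice(["up", "down"], size=60)
            tables.append(_table(dict(zip(chosen, dirs)), f"c{c}"))
        shared = degsets.intersect_contrasts(tables, True)
        expected = set()
        for g in genes:
            if all(g in t.index for t in tables):
                dirs = {t.at[g, "direction"] for t in tables}
                if len(dirs) == 1:
                    expected.add(g)
        assert set(shared.index) == expected

    def test_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(40)]
        tables = [
            _table(dict(zip(rng.choice(genes, 25, replace=False),
                            rng.choice(["up", "down"], 25))), f"c{i}")
            for i in range(3)
        ]
        base = degsets.intersect_contrasts(tables)
        rev = degsets.intersect_contrasts(tables[::-1])
        dup = degsets.intersect_contrasts(tables + [tables[0]])
        assert base.equals(rev) and base.equals(dup)


class TestPartition:
    def _annot(self, n_x, n_auto):
        records = [(f"x{i}", "chrX", 1 + i, 100 + i, "+") for i in range(n_x)]
        records += [(f"a{i}", "chr1", 1 + i, 100 + i, "+") for i in range(n_auto)]
        return GeneAnnotation.from_records(records)

    def test_28_up_5_down_gives_ratio_5_6(self):
        annot = self._annot(33, 1)
        dirs = ["up"] * 28 + ["down"] * 5
        genes = pd.DataFrame({"direction": dirs},
                             index=[f"x{i}" for i in range(33)])
        per_chrom, totals = degsets.partition_by_chromosome(genes, annot)
        row = per_chrom.set_index("chrom").loc["chrX"]
        assert (row["n_up"], row["n_down"]) == (28, 5)
        assert row["up_down_ratio"] == pytest.approx(5.6)
        assert totals["x"] == {"n_up": 28, "n_down": 5}

    def test_zero_down_reported_as_infinity(self):
        annot = self._annot(2, 2)
        genes = pd.DataFrame({"direction": ["up", "up"]}, index=["x0", "x1"])
        per_chrom, _ = degsets.partition_by_chromosome(genes, annot)
        assert np.isinf(per_chrom.set_index("chrom").at["chrX", "up_down_ratio"])

    def test_untouched_chromosome_omitted(self):
        annot = self._annot(2, 2)
        genes = pd.DataFrame({"direction": ["up"]}, index=["a0"])
        per_chrom, _ = degsets.partition_by_chromosome(genes, annot)
        assert "chrX" not in set(per_chrom["chrom"])

    def test_random_assignment_matches_tally(self):
        rng = np.random.default_rng(11)
        records = []
        chroms = [f"chr{c}" for c in range(1, 6)]
        for i in range(50):
            records.append((f"g{i}", rng.choice(chroms), 1 + i, 100 + i, "+"))
        annot = GeneAnnotation.from_records(records)
        dirs = rng.choice(["up", "down"], 50)
        genes = pd.DataFrame({"direction": dirs},
                             index=[f"g{i}" for i in range(50)])
        per_chrom, _ = degsets.partition_by_chromosome(genes, annot)
        for _, row in per_chrom.iterrows():
            on_c = [i for i in range(50)
                    if annot.chromosome_of(f"g{i}") == row["chrom"]]
            assert row["n_up"] == sum(dirs[i] == "up" for i in on_c)
            assert row["n_down"] == sum(dirs[i] == "down" for i in on_c)

    def test_unannotated_gene_raises_with_offenders(self):
        annot = self._annot(1, 1)
        genes = pd.DataFrame({"direction": ["up"]}, index=["ghost"])
        with pytest.raises(DataError, match="ghost"):
            degsets.partition_by_chromosome(genes, annot)


class TestEscapees:
    def test_printed_composition_8_3_17(self):
        x_up = [f"x{i}" for i in range(28)]
        catalog = EscapeeCatalog(frozenset(x_up[:8]), frozenset(x_up[8:11]))
        classes = degsets.classify_escapees(x_up, catalog)
        assert (len(classes["constitutive"]), len(classes["variable"]),
                len(classes["novel"])) == (8, 3, 17)

    def test_empty_catalog_all_novel(self):
        catalog = EscapeeCatalog(frozenset(), frozenset())
        classes = degsets.classify_escapees(["x0", "x1"], catalog)
        assert classes["novel"] == {"x0", "x1"}
        assert not classes["constitutive"] and not classes["variable"]

    def test_random_membership_partition_is_complete_and_disjoint(self):
        rng = np.random.default_rng(13)
        genes = [f"x{i}" for i in range(30)]
        cons = set(rng.choice(genes, 6, replace=False))
        var = set(rng.choice(sorted(set(genes) - cons), 5, replace=False))
        catalog = EscapeeCatalog(frozenset(cons), frozenset(var))
        classes = degsets.classify_escapees(genes, catalog)
        assert classes["constitutive"] == cons & set(genes)
        assert classes["variable"] == var & set(genes)
        union = classes["constitutive"] | classes["variable"] | classes["novel"]
        assert union == set(genes)
        assert (len(classes["constitutive"]) + len(classes["variable"])
                + len(classes["novel"])) == len(genes)

    def test_non_x_gene_rejected_when_annotated(self):
        annot = GeneAnnotation.from_records(
            [("x0", "chrX", 1, 10, "+"), ("a0", "chr1", 1, 10, "+")])
        catalog = EscapeeCatalog(frozenset(), frozenset())
        with pytest.raises(DataError, match="a0"):
            degsets.classify_escapees(["x0", "a0"], catalog, annot)
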