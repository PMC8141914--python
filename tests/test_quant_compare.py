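"""Normalization, ranking, correlation and batch comparison."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from circtk.quant_compare import (
    ExpressionTable,
    batch_expression,
    compare_batch_counts,
    cross_expression_correlation,
    gene_expression,
    isoform_balance,
    normalized_counts,
    overlap_pct,
    per_million,
    tmm_factors,
    top_n,
)


def tmm_oracle(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> pd.Series:
    """Literal, loop-level transcription of the published TMM formula,
    independent of the vectorized implementation."""
    cols = list(counts.columns)
    lib = {c: counts[c].sum() for c in cols}
    f75 = {c: np.quantile(counts[c] / lib[c], 0.75) for c in cols}
    mean75 = sum(f75.values()) / len(cols)
    ref = min(cols, key=lambda c: abs(f75[c] - mean75))
    factors = {}
    for col in cols:
        ms, aas, vs = [], [], []
        for y, yr in zip(counts[col], counts[ref]):
            if y > 0 and yr > 0:
                p, pr = y / lib[col], yr / lib[ref]
                ms.append(math.log2(p / pr))
                aas.append(0.5 * math.log2(p * pr))
                vs.append((lib[col] - y) / (lib[col] * y)
                          + (lib[ref] - yr) / (lib[ref] * yr))
        if not ms or max(abs(m) for m in ms) < 1e-6:
            factors[col] = 1.0
            continue
        n = len(ms)
        lo_m, lo_a = math.floor(n * trim_m) + 1, math.floor(n * trim_a) + 1
        hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a

        def ranks(values):
            order = sorted(range(n), key=lambda i: values[i])
            r = [0.0] * n
            i = 0
            while i < n:
                j = i
                while j + 1 < n and values[order[j + 1]] == values[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    r[order[k]] = avg
                i = j + 1
            return r

        rm, ra = ranks(ms), ranks(aas)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
        factors[col] = 2.0 ** (num / den) if den else 1.0
    log_mean = sum(math.log(f) for f in factors.values()) / len(cols)
    return pd.Series({c: f / math.exp(log_mean) for c, f in factors.items()})


def small_table(counts: pd.DataFrame, batches=None) -> ExpressionTable:
    lib = counts.sum(axis=0).astype(float) * 100
    batches = batches or {c: "b1" for c in counts.columns}
    bm = pd.DataFrame({"species": "s", "tissue": "t",
                       "batch_id": pd.Series(batches)})
    bm.index.name = "dataset_id"
    return ExpressionTable(counts, lib, bm)


class TestPerMillion:
    def test_basic(self):
        assert per_million(500, 50_000_000) == pytest.approx(10.0)
        assert per_million(0, 1_000) == 0.0

    def test_homogeneity(self):
        assert per_million(100, 1e6) == per_million(200, 2e6)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            per_million(1, 0)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        col = pd.Series([10, 0, 5, 100, 7])
        f = tmm_factors(pd.DataFrame({"a": col, "b": col}))
        assert f.tolist() == pytest.approx([1.0, 1.0])

    def test_pure_depth_difference_normalizes_away(self):
        rng = np.random.default_rng(2)
        a = pd.Series(rng.negative_binomial(5, 0.2, size=300))
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        table = small_table(counts)
        norm = normalized_counts(table)
        pd.testing.assert_series_equal(norm["a"], norm["b"], check_names=False)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.1, size=(200, 4)) *
            rng.integers(1, 4, size=(1, 4)),
            columns=list("ABCD"))
        got = tmm_factors(counts)
        want = tmm_oracle(counts)
        assert np.allclose(got.values, want.values, atol=1e-6)

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check one matrix against Bioconductor edgeR::calcNormFactors."""
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.1, size=(150, 3)) *
            rng.integers(1, 4, size=(1, 3)), columns=list("ABC"))
        mat_path = tmp_path / "m.tsv"
        counts.to_csv(mat_path, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            m <- as.matrix(read.delim("{mat_path}"))
            cat(sprintf("%.10f", calcNormFactors(m, method="TMM")), sep="\\n")
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        want = [float(x) for x in res.stdout.split()]
        assert np.allclose(tmm_factors(counts).values, want, atol=1e-8)

    def test_scale_invariance_before_recentring(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.negative_binomial(8, 0.2, size=(300, 3)),
                              columns=list("ABC"))
        scaled = counts.copy()
        scaled["C"] = counts["C"] * 4
        f0 = tmm_factors(counts, ref_column="A")
        f1 = tmm_factors(scaled, ref_column="A")
        # recentred factors shift together; the C/A factor ratio is preserved
        assert f1["C"] / f1["A"] == pytest.approx(f0["C"] / f0["A"], rel=1e-2)

    def test_all_zero_column_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="'b'"):
            tmm_factors(counts)


class TestBatchExpression:
    def test_single_dataset_batch_is_normalized_column(self):
        counts = pd.DataFrame({"d1": [10, 0, 4], "d2": [5, 3, 1]},
                              index=["c1", "c2", "c3"])
        table = small_table(counts, {"d1": "b1", "d2": "b2"})
        factors = pd.Series(1.0, index=["d1", "d2"])
        expr = batch_expression(table, "b1", factors)
        lib = table.library_sizes["d1"]
        assert expr.tolist() == pytest.approx([10 * 1e6 / lib, 0.0, 4 * 1e6 / lib])

    def test_absent_circ_is_zero(self):
        counts = pd.DataFrame({"d1": [0], "d2": [0]}, index=["c1"])
        counts.loc["c2"] = [5, 5]
        table = small_table(counts)
        assert batch_expression(table, "b1", pd.Series(1.0, index=["d1", "d2"]))["c1"] == 0

    def test_dataset_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 3)),
                              columns=["d1", "d2", "d3"],
                              index=[f"c{i}" for i in range(50)])
        table1 = small_table(counts)
        table2 = small_table(counts[["d3", "d1", "d2"]])
        e1 = batch_expression(table1, "b1")
        e2 = batch_expression(table2, "b1")
        pd.testing.assert_series_equal(e1, e2)

    def test_unknown_batch_errors(self):
        table = small_table(pd.DataFrame({"d1": [1], "d2": [2]}))
        with pytest.raises(KeyError):
            batch_expression(table, "nope")


class TestGeneExpression:
    def test_per_gene_sum(self):
        expr = pd.Series({"c1": 7.0, "c2": 3.0, "c3": 11.0})
        genes, residual = gene_expression({"c1": "G1", "c2": "G1"}, expr)
        assert genes["G1"] == pytest.approx(10.0)
        assert residual == pytest.approx(11.0)

    def test_all_unannotated(self):
        expr = pd.Series({"c1": 5.0})
        genes, residual = gene_expression({}, expr)
        assert len(genes) == 0 and residual == 5.0

    def test_conservation(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.poisson(10, size=(40, 3)),
                            index=[f"c{i}" for i in range(40)],
                            columns=list("xyz")).astype(float)
        parent = {f"c{i}": f"G{i % 7}" for i in range(0, 40, 2)}
        genes, residual = gene_expression(parent, expr)
        pd.testing.assert_series_equal(genes.sum(axis=0) + residual,
                                       expr.sum(axis=0))


class TestRanking:
    def test_top_100_of_150_distinct(self):
        expr = pd.Series({f"c{i:03d}": float(i) for i in range(1, 151)})
        top = top_n(expr, 100)
        assert len(top) == 100
        assert top[0] == "c150"
        assert set(top) == {f"c{i:03d}" for i in range(51, 151)}

    def test_n_all_is_full_ranking(self):
        expr = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0})
        assert top_n(expr, 3) == ["a", "c", "b"]

    def test_tie_break_lexicographic(self):
        expr = pd.Series({"zz": 5.0, "aa": 5.0, "mm": 9.0})
        assert top_n(expr, 2) == ["mm", "aa"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        expr = pd.Series(rng.uniform(1, 100, size=60),
                         index=[f"c{i}" for i in range(60)])
        assert top_n(expr, 20) == top_n(np.log10(expr) ** 3, 20)

    def test_overlap_examples(self):
        a = [f"c{i}" for i in range(100)]
        b = a[:72] + [f"x{i}" for i in range(28)]
        assert overlap_pct(a, a) == 100.0
        assert overlap_pct(a, ["y" + s for s in a]) == 0.0
        assert overlap_pct(a, b) == pytest.approx(72.0)
        assert overlap_pct(a, b) == overlap_pct(b, a)

    def test_overlap_length_mismatch(self):
        with pytest.raises(ValueError):
            overlap_pct(["a"], ["a", "b"])


class TestIsoformBalance:
    def test_dominance_and_max_min(self):
        expr = pd.Series({"c1": 100.0, "c2": 10.0, "c3": 5.0})
        parent = {c: "G" for c in expr.index}
        assert isoform_balance("G", expr, parent) == (3, 10.0, 20.0)

    def test_single_isoform_infinite_dominance(self):
        n, dom, mm = isoform_balance("G", pd.Series({"c1": 5.0}), {"c1": "G"})
        assert (n, dom, mm) == (1, math.inf, math.inf)


class TestCrossCorrelation:
    def test_proportional_is_r1(self):
        a = pd.Series({f"g{i}": 10.0 * (i + 2) ** 2 for i in range(20)})
        b = 3.0 * a.rename(lambda s: s + "_b")
        pairs = [(f"g{i}", f"g{i}_b") for i in range(20)]
        n, r = cross_expression_correlation(a, b, pairs)
        assert r == pytest.approx(1.0)

    def test_expression_filter_boundary(self):
        a = pd.Series({"g1": 10.0, "g2": 1000.0, "g3": 500.0, "g4": 300.0})
        b = a.copy()
        pairs = [(g, g) for g in a.index]
        n, r = cross_expression_correlation(a, b, pairs, min_log10=1.2)
        assert n == 3  # g1 has log10 = 1.0, excluded on both sides

    def test_known_rho_recovered(self):
        """Bivariate log-normal with rho = 0.7 at n = 500: the sample r on
        log values stays within the Fisher-z sampling band (+/- 0.08)."""
        rng = np.random.default_rng(9)
        z = rng.multivariate_normal([3, 3], [[1, 0.7], [0.7, 1]], size=500)
        a = pd.Series(10.0 ** z[:, 0], index=[f"g{i}" for i in range(500)])
        b = pd.Series(10.0 ** z[:, 1], index=[f"g{i}" for i in range(500)])
        n, r = cross_expression_correlation(a, b, [(g, g) for g in a.index],
                                            min_log10=-10)
        assert abs(r - 0.7) < 0.08

    def test_too_few_pairs_errors(self):
        a = pd.Series({"g1": 100.0, "g2": 100.0})
        with pytest.raises(ValueError, match="undefined"):
            cross_expression_correlation(a, a, [("g1", "g1"), ("g2", "g2")])


class TestBatchComparison:
    def test_fully_separated_3v3(self):
        stat, p = compare_batch_counts([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = compare_batch_counts([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_6v6(self):
        _, p = compare_batch_counts(list(range(6)), list(range(10, 16)))
        assert p == pytest.approx(2 / 924)

    def test_small_groups_error(self):
        with pytest.raises(ValueError):
            compare_batch_counts([1], [2, 3])
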