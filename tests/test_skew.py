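import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelichrom import skew, synthetic
from allelichrom.skew import (bh_fdr, binomial_skew_test, call_skewed,
                              classify_concordance, hypergeometric_overlap,
                              log2_skew, skewed_set_summary)


def exact_binomial_two_sided(m, c):
    """Independent oracle: exact doubled-tail p via rational arithmetic."""
    n = m + c
    k = min(m, c)
    tail = sum(Fraction(math.comb(n, i), 2 ** n) for i in range(k + 1))
    return float(min(Fraction(1), 2 * tail))


def brute_force_bh(p):
    """Independent oracle: textbook BH step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def exact_hypergeom_upper_tail(k, n_universe, n_reference, n_drawn):
    """Independent oracle: P(overlap >= k) by rational tail summation."""
    total = math.comb(n_universe, n_drawn)
    acc = Fraction(0)
    for i in range(k, min(n_reference, n_drawn) + 1):
        if n_drawn - i > n_universe - n_reference:
            continue
        acc += Fraction(math.comb(n_reference, i)
                        * math.comb(n_universe - n_reference, n_drawn - i),
                        total)
    return float(acc)


class TestBinomialSkewTest:
    def test_symmetric_center(self):
        assert binomial_skew_test(8, 8) == 1.0

    def test_extreme_tail_closed_form(self):
        assert binomial_skew_test(15, 0) == pytest.approx(2 * 0.5 ** 15)
        assert binomial_skew_test(15, 0) == pytest.approx(6.1035e-5, rel=1e-4)

    def test_12_vs_3_brute_force(self):
        # sum of Binomial(15, 1/2) pmf over k >= 12, doubled = 0.03515625
        assert binomial_skew_test(12, 3) == pytest.approx(0.03515625)

    def test_symmetry_in_arguments(self):
        assert binomial_skew_test(12, 3) == binomial_skew_test(3, 12)

    def test_exhaustive_oracle_up_to_30(self):
        for n in range(1, 31):
            for m in range(n + 1):
                expected = exact_binomial_two_sided(m, n - m)
                got = binomial_skew_test(m, n - m)
                assert got == pytest.approx(expected, rel=1e-12), (m, n - m)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            binomial_skew_test(0, 0)


class TestBhFdr:
    def test_four_values(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_brute_force_oracle_1000_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p),
                                       rtol=1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestLog2Skew:
    def test_exact_two_fold(self):
        assert log2_skew(20, 10, 0) == pytest.approx(1.0)

    def test_symmetry_zero(self):
        for k in (1, 7, 100):
            assert log2_skew(k, k, 0.5) == 0.0

    def test_zero_count_pseudocount(self):
        assert log2_skew(15, 0, 0.5) == pytest.approx(math.log2(15.5 / 0.5))
        assert log2_skew(15, 0, 0.5) == pytest.approx(4.954196, rel=1e-6)

    def test_pseudocount_not_applied_to_nonzero(self):
        assert log2_skew(20, 10, 0.5) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_skew(-1, 5, 0.5)

    @given(st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=200)
    def test_antisymmetry(self, m, c):
        if m + c == 0:
            return
        assert log2_skew(m, c, 0.5) == pytest.approx(-log2_skew(c, m, 0.5))


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "n_mus", "n_cas"])


class TestCallSkewed:
    def test_ten_gene_fixture_filter_semantics(self):
        """Every filter class exercised: untestable, fold-fail, FDR-fail,
        skewed, and zero-against-positive (infinite fold)."""
        rows = [("untestable", 10, 2),      # 12 < 15 reads
                ("balanced", 50, 48),       # fold 1.04
                ("foldfail", 20, 15),       # fold 1.33 < 2
                ("skew1", 30, 5),           # fold 6
                ("skew2", 40, 4),
                ("skew3", 60, 3),
                ("zerocas", 20, 0),         # infinite fold
                ("mild", 12, 8),            # fold 1.5, untestable? 20 >= 15
                ("fdrfail", 11, 4),         # fold 2.75 but p too big
                ("caskew", 5, 45)]
        calls = call_skewed(_table(rows), "K4me3").set_index("gene_id")
        assert not calls.loc["untestable", "passed_min_reads"]
        assert not calls.loc["untestable", "is_skewed"]
        assert np.isnan(calls.loc["untestable", "p_value"])
        assert calls.loc["balanced", "passed_min_reads"]
        assert not calls.loc["balanced", "is_skewed"]
        assert not calls.loc["foldfail", "passed_fold"]
        assert not calls.loc["foldfail", "is_skewed"]
        assert calls.loc["fdrfail", "passed_fold"]
        assert not calls.loc["fdrfail", "passed_fdr"]
        for g in ("skew1", "skew2", "skew3", "zerocas"):
            assert calls.loc[g, "is_skewed"], g
            assert calls.loc[g, "direction"] == "mus"
        assert calls.loc["caskew", "is_skewed"]
        assert calls.loc["caskew", "direction"] == "cas"

    def test_fdr_matches_manual_bh_within_assay(self):
        rows = [(f"g{i}", 30 - i, 5 + i) for i in range(10)]
        calls = call_skewed(_table(rows), "K4me3")
        testable = calls["passed_min_reads"]
        manual = brute_force_bh(calls.loc[testable, "p_value"])
        np.testing.assert_allclose(calls.loc[testable, "fdr"], manual)

    def test_flag_conjunction(self):
        rows = [(f"g{i}", int(m), int(c)) for i, (m, c) in
                enumerate(np.random.default_rng(1).integers(0, 60, (200, 2)))]
        calls = call_skewed(_table(rows), "x")
        expected = (calls["passed_min_reads"] & calls["passed_fold"]
                    & calls["passed_fdr"])
        assert (calls["is_skewed"] == expected).all()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        rows = [(f"g{i}", int(m), int(c)) for i, (m, c) in
                enumerate(rng.integers(0, 80, (500, 2)))]
        strict = call_skewed(_table(rows), "x", min_reads=20, fold=3.0,
                             fdr_max=0.01)
        loose = call_skewed(_table(rows), "x", min_reads=15, fold=2.0,
                            fdr_max=0.05)
        strict_set = set(strict.loc[strict["is_skewed"], "gene_id"])
        loose_set = set(loose.loc[loose["is_skewed"], "gene_id"])
        assert strict_set <= loose_set

    def test_allele_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        rows = [(f"g{i}", int(m), int(c)) for i, (m, c) in
                enumerate(rng.integers(0, 80, (300, 2)))]
        table = _table(rows)
        swapped = table.rename(columns={"n_mus": "n_cas", "n_cas": "n_mus"})
        a = call_skewed(table, "x")
        b = call_skewed(swapped, "x")
        nz = a["passed_min_reads"]
        np.testing.assert_allclose(a.loc[nz, "log2_ratio"],
                                   -b.loc[nz, "log2_ratio"])
        np.testing.assert_allclose(a.loc[nz, "p_value"], b.loc[nz, "p_value"])
        assert (a["is_skewed"] == b["is_skewed"]).all()
        flipped = {"mus": "cas", "cas": "mus", "none": "none"}
        assert (b["direction"] == a["direction"].map(flipped)).all()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_skewed(_table([("g", 5, 5)]), "x", min_reads=0)
        with pytest.raises(ValueError):
            call_skewed(_table([("g", 5, 5)]), "x", fdr_max=0.0)


class TestSkewedSetSummary:
    def _calls(self, skewed_ids, universe):
        rows = [(g, 40, 2) if g in skewed_ids else (g, 20, 18)
                for g in universe]
        return call_skewed(_table(rows), "x")

    def test_disjoint_sets(self):
        universe = [f"g{i}" for i in range(40)]
        calls = {"A": self._calls(set(universe[:5]), universe),
                 "B": self._calls(set(universe[10:15]), universe)}
        summary = skewed_set_summary(calls)
        assert summary["pairwise"][("A", "B")] == 0

    def test_identical_sets(self):
        universe = [f"g{i}" for i in range(40)]
        calls = {"A": self._calls(set(universe[:7]), universe),
                 "B": self._calls(set(universe[:7]), universe)}
        summary = skewed_set_summary(calls)
        assert summary["pairwise"][("A", "B")] == 7
        assert summary["per_assay"]["A"]["n_skewed"] == 7

    def test_truth_table_brute_force(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(60)]
        sets = {m: set(rng.choice(universe, size=10, replace=False))
                for m in ("A", "B", "C")}
        calls = {m: self._calls(s, universe) for m, s in sets.items()}
        summary = skewed_set_summary(calls)
        for (x, y), n in summary["pairwise"].items():
            assert n == len(sets[x] & sets[y])
        for (x, y, z), n in summary["triple"].items():
            assert n == len(sets[x] & sets[y] & sets[z])
        union = len(sets["A"] | sets["B"] | sets["C"])
        assert summary["union_fraction"] == pytest.approx(union / 60)


class TestHypergeometricOverlap:
    def test_skewed_equals_universe(self):
        universe = {f"g{i}" for i in range(100)}
        ref = {f"g{i}" for i in range(10)}
        assert hypergeometric_overlap(universe, ref, universe) == pytest.approx(1.0)

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(1000)]
        skewed = set(universe[:50])
        ref = set(universe[990:])
        assert hypergeometric_overlap(skewed, ref, universe) == pytest.approx(1.0)

    def test_full_overlap_tiny_sets(self):
        universe = [f"g{i}" for i in range(10000)]
        skewed = set(universe[:3])
        ref = set(universe[:3])
        p = hypergeometric_overlap(skewed, ref, universe)
        assert p == pytest.approx(exact_hypergeom_upper_tail(3, 10000, 3, 3),
                                  rel=1e-9)
        assert p < 1e-9

    def test_exact_oracle_all_sizes_up_to_50(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n_u = int(rng.integers(1, 51))
            n_ref = int(rng.integers(0, n_u + 1))
            n_skew = int(rng.integers(0, n_u + 1))
            universe = [f"g{i}" for i in range(n_u)]
            ref = set(rng.choice(universe, size=n_ref, replace=False))
            skewed = set(rng.choice(universe, size=n_skew, replace=False))
            k = len(skewed & ref)
            expected = exact_hypergeom_upper_tail(k, n_u, n_ref, n_skew)
            got = hypergeometric_overlap(skewed, ref, universe)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-300)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(set(), set(), set())


class TestClassifyConcordance:
    def _hybrid(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2_ratio",
                                           "is_skewed"])

    def _inbred(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2_ratio",
                                           "significant"])

    def test_classes(self):
        hybrid = self._hybrid([("a", 2.0, True), ("b", 1.5, True),
                               ("c", 0.1, False), ("d", 0.0, False)])
        inbred = self._inbred([("a", 2.0, True), ("b", 0.1, False),
                               ("c", 1.8, True), ("d", 0.05, False)])
        cls = classify_concordance(hybrid, inbred).set_index("gene_id")
        assert cls.loc["a", "concordance"] == "genetic"
        assert cls.loc["b", "concordance"] == "sequence_independent"
        assert cls.loc["c", "concordance"] == "other_discordant"
        assert cls.loc["d", "concordance"] == "concordant_null"

    def test_missing_genes_excluded(self):
        hybrid = self._hybrid([("a", 2.0, True), ("only_h", 1.0, True)])
        inbred = self._inbred([("a", 2.0, True), ("only_i", 1.0, True)])
        cls = classify_concordance(hybrid, inbred)
        assert set(cls["gene_id"]) == {"a"}

    def test_exactly_one_class_per_gene(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(50)]
        hybrid = self._hybrid([(g, rng.normal(), bool(rng.integers(2)))
                               for g in genes])
        inbred = self._inbred([(g, rng.normal(), bool(rng.integers(2)))
                               for g in genes])
        cls = classify_concordance(hybrid, inbred)
        assert len(cls) == 50
        assert cls["concordance"].isin(skew.CONCORDANCE_CLASSES).all()


class TestNullCalibration:
    def test_null_generator_low_false_positive_rate(self):
        g = synthetic.null_config(4000, seed=17)
        _, _, counts = synthetic.generate_dataset(g)
        calls = call_skewed(counts["K4me3"], "K4me3")
        testable = calls["passed_min_reads"].sum()
        assert testable > 500
        assert calls["is_skewed"].sum() / testable < 0.01
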