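from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domainspot.catalog import ColumnCount
from domainspot.hotspots import (
    align_family,
    binomial_tail,
    detect_hotspots,
    run_hotspot_analysis,
    scan_hotspots,
    summary_frame,
)
from domainspot.io import MISSENSE, INDEL, TRUNCATION, FamilyMSA
from conftest import make_mapped


def exact_tail(n, k, p_frac):
    """Independent oracle: term-by-term sum in exact rational arithmetic."""
    p = Fraction(p_frac)
    return sum(comb(n, i) * p ** i * (1 - p) ** (n - i) for i in range(k, n + 1))


def counts(family, mclass, ks):
    return [ColumnCount(family, col, mclass, k, frozenset({f"P{col}"}))
            for col, k in ks.items()]


class TestBinomialTail:
    def test_k_zero_is_total_probability(self):
        assert binomial_tail(17, 0, 0.3) == 1.0

    def test_single_term(self):
        assert binomial_tail(2, 2, 0.5) == pytest.approx(0.25, rel=1e-14)

    def test_matches_exact_rational_sum(self):
        expected = exact_tail(10, 3, Fraction(1, 10))
        assert binomial_tail(10, 3, 0.1) == pytest.approx(float(expected),
                                                          rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_probability_rejected(self, p):
        with pytest.raises(ValueError):
            binomial_tail(10, 2, p)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 6, 0.1)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=2, max_value=80))
    def test_strictly_decreasing_in_k(self, n):
        p = 0.02
        tails = [binomial_tail(n, k, p) for k in range(n + 1)]
        assert all(a > b for a, b in zip(tails, tails[1:]))


class TestDetectHotspots:
    def test_worked_example_two_of_two(self):
        # n=2 mutations, both at one column of a 100-column MSA
        (test,) = detect_hotspots(counts("F", MISSENSE, {5: 2}), 100, MISSENSE,
                                  alpha=0.05, m_total=1)
        assert test.p_value == pytest.approx(1e-4, rel=1e-12)
        assert test.n == 2 and test.significant

    def test_scatter_below_filter_tests_nothing(self):
        cc = counts("F", MISSENSE, {c: 1 for c in range(1, 21)})
        assert detect_hotspots(cc, 100, MISSENSE, 0.05) == []

    def test_massive_pileup_is_significant(self):
        cc = counts("F", MISSENSE, {7: 30, **{c: 1 for c in range(8, 78)}})
        (test,) = detect_hotspots(cc, 100, MISSENSE, 0.05, m_total=100000)
        assert test.n == 100 and test.k == 30 and test.significant

    def test_singletons_count_toward_n(self):
        cc = counts("F", MISSENSE, {1: 3, 2: 1, 3: 1})
        (test,) = detect_hotspots(cc, 50, MISSENSE, 0.05)
        assert test.n == 5 and test.k == 3

    def test_foreign_class_rejected(self):
        with pytest.raises(ValueError):
            detect_hotspots(counts("F", INDEL, {1: 2}), 50, MISSENSE, 0.05)


class TestScanHotspots:
    def test_global_correction_uses_all_tested_positions(self):
        mapped = ([make_mapped(family="A", column=3)] * 2
                  + [make_mapped(family="B", column=8)] * 2)
        tests = scan_hotspots(mapped, {"A": 100, "B": 100}, MISSENSE)
        assert len(tests) == 2
        for t in tests:
            assert t.p_corrected == pytest.approx(2 * t.p_value)

    def test_per_family_correction(self):
        mapped = ([make_mapped(family="A", column=3)] * 2
                  + [make_mapped(family="B", column=8)] * 2)
        tests = scan_hotspots(mapped, {"A": 100, "B": 100}, MISSENSE,
                              correction="per-family")
        for t in tests:
            assert t.p_corrected == pytest.approx(t.p_value)  # m = 1 each

    def test_empty_input(self):
        assert scan_hotspots([], {}, MISSENSE) == []


class TestRunHotspotAnalysis:
    def _mapped(self):
        og = [make_mapped(family="F", column=5, protein="OGP")] * 10
        ts = [make_mapped(family="F", column=c, protein="TSP")
              for c in range(1, 6)]
        return og + ts

    def test_og_only_signal_absent_from_ts_run(self):
        labels = {"OGP": "OG", "TSP": "TS"}
        runs = run_hotspot_analysis(self._mapped(), {"F": 100}, labels, MISSENSE)
        assert len(runs["OG"].significant) == 1
        assert runs["TS"].significant == []
        assert len(runs["genome"].significant) == 1

    def test_label_permutation_leaves_genome_unchanged(self):
        mapped = self._mapped()
        runs_a = run_hotspot_analysis(mapped, {"F": 100},
                                      {"OGP": "OG", "TSP": "TS"}, MISSENSE)
        runs_b = run_hotspot_analysis(mapped, {"F": 100},
                                      {"OGP": "TS", "TSP": "OG"}, MISSENSE)
        for ta, tb in zip(runs_a["genome"].tests, runs_b["genome"].tests):
            assert (ta.key, ta.p_value, ta.significant) == \
                   (tb.key, tb.p_value, tb.significant)

    def test_both_label_enters_both_strata(self):
        mapped = [make_mapped(family="F", column=5, protein="DUAL")] * 4
        runs = run_hotspot_analysis(mapped, {"F": 100}, {"DUAL": "both"},
                                    MISSENSE)
        assert runs["TS"].recorded_hotspots == 1
        assert runs["OG"].recorded_hotspots == 1

    def test_empty_catalog_all_zero(self):
        runs = run_hotspot_analysis([], {"F": 100}, {}, MISSENSE)
        frame = summary_frame({MISSENSE: runs})
        assert (frame["recorded_hotspots"] == 0).all()

    def test_class_independence(self):
        labels = {"OGP": "OG", "TSP": "TS"}
        with_indels = self._mapped() + [make_mapped(family="F", column=9,
                                                    mclass=INDEL)] * 5
        runs_a = run_hotspot_analysis(self._mapped(), {"F": 100}, labels, MISSENSE)
        runs_b = run_hotspot_analysis(with_indels, {"F": 100}, labels, MISSENSE)
        for dataset in ("TS", "OG", "genome"):
            assert [(t.key, t.p_value) for t in runs_a[dataset].tests] == \
                   [(t.key, t.p_value) for t in runs_b[dataset].tests]


class TestAlignFamily:
    def test_identical_sequences_gap_free(self):
        msa = align_family({"a/1-5": "ACDEF", "b/1-5": "ACDEF",
                            "c/1-5": "ACDEF"}, "F")
        assert msa.length == 5
        assert all("-" not in row for row in msa.rows.values())

    def test_single_deletion_opens_one_gap(self):
        msa = align_family({"a/1-5": "ACDEF", "b/1-4": "ACEF"}, "F")
        assert msa.length == 5
        assert FamilyMSA.ungap(msa.rows["b/1-4"]) == "ACEF"
        assert msa.rows["b/1-4"].count("-") == 1
        assert msa.rows["a/1-5"] == "ACDEF"

    def test_singleton_family(self):
        msa = align_family({"a/1-3": "ACD"}, "F")
        assert msa.rows == {"a/1-3": "ACD"}

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            align_family({}, "F")

    def test_rows_ungap_to_inputs(self):
        rng = np.random.default_rng(3)
        seqs = {}
        base = "ACDEFGHIKLMNPQRSTVWY" * 2
        for i in range(5):
            seq = list(base)
            for _ in range(rng.integers(0, 6)):
                seq.pop(rng.integers(0, len(seq)))
            seqs[f"s{i}/1-{len(seq)}"] = "".join(seq)
        msa = align_family(seqs, "F")
        lengths = {len(r) for r in msa.rows.values()}
        assert len(lengths) == 1
        for key, row in msa.rows.items():
            assert FamilyMSA.ungap(row) == seqs[key]
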