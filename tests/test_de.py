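"""Normalization, fold change and the two-library exact test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualsage.de import (
    call_significant,
    fc_histogram,
    fold_change,
    frequency_classes,
    normalize,
    tag_test_pvalue,
)
from dualsage.simulate import SimConfig, simulate_tag_libraries, simulate_transcriptomes
from dualsage.tags import InputError, clean_table

from conftest import make_table

N1_STUDY, N2_STUDY = 1_666_059, 3_598_159


def ac_pvalue_exact(x, y, n1, n2):
    """Brute-force tail summation of the conditional law in exact rationals.

    P(y'|x) = r^y' C(x+y', x) / (1+r)^(x+y'+1) with r = n2/n1; the upper
    tail is 1 minus the lower tail below y (the law sums to 1 exactly).
    """
    r = Fraction(n2, n1)

    def pmf(yp):
        return r**yp * math.comb(x + yp, x) / (1 + r) ** (x + yp + 1)

    lower = sum(pmf(t) for t in range(y + 1))
    upper = 1 - (lower - pmf(y))
    return min(Fraction(1), 2 * min(lower, upper))


class TestNormalize:
    def test_identity_scale(self):
        assert normalize(100, 1_000_000) == 100.0

    def test_study_library_size(self):
        assert normalize(1, N1_STUDY) == pytest.approx(0.600219, rel=1e-5)

    def test_zero_count(self):
        assert normalize(0, 123) == 0.0

    def test_invalid_lib_size(self):
        with pytest.raises(InputError):
            normalize(1, 0)

    def test_conserves_totals(self, rng):
        counts = rng.integers(0, 500, size=200)
        lib = int(counts.sum())
        assert sum(normalize(int(c), lib) for c in counts) == pytest.approx(1e6)


class TestFoldChange:
    def test_symmetry_gives_unity(self):
        fc, lfc, direction = fold_change(10, 10, 1000, 1000)
        assert fc == 1 and lfc == 0 and direction == "none"

    def test_pseudocount_for_absent_tag(self):
        fc, _, direction = fold_change(0, 7, 1000, 1000)
        assert fc == 7 and direction == "up"

    def test_two_computation_paths_agree(self):
        x, y = 50, 200
        fc, lfc, _ = fold_change(x, y, N1_STUDY, N2_STUDY)
        direct = math.log2((y / N2_STUDY) / (x / N1_STUDY))
        assert abs(lfc - direct) < 1e-12

    def test_both_zero_rejected(self):
        with pytest.raises(InputError):
            fold_change(0, 0, 10, 10)


class TestTagTestPvalue:
    def test_center_of_symmetry(self):
        for x in (0, 3, 50):
            assert tag_test_pvalue(x, x, 10**6, 10**6) == pytest.approx(1.0, abs=1e-12)

    def test_matches_exact_rational_tail_sum(self):
        for x, y in [(5, 0), (0, 5), (2, 9), (20, 3), (10, 40)]:
            for n1, n2 in [(10**6, 10**6), (N1_STUDY, N2_STUDY)]:
                p = tag_test_pvalue(x, y, n1, n2)
                exact = float(ac_pvalue_exact(x, y, n1, n2))
                assert p == pytest.approx(exact, rel=1e-9)

    def test_agrees_with_conditional_binomial_oracle(self):
        from scipy.stats import binomtest

        x, y, n = 3, 30, 10**6
        p_ac = tag_test_pvalue(x, y, n, n)
        p_bin = binomtest(y, x + y, 0.5).pvalue
        assert p_ac <= 2 * p_bin and p_bin <= 2 * p_ac
        assert (p_ac < 0.05) == (p_bin < 0.05)

    def test_in_unit_interval(self, rng):
        for _ in range(100):
            x, y = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            p = tag_test_pvalue(x, y, N1_STUDY, N2_STUDY)
            assert 0 < p <= 1

    def test_monotone_away_from_center(self):
        """p is non-increasing as y moves outward from its unimodal peak."""
        x = 20
        for n1, n2 in [(10**6, 10**6), (N1_STUDY, N2_STUDY)]:
            ps = [tag_test_pvalue(x, y, n1, n2) for y in range(0, 200)]
            peak = int(np.argmax(ps))
            assert all(a >= b - 1e-12 for a, b in zip(ps[peak:], ps[peak + 1 :]))
            assert all(a >= b - 1e-12 for a, b in zip(ps[peak::-1], ps[peak - 1 :: -1]))

    def test_binomial_backend_exactly_symmetric(self):
        cases = [(0, 5), (3, 30), (17, 2), (50, 50), (1, 0)]
        for x, y in cases:
            for n1, n2 in [(10**6, 10**6), (N1_STUDY, N2_STUDY)]:
                a = tag_test_pvalue(x, y, n1, n2, method="binomial")
                b = tag_test_pvalue(y, x, n2, n1, method="binomial")
                assert a == pytest.approx(b, abs=1e-14)

    def test_ac_swap_orientations_nearly_agree(self):
        # the conditional AC form is only approximately swap-symmetric:
        # at moderate counts the two orientations agree within half an
        # order of magnitude and give the same decision at alpha=0.05
        # (the exactly symmetric variant is the 'binomial' backend)
        for x in (10, 25, 40, 60, 100):
            for y in (10, 25, 40, 60, 100):
                a = tag_test_pvalue(x, y, N1_STUDY, N2_STUDY)
                b = tag_test_pvalue(y, x, N2_STUDY, N1_STUDY)
                assert abs(math.log10(a / b)) < 0.5
                assert (a < 0.05) == (b < 0.05)

    def test_unknown_method_rejected(self):
        with pytest.raises(InputError):
            tag_test_pvalue(1, 1, 10, 10, method="fisher")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=300),
    st.integers(min_value=0, max_value=300),
    st.integers(min_value=1000, max_value=10**7),
    st.integers(min_value=1000, max_value=10**7),
)
def test_binomial_symmetry_property(x, y, n1, n2):
    a = tag_test_pvalue(x, y, n1, n2, method="binomial")
    b = tag_test_pvalue(y, x, n2, n1, method="binomial")
    assert a == pytest.approx(b, abs=1e-12)


class TestCallSignificant:
    def test_empty_table(self):
        table = make_table([], n_ctl=10, n_inf=10)
        results, summary = call_significant(table)
        assert len(results) == 0 and summary.n_sig == 0

    def test_flags_equal_rule_reapplication(self):
        """Every emitted flag equals an independent recomputation of the
        (p < 0.05, FC >= 2) and (p < 0.05, |log2FC| > 2) rules."""
        cfg = SimConfig(
            n_host_transcripts=500,
            n_symbiont_transcripts=0,
            de_fraction=0.1,
            effect_size=(8.0, 8.0),
            depth_ctl=100_000,
            depth_inf=100_000,
            seed=7,
        )
        host, sym = simulate_transcriptomes(cfg)
        table, _ = simulate_tag_libraries(cfg, host, sym)
        table, _ = clean_table(table)
        results, summary = call_significant(table)
        for _, row in results.iterrows():
            p = tag_test_pvalue(row["count_ctl"], row["count_inf"],
                                table.n_ctl, table.n_inf)
            fc, lfc, _ = fold_change(row["count_ctl"], row["count_inf"],
                                     table.n_ctl, table.n_inf)
            mag = max(fc, 1 / fc)
            assert row["sig_2fold"] == (p < 0.05 and mag >= 2)
            assert row["sig_log2gt2"] == (p < 0.05 and abs(lfc) > 2)
        assert summary.n_sig == results["sig_2fold"].sum()
        assert summary.n_sig > 0  # 8-fold effects at these depths are detectable

    def test_sub_threshold_fold_change_not_significant(self):
        # p well below 0.05 but FC < 2: fails the headline rule
        table = make_table(
            [("CATG" + "G" * 22, 1000, 1500)], n_ctl=10**6, n_inf=10**6
        )
        results, _ = call_significant(table)
        row = results.iloc[0]
        assert row["pvalue"] < 0.05 and row["fc"] < 2
        assert not row["sig_2fold"] and not row["sig_log2gt2"]

    def test_strict_log2_flag_implies_twofold_flag(self, rng, random_tags):
        rows = [
            (t, int(rng.integers(0, 400)), int(rng.integers(0, 400)))
            for t in random_tags(150)
        ]
        rows = [r for r in rows if r[1] + r[2] > 0]
        table = make_table(rows, n_ctl=50_000, n_inf=80_000)
        results, _ = call_significant(table)
        assert (~results["sig_log2gt2"] | results["sig_2fold"]).all()

    def test_all_zero_rows_rejected(self):
        table = make_table([("A" * 26, 0, 0)], n_ctl=10, n_inf=10)
        with pytest.raises(InputError):
            call_significant(table)


class TestFcHistogram:
    def _results(self, fc_dir_pairs):
        rows = []
        for i, (fc, direction) in enumerate(fc_dir_pairs):
            x, y = (100, int(100 * fc)) if direction == "up" else (int(100 * fc), 100)
            rows.append((f"{'ACGT'[i % 4] * 26}"[:26], x, y))
        table = make_table(rows, n_ctl=10**6, n_inf=10**6)
        results, _ = call_significant(table)
        return results

    def test_single_up_tag_in_first_bin(self):
        results = self._results([(3, "up")])
        hist = fc_histogram(results)
        assert hist.loc[0, ["fc_lo", "fc_hi"]].tolist() == [2, 5]
        assert hist.loc[0, "n_up"] == 1 and hist["n_down"].sum() == 0

    def test_boundary_value_goes_to_upper_bin(self):
        hist = fc_histogram(self._results([(5, "up")]))
        assert hist.loc[1, ["fc_lo", "fc_hi"]].tolist() == [5, 10]
        assert hist.loc[1, "n_up"] == 1 and hist.loc[0, "n_up"] == 0

    def test_no_significant_tags_all_zero(self):
        table = make_table([("C" * 26, 100, 100)], n_ctl=10**6, n_inf=10**6)
        results, _ = call_significant(table)
        hist = fc_histogram(results)
        assert hist["n_up"].sum() == 0 and hist["n_down"].sum() == 0

    def test_unsorted_edges_rejected(self):
        with pytest.raises(InputError):
            fc_histogram(self._results([(3, "up")]), bin_edges=(5, 2, 10))


class TestFrequencyClasses:
    def test_all_low(self):
        rows = [(f"{b * 26}", 1, 1) for b in "ACGT"]
        table = make_table(rows, n_ctl=10**6, n_inf=10**6)
        freq = frequency_classes(table)
        assert freq.loc[freq["cpm_hi"] <= 1000, "fraction"].sum() == 1.0

    def test_one_high_among_ten(self):
        rows = [("".join(np.random.default_rng(i).choice(list("ACGT"), 26)), 1, 1)
                for i in range(9)]
        rows.append(("CATG" + "C" * 22, 2000, 2000))
        table = make_table(rows, n_ctl=10**6, n_inf=10**6)
        freq = frequency_classes(table)
        high = freq.loc[freq["cpm_lo"] >= 1000, "fraction"].sum()
        assert high == pytest.approx(0.1)

    def test_fractions_sum_to_one(self, rng, random_tags):
        rows = [(t, int(rng.integers(0, 5000)), int(rng.integers(1, 5000)))
                for t in random_tags(60)]
        table = make_table(rows, n_ctl=10**6, n_inf=2 * 10**6)
        freq = frequency_classes(table)
        assert freq["fraction"].sum() == pytest.approx(1.0)
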