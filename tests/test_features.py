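"""Conservation index, mutant frequency, MI network and cumulative MI."""

import math
from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mitomissense import (
    AlignmentSimSpec,
    attribute_report,
    conservation_index,
    coupled_pair_mi,
    cumulative_mi,
    feature1,
    mutant_frequency,
    pairwise_mi,
    simulate_alignment,
)
from mitomissense.features import EmptyAlignmentError
from mitomissense.msa import ColumnProfile, OrthologAlignment


def make_alignment(columns: list[str]) -> OrthologAlignment:
    """Build a tiny alignment from column strings (row 1 is the reference)."""
    n = len(columns[0])
    rows = ["".join(col[r] for col in columns) for r in range(n)]
    ids = ["REF_HUMAN"] + [f"o{i}" for i in range(n - 1)]
    return OrthologAlignment("p.X", ids, rows, "REF_HUMAN")


def oracle_mi_bits(pairs: list[tuple[str, str]]) -> float:
    """Brute-force plug-in MI: H(X) + H(Y) - H(X,Y) from joint counts."""

    def entropy(counter):
        n = sum(counter.values())
        return -sum(c / n * math.log2(c / n) for c in counter.values())

    return (
        entropy(Counter(x for x, _ in pairs))
        + entropy(Counter(y for _, y in pairs))
        - entropy(Counter(pairs))
    )


class TestConservationAndMutantFrequency:
    def test_ci_is_reference_relative_frequency(self):
        prof = ColumnProfile(1, {"H": 4000, "Y": 1000}, 5000)
        assert conservation_index(prof, "H").ci == pytest.approx(80.0)

    def test_fully_conserved_column(self):
        prof = ColumnProfile(1, {"W": 12}, 12)
        assert conservation_index(prof, "W").ci == pytest.approx(100.0)

    def test_absent_mutant_scores_zero(self):
        prof = ColumnProfile(1, {"A": 10}, 10)
        assert mutant_frequency(prof, "P") == 0.0

    def test_mutant_equal_to_reference_equals_ci(self):
        prof = ColumnProfile(3, {"L": 7, "V": 2, "-": 1}, 10)
        assert mutant_frequency(prof, "L") == conservation_index(prof, "L").ci

    def test_gaps_stay_in_the_denominator(self):
        prof = ColumnProfile(1, {"A": 5, "-": 5}, 10)
        assert conservation_index(prof, "A").ci == pytest.approx(50.0)

    def test_empty_alignment_error(self):
        with pytest.raises(EmptyAlignmentError):
            conservation_index(ColumnProfile(1, {}, 0), "A")

    def test_ci_recovers_planted_conservation_within_3se(self, small_alignment):
        spec, aln = small_alignment
        for pos in (1, 4, 9):  # positions outside the coupled pair
            p = spec.conservation[pos - 1]
            # gaps dilute the expected frequency: P(ref) = p * (1 - gap_rate)
            expect = 100 * p * (1 - spec.gap_rate)
            se = 100 * math.sqrt(expect / 100 * (1 - expect / 100) / aln.n_rows)
            ci = conservation_index(
                aln.column_profile(pos), aln.reference_residue(pos)
            ).ci
            assert abs(ci - expect) <= 3 * se + 100 / aln.n_rows


class TestPairwiseMI:
    def test_perfectly_coupled_binary_columns_give_one_bit(self):
        aln = make_alignment(["AARR", "LLVV"])
        net = pairwise_mi(aln, correction="none")
        assert net.mi[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_constant_columns_give_zero(self):
        aln = make_alignment(["AAAA", "LLLL"])
        net = pairwise_mi(aln, correction="none")
        assert net.mi[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_mixed_columns_match_entropy_oracle(self):
        cols = ["AAAR", "LVLV"]
        aln = make_alignment(cols)
        pairs = list(zip(cols[0], cols[1]))
        net = pairwise_mi(aln, correction="none")
        assert net.mi[0, 1] == pytest.approx(oracle_mi_bits(pairs), abs=1e-9)

    def test_equivalence_with_brute_force_on_random_small_alignments(self):
        """Plug-in MI equals the entropy oracle to 1e-9 bits, gap rows dropped pairwise."""
        rng = np.random.default_rng(123)
        residues = np.array(list("ACDEFGHIKL-"))
        for trial in range(20):
            n_rows, n_cols = int(rng.integers(4, 11)), int(rng.integers(2, 6))
            mat = rng.choice(residues, size=(n_rows - 1, n_cols), p=[0.085] * 10 + [0.15])
            ref = rng.choice(residues[:-1], size=n_cols)  # ungapped reference
            cols = ["".join([ref[c]] + mat[:, c].tolist()) for c in range(n_cols)]
            aln = make_alignment(cols)
            net = pairwise_mi(aln, correction="none")
            for i, j in combinations(range(n_cols), 2):
                pairs = [
                    (cols[i][r], cols[j][r])
                    for r in range(n_rows)
                    if cols[i][r] != "-" and cols[j][r] != "-"
                ]
                assert net.mi[i, j] == pytest.approx(oracle_mi_bits(pairs), abs=1e-9)

    def test_matrix_symmetric_nonnegative_diagonal_entropy(self):
        aln = make_alignment(["AARR", "LLVV", "WWWF"])
        net = pairwise_mi(aln, correction="none")
        assert np.allclose(net.mi, net.mi.T)
        assert (net.mi >= -1e-12).all()
        # self-MI is the column's plug-in entropy
        assert net.mi[0, 0] == pytest.approx(1.0)  # two equiprobable states
        pairs = list(zip("WWWF", "WWWF"))
        assert net.mi[2, 2] == pytest.approx(oracle_mi_bits(pairs), abs=1e-12)

    def test_planted_coupled_pair_ranks_top(self, small_alignment):
        spec, aln = small_alignment
        net = pairwise_mi(aln, correction="none")
        iu = np.triu_indices(net.mi.shape[0], k=1)
        top = np.argmax(net.mi[iu])
        i, j, c = spec.coevolving_pairs[0]
        assert (iu[0][top] + 1, iu[1][top] + 1) == (i, j)
        # and its MI approaches the closed-form planted value
        assert net.mi[i - 1, j - 1] == pytest.approx(coupled_pair_mi(c), abs=0.1)

    def test_too_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            pairwise_mi(make_alignment(["AA"]))


class TestCumulativeMI:
    def test_cmi_rel_attains_0_and_100(self, small_alignment):
        _, aln = small_alignment
        net = cumulative_mi(pairwise_mi(aln), z_threshold=1.0)
        assert net.cmi_rel.min() == pytest.approx(0.0)
        assert net.cmi_rel.max() == pytest.approx(100.0)

    def test_cmi_raw_equals_brute_force_sum_of_retained(self):
        rng = np.random.default_rng(5)
        cols = ["".join(rng.choice(list("AR"), 30)) for _ in range(5)]
        cols = ["A" + c for c in cols]  # ungapped reference row
        aln = make_alignment(cols)
        net = cumulative_mi(pairwise_mi(aln, correction="none"), z_threshold=0.5)
        L = 5
        for i in range(L):
            expect = sum(
                net.mi[i, j] for j in range(L) if j != i and net.retained[i, j]
            )
            assert net.cmi_raw[i] == pytest.approx(expect, abs=1e-12)

    def test_degenerate_scale_warns_and_zeroes(self):
        aln = make_alignment(["AAAA", "LLLL", "VVVV"])
        with pytest.warns(UserWarning, match="degenerate"):
            net = cumulative_mi(pairwise_mi(aln, correction="none"))
        assert (net.cmi_rel == 0).all()

    def test_cmi_rel_monotone_in_cmi_raw(self, small_alignment):
        _, aln = small_alignment
        net = cumulative_mi(pairwise_mi(aln), z_threshold=1.0)
        order = np.argsort(net.cmi_raw)
        assert (np.diff(net.cmi_rel[order]) >= -1e-12).all()


class TestFeature1:
    def test_sum_of_ci_and_relative_cmi(self, small_alignment):
        _, aln = small_alignment
        net = cumulative_mi(pairwise_mi(aln), z_threshold=1.0)
        ci = conservation_index(aln.column_profile(3), aln.reference_residue(3))
        f1 = feature1(ci, net, 3)
        assert f1 == pytest.approx(ci.ci + net.cmi_rel_at(3))
        assert 0.0 <= f1 <= 200.0

    def test_position_mismatch_rejected(self, small_alignment):
        _, aln = small_alignment
        net = cumulative_mi(pairwise_mi(aln), z_threshold=1.0)
        ci = conservation_index(aln.column_profile(3), aln.reference_residue(3))
        with pytest.raises(ValueError):
            feature1(ci, net, 4)


class TestAttributeReport:
    def test_reflects_planted_separation(self):
        rng = np.random.default_rng(2)
        n = 300
        df = pd.DataFrame({
            "f1": np.r_[rng.normal(100, 10, n), rng.normal(80, 10, n)],
            "f2": np.r_[rng.normal(2, 1, n), rng.normal(8, 1, n)],
            "f3": rng.normal(10, 3, 2 * n),
            "label": ["damaging"] * n + ["neutral"] * n,
        })
        rep = attribute_report(df)
        means = rep["by_class"]
        assert means.loc["damaging", ("f1", "mean")] == pytest.approx(
            df.loc[df.label == "damaging", "f1"].mean()
        )
        assert abs(rep["standardized_mean_diff"]["f1"]) > 1
        assert abs(rep["standardized_mean_diff"]["f3"]) < 0.3

    def test_identical_classes_show_no_separation(self):
        df = pd.DataFrame({
            "f1": [1.0, 2.0, 1.0, 2.0], "f2": [0.0, 1.0, 0.0, 1.0],
            "f3": [5.0, 6.0, 5.0, 6.0],
            "label": ["damaging", "damaging", "neutral", "neutral"],
        })
        rep = attribute_report(df)
        assert all(abs(v) < 1e-9 for v in rep["standardized_mean_diff"].values())

    def test_single_class_and_empty_rejected(self):
        df = pd.DataFrame({"f1": [1.0], "f2": [1.0], "f3": [1.0], "label": ["neutral"]})
        with pytest.raises(ValueError):
            attribute_report(df)
        with pytest.raises(ValueError):
            attribute_report(df.iloc[0:0])
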