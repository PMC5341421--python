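"""Domain annotations, composition statistics, substitution tables, Feature 3."""

import numpy as np
import pandas as pd
import pytest

from mitomissense import (
    DomainAnnotation,
    build_substitution_tables,
    domain_composition,
    feature3,
    read_domain_tsv,
)
from mitomissense.domains import AnnotationError, write_domain_tsv
from mitomissense.msa import OrthologAlignment


def make_alignment(pid: str, rows: list[str]) -> OrthologAlignment:
    ids = ["REF_HUMAN"] + [f"o{i}" for i in range(len(rows) - 1)]
    return OrthologAlignment(pid, ids, rows, "REF_HUMAN")


TOY_ANN = DomainAnnotation(
    "p.X", ((1, 10, "IM"), (11, 30, "TM"), (31, 40, "M"))
)


class TestAnnotation:
    @pytest.mark.parametrize("pos,label", [(1, "IM"), (10, "IM"), (11, "TM"),
                                           (30, "TM"), (31, "M"), (40, "M")])
    def test_domain_of_boundaries(self, pos, label):
        assert TOY_ANN.domain_of(pos) == label

    def test_positions_outside_are_lookup_errors(self):
        with pytest.raises(IndexError):
            TOY_ANN.domain_of(41)

    @pytest.mark.parametrize("intervals", [
        ((1, 10, "IM"), (12, 20, "TM")),      # hole
        ((1, 10, "IM"), (5, 20, "TM")),       # overlap
        ((2, 10, "IM"),),                     # does not start at 1
        ((1, 10, "XX"),),                     # unknown label
    ])
    def test_bad_partitions_fail_at_load_time(self, intervals):
        with pytest.raises(AnnotationError):
            DomainAnnotation("p.X", intervals)

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "dom.tsv"
        write_domain_tsv({"p.X": TOY_ANN}, path)
        back = read_domain_tsv(path)
        assert back["p.X"] == TOY_ANN

    def test_length_mismatch_with_alignment(self):
        aln = make_alignment("p.X", ["LLKA", "LLKA"])
        with pytest.raises(AnnotationError):
            build_substitution_tables({"p.X": aln}, {"p.X": TOY_ANN})


class TestComposition:
    def test_toy_counts_and_percentages(self):
        aln = make_alignment("p.X", ["LLKA", "LLKA", "LVKA"])
        ann = DomainAnnotation("p.X", ((1, 4, "TM"),))
        comp = domain_composition({"p.X": aln}, {"p.X": ann})
        tm = comp[comp.domain == "TM"].set_index("aa")
        assert tm.loc["L", "N"] == 2 and tm.loc["L", "percent"] == pytest.approx(50.0)
        assert tm.loc["K", "N"] == 1 and tm.loc["A", "N"] == 1
        # composition percentages sum to 100 within each domain
        assert comp.groupby("domain")["percent"].sum().round(6).eq(100).all()

    def test_mean_ci_is_average_of_per_position_cis(self):
        # L column: 3/3 conserved (CI 100); second L column: 2/3 (CI 66.7)
        aln = make_alignment("p.X", ["LL", "LL", "LV"])
        ann = DomainAnnotation("p.X", ((1, 2, "M"),))
        comp = domain_composition({"p.X": aln}, {"p.X": ann})
        row = comp[(comp.domain == "M") & (comp.aa == "L")].iloc[0]
        assert row["CI"] == pytest.approx(round((100 + 200 / 3) / 2, 1))

    def test_missing_alignment_is_skipped_with_warning(self, caplog):
        aln = make_alignment("p.X", ["LL", "LL"])
        anns = {"p.X": DomainAnnotation("p.X", ((1, 2, "M"),)),
                "p.Y": DomainAnnotation("p.Y", ((1, 2, "TM"),))}
        with caplog.at_level("WARNING"):
            comp = domain_composition({"p.X": aln}, anns)
        assert "p.Y" in caplog.text
        assert set(comp.domain) == {"M"}


class TestSubstitutionTables:
    def test_single_mutant_renormalization(self):
        # one TM column, reference A, observed A:90 T:10 -> A->T is 100%
        rows = ["A"] + ["A"] * 89 + ["T"] * 10
        aln = make_alignment("p.X", rows)
        ann = DomainAnnotation("p.X", ((1, 1, "TM"),))
        tables = build_substitution_tables({"p.X": aln}, {"p.X": ann})
        assert tables["TM"].frequency("A", "T") == pytest.approx(100.0)

    def test_two_mutant_split(self):
        rows = ["A"] + ["A"] * 79 + ["T"] * 10 + ["S"] * 10
        aln = make_alignment("p.X", rows)
        ann = DomainAnnotation("p.X", ((1, 1, "TM"),))
        tables = build_substitution_tables({"p.X": aln}, {"p.X": ann})
        assert tables["TM"].frequency("A", "T") == pytest.approx(50.0)
        assert tables["TM"].frequency("A", "S") == pytest.approx(50.0)

    def test_pooled_tally_matches_brute_force(self):
        """Counts pooled over positions/polypeptides equal a direct tally."""
        rng = np.random.default_rng(9)
        residues = list("ARNDC")
        cols_x = ["".join(rng.choice(residues, 30)) for _ in range(3)]
        cols_x = ["A" + c for c in cols_x]
        rows_x = ["".join(t) for t in zip(*cols_x)]
        aln = make_alignment("p.X", rows_x)
        ann = DomainAnnotation("p.X", ((1, 2, "TM"), (3, 3, "M")))
        tables = build_substitution_tables({"p.X": aln}, {"p.X": ann})
        # brute force for domain TM, wild-type A (reference residue of cols 1-2)
        from collections import Counter

        tally = Counter(cols_x[0]) + Counter(cols_x[1])
        off = {aa: c for aa, c in tally.items() if aa not in ("A", "-")}
        total = sum(off.values())
        for aa, c in off.items():
            assert tables["TM"].frequency("A", aa) == pytest.approx(100 * c / total)

    def test_freq_rows_sum_to_100_and_scale_invariance(self):
        rows = ["A"] + ["A"] * 9 + ["T"] * 6 + ["S"] * 4 + ["-"] * 5
        aln = make_alignment("p.X", rows)
        ann = DomainAnnotation("p.X", ((1, 1, "M"),))
        tables = build_substitution_tables({"p.X": aln}, {"p.X": ann})
        assert tables["M"].freq[0].sum() == pytest.approx(100.0, abs=1e-6)
        # duplicating every row must not change frequencies
        aln2 = make_alignment("p.X", rows + rows[1:] + [rows[0]])
        tables2 = build_substitution_tables({"p.X": aln2}, {"p.X": ann})
        assert np.allclose(tables["M"].freq, tables2["M"].freq)

    def test_recovers_planted_substitution_profile_within_3se(self):
        """Off-diagonal frequencies estimate the planted conditional distribution."""
        rng = np.random.default_rng(21)
        planted = {"T": 0.6, "S": 0.3, "G": 0.1}
        n = 3000
        draws = rng.choice(list(planted), p=list(planted.values()), size=n)
        rows = ["A"] + ["A"] * n + draws.tolist()
        aln = make_alignment("p.X", ["".join(r) for r in rows])
        ann = DomainAnnotation("p.X", ((1, 1, "TM"),))
        tables = build_substitution_tables({"p.X": aln}, {"p.X": ann})
        for aa, p in planted.items():
            se = 100 * np.sqrt(p * (1 - p) / n)
            assert abs(tables["TM"].frequency("A", aa) - 100 * p) <= 3 * se

    def test_mean_pooling_option(self):
        # same wild type in two alignments of very different depths: count
        # pooling weighs the deep alignment more, mean pooling weighs the
        # positions equally
        deep = make_alignment("p.X", ["A"] + ["A"] * 9 + ["T"] * 10)   # 20 rows
        shallow = make_alignment("p.Y", ["A"] + ["S"] * 4)             # 5 rows
        anns = {"p.X": DomainAnnotation("p.X", ((1, 1, "TM"),)),
                "p.Y": DomainAnnotation("p.Y", ((1, 1, "TM"),))}
        alns = {"p.X": deep, "p.Y": shallow}
        by_counts = build_substitution_tables(alns, anns)
        by_mean = build_substitution_tables(alns, anns, pooling="mean")
        assert by_counts["TM"].frequency("A", "T") == pytest.approx(100 * 10 / 14)
        assert by_mean["TM"].frequency("A", "T") == pytest.approx(
            100 * 0.5 / (0.5 + 0.8)
        )


class TestFeature3:
    def test_unobserved_substitution_is_zero(self):
        rows = ["A"] + ["A"] * 9
        aln = make_alignment("p.X", rows)
        ann = DomainAnnotation("p.X", ((1, 1, "IM"),))
        tables = build_substitution_tables({"p.X": aln}, {"p.X": ann})
        assert feature3(tables, "A", "W", "IM") == 0.0

    def test_unknown_domain_label_rejected(self):
        rows = ["A"] + ["A"] * 9
        aln = make_alignment("p.X", rows)
        ann = DomainAnnotation("p.X", ((1, 1, "IM"),))
        tables = build_substitution_tables({"p.X": aln}, {"p.X": ann})
        with pytest.raises(KeyError):
            feature3(tables, "A", "T", "OUTER")
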