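"""PASS selection, PAS assignment, RED arithmetic and APA classification."""

import numpy as np
import pandas as pd
import pytest

from cpai.apa import (
    assign_lap_to_pas,
    autr_table,
    build_isoform_counts,
    classify_pas_multiplicity,
    cross_sample_apa_bias,
    lengthening_vs_autr,
    pick_top2_utr3,
    red_3utr,
    red_ipa,
    select_polya_reads,
    terminal_a_run,
)
from cpai.core import GeneModel
from cpai.simulate import SimConfig, simulate_3p_reads, simulate_genome
from conftest import make_isoform_table


class TestPolyASelection:
    @pytest.mark.parametrize(
        "seq, kept",
        [
            ("ACGT" * 10 + "A" * 15, True),   # exactly 15 terminal A's
            ("ACGT" * 10 + "A" * 14, False),  # one short
            ("ACGT" * 5 + "A" * 10 + "G" + "A" * 15, True),  # terminal run qualifies
            ("A" * 30 + "G", False),          # run not terminal
        ],
    )
    def test_terminal_a_rule(self, seq, kept):
        result = select_polya_reads([("read", seq)])
        assert ("read" in result) is kept

    def test_empty_input_empty_set(self):
        assert select_polya_reads([]) == set()

    def test_terminal_a_run_lengths(self):
        assert terminal_a_run("GGGAAA") == 3
        assert terminal_a_run("AAAG") == 0


def _reads(laps, strand="+", mapq=60):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [int(l) - 40 for l in laps],
            "end": [int(l) + 10 for l in laps],
            "read_id": [f"r{i}" for i in range(len(laps))],
            "mapq": mapq,
            "strand": strand,
            "lap": [float(l) for l in laps],
        }
    )


def _pas(positions, strand="+", cls="utr3", gene="g"):
    return pd.DataFrame(
        {
            "pas_id": [f"p{i}" for i in range(len(positions))],
            "gene_id": gene,
            "chrom": "chr1",
            "strand": strand,
            "position": positions,
            "location_class": cls,
        }
    )


class TestAssignment:
    def test_tolerance_boundary_inclusive(self):
        res = assign_lap_to_pas(_reads([1024]), _pas([1000]))
        assert res.assignments.tolist() == ["p0"]

    def test_beyond_tolerance_unassigned(self):
        res = assign_lap_to_pas(_reads([1025]), _pas([1000]))
        assert res.assignments.empty
        assert res.n_unassigned == 1

    def test_low_mapq_discarded_first(self):
        res = assign_lap_to_pas(_reads([1000], mapq=9), _pas([1000]))
        assert res.assignments.empty
        assert res.n_low_mapq == 1

    def test_nearest_pas_wins(self):
        res = assign_lap_to_pas(_reads([1010]), _pas([1000, 1040]))
        assert res.assignments.tolist() == ["p0"]

    def test_equidistant_tie_takes_5prime_most(self):
        res_plus = assign_lap_to_pas(_reads([1012]), _pas([1000, 1024]))
        assert res_plus.assignments.tolist() == ["p0"]
        res_minus = assign_lap_to_pas(
            _reads([1012], strand="-"), _pas([1000, 1024], strand="-")
        )
        assert res_minus.assignments.tolist() == ["p1"]  # higher coord is 5'-most

    def test_missing_lap_skipped_with_count(self):
        reads = _reads([1000])
        reads.loc[0, "lap"] = np.nan
        res = assign_lap_to_pas(reads, _pas([1000]))
        assert res.n_missing_lap == 1
        assert res.assignments.empty

    def test_simulated_assignment_complete_without_decoys(self):
        sim = simulate_genome(
            SimConfig(n_genes=20, seed=21, expression_rate=100.0, with_sequence=False)
        )
        tp = simulate_3p_reads(sim, "control")
        res = assign_lap_to_pas(tp.alignments, sim.pas)
        assert len(res.assignments) == len(tp.alignments)
        # and every read lands on its true PAS (jitter <= tolerance)
        truth = tp.true_pas.loc[res.assignments.index]
        assert (res.assignments == truth).mean() > 0.99


class TestTop2Selection:
    def test_top_two_by_summed_usage_labelled_by_position(self):
        tab = make_isoform_table(
            [
                ("g", "a", "c", "+", 100, "utr3", (60, 40)),
                ("g", "b", "c", "+", 500, "utr3", (50, 30)),
                ("g", "c", "c", "+", 900, "utr3", (3, 2)),
            ],
            ["t", "c"],
        )
        assert pick_top2_utr3(tab, "g", ("t", "c")) == ("a", "b")

    def test_single_utr3_pas_gives_none(self):
        tab = make_isoform_table([("g", "a", "c", "+", 100, "utr3", (60, 40))], ["t", "c"])
        assert pick_top2_utr3(tab, "g", ("t", "c")) is None

    def test_tie_for_second_place_takes_5prime_most(self):
        tab = make_isoform_table(
            [
                ("g", "a", "c", "+", 100, "utr3", (100, 0)),
                ("g", "b", "c", "+", 500, "utr3", (10, 10)),
                ("g", "c", "c", "+", 900, "utr3", (10, 10)),
            ],
            ["t", "c"],
        )
        assert pick_top2_utr3(tab, "g", ("t", "c")) == ("a", "b")

    def test_intronic_pas_ignored(self):
        tab = make_isoform_table(
            [
                ("g", "i", "c", "+", 50, "intronic", (500, 500)),
                ("g", "a", "c", "+", 100, "utr3", (60, 40)),
            ],
            ["t", "c"],
        )
        assert pick_top2_utr3(tab, "g", ("t", "c")) is None


GENE = GeneModel("g", "c", "+", 10, 950, [(10, 1000)], [])


class TestRED:
    def test_identical_counts_give_zero_ns(self):
        tab = make_isoform_table(
            [
                ("g", "p", "c", "+", 500, "utr3", (10, 10)),
                ("g", "d", "c", "+", 900, "utr3", (10, 10)),
            ],
            ["t", "c"],
        )
        res = red_3utr(tab, [GENE], "t", "c")
        assert res["red"].iloc[0] == 0.0
        assert res["class"].iloc[0] == "NS"

    def test_pseudocount_arithmetic(self):
        tab = make_isoform_table(
            [
                ("g", "p", "c", "+", 500, "utr3", (10, 10)),
                ("g", "d", "c", "+", 900, "utr3", (20, 10)),
            ],
            ["t", "c"],
        )
        res = red_3utr(tab, [GENE], "t", "c")
        assert res["red"].iloc[0] == pytest.approx(np.log2(21 / 11), abs=1e-12)

    def test_antisymmetry_under_sample_swap(self):
        tab = make_isoform_table(
            [
                ("g", "p", "c", "+", 500, "utr3", (120, 80)),
                ("g", "d", "c", "+", 900, "utr3", (40, 90)),
            ],
            ["t", "c"],
        )
        fwd = red_3utr(tab, [GENE], "t", "c")
        rev = red_3utr(tab, [GENE], "c", "t")
        assert fwd["red"].iloc[0] == pytest.approx(-rev["red"].iloc[0])
        assert fwd["p"].iloc[0] == pytest.approx(rev["p"].iloc[0])

    def test_usage_shift_recovered_at_depth(self):
        # (0.8, 0.2) -> (0.5, 0.5): RED converges to log2(1) - log2(0.25) = 2
        rng = np.random.default_rng(22)
        n = 10_000
        p_c, d_c = rng.binomial(n, 0.8), 0
        d_c = n - p_c
        p_t = rng.binomial(n, 0.5)
        d_t = n - p_t
        tab = make_isoform_table(
            [
                ("g", "p", "c", "+", 500, "utr3", (p_t, p_c)),
                ("g", "d", "c", "+", 900, "utr3", (d_t, d_c)),
            ],
            ["t", "c"],
        )
        res = red_3utr(tab, [GENE], "t", "c")
        assert res["red"].iloc[0] == pytest.approx(2.0, abs=0.1)
        assert res["class"].iloc[0] == "lengthened"


class TestIPA:
    def test_no_intronic_pas_skipped(self):
        tab = make_isoform_table(
            [("g", "a", "c", "+", 100, "utr3", (10, 10))], ["t", "c"]
        )
        assert red_ipa(tab, [GENE], "t", "c").empty

    def test_ipa_suppression_arithmetic(self):
        tab = make_isoform_table(
            [
                ("g", "i", "c", "+", 50, "intronic", (25, 50)),
                ("g", "a", "c", "+", 900, "terminal_exon", (75, 50)),
            ],
            ["t", "c"],
        )
        res = red_ipa(tab, [GENE], "t", "c")
        assert res["red"].iloc[0] == pytest.approx(np.log2(26 / 76), abs=1e-12)

    def test_top_ipa_only_is_used(self):
        tab = make_isoform_table(
            [
                ("g", "i1", "c", "+", 50, "intronic", (30, 30)),
                ("g", "i2", "c", "+", 80, "intronic", (5, 5)),
                ("g", "a", "c", "+", 900, "terminal_exon", (50, 50)),
            ],
            ["t", "c"],
        )
        res = red_ipa(tab, [GENE], "t", "c")
        assert res["IPA_id"].iloc[0] == "i1"
        assert res["ipa_treated"].iloc[0] == 30


class TestMultiplicity:
    @pytest.mark.parametrize(
        "shares, expected",
        [
            ((60, 40), "multi_pas"),
            ((97, 3), "single_major"),
            ((92, 8), "other"),
        ],
    )
    def test_share_rules(self, shares, expected):
        tab = make_isoform_table(
            [
                ("g", "a", "c", "+", 500, "utr3", (shares[0],)),
                ("g", "b", "c", "+", 900, "utr3", (shares[1],)),
            ],
            ["s"],
        )
        assert classify_pas_multiplicity(tab, "g") == expected

    def test_intronic_counts_in_denominator_only(self):
        # last-exon share of 96% of *total* (incl. IPA) is required
        tab = make_isoform_table(
            [
                ("g", "i", "c", "+", 50, "intronic", (20,)),
                ("g", "a", "c", "+", 900, "utr3", (80,)),
            ],
            ["s"],
        )
        assert classify_pas_multiplicity(tab, "g") == "other"


class TestCrossSampleAndAUTR:
    def test_count_swap_negates_delta(self):
        tab = make_isoform_table(
            [
                ("g", "p", "c", "+", 500, "utr3", (120, 40)),
                ("g", "d", "c", "+", 900, "utr3", (60, 90)),
            ],
            ["hepg2", "hela"],
        )
        fwd, _ = cross_sample_apa_bias(tab, [GENE], "hepg2", "hela")
        rev, _ = cross_sample_apa_bias(tab, [GENE], "hela", "hepg2")
        assert fwd["red"].iloc[0] == pytest.approx(-rev["red"].iloc[0])

    def test_autr_binning_two_genes_per_bin(self):
        rows = []
        genes = []
        for i in range(10):
            gid = f"g{i}"
            rows += [
                (gid, f"{gid}p", "c", "+", 100, "utr3", (50, 50)),
                (gid, f"{gid}d", "c", "+", 100 + 200 * (i + 1), "utr3", (50, 50)),
            ]
            genes.append(GeneModel(gid, "c", "+", 10, 3000, [(10, 3100)], []))
        tab = make_isoform_table(rows, ["t", "c"])
        res = red_3utr(tab, genes, "t", "c")
        autr = autr_table(res, tab.pas)
        assert sorted(autr["autr_len"]) == [200 * (i + 1) for i in range(10)]
        bins = lengthening_vs_autr(res, autr, k=5)
        assert bins["n"].tolist() == [2] * 5

    def test_flat_red_gives_flat_bins(self):
        rows, genes = [], []
        for i in range(10):
            gid = f"g{i}"
            rows += [
                (gid, f"{gid}p", "c", "+", 100, "utr3", (50, 50)),
                (gid, f"{gid}d", "c", "+", 100 + 100 * (i + 1), "utr3", (50, 50)),
            ]
            genes.append(GeneModel(gid, "c", "+", 10, 3000, [(10, 3100)], []))
        tab = make_isoform_table(rows, ["t", "c"])
        res = red_3utr(tab, genes, "t", "c")
        bins = lengthening_vs_autr(res, autr_table(res, tab.pas), k=5)
        assert bins["mean_red"].to_numpy() == pytest.approx(np.zeros(5))


class TestBuildIsoformCounts:
    def test_retained_ids_filter_applied(self):
        reads = _reads([1000, 1000, 1040])
        pas = _pas([1000, 1040])
        counts = build_isoform_counts(
            {"s": reads}, pas, retained_ids={"s": {"r0", "r2"}}
        )
        col = counts.counts["s"]
        assert col.loc[("g", "p0")] == 1
        assert col.loc[("g", "p1")] == 1
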