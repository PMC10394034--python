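"""Pair construction, CROSS/CRISS arithmetic and stratification tables."""

import numpy as np
import pandas as pd
import pytest

from cpai.core import AlignmentIndex, GeneModel, empty_alignments
from cpai.neighbors import (
    build_pairs,
    criss,
    criss_table,
    cross,
    distance_trend,
    stratify_5x5,
)
from cpai.simulate import SimConfig, simulate_chr_reads, simulate_genome


def _gene(gid, strand, lo, hi):
    tss, pas = (lo, hi) if strand == "+" else (hi, lo)
    return GeneModel(gid, "chr1", strand, tss, pas, [(lo, hi + 1 if strand == "+" else hi)], [])


class TestBuildPairs:
    def test_convergent_orientation_and_distance(self):
        a = _gene("a", "+", 1000, 5000)
        b = _gene("b", "-", 5500, 9000)
        pairs = build_pairs([a, b])
        assert pairs.loc["a", "orientation"] == "convergent"
        assert pairs.loc["a", "distance"] == 500

    def test_tandem_only_for_downstream_goi(self):
        a = _gene("a", "+", 1000, 5000)
        b = _gene("b", "+", 5300, 9000)
        pairs = build_pairs([a, b])
        assert pairs.loc["b", "orientation"] == "tandem"   # NNG upstream
        assert pairs.loc["a", "orientation"] == "other"    # NNG downstream
        assert pairs.loc["b", "distance"] == 300

    def test_divergent_heads_facing(self):
        a = _gene("a", "-", 1000, 5000)
        b = _gene("b", "+", 5500, 9000)
        pairs = build_pairs([a, b])
        assert pairs.loc["a", "orientation"] == "divergent"

    def test_overlapping_genes_clamped_to_other(self):
        a = _gene("a", "+", 1000, 5000)
        b = _gene("b", "-", 4000, 9000)
        pairs = build_pairs([a, b])
        assert pairs.loc["a", "orientation"] == "other"
        assert pairs.loc["a", "distance"] == 0

    def test_nearest_neighbor_chosen(self):
        a = _gene("a", "+", 1000, 5000)
        b = _gene("b", "-", 5500, 9000)
        c = _gene("c", "+", 20_000, 25_000)
        pairs = build_pairs([a, b, c])
        assert pairs.loc["a", "nng_id"] == "b"
        assert pairs.loc["c", "nng_id"] == "b"

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            build_pairs([_gene("a", "+", 0, 100)])


def _aln(rows):
    df = empty_alignments()
    for i, (start, end, strand) in enumerate(rows):
        df.loc[i] = ["chr1", start, end, f"r{i}", 60, strand, np.nan]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


class TestCross:
    def test_pseudocount_arithmetic(self):
        g = _gene("g", "+", 1000, 5000)
        rows = [(4500, 4600, "-")] * 8 + [(4500, 4600, "+")] * 2
        val = cross(g, AlignmentIndex(_aln(rows)))
        assert val == pytest.approx(np.log2(9 / 3))

    def test_balanced_signal_gives_zero(self):
        g = _gene("g", "+", 1000, 5000)
        rows = [(4500, 4600, "-")] * 5 + [(4200, 4300, "+")] * 5
        assert cross(g, AlignmentIndex(_aln(rows))) == 0.0

    def test_no_antisense_pseudocount_floor(self):
        g = _gene("g", "+", 1000, 5000)
        rows = [(4500, 4600, "+")] * 7
        assert cross(g, AlignmentIndex(_aln(rows))) == pytest.approx(np.log2(1 / 8))

    def test_strand_inversion_flips_sign(self):
        g = _gene("g", "+", 1000, 5000)
        rows = [(4500, 4600, "-")] * 8 + [(4500, 4600, "+")] * 2
        df = _aln(rows)
        flipped = df.assign(strand=df["strand"].map({"+": "-", "-": "+"}))
        assert cross(g, AlignmentIndex(df)) == pytest.approx(
            -cross(g, AlignmentIndex(flipped))
        )

    def test_region_is_last_kb_in_transcript_direction(self):
        g = _gene("g", "-", 1000, 5000)
        # last 1 kb of a minus-strand gene is its genomic start
        rows = [(1100, 1200, "+")] * 4  # antisense for the minus gene
        assert cross(g, AlignmentIndex(_aln(rows))) == pytest.approx(np.log2(5 / 1))


class TestCriss:
    def test_identical_samples_give_zero(self):
        sim = simulate_genome(
            SimConfig(n_genes=2, seed=40, pair_layout=(("tandem", 1500),),
                      with_sequence=False)
        )
        aln = simulate_chr_reads(sim, "treated")
        idx = AlignmentIndex(aln)
        pairs = build_pairs(sim.genes)
        tab = criss_table(pairs, sim.genes, idx, idx,
                          {"treated": len(aln), "control": len(aln)})
        assert tab["criss"].abs().max() == pytest.approx(0.0)

    def test_planted_gain_recovered(self):
        # a 4x readthrough gain planted at the pair's upstream gene only,
        # against unchanged background genes, so library totals stay matched
        r_treated = [0.05] * 10
        r_treated[0] = 0.2
        sim = simulate_genome(
            SimConfig(n_genes=10, seed=41, pair_layout=(("tandem", 2000),),
                      expression_rate=20_000.0, expression_sigma=0.0,
                      readthrough_control=0.05, readthrough_treated=tuple(r_treated),
                      with_sequence=False)
        )
        t = simulate_chr_reads(sim, "treated")
        c = simulate_chr_reads(sim, "control")
        pairs = build_pairs(sim.genes)
        tab = criss_table(pairs, sim.genes, AlignmentIndex(t), AlignmentIndex(c),
                          {"treated": len(t), "control": len(c)})
        assert tab["criss"].loc["g00001"] == pytest.approx(2.0, abs=0.25)

    def test_non_tandem_pair_rejected(self):
        sim = simulate_genome(
            SimConfig(n_genes=2, seed=42, pair_layout=(("convergent", 1500),),
                      with_sequence=False)
        )
        pairs = build_pairs(sim.genes)
        by_id = {g.gene_id: g for g in sim.genes}
        idx = AlignmentIndex(empty_alignments())
        with pytest.raises(ValueError):
            criss(pairs.iloc[0], by_id, idx, idx, {"treated": 1, "control": 1})


class TestStratification:
    def _pairs_df(self, n=200, seed=43):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "distance": rng.uniform(100, 10_000, n),
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
            }
        )

    def test_constant_response_constant_cells(self):
        df = self._pairs_df()
        df["resp"] = 1.5
        tab = stratify_5x5(df, "x", "y", "resp")
        assert np.allclose(tab.to_numpy(), 1.5)

    def test_x_only_monotone_response(self):
        df = self._pairs_df(500)
        df["resp"] = df["x"]
        tab = stratify_5x5(df, "x", "y", "resp")
        col_means = tab.median(axis=0).to_numpy()
        assert np.all(np.diff(col_means) > 0)
        row_spread = tab.median(axis=1).to_numpy()
        assert np.ptp(row_spread) < 0.5

    def test_bottom_40pct_distance_filter(self):
        df = self._pairs_df(100)
        df["resp"] = 1.0
        cutoff = np.quantile(df["distance"], 0.4)
        tab = stratify_5x5(df, "x", "y", "resp", short_distance_only=True)
        n_cells = tab.notna().sum().sum()
        assert n_cells <= 25
        # filter keeps exactly the 40 shortest distances -> 40 pairs in table
        kept = df[df["distance"].rank(method="first") <= 40]
        assert (kept["distance"] <= cutoff + 1e-9).all()

    def test_sparse_table_allows_empty_cells(self):
        df = self._pairs_df(24)
        df["resp"] = 1.0
        tab = stratify_5x5(df, "x", "y", "resp")
        assert tab.isna().sum().sum() >= 1


class TestDistanceTrend:
    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"distance": [1, 2, 3], "resp": [1, 2, 3]})
        with pytest.raises(ValueError):
            distance_trend(df, "resp")

    def test_null_calibration(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            df = pd.DataFrame(
                {"distance": rng.uniform(0, 1, 300), "resp": rng.normal(size=300)}
            )
            _, p = distance_trend(df, "resp")
            hits += p < 0.05
        assert hits <= 4

    def test_planted_monotone_effect_detected(self):
        rng = np.random.default_rng(44)
        d = rng.uniform(0, 1, 400)
        df = pd.DataFrame({"distance": d, "resp": 2 * d + rng.normal(0, 0.5, 400)})
        summary, p = distance_trend(df, "resp")
        assert p < 0.01
        assert summary.loc[4, "median"] > summary.loc[0, "median"]
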