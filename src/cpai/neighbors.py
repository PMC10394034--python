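"""Nearest-neighbor gene pairs and transcriptional-interference scores.

CROSS (overlapping-signal score): log2 antisense/sense read-count ratio in
a gene's last 1 kb, computed on the treated sample — a proxy for Pol II
collision between convergent (tail-to-tail) neighbors.  CRISS
(intervening-signal score): log2 treated/control depth-normalized read
density in the gap of a tandem (head-to-tail) pair — a proxy for read-in
from the upstream gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AlignmentIndex, GeneModel
from .stats import equal_count_bins, ks_two_sample


def build_pairs(genes: list[GeneModel]) -> pd.DataFrame:
    """For each gene (GOI) find its nearest neighbor gene (NNG) by the gap
    between facing gene-body ends, and classify the pair orientation.

    ``convergent``: 3' ends facing; ``divergent``: 5' ends facing;
    ``tandem``: same strand with the NNG transcriptionally upstream of the
    GOI.  Overlapping bodies get distance 0 and orientation ``other``.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes to build pairs")
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: g.body_start)
        starts = np.array([g.body_start for g in glist])
        ends = np.array([g.body_end for g in glist])
        for i, goi in enumerate(glist):
            gaps = np.maximum(
                np.maximum(starts - goi.body_end, goi.body_start - ends), 0
            )
            gaps[i] = np.iinfo(np.int64).max
            if len(glist) < 2:
                continue
            j = int(np.argmin(gaps))
            nng = glist[j]
            dist = int(gaps[j])
            overlap = (nng.body_start < goi.body_end) and (nng.body_end > goi.body_start)
            if overlap:
                orientation, dist = "other", 0
            elif goi.strand == nng.strand:
                # tandem requires the NNG 3' end upstream of the GOI 5' end
                if goi.strand == "+":
                    upstream = nng.body_end <= goi.body_start
                else:
                    upstream = nng.body_start >= goi.body_end
                orientation = "tandem" if upstream else "other"
            else:
                left, right = (goi, nng) if goi.body_start <= nng.body_start else (nng, goi)
                if left.strand == "+" and right.strand == "-":
                    orientation = "convergent"
                elif left.strand == "-" and right.strand == "+":
                    orientation = "divergent"
                else:
                    orientation = "other"
            rows.append((goi.gene_id, nng.gene_id, orientation, dist))
    return pd.DataFrame(
        rows, columns=["goi_id", "nng_id", "orientation", "distance"]
    ).set_index("goi_id")


def cross(
    gene: GeneModel, treated: AlignmentIndex, region: int = 1000, pseudocount: int = 1
) -> float:
    """log2[(antisense + 1)/(sense + 1)] read counts in the gene's last
    ``region`` nt, treated sample."""
    lo, hi = gene.last_kb(region)
    anti_strand = "-" if gene.strand == "+" else "+"
    n_sense = treated.count(gene.chrom, lo, hi, gene.strand)
    n_anti = treated.count(gene.chrom, lo, hi, anti_strand)
    return float(np.log2((n_anti + pseudocount) / (n_sense + pseudocount)))


def cross_table(
    genes: list[GeneModel], treated: AlignmentIndex, region: int = 1000
) -> pd.DataFrame:
    return pd.DataFrame(
        {"cross": [cross(g, treated, region) for g in genes]},
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )


def criss(
    pair: pd.Series,
    genes_by_id: dict[str, GeneModel],
    treated: AlignmentIndex,
    control: AlignmentIndex,
    totals: dict[str, int],
    strand_specific: bool = True,
) -> float:
    """log2 ratio of depth-normalized intervening-region read density,
    treated over control, for a tandem pair.

    The intervening signal is counted on the upstream (NNG) gene's strand
    by default (read-in continuation); ``strand_specific=False`` counts
    both strands.  Densities are divided by sample total mapped reads; a
    one-base pseudo-density on the same normalized scale keeps the log2
    finite.
    """
    if pair["orientation"] != "tandem":
        raise ValueError("CRISS is defined for tandem pairs only")
    goi = genes_by_id[pair.name if isinstance(pair.name, str) else pair["goi_id"]]
    nng = genes_by_id[pair["nng_id"]]
    gap_lo = min(goi.body_end, nng.body_end)
    gap_hi = max(goi.body_start, nng.body_start)
    if gap_hi <= gap_lo:
        return float("nan")
    length = gap_hi - gap_lo
    strands = [nng.strand] if strand_specific else ["+", "-"]

    def norm_density(idx: AlignmentIndex, total: int) -> float:
        bases = sum(idx.overlap_bases(goi.chrom, gap_lo, gap_hi, s) for s in strands)
        return bases / length / max(total, 1)

    rho_t = norm_density(treated, totals["treated"])
    rho_c = norm_density(control, totals["control"])
    eps = 1.0 / length / max(min(totals["treated"], totals["control"]), 1)
    return float(np.log2((rho_t + eps) / (rho_c + eps)))


def criss_table(
    pairs: pd.DataFrame,
    genes: list[GeneModel],
    treated: AlignmentIndex,
    control: AlignmentIndex,
    totals: dict[str, int],
    strand_specific: bool = True,
) -> pd.DataFrame:
    """CRISS for every tandem pair with a positive intervening length."""
    by_id = {g.gene_id: g for g in genes}
    tandem = pairs[pairs["orientation"] == "tandem"]
    vals, idx = [], []
    for goi_id, row in tandem.iterrows():
        if row["distance"] <= 0:
            continue
        vals.append(criss(row.rename(goi_id), by_id, treated, control, totals,
                          strand_specific))
        idx.append(goi_id)
    return pd.DataFrame({"criss": vals}, index=pd.Index(idx, name="goi_id"))


def stratify_5x5(
    table: pd.DataFrame,
    x: str,
    y: str,
    response: str,
    k: int = 5,
    short_distance_only: bool = False,
    distance_col: str = "distance",
    bottom_fraction: float = 0.4,
) -> pd.DataFrame:
    """k x k median-response table with equal-count bins independently on
    the two axes; optionally restricted to the shortest ``bottom_fraction``
    of pair distances first.  Empty cells are NaN."""
    df = table.dropna(subset=[x, y, response]).copy()
    if short_distance_only:
        ranks = df[distance_col].rank(method="first")
        df = df[ranks <= np.ceil(bottom_fraction * len(df))]
    df["_xbin"] = equal_count_bins(df[x].to_numpy(), k)
    df["_ybin"] = equal_count_bins(df[y].to_numpy(), k)
    out = df.pivot_table(
        index="_ybin", columns="_xbin", values=response, aggfunc="median"
    ).reindex(index=range(k), columns=range(k))
    out.index.name = f"{y}_bin"
    out.columns.name = f"{x}_bin"
    return out


def distance_trend(
    table: pd.DataFrame,
    response: str,
    k: int = 5,
    distance_col: str = "distance",
) -> tuple[pd.DataFrame, float]:
    """Quintile bins of pair distance with the response distribution per
    bin, plus a two-sided K-S p-value for bin 1 vs bin 5."""
    df = table.dropna(subset=[distance_col, response])
    if len(df) < k:
        raise ValueError(f"need at least {k} pairs, got {len(df)}")
    bins = equal_count_bins(df[distance_col].to_numpy(), k)
    df = df.assign(bin=bins)
    grouped = df.groupby("bin")[response]
    summary = pd.DataFrame(
        {"n": grouped.size(), "median": grouped.median(), "mean": grouped.mean()}
    )
    _, p = ks_two_sample(
        df.loc[df["bin"] == 0, response].to_numpy(),
        df.loc[df["bin"] == k - 1, response].to_numpy(),
    )
    return summary, p
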