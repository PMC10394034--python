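"""Count-based differential gene expression.

Reads are counted per gene body (strand-aware), counts normalized by total
mapped reads with a pseudocount of 1, significance assessed per gene by
Fisher's exact test on gene-vs-rest-of-library counts, BH-adjusted, and a
fold-change threshold (1.2 or 2) applied to call regulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AlignmentIndex, GeneModel
from .stats import bh_adjust, fisher_exact_2x2

CALLS = ("UP", "DN", "NS")

UPSET_GROUPS = (
    "UPboth", "DNboth", "UP_A", "DN_A", "UP_B", "DN_B", "UP_A&DN_B", "DN_A&UP_B",
)


@dataclass
class GeneCountMatrix:
    """Gene x sample read counts plus per-sample total mapped reads."""

    counts: pd.DataFrame           # index gene_id, one column per sample
    totals: dict[str, int]

    def __post_init__(self):
        for s in self.counts.columns:
            if s not in self.totals:
                raise ValueError(f"no total_mapped for sample {s!r}")
            if self.totals[s] < int(self.counts[s].sum()):
                raise ValueError(f"total_mapped < column sum for sample {s!r}")


def count_genes(
    genes: list[GeneModel],
    alignments: dict[str, "AlignmentIndex | pd.DataFrame"],
    totals: dict[str, int] | None = None,
) -> GeneCountMatrix:
    """Count reads overlapping each gene body by >= 1 nt on the gene's
    strand.  A read overlapping two gene bodies counts for both."""
    indexes = {
        s: a if isinstance(a, AlignmentIndex) else AlignmentIndex(a)
        for s, a in alignments.items()
    }
    if totals is None:
        totals = {s: idx.n_total for s, idx in indexes.items()}
    data = {
        s: [idx.count(g.chrom, g.body_start, g.body_end, g.strand) for g in genes]
        for s, idx in indexes.items()
    }
    counts = pd.DataFrame(data, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    return GeneCountMatrix(counts, dict(totals))


def filter_expressed(
    m: GeneCountMatrix,
    samples: list[str] | None = None,
    min_reads: int = 5,
    how: str = "any",
) -> GeneCountMatrix:
    """Keep genes with more than ``min_reads`` reads in a sample.

    ``how='any'`` (default) requires the strict threshold in at least one
    of the given samples; ``how='all'`` in every one.
    """
    cols = samples or list(m.counts.columns)
    above = m.counts[cols] > min_reads
    keep = above.any(axis=1) if how == "any" else above.all(axis=1)
    return GeneCountMatrix(m.counts.loc[keep].copy(), dict(m.totals))


def de_test(
    m: GeneCountMatrix,
    treated: str,
    control: str,
    fc: float = 1.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene log2Ratio, Fisher p, BH-adjusted p and UP/DN/NS call.

    log2Ratio = log2[ (c_t+1)/T_t / ((c_c+1)/T_c) ]; the Fisher 2x2 table
    is [[c_t, T_t-c_t], [c_c, T_c-c_c]] on raw counts.
    """
    c_t = m.counts[treated].to_numpy(np.int64)
    c_c = m.counts[control].to_numpy(np.int64)
    t_t, t_c = int(m.totals[treated]), int(m.totals[control])
    log2ratio = np.log2((c_t + 1) / t_t) - np.log2((c_c + 1) / t_c)
    p = np.array([
        fisher_exact_2x2(a, t_t - a, b, t_c - b) for a, b in zip(c_t, c_c)
    ])
    p_adj = bh_adjust(p)
    call = np.where(
        (p_adj < alpha) & (np.abs(log2ratio) >= np.log2(fc)),
        np.where(log2ratio > 0, "UP", "DN"),
        "NS",
    )
    return pd.DataFrame(
        {
            "gene_id": m.counts.index,
            "count_t": c_t,
            "count_c": c_c,
            "log2ratio": log2ratio,
            "p": p,
            "p_adj": p_adj,
            "call": call,
        }
    ).set_index("gene_id")


def classify_dose_dependent(low: pd.DataFrame, high: pd.DataFrame) -> pd.Index:
    """Genes significantly regulated at the high dose, with the same sign
    of change at both doses and strictly stronger regulation at the high
    dose."""
    joined = high.join(low, lsuffix="_hi", rsuffix="_lo", how="inner")
    keep = (
        (joined["call_hi"] != "NS")
        & (np.sign(joined["log2ratio_hi"]) == np.sign(joined["log2ratio_lo"]))
        & (joined["log2ratio_hi"].abs() > joined["log2ratio_lo"].abs())
    )
    return joined.index[keep]


def upset_8group(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> tuple[pd.Series, float]:
    """Partition genes regulated in at least one of two experiments into
    the eight concordance/discordance groups, and report the DN/UP count
    ratio over all per-experiment regulation calls."""
    joined = calls_a[["call"]].join(calls_b[["call"]], lsuffix="_a", rsuffix="_b", how="outer")
    a = joined["call_a"].fillna("NS")
    b = joined["call_b"].fillna("NS")
    label = pd.Series("NS", index=joined.index, dtype=object)
    label[(a == "UP") & (b == "UP")] = "UPboth"
    label[(a == "DN") & (b == "DN")] = "DNboth"
    label[(a == "UP") & (b == "NS")] = "UP_A"
    label[(a == "DN") & (b == "NS")] = "DN_A"
    label[(a == "NS") & (b == "UP")] = "UP_B"
    label[(a == "NS") & (b == "DN")] = "DN_B"
    label[(a == "UP") & (b == "DN")] = "UP_A&DN_B"
    label[(a == "DN") & (b == "UP")] = "DN_A&UP_B"
    label = label[label != "NS"]
    n_dn = int((a == "DN").sum() + (b == "DN").sum())
    n_up = int((a == "UP").sum() + (b == "UP").sum())
    ratio = n_dn / n_up if n_up else float("inf") if n_dn else float("nan")
    return label, ratio
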