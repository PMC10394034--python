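"""Alternative polyadenylation quantification from 3'-end reads.

PASS (poly(A)-site-supporting) reads are 3'-end reads with a terminal
A-run whose last aligned position (LAP) falls within +/- 24 nt of an
annotated PAS.  Per-gene isoform counts feed the Relative Expression
Difference (RED): the between-sample change of the log2 distal/proximal
isoform-abundance ratio, with Fisher/BH significance and a log2(1.2)
effect threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LAST_EXON_CLASSES, GeneModel
from .stats import bh_adjust, equal_count_bins, fisher_exact_2x2

logger = logging.getLogger("cpai")


# ---------------------------------------------------------------------------
# PASS selection and assignment
# ---------------------------------------------------------------------------

def terminal_a_run(seq: str) -> int:
    """Length of the contiguous run of A's at the 3' terminus."""
    n = 0
    for ch in reversed(seq.upper()):
        if ch != "A":
            break
        n += 1
    return n


def select_polya_reads(reads, min_a: int = 15) -> set[str]:
    """IDs of reads ending in >= ``min_a`` consecutive A's.

    ``reads`` is an iterable of Bio.SeqRecord (e.g. from
    ``Bio.SeqIO.parse(path, "fastq")``) or of (id, sequence) pairs.
    """
    kept = set()
    for rec in reads:
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq)
        else:
            rid, seq = rec
        if terminal_a_run(seq) >= min_a:
            kept.add(rid)
    return kept


@dataclass
class AssignmentResult:
    assignments: pd.Series      # read_id -> pas_id, assigned reads only
    n_input: int
    n_low_mapq: int
    n_missing_lap: int
    n_unassigned: int


def assign_lap_to_pas(
    lap_reads: pd.DataFrame,
    pas: pd.DataFrame,
    tol: int = 24,
    min_mapq: int = 10,
) -> AssignmentResult:
    """Assign each read's LAP to the nearest same-strand PAS within
    ``tol`` nt; exact ties go to the 5'-most PAS in transcript direction.
    Reads with MAPQ < ``min_mapq`` are discarded first; reads matching no
    PAS are excluded from all downstream APA counts.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    n_input = len(lap_reads)
    missing = lap_reads["lap"].isna()
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning("%d reads without LAP skipped", n_missing)
    df = lap_reads[~missing]
    low = df["mapq"] < min_mapq
    n_low = int(low.sum())
    df = df[~low]

    out_idx: list[np.ndarray] = []
    out_pas: list[np.ndarray] = []
    n_unassigned = 0
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=False):
        psub = pas[(pas["chrom"] == chrom) & (pas["strand"] == strand)]
        if psub.empty:
            n_unassigned += len(sub)
            continue
        pos = psub["position"].to_numpy(np.int64)
        ids = psub["pas_id"].to_numpy(object)
        order = np.argsort(pos, kind="stable")
        pos, ids = pos[order], ids[order]
        laps = sub["lap"].to_numpy(np.int64)
        right = np.searchsorted(pos, laps, side="left")
        left = right - 1
        d_left = np.where(left >= 0, np.abs(laps - pos[np.clip(left, 0, None)]), np.iinfo(np.int64).max)
        d_right = np.where(right < len(pos), np.abs(pos[np.clip(right, None, len(pos) - 1)] - laps),
                           np.iinfo(np.int64).max)
        # nearest wins; on an exact tie take the 5'-most in transcript
        # direction: lower coordinate on +, higher coordinate on -.
        if strand == "+":
            choose_left = d_left <= d_right
        else:
            choose_left = d_left < d_right
        chosen = np.where(choose_left, np.clip(left, 0, None), np.clip(right, None, len(pos) - 1))
        dist = np.where(choose_left, d_left, d_right)
        ok = dist <= tol
        n_unassigned += int((~ok).sum())
        out_idx.append(sub.index.to_numpy()[ok])
        out_pas.append(ids[chosen[ok]])
    if out_idx:
        idx = np.concatenate(out_idx)
        vals = np.concatenate(out_pas)
        read_ids = lap_reads.loc[idx, "read_id"].to_numpy()
    else:
        read_ids, vals = np.empty(0, object), np.empty(0, object)
    assignments = pd.Series(vals, index=pd.Index(read_ids, name="read_id"), name="pas_id")
    return AssignmentResult(assignments, n_input, n_low, n_missing, n_unassigned)


# ---------------------------------------------------------------------------
# Isoform count tables
# ---------------------------------------------------------------------------

@dataclass
class IsoformCountTable:
    """(gene_id, pas_id) x sample PASS-read counts."""

    counts: pd.DataFrame   # MultiIndex (gene_id, pas_id), one column per sample
    pas: pd.DataFrame      # the PAS annotation the counts refer to

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def gene(self, gene_id: str) -> pd.DataFrame:
        try:
            return self.counts.loc[gene_id]
        except KeyError:
            return self.counts.iloc[0:0].droplevel(0)


def build_isoform_counts(
    samples: dict[str, pd.DataFrame],
    pas: pd.DataFrame,
    retained_ids: dict[str, set[str]] | None = None,
    tol: int = 24,
    min_mapq: int = 10,
) -> IsoformCountTable:
    """Assign PASS reads sample by sample and tabulate per-PAS counts.

    ``retained_ids`` optionally restricts each sample to the poly(A)
    read-id set from :func:`select_polya_reads`; ``None`` keeps all reads
    (pre-filtered input).
    """
    full_index = pd.MultiIndex.from_frame(pas[["gene_id", "pas_id"]])
    cols = {}
    for sample, aln in samples.items():
        df = aln
        if retained_ids is not None and retained_ids.get(sample) is not None:
            df = df[df["read_id"].isin(retained_ids[sample])]
        res = assign_lap_to_pas(df, pas, tol=tol, min_mapq=min_mapq)
        vc = res.assignments.value_counts()
        cols[sample] = vc
    pas_counts = pd.DataFrame(cols).reindex(pas["pas_id"]).fillna(0).astype(np.int64)
    pas_counts.index = full_index
    return IsoformCountTable(pas_counts, pas)


# ---------------------------------------------------------------------------
# 3'UTR APA and IPA via RED
# ---------------------------------------------------------------------------

def pick_top2_utr3(
    counts: IsoformCountTable, gene_id: str, samples: tuple[str, str]
) -> tuple[str, str] | None:
    """The two last-exon 3'UTR PASs with the highest summed usage across
    the two compared samples, labelled (pPAS, dPAS) by transcript-direction
    order.  Returns None when fewer than two such PASs have signal."""
    sub = counts.gene(gene_id)
    if sub.empty:
        return None
    meta = counts.pas.set_index("pas_id")
    utr3 = [p for p in sub.index if meta.loc[p, "location_class"] == "utr3"]
    sub = sub.loc[utr3]
    use = sub[list(samples)].sum(axis=1)
    nonzero = use[use > 0]
    if len(nonzero) < 2:
        return None
    strand = meta.loc[nonzero.index[0], "strand"]
    pos = meta.loc[nonzero.index, "position"]
    # rank by usage, break ties toward the 5'-most PAS
    tie_key = pos if strand == "+" else -pos
    ranking = pd.DataFrame({"use": nonzero, "tie": tie_key}).sort_values(
        ["use", "tie"], ascending=[False, True], kind="stable"
    )
    top2 = list(ranking.index[:2])
    p0, p1 = sorted(top2, key=lambda p: tie_key.loc[p])
    return p0, p1


def _red_row(n_t, m_t, n_c, m_c, pseudocount: int):
    """RED and Fisher p for numerator/denominator counts in two samples."""
    q = pseudocount
    red = (np.log2(n_t + q) - np.log2(m_t + q)) - (np.log2(n_c + q) - np.log2(m_c + q))
    p = fisher_exact_2x2(n_t, m_t, n_c, m_c)
    return red, p


def _finalize_red(df: pd.DataFrame, fc: float, alpha: float,
                  pos_label: str, neg_label: str) -> pd.DataFrame:
    if df.empty:
        df["p_adj"] = df["class"] = pd.Series(dtype=object)
        return df
    df = df.copy()
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    sig = (df["p_adj"] < alpha) & (df["red"].abs() > np.log2(fc))
    df["class"] = np.where(sig, np.where(df["red"] > 0, pos_label, neg_label), "NS")
    return df


def red_3utr(
    counts: IsoformCountTable,
    genes: list[GeneModel],
    treated: str,
    control: str,
    fc: float = 1.2,
    alpha: float = 0.05,
    pseudocount: int = 1,
) -> pd.DataFrame:
    """RED for the top-two 3'UTR isoforms of every eligible gene.

    RED = log2[(d_t+1)/(p_t+1)] - log2[(d_c+1)/(p_c+1)]; positive values
    indicate 3'UTR lengthening in the treated sample.  Significance:
    Fisher's exact on the raw 2x2 counts, BH across genes, |RED| >
    log2(fc).
    """
    rows = []
    for g in genes:
        pick = pick_top2_utr3(counts, g.gene_id, (treated, control))
        if pick is None:
            continue
        p_id, d_id = pick
        sub = counts.gene(g.gene_id)
        d_t, d_c = int(sub.loc[d_id, treated]), int(sub.loc[d_id, control])
        p_t, p_c = int(sub.loc[p_id, treated]), int(sub.loc[p_id, control])
        red, p = _red_row(d_t, p_t, d_c, p_c, pseudocount)
        rows.append((g.gene_id, p_id, d_id, d_t, p_t, d_c, p_c, red, p))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "pPAS_id", "dPAS_id", "d_treated", "p_treated",
                 "d_control", "p_control", "red", "p"],
    ).set_index("gene_id")
    return _finalize_red(df, fc, alpha, "lengthened", "shortened")


def red_ipa(
    counts: IsoformCountTable,
    genes: list[GeneModel],
    treated: str,
    control: str,
    fc: float = 1.2,
    alpha: float = 0.05,
    pseudocount: int = 1,
) -> pd.DataFrame:
    """RED for intronic polyadenylation: the top-expressed intronic PAS
    against all last-exon (TPA) isoforms combined; negative RED means the
    IPA isoform is relatively suppressed in the treated sample."""
    meta = counts.pas.set_index("pas_id")
    rows = []
    for g in genes:
        sub = counts.gene(g.gene_id)
        if sub.empty:
            continue
        classes = meta.loc[sub.index, "location_class"]
        ipa = sub[classes == "intronic"]
        tpa = sub[classes.isin(LAST_EXON_CLASSES)]
        if ipa.empty or tpa.empty:
            continue
        use = ipa[[treated, control]].sum(axis=1)
        if use.max() <= 0:
            continue
        top = use.idxmax()
        i_t, i_c = int(ipa.loc[top, treated]), int(ipa.loc[top, control])
        t_t, t_c = int(tpa[treated].sum()), int(tpa[control].sum())
        red, p = _red_row(i_t, t_t, i_c, t_c, pseudocount)
        rows.append((g.gene_id, top, i_t, t_t, i_c, t_c, red, p))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "IPA_id", "ipa_treated", "tpa_treated",
                 "ipa_control", "tpa_control", "red", "p"],
    ).set_index("gene_id")
    return _finalize_red(df, fc, alpha, "IPA_up", "IPA_down")


def classify_pas_multiplicity(
    counts: IsoformCountTable, gene_id: str, samples: list[str] | None = None
) -> str:
    """``multi_pas`` when >= 2 last-exon PASs each carry > 10% of the
    gene's total isoform counts; ``single_major`` when one last-exon PAS
    carries > 95%; else ``other``."""
    sub = counts.gene(gene_id)
    if sub.empty:
        return "other"
    cols = samples or list(sub.columns)
    meta = counts.pas.set_index("pas_id")
    total = sub[cols].sum(axis=1)
    denom = total.sum()
    if denom == 0:
        return "other"
    share = total / denom
    last_exon = share[meta.loc[share.index, "location_class"].isin(LAST_EXON_CLASSES)]
    if (last_exon > 0.10).sum() >= 2:
        return "multi_pas"
    if (last_exon > 0.95).any():
        return "single_major"
    return "other"


def cross_sample_apa_bias(
    counts: IsoformCountTable,
    genes: list[GeneModel],
    line_b: str,
    line_a: str,
    fc: float = 1.2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Between-cell-line 3'UTR isoform bias: identical arithmetic to
    :func:`red_3utr` with line B in the treated role.  Also reports the
    lengthened/shortened gene counts and their ratio."""
    df = red_3utr(counts, genes, line_b, line_a, fc=fc, alpha=alpha)
    n_len = int((df["class"] == "lengthened").sum())
    n_sho = int((df["class"] == "shortened").sum())
    summary = {
        "lengthened": n_len,
        "shortened": n_sho,
        "ratio": n_len / n_sho if n_sho else float("inf") if n_len else float("nan"),
    }
    return df, summary


# ---------------------------------------------------------------------------
# aUTR size analysis
# ---------------------------------------------------------------------------

def autr_table(red_df: pd.DataFrame, pas: pd.DataFrame) -> pd.DataFrame:
    """aUTR length (nt between the selected pPAS and dPAS) per gene."""
    pos = pas.set_index("pas_id")["position"]
    autr = (pos.loc[red_df["dPAS_id"]].to_numpy() - pos.loc[red_df["pPAS_id"]].to_numpy())
    out = pd.DataFrame({"gene_id": red_df.index, "autr_len": np.abs(autr)}).set_index("gene_id")
    if (out["autr_len"] <= 0).any():
        raise ValueError("aUTR length must be positive")
    return out


def lengthening_vs_autr(
    red_df: pd.DataFrame, autr: pd.DataFrame, k: int = 5
) -> pd.DataFrame:
    """Mean RED +/- SEM in ``k`` equal-count bins of aUTR size."""
    joined = red_df[["red"]].join(autr, how="inner").dropna()
    bins = equal_count_bins(joined["autr_len"].to_numpy(), k)
    joined = joined.assign(bin=bins)
    grouped = joined.groupby("bin")
    out = pd.DataFrame(
        {
            "n": grouped.size(),
            "autr_min": grouped["autr_len"].min(),
            "autr_max": grouped["autr_len"].max(),
            "mean_red": grouped["red"].mean(),
            "sem_red": grouped["red"].sem(),
        }
    )
    return out
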