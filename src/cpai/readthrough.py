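"""Transcriptional readthrough scoring from chromatin RNA-seq.

RTS = log2 of read density in the 4 kb window downstream of a gene's last
PAS over the density of the gene body (TSS to last PAS), measured on the
gene's own strand.  Delta RTS (treated minus control) measures the change
of readthrough between two samples.  Genes whose readthrough window
overlaps another gene are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .core import AlignmentIndex, GeneModel
from .stats import ks_two_sample


def rts(
    gene: GeneModel,
    alignments: AlignmentIndex,
    window: int = 4000,
    chrom_length: int | None = None,
    pseudodensity: bool = True,
) -> float:
    """Readthrough score of one gene in one sample.

    Densities are overlap-bases per nt on the gene's strand.  A
    pseudodensity of one base per region keeps the log2 finite for
    zero-coverage regions; with ``pseudodensity=False`` a zero body
    density yields NaN.
    """
    wlo, whi = gene.downstream_window(window)
    if chrom_length is not None:
        wlo, whi = max(0, wlo), min(chrom_length, whi)
    else:
        wlo = max(0, wlo)
    if whi - wlo < window:  # truncated window: not comparable, drop
        return float("nan")
    rho_down = alignments.overlap_bases(gene.chrom, wlo, whi, gene.strand) / window
    rho_body = alignments.overlap_bases(
        gene.chrom, gene.body_start, gene.body_end, gene.strand
    ) / gene.body_length
    if pseudodensity:
        rho_down += 1.0 / window
        rho_body += 1.0 / gene.body_length
    elif rho_body == 0:
        return float("nan")
    elif rho_down == 0:
        return float("-inf")
    return float(np.log2(rho_down / rho_body))


def exclude_overlapping(genes: list[GeneModel], window: int = 4000) -> list[GeneModel]:
    """Genes whose downstream readthrough window intersects no other
    gene's body on either strand."""
    bodies = np.array([[g.body_start, g.body_end] for g in genes])
    chroms = np.array([g.chrom for g in genes])
    eligible = []
    for i, g in enumerate(genes):
        wlo, whi = g.downstream_window(window)
        hit = (chroms == g.chrom) & (bodies[:, 0] < whi) & (bodies[:, 1] > wlo)
        hit[i] = False
        if not hit.any():
            eligible.append(g)
    return eligible


def rts_table(
    genes: list[GeneModel],
    samples: dict[str, AlignmentIndex],
    window: int = 4000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    rows = {}
    for name, idx in samples.items():
        clens = chrom_lengths or {}
        rows[f"rts_{name}"] = [
            rts(g, idx, window=window, chrom_length=clens.get(g.chrom)) for g in genes
        ]
    return pd.DataFrame(rows, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def delta_rts(rts_treated: pd.Series, rts_control: pd.Series) -> pd.DataFrame:
    """Per-gene Delta RTS = treated - control (NaN where either is)."""
    df = pd.DataFrame({"rts_treated": rts_treated, "rts_control": rts_control})
    df["delta_rts"] = df["rts_treated"] - df["rts_control"]
    return df


def delta_rts_summary(delta: pd.Series) -> dict:
    vals = delta.dropna().to_numpy()
    return {
        "n": int(len(vals)),
        "median": float(np.median(vals)) if len(vals) else float("nan"),
        "cdf_x": np.sort(vals),
        "cdf_y": np.arange(1, len(vals) + 1) / len(vals) if len(vals) else np.empty(0),
    }


def compare_delta_rts(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Two-sided K-S between two Delta RTS distributions."""
    return ks_two_sample(a.dropna().to_numpy(), b.dropna().to_numpy())


# ---------------------------------------------------------------------------
# Metagene profile around the last PAS
# ---------------------------------------------------------------------------

def metagene(
    genes: list[GeneModel],
    alignments: AlignmentIndex,
    half: int = 5000,
    trim: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-gene coverage over +/- ``half`` nt around the last PAS in
    transcript orientation, each gene normalized by its gene-body mean
    coverage; the summary curve is the per-position mean after dropping
    the top and bottom ``trim`` fraction of gene values.

    Returns (gene x position matrix, trimmed-mean curve); positions run
    -half .. half-1 with 0 at the last PAS.
    """
    mats, ids = [], []
    for g in genes:
        lo, hi = g.last_pas - half, g.last_pas + half
        cov = alignments.coverage(g.chrom, lo, hi, g.strand).astype(float)
        if g.strand == "-":
            cov = cov[::-1]
        body_mean = alignments.overlap_bases(
            g.chrom, g.body_start, g.body_end, g.strand
        ) / g.body_length
        if body_mean <= 0:
            continue
        mats.append(cov / body_mean)
        ids.append(g.gene_id)
    if not mats:
        raise ValueError("no gene with nonzero body coverage")
    mat = pd.DataFrame(
        np.vstack(mats), index=pd.Index(ids, name="gene_id"),
        columns=np.arange(-half, half),
    )
    curve = scipy.stats.trim_mean(mat.to_numpy(), proportiontocut=trim, axis=0)
    return mat, curve


# ---------------------------------------------------------------------------
# Expression-matched gene-set comparison
# ---------------------------------------------------------------------------

def matched_set_compare(
    members: pd.Index,
    delta: pd.Series,
    expression: pd.Series,
    seed: int = 0,
    n_bins: int = 10,
) -> tuple[float, pd.Index]:
    """K-S on Delta RTS between a gene set and expression-matched controls.

    Controls are drawn 1:1 from non-members within the same expression
    decile (seeded sampling with replacement only if a decile runs dry).
    """
    rng = np.random.default_rng(seed)
    pool = delta.dropna().index.intersection(expression.dropna().index)
    members = pd.Index(members).intersection(pool)
    if len(members) == 0:
        raise ValueError("empty member set")
    expr = expression.loc[pool]
    deciles = pd.Series(
        pd.qcut(expr.rank(method="first"), n_bins, labels=False), index=pool
    )
    nonmembers = pool.difference(members)
    controls: list[str] = []
    for d, msub in deciles.loc[members].groupby(deciles.loc[members]):
        cands = nonmembers.intersection(deciles.index[deciles == d])
        need = len(msub)
        if len(cands) == 0:
            continue
        take = rng.choice(len(cands), size=need, replace=len(cands) < need)
        controls.extend(cands[take])
    control_idx = pd.Index(controls)
    _, p = ks_two_sample(delta.loc[members].to_numpy(), delta.loc[control_idx].to_numpy())
    return p, control_idx
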