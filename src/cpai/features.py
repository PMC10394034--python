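"""Per-gene features and the individual/cumulative R^2 ranking.

Feature importance is the R^2 of a single-feature OLS of the per-gene
expression change (log2Ratio) on that feature; the cumulative R^2 of a
feature is the R^2 of the fit on the feature together with all features
ranking above it.  Ablation reports the drop of the all-feature R^2 when
named features are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel
from .stats import ols_r2

logger = logging.getLogger("cpai")


def gc_content(seq: str) -> float:
    seq = seq.upper()
    n = sum(seq.count(b) for b in "ACGT")
    if n == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / n


def gene_density(genes: list[GeneModel], window: int) -> pd.Series:
    """Number of gene bodies (including the gene itself) overlapping a
    window of the given width centered on each gene's body midpoint."""
    chroms = np.array([g.chrom for g in genes])
    lo = np.array([g.body_start for g in genes])
    hi = np.array([g.body_end for g in genes])
    out = []
    for g in genes:
        mid = (g.body_start + g.body_end) // 2
        wlo, whi = mid - window // 2, mid + window // 2
        out.append(int(((chroms == g.chrom) & (lo < whi) & (hi > wlo)).sum()))
    return pd.Series(out, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def compute_features(
    genes: list[GeneModel],
    genome,
    pas: pd.DataFrame,
    stability: pd.DataFrame | None = None,
    delta_rts: pd.Series | None = None,
    distance_to_nng: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene feature table.

    ``genome`` is any mapping whose ``genome[chrom][start:end]`` slice
    stringifies to sequence (a dict of strings or a pyfaidx Fasta).  Genes
    with any undefined feature are dropped listwise (count logged).
    """
    idx = pd.Index([g.gene_id for g in genes], name="gene_id")
    n_pas = pas.groupby("gene_id").size()
    rows = {}
    rows["gc_content"] = [
        gc_content(str(genome[g.chrom][g.body_start:g.body_end])) for g in genes
    ]
    rows["gene_size"] = [g.body_length for g in genes]
    rows["total_intron_size"] = [sum(e - s for s, e in g.introns) for g in genes]
    rows["largest_intron"] = [
        max((e - s for s, e in g.introns), default=0) for g in genes
    ]
    feats = pd.DataFrame(rows, index=idx)
    feats["gene_density_100kb"] = gene_density(genes, 100_000)
    feats["gene_density_1mb"] = gene_density(genes, 1_000_000)
    feats["n_pas"] = n_pas.reindex(idx).fillna(0).astype(int)
    if stability is not None:
        stab = stability.set_index("gene_id")["stability_score"] \
            if "gene_id" in stability.columns else stability["stability_score"]
        feats["stability_score"] = stab.reindex(idx)
    if delta_rts is not None:
        feats["delta_rts"] = delta_rts.reindex(idx)
    if distance_to_nng is not None:
        feats["distance_to_nng"] = distance_to_nng.reindex(idx)
    n_before = len(feats)
    feats = feats.dropna()
    if len(feats) < n_before:
        logger.info("dropped %d genes with undefined features", n_before - len(feats))
    return feats


@dataclass
class RegressionReport:
    """Per-feature individual R^2, correlation sign and cumulative R^2,
    sorted by individual R^2 descending, plus the all-feature R^2."""

    table: pd.DataFrame
    overall_r2: float


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def rank_features(y, X: pd.DataFrame) -> RegressionReport:
    """Rank features by single-feature R^2; cumulative R^2 of the k-th
    ranked feature uses the top-k features jointly (z-scored for
    conditioning; R^2 is unaffected by affine feature rescaling)."""
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xz = _zscore(X.to_numpy(dtype=float))
    indiv, signs = [], []
    for j in range(Xz.shape[1]):
        beta, r2 = ols_r2(y, Xz[:, [j]])
        indiv.append(r2)
        signs.append(int(np.sign(beta[1])) if beta[1] != 0 else 0)
    order = np.argsort(indiv, kind="stable")[::-1]
    cumulative = []
    for k in range(1, len(order) + 1):
        _, r2 = ols_r2(y, Xz[:, order[:k]])
        cumulative.append(r2)
    _, overall = ols_r2(y, Xz)
    table = pd.DataFrame(
        {
            "feature": [names[j] for j in order],
            "individual_r2": [indiv[j] for j in order],
            "sign": [signs[j] for j in order],
            "cumulative_r2": cumulative,
        }
    ).set_index("feature")
    return RegressionReport(table, overall)


def ablate(y, X: pd.DataFrame, drop: list[str]) -> float:
    """Drop of the all-feature R^2 when the named features are removed
    (non-negative by OLS nesting)."""
    y = np.asarray(y, dtype=float)
    missing = set(drop) - set(X.columns)
    if missing:
        raise KeyError(f"unknown features: {sorted(missing)}")
    _, full = ols_r2(y, _zscore(X.to_numpy(dtype=float)))
    kept = [c for c in X.columns if c not in set(drop)]
    if kept:
        _, reduced = ols_r2(y, _zscore(X[kept].to_numpy(dtype=float)))
    else:
        reduced = 0.0
    return max(full - reduced, 0.0)
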