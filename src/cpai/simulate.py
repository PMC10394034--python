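"""Synthetic data generator with known ground truth.

Emulates the statistical structure of the study inputs the pipeline
consumes: a gene annotation laid out on one synthetic chromosome with
configurable neighbor arrangements, per-gene polyadenylation-site (PAS)
annotations, chromatin (nascent) RNA-seq alignments with configurable
per-gene readthrough fractions, QuantSeq-style 3'-end reads with terminal
A-runs and PAS-jittered last-aligned positions (LAPs), per-gene RNA
stability scores linear in GC content, and per-cell reporter fluorescence.

Counts are Poisson throughout.  Every read is confined to the compartment
that generated it (gene body, downstream readthrough window, or the
penetration of that window into a neighbor's body), so a readthrough
fraction of zero yields exactly zero signal past the last PAS and the
expected downstream/body density ratio equals the configured fraction.
Readthrough reads entering a convergent partner's body *are* the antisense
collision signal, and those crossing a tandem pair's gap *are* the
intervening read-in signal; no separate noise tracks are injected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ALIGNMENT_COLUMNS,
    GeneModel,
    write_alignments,
    write_gtf,
    write_pas_table,
    write_score_table,
)

CONDITIONS = ("control", "treated")


@dataclass
class SimConfig:
    """Knobs of the generator.  Scalar per-gene parameters may also be
    given as sequences of length ``n_genes``."""

    n_genes: int = 100
    seed: int = 0
    genome_length: int | None = None          # computed from layout if None
    gene_span: tuple[int, int] = (3000, 8000)  # genomic span per gene (nt)
    n_exons: tuple[int, int] = (1, 3)
    intergenic_gap: int = 12000                # gap between unpaired genes
    margin: int = 6000                         # exceeds the readthrough window
    #: forced neighbor arrangements, e.g. (("convergent", 800), ("tandem", 1500));
    #: each entry consumes the next two genes and fixes their facing-end gap
    pair_layout: tuple = ()
    # expression & differential effects
    expression_rate: float = 200.0             # expected gene-body reads, control
    expression_sigma: float = 0.75             # lognormal spread across genes
    de_effect_fraction: float = 0.0            # fraction of genes with planted fold
    de_effect_fold: float = 2.0                # fold applied (up or down, 50/50)
    # readthrough
    readthrough_control: float | tuple = 0.05  # r = downstream/body density
    readthrough_treated: float | tuple = 0.5
    readthrough_window: int = 4000
    antisense_leak: float = 1.0                # attenuation inside a partner body
    # PAS structure and usage
    utr3_pas_range: tuple[int, int] = (1, 3)
    p_intronic_pas: float = 0.3
    autr_range: tuple[int, int] = (300, 2000)  # pPAS-dPAS spacing
    usage_control: tuple | None = None         # fixed 5'->3' 3'UTR usage vector
    usage_treated: tuple | None = None
    distal_shift: float = 0.25                 # treated mass moved pPAS -> dPAS
    ipa_fraction: float = 0.15                 # intronic PAS usage share
    ipa_fold_treated: float = 1.0
    # 3'-end reads
    lap_jitter_sd: float = 8.0
    lap_jitter_max: int = 24
    polya_len: int = 18
    polya_read_fraction: float = 1.0
    decoy_fraction: float = 0.0                # internal-priming LAPs >24 nt from any PAS
    lowmapq_fraction: float = 0.0
    read_len_chr: int = 100
    read_len_3p: int = 50
    background_rate: float = 0.0               # intergenic reads per nt per strand
    # sequence & stability
    gc_range: tuple[float, float] = (0.35, 0.65)
    stability_slope: float = 8.0
    stability_sd: float = 1.0
    with_sequence: bool = True


@dataclass
class TruthTable:
    """Ground truth written alongside every simulated dataset."""

    genes: pd.DataFrame   # per-gene expression, readthrough, GC, stability ...
    pas: pd.DataFrame     # per-PAS usage per condition
    pairs: pd.DataFrame   # forced neighbor arrangements

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="list"),
            "pas": self.pas.to_dict(orient="list"),
            "pairs": self.pairs.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SimData:
    config: SimConfig
    genes: list[GeneModel]
    pas: pd.DataFrame
    truth: TruthTable
    genome: dict[str, str] | None
    chrom_lengths: dict[str, int]

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}


def _per_gene(value, n: int, rng=None) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if len(arr) != n:
        raise ValueError(f"per-gene parameter of length {len(arr)} != n_genes={n}")
    return arr


# ---------------------------------------------------------------------------
# Genome / annotation
# ---------------------------------------------------------------------------

def _usage_vectors(cfg: SimConfig, n_utr3: int, has_ipa: bool, rng) -> tuple[np.ndarray, np.ndarray]:
    """(control, treated) usage over [utr3 PASs 5'->3'] + [intronic] if present."""
    if cfg.usage_control is not None and len(cfg.usage_control) == n_utr3:
        u_c = np.asarray(cfg.usage_control, dtype=float)
    else:
        # proximal-dominant baseline usage
        alpha = np.arange(n_utr3, 0, -1, dtype=float) + 1.0
        u_c = rng.dirichlet(alpha)
    if cfg.usage_treated is not None and len(cfg.usage_treated) == n_utr3:
        u_t = np.asarray(cfg.usage_treated, dtype=float)
    else:
        u_t = u_c.copy()
        if n_utr3 >= 2:
            shift = min(cfg.distal_shift, max(u_t[0] - 0.05, 0.0))
            u_t[0] -= shift
            u_t[-1] += shift
    u_c = u_c / u_c.sum()
    u_t = u_t / u_t.sum()
    if has_ipa:
        ic, it = cfg.ipa_fraction, min(cfg.ipa_fraction * cfg.ipa_fold_treated, 0.9)
        u_c = np.append(u_c * (1 - ic), ic)
        u_t = np.append(u_t * (1 - it), it)
    return u_c, u_t


def simulate_genome(config: SimConfig) -> SimData:
    """Lay out genes, PASs, sequence and ground truth; deterministic in seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    chrom = "chrS"

    # -- strands and layout ------------------------------------------------
    spans = rng.integers(cfg.gene_span[0], cfg.gene_span[1] + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    starts = np.zeros(n, dtype=np.int64)
    cursor = cfg.margin
    gi = 0
    pair_rows = []
    for orientation, gap in cfg.pair_layout:
        if gi + 1 >= n:
            raise ValueError(f"pair_layout needs gene {gi + 1} but n_genes={n}")
        la, lb = int(spans[gi]), int(spans[gi + 1])
        if orientation == "convergent":       # tail-to-tail: + then -
            strands[gi], strands[gi + 1] = "+", "-"
            starts[gi] = cursor
            # facing body ends: A body end = start+la-1; B body start = B.last_pas
            starts[gi + 1] = cursor + la - 1 + gap
        elif orientation == "tandem":         # head-to-tail, same strand (+)
            strands[gi], strands[gi + 1] = "+", "+"
            starts[gi] = cursor
            starts[gi + 1] = cursor + la - 1 + gap
        elif orientation == "divergent":      # head-to-head: - then +
            strands[gi], strands[gi + 1] = "-", "+"
            starts[gi] = cursor
            starts[gi + 1] = cursor + la + gap
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        pair_rows.append((f"g{gi:05d}", f"g{gi + 1:05d}", orientation, int(gap)))
        cursor = int(starts[gi + 1]) + lb + cfg.intergenic_gap
        gi += 2
    while gi < n:
        starts[gi] = cursor
        cursor += int(spans[gi]) + cfg.intergenic_gap
        gi += 1
    genome_length = cursor + cfg.margin
    if cfg.genome_length is not None:
        if cfg.genome_length < genome_length:
            first_bad = int(np.argmax(starts + spans + cfg.margin > cfg.genome_length))
            raise ValueError(
                f"genome_length={cfg.genome_length} cannot place gene g{first_bad:05d}"
            )
        genome_length = cfg.genome_length

    # -- per-gene structure, PASs, truth ------------------------------------
    expr_c = _per_gene(cfg.expression_rate, n) * rng.lognormal(0.0, cfg.expression_sigma, n)
    de_fold = np.ones(n)
    if cfg.de_effect_fraction > 0:
        hit = rng.random(n) < cfg.de_effect_fraction
        up = rng.random(n) < 0.5
        de_fold = np.where(hit, np.where(up, cfg.de_effect_fold, 1.0 / cfg.de_effect_fold), 1.0)
    expr_t = expr_c * de_fold
    r_c = np.clip(_per_gene(cfg.readthrough_control, n), 0.0, None)
    r_t = np.clip(_per_gene(cfg.readthrough_treated, n), 0.0, None)
    gc = rng.uniform(cfg.gc_range[0], cfg.gc_range[1], size=n)
    stability = cfg.stability_slope * (gc - 0.5) + rng.normal(0.0, cfg.stability_sd, n)

    genes: list[GeneModel] = []
    pas_rows, truth_pas_rows, gene_rows = [], [], []
    for i in range(n):
        gene_id = f"g{i:05d}"
        s, span, strand = int(starts[i]), int(spans[i]), str(strands[i])
        e = s + span
        # exon structure in genomic coordinates; last exon >= autr_max + 500
        n_ex = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
        last_exon_min = min(cfg.autr_range[1] + 500, span - 200 * (n_ex - 1) - 100)
        last_exon_min = max(last_exon_min, min(500, span // 2))
        exons, introns = [], []
        if n_ex == 1 or span < last_exon_min + 600 * (n_ex - 1):
            exons = [(s, e)]
        else:
            # split the 5' part into n_ex-1 exons with introns between
            five_len = span - last_exon_min
            cuts = np.sort(rng.integers(200, five_len - 200, size=2 * (n_ex - 1) - 1))
            bounds = [0, *cuts.tolist(), five_len]
            segs = [(bounds[j], bounds[j + 1]) for j in range(len(bounds) - 1)]
            rel_exons = segs[0::2] + [(five_len, span)]
            rel_introns = segs[1::2]
            if strand == "+":
                exons = [(s + a, s + b) for a, b in rel_exons]
                introns = [(s + a, s + b) for a, b in rel_introns]
            else:  # mirror so the last exon is at the 5' genomic side
                exons = [(e - b, e - a) for a, b in rel_exons][::-1]
                introns = [(e - b, e - a) for a, b in rel_introns][::-1]
            exons = [(a, b) for a, b in exons if b > a]
            introns = [(a, b) for a, b in introns if b > a]
        if not exons:
            exons = [(s, e)]

        # 3'UTR PASs in the last exon; last PAS at the 3' terminus of the span
        n_utr3 = int(rng.integers(cfg.utr3_pas_range[0], cfg.utr3_pas_range[1] + 1))
        last_exon = exons[-1] if strand == "+" else exons[0]
        exon_len = last_exon[1] - last_exon[0]
        n_utr3 = max(1, min(n_utr3, 1 + (exon_len - 200) // (cfg.autr_range[0] + 60)))
        offsets = [0]
        for _ in range(n_utr3 - 1):
            lo, hi = cfg.autr_range
            hi = min(hi, exon_len - 100 - offsets[-1] - lo)
            step = int(rng.integers(lo, max(lo + 1, hi + 1)))
            offsets.append(offsets[-1] + step)
        offsets = offsets[::-1]  # 5'-most first
        if strand == "+":
            utr3_pos = [e - 1 - off for off in offsets]
        else:
            utr3_pos = [s + off for off in offsets]
        has_ipa = bool(introns) and rng.random() < cfg.p_intronic_pas
        pas_positions = list(utr3_pos)
        pas_classes = ["terminal_exon" if n_utr3 == 1 else "utr3"] * n_utr3
        if n_utr3 > 1:
            pas_classes = ["utr3"] * n_utr3
        if has_ipa:
            intr = introns[0] if strand == "+" else introns[-1]
            ipa_pos = int((intr[0] + intr[1]) // 2)
            pas_positions.append(ipa_pos)
            pas_classes.append("intronic")
        u_c, u_t = _usage_vectors(cfg, n_utr3, has_ipa, rng)

        pas_ids = []
        for k, (pos, cls) in enumerate(zip(pas_positions, pas_classes)):
            pid = f"{gene_id}.p{k}"
            pas_ids.append(pid)
            pas_rows.append((pid, gene_id, chrom, strand, int(pos), cls))
            truth_pas_rows.append((pid, gene_id, int(pos), cls, float(u_c[k]), float(u_t[k])))

        last_pas = int(e - 1 if strand == "+" else s)
        tss = int(s if strand == "+" else e - 1)
        # order pas_ids 5'->3' in transcript direction
        order = np.argsort([p if strand == "+" else -p for p in pas_positions], kind="stable")
        genes.append(
            GeneModel(gene_id, chrom, strand, tss, last_pas, exons,
                      [pas_ids[j] for j in order])
        )
        gene_rows.append(
            (gene_id, chrom, strand, tss, last_pas, min(tss, last_pas),
             max(tss, last_pas), float(expr_c[i]), float(expr_t[i]),
             float(r_c[i]), float(r_t[i]), float(de_fold[i]), float(gc[i]),
             float(stability[i]))
        )

    pas_df = pd.DataFrame(
        pas_rows, columns=["pas_id", "gene_id", "chrom", "strand", "position", "location_class"]
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "chrom", "strand", "tss", "last_pas", "body_start",
                     "body_end", "expression_control", "expression_treated",
                     "r_control", "r_treated", "de_fold", "gc", "stability"],
        ),
        pas=pd.DataFrame(
            truth_pas_rows,
            columns=["pas_id", "gene_id", "position", "location_class",
                     "usage_control", "usage_treated"],
        ),
        pairs=pd.DataFrame(pair_rows, columns=["a_id", "b_id", "orientation", "gap"]),
    )

    genome = None
    if cfg.with_sequence:
        seq = np.empty(genome_length, dtype="U1")
        bases = np.array(list("ACGT"))
        bg = rng.choice(4, size=genome_length, p=[0.25, 0.25, 0.25, 0.25])
        seq[:] = bases[bg]
        for i, g in enumerate(genes):
            lo = min(g.exons[0][0], g.body_start)
            hi = max(g.exons[-1][1], g.body_end)
            p_gc = gc[i] / 2
            p = [(1 - gc[i]) / 2, p_gc, p_gc, (1 - gc[i]) / 2]
            seq[lo:hi] = bases[rng.choice(4, size=hi - lo, p=p)]
        genome = {chrom: "".join(seq)}

    return SimData(cfg, genes, pas_df, truth, genome, {chrom: genome_length})


# ---------------------------------------------------------------------------
# chrRNA-seq reads
# ---------------------------------------------------------------------------

def _uniform_reads(rng, lo: int, hi: int, rate_per_nt: float, read_len: int):
    """Poisson number of reads fully contained in [lo, hi) at the given
    per-nt read rate; returns (starts, ends)."""
    length = hi - lo
    if length <= 0 or rate_per_nt <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    n = rng.poisson(rate_per_nt * length)
    if n == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rl = min(read_len, length)
    starts = rng.integers(lo, hi - rl + 1, size=n)
    return starts, starts + rl


def simulate_chr_reads(
    sim: SimData, condition: str, depth_scale: float = 1.0, seed: int | None = None
) -> pd.DataFrame:
    """Simulate strand-resolved chromatin RNA-seq alignments.

    Gene bodies receive uniform reads at a rate proportional to expression;
    the downstream readthrough window receives rate x r(condition), with
    the ``antisense_leak`` attenuation applied wherever the window runs
    inside another gene's body.
    """
    cfg = sim.config
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if seed is None:
        seed = cfg.seed + 104729 + 15485863 * CONDITIONS.index(condition)
    rng = np.random.default_rng(seed)
    tg = sim.truth.genes
    expr = tg[f"expression_{condition}"].to_numpy() * depth_scale
    r = tg[f"r_{condition}"].to_numpy()
    body_lo = tg["body_start"].to_numpy()
    body_hi = tg["body_end"].to_numpy()
    # sorted body intervals for leak segmentation
    order = np.argsort(body_lo)
    sb_lo, sb_hi = body_lo[order], body_hi[order]

    chrom = sim.genes[0].chrom if sim.genes else "chrS"
    chrom_len = sim.chrom_lengths[chrom]
    all_starts, all_ends, all_strands = [], [], []
    for i, g in enumerate(sim.genes):
        lam = expr[i] / g.body_length  # reads per nt
        s, e = _uniform_reads(rng, g.body_start, g.body_end, lam, cfg.read_len_chr)
        all_starts.append(s); all_ends.append(e)
        all_strands.append(np.full(len(s), g.strand, dtype=object))
        if r[i] <= 0:
            continue
        wlo, whi = g.downstream_window(cfg.readthrough_window)
        wlo, whi = max(0, wlo), min(chrom_len, whi)
        if whi <= wlo:
            continue
        # split the window at other gene bodies to apply the leak factor
        cuts = {wlo, whi}
        jlo = np.searchsorted(sb_hi, wlo, side="right") - 2
        for j in range(max(0, jlo), len(sb_lo)):
            if sb_lo[j] >= whi:
                break
            a, b = max(sb_lo[j], wlo), min(sb_hi[j], whi)
            if b > a and not (sb_lo[j] == body_lo[i] and sb_hi[j] == body_hi[i]):
                cuts.update((int(a), int(b)))
        cuts = sorted(cuts)
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = (a + b) // 2
            inside = np.any((sb_lo <= mid) & (sb_hi > mid) & ~((sb_lo == body_lo[i]) & (sb_hi == body_hi[i])))
            rate = lam * r[i] * (cfg.antisense_leak if inside else 1.0)
            s, e = _uniform_reads(rng, a, b, rate, cfg.read_len_chr)
            all_starts.append(s); all_ends.append(e)
            all_strands.append(np.full(len(s), g.strand, dtype=object))
    if cfg.background_rate > 0:
        for strand in "+-":
            s, e = _uniform_reads(rng, 0, chrom_len, cfg.background_rate * depth_scale,
                                  cfg.read_len_chr)
            all_starts.append(s); all_ends.append(e)
            all_strands.append(np.full(len(s), strand, dtype=object))

    starts = np.concatenate(all_starts) if all_starts else np.empty(0, np.int64)
    ends = np.concatenate(all_ends) if all_ends else np.empty(0, np.int64)
    strands = np.concatenate(all_strands) if all_strands else np.empty(0, object)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "read_id": np.char.add(f"{condition[0]}c", np.arange(len(starts)).astype(str)),
            "mapq": np.int64(60),
            "strand": strands,
            "lap": np.nan,
        }
    )
    return df.sort_values("start", kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# 3'-end (QuantSeq-style) reads
# ---------------------------------------------------------------------------

@dataclass
class ThreePrimeReads:
    alignments: pd.DataFrame        # with lap column filled
    true_pas: pd.Series             # read_id -> pas_id ("" for decoys)
    fastq: list | None = None       # Bio.SeqRecord list when sequences requested


def _decoy_positions(gene: GeneModel, pas_positions: np.ndarray, margin: int) -> np.ndarray:
    pos = np.arange(gene.body_start, gene.body_end)
    if len(pas_positions):
        dist = np.min(np.abs(pos[:, None] - pas_positions[None, :]), axis=1)
        pos = pos[dist > margin]
    return pos


def simulate_3p_reads(
    sim: SimData,
    condition: str,
    depth_scale: float = 1.0,
    seed: int | None = None,
    sequences: bool = False,
) -> ThreePrimeReads:
    """Simulate 3'-end reads: one annotated PAS drawn per read from the
    condition's usage vector, LAP = PAS position + truncated Gaussian
    jitter; a ``decoy_fraction`` of internal-priming reads get LAPs more
    than ``lap_jitter_max`` nt from every PAS."""
    cfg = sim.config
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if seed is None:
        seed = cfg.seed + 224737 + 32452843 * CONDITIONS.index(condition)
    rng = np.random.default_rng(seed)
    usage_col = f"usage_{condition}"
    tg = sim.truth.genes
    expr = tg[f"expression_{condition}"].to_numpy() * depth_scale
    pas_by_gene = dict(tuple(sim.truth.pas.groupby("gene_id", sort=False)))
    all_pas_pos = np.sort(sim.pas["position"].to_numpy())

    rows_start, rows_end, rows_lap, rows_strand, rows_true = [], [], [], [], []
    chrom = sim.genes[0].chrom if sim.genes else "chrS"
    rl = cfg.read_len_3p
    for i, g in enumerate(sim.genes):
        n = rng.poisson(expr[i])
        if n == 0:
            continue
        psub = pas_by_gene[g.gene_id]
        usage = psub[usage_col].to_numpy()
        if not np.isfinite(usage).all() or usage.sum() <= 0:
            raise ValueError(f"usage vector undefined for {g.gene_id}/{condition}")
        usage = usage / usage.sum()
        n_decoy = rng.binomial(n, cfg.decoy_fraction) if cfg.decoy_fraction > 0 else 0
        n_true = n - n_decoy
        pick = rng.choice(len(psub), size=n_true, p=usage)
        jit = np.clip(
            np.rint(rng.normal(0.0, cfg.lap_jitter_sd, size=n_true)),
            -cfg.lap_jitter_max, cfg.lap_jitter_max,
        ).astype(np.int64)
        laps = psub["position"].to_numpy()[pick] + jit
        true_ids = psub["pas_id"].to_numpy()[pick]
        if n_decoy:
            allowed = _decoy_positions(g, all_pas_pos, cfg.lap_jitter_max + 1)
            if len(allowed) == 0:
                n_decoy = 0
            else:
                dl = rng.choice(allowed, size=n_decoy)
                laps = np.concatenate([laps, dl])
                true_ids = np.concatenate([true_ids, np.array([""] * n_decoy, dtype=object)])
        m = len(laps)
        if g.strand == "+":
            starts, ends = laps - rl + 1, laps + 1
        else:
            starts, ends = laps, laps + rl
        rows_start.append(np.clip(starts, 0, None))
        rows_end.append(ends)
        rows_lap.append(laps)
        rows_strand.append(np.full(m, g.strand, dtype=object))
        rows_true.append(true_ids)

    if rows_start:
        starts = np.concatenate(rows_start)
        ends = np.concatenate(rows_end)
        laps = np.concatenate(rows_lap)
        strands = np.concatenate(rows_strand)
        true_ids = np.concatenate(rows_true)
    else:
        starts = ends = laps = np.empty(0, np.int64)
        strands = true_ids = np.empty(0, object)
    n_reads = len(starts)
    mapq = np.full(n_reads, 60, dtype=np.int64)
    if cfg.lowmapq_fraction > 0:
        mapq[rng.random(n_reads) < cfg.lowmapq_fraction] = 5
    read_ids = pd.Index([f"{condition[0]}p{j}" for j in range(n_reads)])
    aln = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "read_id": read_ids,
            "mapq": mapq,
            "strand": strands,
            "lap": laps.astype(float),
        }
    )
    true_pas = pd.Series(true_ids, index=read_ids, name="true_pas")

    fastq = None
    if sequences:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        if sim.genome is None:
            raise ValueError("sequences=True requires with_sequence=True genome")
        seq = sim.genome[chrom]
        has_tail = rng.random(n_reads) < cfg.polya_read_fraction
        fastq = []
        for j in range(n_reads):
            s, e = int(aln["start"].iloc[j]), int(aln["end"].iloc[j])
            body = seq[s:e]
            if strands[j] == "-":
                body = str(Seq(body).reverse_complement())
            tail = "A" * cfg.polya_len if has_tail[j] else "G" * 2
            full = body + tail
            rec = SeqRecord(Seq(full), id=str(read_ids[j]), description="")
            rec.letter_annotations["phred_quality"] = [35] * len(full)
            fastq.append(rec)
    return ThreePrimeReads(aln, true_pas, fastq)


# ---------------------------------------------------------------------------
# Reporter fluorescence
# ---------------------------------------------------------------------------

def simulate_reporter(
    long_fractions: dict[str, float],
    n_cells: int,
    noise_cv: float = 0.2,
    seed: int = 0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Per-cell (red, green) fluorescence for a two-color APA reporter.

    Green scales with the long-isoform fraction, red with total output;
    both share a lognormal cell-size factor and carry independent
    multiplicative lognormal noise with the given CV (median 1, so
    log-ratios are unbiased).  The control construct lacking the proximal
    PAS has long fraction 1.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    conds = dict(long_fractions)
    if include_control:
        conds["__control__"] = 1.0
    rows = []
    for label, frac in conds.items():
        if not (0 < frac <= 1):
            raise ValueError(f"long fraction must be in (0, 1], got {frac} for {label}")
        construct = "control_no_pPAS" if label == "__control__" else "test"
        condition = "control" if label == "__control__" else label
        size = rng.lognormal(0.0, 0.4, size=n_cells)
        red = size * rng.lognormal(0.0, sigma, size=n_cells)
        green = frac * size * rng.lognormal(0.0, sigma, size=n_cells)
        for j in range(n_cells):
            rows.append((f"{condition}:{construct}:{j}", condition, construct,
                         float(red[j]), float(green[j])))
    return pd.DataFrame(rows, columns=["cell_id", "condition", "construct", "red", "green"])


# ---------------------------------------------------------------------------
# Lightweight feature-table generator (no sequence needed)
# ---------------------------------------------------------------------------

def simulate_feature_table(
    n_genes: int,
    seed: int = 0,
    r2_targets: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-gene feature matrix with realistic scales plus a response whose
    variance decomposes into the requested per-feature R^2 contributions
    (independent latent components; remaining variance is Gaussian noise).
    """
    rng = np.random.default_rng(seed)
    r2 = dict(r2_targets or {})
    if sum(r2.values()) > 1:
        raise ValueError("sum of target R^2 exceeds 1")
    z = {}
    z["gc_content"] = rng.normal(size=n_genes)
    z["stability_score"] = 0.5 * z["gc_content"] + np.sqrt(1 - 0.25) * rng.normal(size=n_genes)
    z["gene_size"] = rng.normal(size=n_genes)
    z["total_intron_size"] = 0.8 * z["gene_size"] + 0.6 * rng.normal(size=n_genes)
    z["largest_intron"] = 0.7 * z["total_intron_size"] + 0.71 * rng.normal(size=n_genes)
    z["gene_density_100kb"] = rng.normal(size=n_genes)
    z["gene_density_1mb"] = 0.6 * z["gene_density_100kb"] + 0.8 * rng.normal(size=n_genes)
    z["n_pas"] = rng.normal(size=n_genes)
    z["delta_rts"] = rng.normal(size=n_genes)
    z["distance_to_nng"] = rng.normal(size=n_genes)
    y = np.zeros(n_genes)
    for name, target in r2.items():
        if name not in z:
            raise KeyError(f"unknown feature {name!r}")
        zz = (z[name] - z[name].mean()) / z[name].std()
        y += np.sqrt(target) * zz
    y += np.sqrt(max(1e-12, 1 - sum(r2.values()))) * rng.normal(size=n_genes)

    feats = pd.DataFrame(index=[f"g{i:05d}" for i in range(n_genes)])
    feats["gc_content"] = np.clip(0.5 + 0.08 * z["gc_content"], 0.25, 0.8)
    feats["gene_size"] = np.exp(9 + 0.9 * z["gene_size"]).astype(int)
    feats["total_intron_size"] = np.exp(8.5 + z["total_intron_size"]).astype(int)
    feats["largest_intron"] = np.exp(7.8 + z["largest_intron"]).astype(int)
    feats["gene_density_100kb"] = np.clip(np.rint(2.5 + z["gene_density_100kb"]), 1, None)
    feats["gene_density_1mb"] = np.clip(np.rint(12 + 4 * z["gene_density_1mb"]), 1, None)
    feats["n_pas"] = np.clip(np.rint(2.5 + z["n_pas"]), 1, 8)
    feats["stability_score"] = 2 * z["stability_score"]
    feats["delta_rts"] = 0.8 * z["delta_rts"] + 1.0
    feats["distance_to_nng"] = np.exp(9.5 + z["distance_to_nng"]).astype(int)
    feats.index.name = "gene_id"
    return feats, y


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def write_dataset(sim: SimData, outdir, depth_scale: float = 1.0) -> dict[str, str]:
    """Write the standard file bundle for one simulated experiment."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if sim.genome is not None:
        fa = out / "genome.fa"
        with open(fa, "w") as fh:
            for chrom, seq in sim.genome.items():
                fh.write(f">{chrom}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k:k + 80] + "\n")
        paths["genome"] = str(fa)
    write_gtf(sim.genes, out / "genes.gtf")
    paths["genes"] = str(out / "genes.gtf")
    write_pas_table(sim.pas, out / "pas.tsv")
    paths["pas"] = str(out / "pas.tsv")
    stab = sim.truth.genes[["gene_id", "stability"]].rename(columns={"stability": "stability_score"})
    write_score_table(stab, out / "stability.tsv")
    paths["stability"] = str(out / "stability.tsv")
    for condition in CONDITIONS:
        aln = simulate_chr_reads(sim, condition, depth_scale)
        p = out / f"{condition}.chr.aln.tsv"
        write_alignments(aln, p)
        paths[f"chr_{condition}"] = str(p)
        tp = simulate_3p_reads(sim, condition, depth_scale, sequences=sim.genome is not None)
        p = out / f"{condition}.3p.aln.tsv"
        write_alignments(tp.alignments, p)
        paths[f"3p_{condition}"] = str(p)
        if tp.fastq is not None:
            from Bio import SeqIO

            fq = out / f"{condition}.3p.fastq"
            SeqIO.write(tp.fastq, str(fq), "fastq")
            paths[f"fastq_{condition}"] = str(fq)
    sim.truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    return paths
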