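"""Domain types, coordinate conventions and interval/coverage primitives.

All genomic intervals are 0-based half-open internally.  GTF records
(1-based, closed) are converted on read and write; BED is native.  Strand
is ``+``/``-`` and always refers to the strand of the originating RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cpai")

#: columns of the alignment table (BED6-compatible prefix, plus ``lap``)
ALIGNMENT_COLUMNS = ["chrom", "start", "end", "read_id", "mapq", "strand", "lap"]

PAS_COLUMNS = ["pas_id", "gene_id", "chrom", "strand", "position", "location_class"]

LOCATION_CLASSES = {"utr3", "intronic", "terminal_exon"}
#: PAS classes that live in the 3'-terminal exon (TPA isoforms)
LAST_EXON_CLASSES = {"utr3", "terminal_exon"}


class ParseError(ValueError):
    """Raised for malformed annotation lines; carries the line number."""


@dataclass
class GeneModel:
    """One gene, reduced to its longest isoform.

    ``tss`` is the 5'-most transcribed position and ``last_pas`` the
    cleavage site of the 3'-most PAS, both in genomic coordinates — so
    ``tss > last_pas`` for minus-strand genes.  The gene body is the
    interval between the two.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    last_pas: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    pas_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"empty exon [{s},{e}) in {self.gene_id}")
        if self.body_length <= 0:
            raise ValueError(f"gene body of {self.gene_id} has length 0")

    # -- derived geometry ------------------------------------------------
    @property
    def body_start(self) -> int:
        return min(self.tss, self.last_pas)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.last_pas)

    @property
    def body_length(self) -> int:
        return self.body_end - self.body_start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def downstream_window(self, size: int = 4000) -> tuple[int, int]:
        """Half-open interval extending ``size`` nt 3' of the last PAS in
        transcript direction."""
        if self.strand == "+":
            return (self.body_end, self.body_end + size)
        return (self.body_start - size, self.body_start)

    def last_kb(self, size: int = 1000) -> tuple[int, int]:
        """The 3'-most ``size`` nt of the gene body (clipped to the body)."""
        size = min(size, self.body_length)
        if self.strand == "+":
            return (self.body_end - size, self.body_end)
        return (self.body_start, self.body_start + size)


@dataclass
class Sample:
    """Bookkeeping for one sequencing library."""

    sample_id: str
    condition: str  # "treated" | "control"
    dose_label: str = ""
    alignment_path: str | None = None
    total_mapped: int = 0


# ---------------------------------------------------------------------------
# Alignment tables and the interval index
# ---------------------------------------------------------------------------

def empty_alignments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "read_id": pd.Series(dtype=str),
            "mapq": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "lap": pd.Series(dtype=float),
        }
    )


def read_alignments(path) -> pd.DataFrame:
    """Read the 7-column tab-separated alignment table (``.`` = missing lap)."""
    df = pd.read_csv(
        path, sep="\t", names=ALIGNMENT_COLUMNS, header=0, na_values=["."],
        dtype={"chrom": str, "read_id": str, "strand": str},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["mapq"] = df["mapq"].astype(np.int64)
    df["lap"] = df["lap"].astype(float)
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).sum())
        raise ParseError(f"{bad} alignment(s) with start >= end in {path}")
    return df


def write_alignments(df: pd.DataFrame, path) -> None:
    out = df[ALIGNMENT_COLUMNS].copy()
    out["lap"] = out["lap"].map(lambda v: "." if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


class AlignmentIndex:
    """Per-(chrom, strand) start-sorted arrays supporting fast interval
    queries: overlap counting, clipped-overlap summing and coverage.

    The index keeps, for every (chrom, strand) bucket, starts sorted
    ascending plus the matching ends, and the maximum interval length —
    enough to restrict any query to a contiguous start-slice.
    """

    def __init__(self, alignments: pd.DataFrame):
        self.n_total = len(alignments)
        self._buckets: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, int]] = {}
        if self.n_total == 0:
            return
        for (chrom, strand), sub in alignments.groupby(["chrom", "strand"], sort=False):
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            max_len = int((ends - starts).max())
            self._buckets[(str(chrom), str(strand))] = (starts, ends, max_len)

    def _slice(self, chrom: str, strand: str, start: int, end: int):
        bucket = self._buckets.get((chrom, strand))
        if bucket is None:
            return None
        starts, ends, max_len = bucket
        lo = np.searchsorted(starts, start - max_len, side="left")
        hi = np.searchsorted(starts, end, side="left")
        s, e = starts[lo:hi], ends[lo:hi]
        keep = e > start
        return s[keep], e[keep]

    def overlapping(self, chrom: str, start: int, end: int, strand: str):
        """(starts, ends) of alignments overlapping [start, end) on strand."""
        sl = self._slice(chrom, strand, start, end)
        if sl is None:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        return sl

    def count(self, chrom: str, start: int, end: int, strand: str) -> int:
        return len(self.overlapping(chrom, start, end, strand)[0])

    def overlap_bases(self, chrom: str, start: int, end: int, strand: str) -> int:
        s, e = self.overlapping(chrom, start, end, strand)
        if len(s) == 0:
            return 0
        return int(np.sum(np.minimum(e, end) - np.maximum(s, start)))

    def coverage(self, chrom: str, start: int, end: int, strand: str) -> np.ndarray:
        """Per-base read coverage over [start, end) on the given strand."""
        length = end - start
        cov = np.zeros(length + 1, dtype=np.int64)
        s, e = self.overlapping(chrom, start, end, strand)
        if len(s):
            np.add.at(cov, np.clip(s - start, 0, length), 1)
            np.add.at(cov, np.clip(e - start, 0, length), -1)
        return np.cumsum(cov[:-1])


def region_density(
    alignments: "AlignmentIndex | pd.DataFrame",
    chrom: str,
    start: int,
    end: int,
    strand: str,
    mode: str = "overlap_bases",
) -> float:
    """Read density over a strand-resolved half-open region.

    ``overlap_bases`` returns summed clipped overlap lengths divided by the
    region length (coverage-like); ``read_count`` returns the number of
    alignments overlapping the region by >= 1 nt.
    """
    if end <= start:
        raise ValueError(f"region [{start},{end}) has non-positive length")
    if not isinstance(alignments, AlignmentIndex):
        alignments = AlignmentIndex(alignments)
    if mode == "overlap_bases":
        return alignments.overlap_bases(chrom, start, end, strand) / (end - start)
    if mode == "read_count":
        return float(alignments.count(chrom, start, end, strand))
    raise ValueError(f"unknown density mode {mode!r}")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_pas_table(path) -> pd.DataFrame:
    """Read a polyA_DB-style PAS table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"pas_id": str, "gene_id": str, "chrom": str})
    missing = set(PAS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"PAS table {path} missing columns: {sorted(missing)}")
    bad = ~df["location_class"].isin(LOCATION_CLASSES)
    if bad.any():
        raise ParseError(
            f"PAS table {path}: unknown location_class {df.loc[bad, 'location_class'].unique()}"
        )
    return df


def write_pas_table(df: pd.DataFrame, path) -> None:
    df[PAS_COLUMNS].to_csv(path, sep="\t", index=False)


def _isoform_exons_from_gtf(path) -> pd.DataFrame:
    import pyranges

    gr = pyranges.read_gtf(path)  # converts to 0-based half-open
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    exons = df[df["Feature"] == "exon"]
    if exons.empty:
        raise ParseError(f"no exon records in {path}")
    return pd.DataFrame(
        {
            "gene_id": exons["gene_id"].astype(str),
            "transcript_id": exons.get("transcript_id", exons["gene_id"]).astype(str),
            "chrom": exons["Chromosome"].astype(str),
            "start": exons["Start"].astype(np.int64),
            "end": exons["End"].astype(np.int64),
            "strand": exons["Strand"].astype(str),
        }
    )


def _isoform_exons_from_bed12(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{i}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom, start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
            gene_id = name.split("|")[0]
            for sz, off in zip(sizes, offsets):
                rows.append((gene_id, name, chrom, start + off, start + off + sz, strand))
    if not rows:
        raise ParseError(f"no records in {path}")
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand"]
    )


def read_gene_models(path, pas_table: pd.DataFrame | None = None) -> list[GeneModel]:
    """Build :class:`GeneModel` objects from a GTF or BED12 annotation.

    When a gene has several isoforms the longest (summed exon length,
    genomic span as tie-break) is retained.  ``last_pas`` is the 3'-most
    PAS of the gene in transcript direction when a PAS table is given;
    otherwise the annotated 3' end stands in for it.
    """
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        exons = _isoform_exons_from_bed12(path)
    else:
        exons = _isoform_exons_from_gtf(path)

    pas_by_gene: dict[str, pd.DataFrame] = {}
    if pas_table is not None:
        pas_by_gene = {g: sub for g, sub in pas_table.groupby("gene_id")}

    genes: list[GeneModel] = []
    for gene_id, gsub in exons.groupby("gene_id", sort=True):
        # longest isoform wins
        best_tx, best_key = None, (-1, -1)
        for tx, tsub in gsub.groupby("transcript_id"):
            key = (int((tsub["end"] - tsub["start"]).sum()),
                   int(tsub["end"].max() - tsub["start"].min()))
            if key > best_key:
                best_key, best_tx = key, tsub
        tsub = best_tx
        if tsub is None or tsub.empty:
            logger.warning("gene %s has zero exons; skipped", gene_id)
            continue
        chrom = str(tsub["chrom"].iloc[0])
        strand = str(tsub["strand"].iloc[0])
        ex = sorted(zip(tsub["start"].astype(int), tsub["end"].astype(int)))
        span_lo, span_hi = ex[0][0], ex[-1][1]
        tss = span_lo if strand == "+" else span_hi - 1
        pas_ids: list[str] = []
        if gene_id in pas_by_gene:
            psub = pas_by_gene[gene_id].sort_values(
                "position", ascending=(strand == "+"), kind="stable"
            )
            pas_ids = list(psub["pas_id"])  # 5' -> 3' in transcript direction
            last_pas = int(psub["position"].iloc[-1])
        else:
            last_pas = span_hi - 1 if strand == "+" else span_lo
        genes.append(GeneModel(gene_id, chrom, strand, tss, last_pas, ex, pas_ids))
    return genes


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write gene + exon records (Ensembl dialect, 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            span_lo = min(g.exons[0][0], g.body_start)
            span_hi = max(g.exons[-1][1], g.body_end)
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tcpai\tgene\t{span_lo + 1}\t{span_hi}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for (s, e) in g.exons:
                fh.write(
                    f"{g.chrom}\tcpai\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f'{attrs} transcript_id "{g.gene_id}.t1";\n'
                )


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def write_score_table(df: pd.DataFrame, path, key: str = "gene_id") -> None:
    """Write a per-gene score table as TSV; NaN serialized as ``NA``."""
    if key in df.columns and df[key].duplicated().any():
        dups = df.loc[df[key].duplicated(), key].unique()
        raise ValueError(f"duplicate {key} in score table: {dups[:5]}")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
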