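"""Domain types, coordinate conventions, interval arithmetic, and file I/O.

All genomic coordinates are held internally as 0-based half-open intervals
(``[start, end)``), the BED convention. Conversions to and from 1-based
inclusive coordinates (GTF/GFF3, bedGraph is already 0-based) happen only
inside the readers and writers in this module, so the rest of the package
never sees more than one convention.

Chromosome names are matched by exact string equality; no "chr" prefix
normalization is performed (an alias map can be applied by the caller).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger("itgscan")

VALID_STRANDS = ("+", "-", ".")

# messages that should be emitted at most once per process
_once_messages: set[str] = set()


def _log_once(msg: str) -> None:
    if msg not in _once_messages:
        _once_messages.add(msg)
        logger.warning(msg)


class ParseError(ValueError):
    """Raised when an input file is malformed; names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    source_class: str = "genic"  # "genic" or "itg"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its exon chain.

    Exons are sorted by start, pairwise non-overlapping, and all share the
    transcript's chromosome and strand; the transcript interval spans exactly
    min(exon start)..max(exon end).
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {ex} not on transcript chrom/strand"
                )
            if ex.start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = ex.end
        if (
            self.interval.start != self.exons[0].start
            or self.interval.end != self.exons[-1].end
        ):
            raise ValueError(
                f"{self.transcript_id}: interval does not span exon chain"
            )

    @property
    def exonic_length(self) -> int:
        """Summed exon length in bp (the transcript's mature length)."""
        return sum(ex.length for ex in self.exons)


@dataclass(frozen=True)
class TERecord:
    te_id: str
    family: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"{self.te_id}: empty TE family")


@dataclass(frozen=True)
class PeakRecord:
    mark: str
    replicate: int
    interval: GenomicInterval
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.score < 0:
            raise ValueError(f"negative peak score: {self.score}")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.align_length < 1:
            raise ValueError(f"align_length must be >= 1, got {self.align_length}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value: {self.e_value}")


@dataclass(frozen=True)
class BedFeature:
    """One BED line: interval plus the optional name/score columns."""

    interval: GenomicInterval
    name: str | None = None
    score: float | None = None


class CoverageTrack:
    """A sparse per-chromosome step function of non-negative coverage.

    Steps within a chromosome are non-overlapping and sorted; positions not
    covered by any step have value 0.
    """

    def __init__(self, steps: dict[str, list[tuple[int, int, float]]]):
        self.steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, chunks in steps.items():
            chunks = sorted(chunks)
            starts = np.array([c[0] for c in chunks], dtype=np.int64)
            ends = np.array([c[1] for c in chunks], dtype=np.int64)
            values = np.array([c[2] for c in chunks], dtype=float)
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"{chrom}: overlapping coverage steps")
            if np.any(values < 0) or not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: coverage values must be finite and >= 0")
            self.steps[chrom] = (starts, ends, values)

    def mean_value(self, chrom: str, start: int, end: int) -> float:
        """Mean coverage over ``[start, end)``; uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self.steps:
            return 0.0
        starts, ends, values = self.steps[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]) / (end - start))

    def genome_mean(self) -> float:
        """Integral of coverage divided by total extent ``[0, max end)`` per chrom."""
        total_area = 0.0
        total_len = 0
        for starts, ends, values in self.steps.values():
            if len(starts) == 0:
                continue
            total_area += float(np.sum((ends - starts) * values))
            total_len += int(ends[-1])
        return total_area / total_len if total_len else 0.0


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap length in bp between two intervals; 0 on overlap/abutment.

    Returns ``None`` when the intervals lie on different chromosomes
    (distance undefined). Strand is ignored.
    """
    if a.chrom != b.chrom:
        return None
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


def tss(gene: GeneRecord | TranscriptModel | GenomicInterval) -> int:
    """Transcription start site: 5' end of the feature on its strand.

    Unstranded features (strand ".") fall back to the left end, as for "+";
    this fallback is logged once per run.
    """
    iv = gene if isinstance(gene, GenomicInterval) else gene.interval
    if iv.strand == "-":
        return iv.end - 1
    if iv.strand == ".":
        _log_once("unstranded feature(s): TSS taken at the left end (as for '+')")
    return iv.start


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_DEFAULT_FEATURE_MAP = {"gene": "gene", "transcript": "transcript", "exon": "exon"}


def read_gtf(
    path: str | Path,
    feature_map: dict[str, str] | None = None,
) -> tuple[list[GeneRecord], list[TranscriptModel]]:
    """Read a GTF/GFF3 file into gene records and transcript models.

    Coordinates are converted from 1-based inclusive to internal 0-based
    half-open. ``feature_map`` maps the roles "gene"/"transcript"/"exon" to
    the feature-type strings used in the file. Transcripts lacking an
    explicit transcript line are inferred from their exon chains. Malformed
    lines raise :class:`ParseError` naming the line number.
    """
    fmap = feature_map or _DEFAULT_FEATURE_MAP
    role_of = {v: k for k, v in fmap.items()}

    genes: list[GeneRecord] = []
    tx_meta: dict[str, dict] = {}
    exon_chains: dict[str, list[GenomicInterval]] = {}
    tx_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise ParseError(f"{path}:{lineno}: unparseable line ({exc})") from exc
            role = role_of.get(feat.featuretype)
            if role is None:
                continue
            if feat.end < feat.start:
                raise ParseError(f"{path}:{lineno}: end < start")
            try:
                iv = GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end,
                    feat.strand if feat.strand in VALID_STRANDS else ".",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc

            attrs = feat.attributes
            gene_id = attrs["gene_id"][0] if "gene_id" in attrs else None
            tx_id = attrs["transcript_id"][0] if "transcript_id" in attrs else None

            if role == "gene":
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: gene line missing gene_id")
                genes.append(GeneRecord(gene_id, iv))
            elif role == "transcript":
                if tx_id is None or gene_id is None:
                    raise ParseError(
                        f"{path}:{lineno}: transcript line missing "
                        "gene_id/transcript_id"
                    )
                if tx_id not in tx_meta:
                    tx_order.append(tx_id)
                tx_meta[tx_id] = {"gene_id": gene_id, "strand": iv.strand}
            else:  # exon
                if tx_id is None or gene_id is None:
                    raise ParseError(
                        f"{path}:{lineno}: exon line missing gene_id/transcript_id"
                    )
                if tx_id not in tx_meta:
                    tx_order.append(tx_id)
                    tx_meta[tx_id] = {"gene_id": gene_id, "strand": iv.strand}
                exon_chains.setdefault(tx_id, []).append(iv)

    seen_gene_ids = set()
    for g in genes:
        if g.gene_id in seen_gene_ids:
            raise ParseError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen_gene_ids.add(g.gene_id)

    transcripts: list[TranscriptModel] = []
    for tx_id in tx_order:
        meta = tx_meta[tx_id]
        exons = sorted(exon_chains.get(tx_id, []), key=lambda e: e.start)
        if not exons:
            raise ParseError(f"{path}: transcript {tx_id!r} has no exon lines")
        strand = meta["strand"]
        exons = [
            GenomicInterval(e.chrom, e.start, e.end, strand) for e in exons
        ]
        span = GenomicInterval(exons[0].chrom, exons[0].start, exons[-1].end, strand)
        transcripts.append(TranscriptModel(tx_id, meta["gene_id"], span, tuple(exons)))
    return genes, transcripts


def write_gtf(
    path: str | Path,
    genes: Iterable[GeneRecord] = (),
    transcripts: Iterable[TranscriptModel] = (),
    source: str = "itgscan",
) -> None:
    """Write gene/transcript/exon features as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )
        for t in transcripts:
            iv = t.interval
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{iv.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in t.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[BedFeature]:
    """Read BED3-BED6; coordinates pass through unchanged (already 0-based)."""
    feats: list[BedFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in VALID_STRANDS else "."
            name = cols[3] if len(cols) >= 4 and cols[3] != "." else None
            score: float | None = None
            if len(cols) >= 5 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                iv = GenomicInterval(cols[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            feats.append(BedFeature(iv, name, score))
    return feats


def write_bed(path: str | Path, feats: Iterable[BedFeature]) -> None:
    with open(path, "w") as fh:
        for f in feats:
            iv = f.interval
            name = f.name if f.name is not None else "."
            score = format(f.score, "g") if f.score is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_te_bed(path: str | Path, default_family: str = "LTR") -> list[TERecord]:
    """Read a TE annotation BED.

    The name column carries ``family:te_id``; a bare name is taken as the
    family, with a positional te_id generated.
    """
    records = []
    for i, feat in enumerate(read_bed(path)):
        name = feat.name or default_family
        if ":" in name:
            family, te_id = name.split(":", 1)
        else:
            family, te_id = name, f"{name}_{i}"
        records.append(TERecord(te_id, family, feat.interval))
    return records


def write_te_bed(path: str | Path, tes: Iterable[TERecord]) -> None:
    write_bed(
        path,
        [BedFeature(t.interval, f"{t.family}:{t.te_id}") for t in tes],
    )


def read_peak_bed(
    path: str | Path, mark: str | None = None, replicate: int | None = None
) -> list[PeakRecord]:
    """Read a peak BED; mark/replicate default-parse from ``<mark>_rep<i>.bed``."""
    if mark is None or replicate is None:
        stem = Path(path).stem
        if "_rep" not in stem:
            raise ValueError(
                f"{path}: cannot infer mark/replicate from filename; "
                "expected <mark>_rep<i>.bed"
            )
        mark_part, rep_part = stem.rsplit("_rep", 1)
        mark = mark or mark_part
        replicate = replicate or int(rep_part)
    return [
        PeakRecord(mark, replicate, f.interval, f.score or 0.0)
        for f in read_bed(path)
    ]


def write_peak_bed(path: str | Path, peaks: Iterable[PeakRecord]) -> None:
    write_bed(
        path,
        [
            BedFeature(p.interval, f"{p.mark}_rep{p.replicate}", p.score)
            for p in peaks
        ],
    )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> CoverageTrack:
    steps: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            steps.setdefault(cols[0], []).append((start, end, value))
    return CoverageTrack(steps)


def write_bedgraph(path: str | Path, track: CoverageTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.steps):
            starts, ends, values = track.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{format(v, 'g')}\n")


# ---------------------------------------------------------------------------
# Homology hits (12-column tabular, BLAST outfmt-6 layout)
# ---------------------------------------------------------------------------

_HOMOLOGY_COLS = [
    "query_id", "subject_id", "pct_identity", "align_length", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "e_value", "bit_score",
]


def read_homology_tab(path: str | Path, e_threshold: float = 1e-5) -> list[HomologyHit]:
    """Read 12-column tabular homology hits; drop self-hits and weak e-values."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ParseError(
            f"{path}: expected 12 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = _HOMOLOGY_COLS
    keep = (df["e_value"] <= e_threshold) & (df["query_id"] != df["subject_id"])
    return [
        HomologyHit(
            str(r.query_id), str(r.subject_id), float(r.pct_identity),
            int(r.align_length), float(r.e_value),
        )
        for r in df[keep].itertuples(index=False)
    ]


def write_homology_tab(path: str | Path, hits: Iterable[HomologyHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{h.align_length}\t0\t0\t1\t{h.align_length}\t1\t"
                f"{h.align_length}\t{h.e_value:g}\t0\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str] | Sequence[tuple[str, str]]) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")
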