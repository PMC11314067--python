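"""Distance-based classification of assembled transcripts against a reference.

Transcripts are classified by the minimum span-to-span gap to any reference
gene on the same chromosome (strand-agnostic):

* gap 0 (overlap/abutment)  -> GENIC_OVERLAP
* 0 < gap < d_p_min         -> PROXIMAL_EXCLUDED (retained, not dropped,
  so per-class counts stay conserved)
* d_p_min <= gap < d_u_min  -> CLASS_P  ("p": 0.5-1.5 kb from a known gene)
* gap >= d_u_min            -> CLASS_U  ("u": at least 1.5 kb away)

"At least 1.5 kb" includes the boundary, so gap == d_u_min is CLASS_U and
the p class is taken half-open to keep the classes disjoint. The ITG
(intergenic gene) set is CLASS_P ∪ CLASS_U.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import GeneRecord, TranscriptModel

logger = logging.getLogger("itgscan")

GENIC_OVERLAP = "GENIC_OVERLAP"
CLASS_P = "CLASS_P"
CLASS_U = "CLASS_U"
PROXIMAL_EXCLUDED = "PROXIMAL_EXCLUDED"

ITG_LABELS = (CLASS_P, CLASS_U)


@dataclass(frozen=True)
class ClassifierConfig:
    """Distance thresholds (bp) for the u/p intergenic classes."""

    d_u_min: int = 1500
    d_p_min: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.d_p_min < self.d_u_min:
            raise ValueError(
                f"require 0 < d_p_min < d_u_min, got {self.d_p_min}, {self.d_u_min}"
            )


@dataclass(frozen=True)
class TranscriptClassification:
    transcript_id: str
    label: str
    nearest_gene_id: str | None
    distance_bp: int | None


class GeneIndex:
    """Per-chromosome index of reference genes for nearest-gap queries."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self._trees: dict[str, IntervalTree] = {}
        by_end: dict[str, list[tuple[int, GeneRecord]]] = {}
        by_start: dict[str, list[tuple[int, GeneRecord]]] = {}
        for g in genes:
            chrom = g.interval.chrom
            self._trees.setdefault(chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g
            )
            by_end.setdefault(chrom, []).append((g.interval.end, g))
            by_start.setdefault(chrom, []).append((g.interval.start, g))
        self._by_end: dict[str, tuple[list[int], list[GeneRecord]]] = {}
        self._by_start: dict[str, tuple[list[int], list[GeneRecord]]] = {}
        for chrom in by_end:
            ends = sorted(by_end[chrom], key=lambda t: t[0])
            starts = sorted(by_start[chrom], key=lambda t: t[0])
            self._by_end[chrom] = ([e for e, _ in ends], [g for _, g in ends])
            self._by_start[chrom] = ([s for s, _ in starts], [g for _, g in starts])

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def nearest(self, chrom: str, start: int, end: int) -> tuple[GeneRecord, int] | None:
        """Nearest gene to ``[start, end)`` and the gap to it (0 on overlap).

        Returns ``None`` when the chromosome holds no reference genes.
        """
        if chrom not in self._trees:
            return None
        hits = self._trees[chrom][start:end]
        if hits:
            best = min(hits, key=lambda h: h.data.gene_id)
            return best.data, 0
        # non-overlapping genes end at or before `start`, or start at or
        # after `end`; the best candidate on each side is found by bisection
        best_gene: GeneRecord | None = None
        best_gap = None
        end_keys, end_genes = self._by_end[chrom]
        i = bisect_right(end_keys, start) - 1
        if i >= 0:
            g = end_genes[i]
            # abutting (gap 0) features do not overlap but count as distance 0
            best_gene, best_gap = g, max(start - g.interval.end, 0)
        start_keys, start_genes = self._by_start[chrom]
        j = bisect_left(start_keys, end)
        if j < len(start_genes):
            g = start_genes[j]
            gap = max(g.interval.start - end, 0)
            if best_gap is None or gap < best_gap:
                best_gene, best_gap = g, gap
        if best_gene is None:
            return None
        return best_gene, best_gap


def classify_transcript(
    t: TranscriptModel, index: GeneIndex, cfg: ClassifierConfig = ClassifierConfig()
) -> TranscriptClassification:
    """Classify one transcript by its minimum gap to any reference gene."""
    iv = t.interval
    res = index.nearest(iv.chrom, iv.start, iv.end)
    if res is None:
        # chromosome absent from the reference: distance undefined; the
        # transcript cannot be near any known gene, so it falls in class u
        logger.warning(
            "%s: chromosome %s absent from reference; CLASS_U with "
            "undefined distance", t.transcript_id, iv.chrom,
        )
        return TranscriptClassification(t.transcript_id, CLASS_U, None, None)
    gene, gap = res
    if gap == 0:
        label = GENIC_OVERLAP
    elif gap >= cfg.d_u_min:
        label = CLASS_U
    elif gap >= cfg.d_p_min:
        label = CLASS_P
    else:
        label = PROXIMAL_EXCLUDED
    return TranscriptClassification(t.transcript_id, label, gene.gene_id, gap)


def classify_transcriptome(
    transcripts: Sequence[TranscriptModel],
    reference_genes: Iterable[GeneRecord],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every transcript; return one row per transcript plus counts.

    The returned counts cover all four labels and sum to the number of
    transcripts. Duplicate transcript_ids are an error.
    """
    seen: set[str] = set()
    for t in transcripts:
        if t.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        seen.add(t.transcript_id)
    if not transcripts:
        logger.warning("classify_transcriptome: empty transcript set")
    index = GeneIndex(reference_genes)
    rows = [classify_transcript(t, index, cfg) for t in transcripts]
    df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in rows],
            "label": [r.label for r in rows],
            "nearest_gene_id": [r.nearest_gene_id for r in rows],
            "distance_bp": [r.distance_bp for r in rows],
        }
    )
    counts = {
        label: int((df["label"] == label).sum())
        for label in (GENIC_OVERLAP, CLASS_P, CLASS_U, PROXIMAL_EXCLUDED)
    }
    counts["ITG"] = counts[CLASS_P] + counts[CLASS_U]
    return df, counts


def select_longest_transcript(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Pick, per gene, the transcript maximizing summed exon length.

    Ties break to the lexicographically smallest transcript_id.
    """
    winners: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = winners.get(t.gene_id)
        if (
            cur is None
            or t.exonic_length > cur.exonic_length
            or (
                t.exonic_length == cur.exonic_length
                and t.transcript_id < cur.transcript_id
            )
        ):
            winners[t.gene_id] = t
    return winners


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    fragment_count: int
    fpkm: float


def compute_fpkm(
    fragment_counts: Mapping[str, int],
    exonic_lengths: Mapping[str, int],
    library_size: int,
) -> list[ExpressionRecord]:
    """FPKM = count x 10^9 / (library_size x length_bp), per transcript."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    out = []
    for tid, count in fragment_counts.items():
        if count < 0:
            raise ValueError(f"{tid}: negative fragment count")
        length = exonic_lengths.get(tid)
        if length is None:
            raise KeyError(f"{tid}: no exonic length provided")
        if length <= 0:
            raise ValueError(f"{tid}: non-positive transcript length")
        fpkm = count * 1e9 / (library_size * length)
        out.append(ExpressionRecord(tid, int(count), fpkm))
    return out


def exon_number_frequency(
    transcripts: Iterable[TranscriptModel],
) -> dict[int, float]:
    """Fraction of transcripts per exon count; fractions sum to 1."""
    counts: dict[int, int] = {}
    n = 0
    for t in transcripts:
        counts[len(t.exons)] = counts.get(len(t.exons), 0) + 1
        n += 1
    if n == 0:
        return {}
    return {k: counts[k] / n for k in sorted(counts)}


def exon_length_stats(transcripts: Iterable[TranscriptModel]) -> dict[str, float]:
    """Median and quartiles of individual exon lengths pooled over transcripts.

    Even-count medians are the mean of the central pair (linear-interpolation
    quantiles).
    """
    lengths = np.array(
        [ex.length for t in transcripts for ex in t.exons], dtype=float
    )
    if lengths.size == 0:
        raise ValueError("no exons")
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {
        "n_exons": int(lengths.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "mean": float(lengths.mean()),
    }
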