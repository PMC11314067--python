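"""Transposable-element insertion proximity statistics.

A TE is a *valid insertion* for a gene when the unsigned span-to-span gap
between TE and gene is at most ``window_bp`` (default 1000 bp, boundary
inclusive); a TE overlapping the gene body has distance 0 and counts.
Upstream and downstream are pooled into a single unsigned distance, which
covers both "within 1000 bp of the upstream or downstream regions" and TEs
contained in exons with one rule.

Distance-binned frequencies are per gene (each gene contributes its nearest
valid TE), with the whole gene class as denominator, so bin fractions sum to
the overall insertion fraction and are directly comparable to the insertion
percentage.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genomic_io import GeneRecord, TERecord, interval_distance


@dataclass(frozen=True)
class TEConfig:
    window_bp: int = 1000
    bin_width_bp: int = 100
    family_filter: frozenset[str] = frozenset({"LTR"})

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.bin_width_bp <= 0:
            raise ValueError("window_bp and bin_width_bp must be positive")
        if self.window_bp % self.bin_width_bp != 0:
            raise ValueError(
                f"window_bp ({self.window_bp}) must be a multiple of "
                f"bin_width_bp ({self.bin_width_bp})"
            )


@dataclass(frozen=True)
class InsertionCall:
    gene_id: str
    te_id: str
    distance_bp: int


@dataclass(frozen=True)
class InsertionSummary:
    n_genes_total: int
    n_genes_with_insertion: int

    @property
    def percentage(self) -> float:
        """Percentage of genes with at least one valid insertion (unrounded)."""
        return 100.0 * self.n_genes_with_insertion / self.n_genes_total

    @property
    def percentage_1dp(self) -> float:
        """Report-time rounding to one decimal place."""
        return round(self.percentage, 1)


def call_valid_insertions(
    genes: Sequence[GeneRecord],
    tes: Iterable[TERecord],
    cfg: TEConfig = TEConfig(),
) -> list[InsertionCall]:
    """All (gene, TE) pairs with gap <= window_bp, family filter applied first.

    Overlapping TEs are included with distance 0.
    """
    by_chrom: dict[str, list[TERecord]] = {}
    for te in tes:
        if cfg.family_filter and te.family not in cfg.family_filter:
            continue
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: (t.interval.start, t.interval.end))
        starts[chrom] = [t.interval.start for t in by_chrom[chrom]]
        max_len[chrom] = max(t.interval.length for t in by_chrom[chrom])

    calls: list[InsertionCall] = []
    for g in genes:
        iv = g.interval
        cand = by_chrom.get(iv.chrom)
        if not cand:
            continue
        # a valid TE starts at or before gene.end + window (a TE starting
        # exactly there has gap == window) and ends at or after
        # gene.start - window, so it starts after that minus its length
        hi = bisect_right(starts[iv.chrom], iv.end + cfg.window_bp)
        lo = bisect_left(
            starts[iv.chrom], iv.start - cfg.window_bp - max_len[iv.chrom]
        )
        for te in cand[lo:hi]:
            d = interval_distance(iv, te.interval)
            if d is not None and d <= cfg.window_bp:
                calls.append(InsertionCall(g.gene_id, te.te_id, d))
    return calls


def insertion_percentage(
    calls: Iterable[InsertionCall], genes: Sequence[GeneRecord]
) -> InsertionSummary:
    """Fraction of genes hit by >= 1 valid insertion; a gene counts once."""
    if not genes:
        raise ValueError("empty gene set")
    hit = {c.gene_id for c in calls}
    return InsertionSummary(len(genes), sum(1 for g in genes if g.gene_id in hit))


def insertion_summary_from_counts(
    n_genes_with_insertion: int, n_genes_total: int
) -> InsertionSummary:
    """Build a summary directly from published gene counts."""
    if n_genes_total <= 0:
        raise ValueError("n_genes_total must be positive")
    if not 0 <= n_genes_with_insertion <= n_genes_total:
        raise ValueError("n_genes_with_insertion out of range")
    return InsertionSummary(n_genes_total, n_genes_with_insertion)


def nearest_distance_per_gene(
    calls: Iterable[InsertionCall],
) -> dict[str, int]:
    """Nearest valid-TE distance per gene with at least one call."""
    nearest: dict[str, int] = {}
    for c in calls:
        if c.gene_id not in nearest or c.distance_bp < nearest[c.gene_id]:
            nearest[c.gene_id] = c.distance_bp
    return nearest


def distance_frequency(
    calls: Iterable[InsertionCall],
    genes: Sequence[GeneRecord],
    cfg: TEConfig = TEConfig(),
) -> pd.DataFrame:
    """Per-bin fraction of genes whose nearest valid TE falls in each bin.

    Bins are [0,100), [100,200), ..., with the last bin closed to include
    the window boundary distance. Denominator is the total gene count, so
    the fractions sum to the insertion fraction.
    """
    if not genes:
        raise ValueError("empty gene set")
    n_bins = cfg.window_bp // cfg.bin_width_bp
    counts = [0] * n_bins
    nearest = nearest_distance_per_gene(calls)
    gene_ids = {g.gene_id for g in genes}
    for gid, d in nearest.items():
        if gid not in gene_ids:
            continue
        b = min(d // cfg.bin_width_bp, n_bins - 1)  # closes the last bin
        counts[b] += 1
    lo = [i * cfg.bin_width_bp for i in range(n_bins)]
    hi = [(i + 1) * cfg.bin_width_bp for i in range(n_bins)]
    return pd.DataFrame(
        {
            "bin_start": lo,
            "bin_end": hi,
            "n_genes": counts,
            "fraction": [c / len(genes) for c in counts],
        }
    )


def insertion_count_histogram(
    calls: Iterable[InsertionCall], genes: Sequence[GeneRecord]
) -> dict[int, int]:
    """Genes per insertion count, including the zero-insertion class."""
    per_gene: dict[str, int] = {g.gene_id: 0 for g in genes}
    for c in calls:
        if c.gene_id in per_gene:
            per_gene[c.gene_id] += 1
    hist: dict[int, int] = {}
    for n in per_gene.values():
        hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))
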