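"""Histone-modification peak assignment, replicate summaries, and metagenes.

A gene is *modified* for a (mark, replicate) when at least one called peak
of that mark/replicate overlaps the ±2 kb window around its TSS. The window
is ``[tss - w, tss + w + 1)`` in internal half-open coordinates so that the
literal position ``tss + w`` is inside, and it is clipped at the chromosome
start.

Per-class proportions follow a mixed-scale reporting convention: the mean
is on the percent scale while the standard deviation is the sample standard
deviation (n−1) of the per-replicate *fractions*. Both scales are exposed.

Metagene profiles scale each gene body to ``body_bins`` equal-width bins
and add fixed-width flank bins on either side; minus-strand genes are
reversed so the profile reads 5'→3', and the profile is normalized by the
genome-wide mean coverage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats
from intervaltree import IntervalTree

from .genomic_io import CoverageTrack, GeneRecord, PeakRecord, tss

logger = logging.getLogger("itgscan")


@dataclass(frozen=True)
class ChipConfig:
    tss_window_bp: int = 2000
    flank_bp: int = 2000
    body_bins: int = 100
    flank_bin_bp: int = 100

    def __post_init__(self) -> None:
        if min(self.tss_window_bp, self.flank_bp, self.body_bins,
               self.flank_bin_bp) <= 0:
            raise ValueError("all ChipConfig fields must be positive")
        if self.flank_bp % self.flank_bin_bp != 0:
            raise ValueError("flank_bp must be a multiple of flank_bin_bp")


@dataclass(frozen=True)
class ModificationCall:
    gene_id: str
    mark: str
    replicate: int
    modified: bool


@dataclass(frozen=True)
class ProportionSummary:
    mark: str
    gene_class: str
    per_replicate_pct: tuple[float, ...]

    @property
    def mean_pct(self) -> float:
        """Arithmetic mean of per-replicate percentages (percent scale)."""
        return float(np.mean(self.per_replicate_pct))

    @property
    def stdev_fraction(self) -> float:
        """Sample standard deviation (n−1) of per-replicate fractions."""
        if len(self.per_replicate_pct) < 2:
            raise ValueError("stdev requires >= 2 replicates")
        if len(set(self.per_replicate_pct)) == 1:
            return 0.0  # exact, avoiding float cancellation noise
        return float(np.std(np.array(self.per_replicate_pct) / 100.0, ddof=1))


@dataclass(frozen=True)
class MetageneProfile:
    mark: str
    gene_class: str
    x: np.ndarray
    y: np.ndarray
    n_genes: int


def tss_window(
    gene: GeneRecord, cfg: ChipConfig = ChipConfig()
) -> tuple[str, int, int]:
    """Half-open TSS window ``[tss-w, tss+w+1)``, clipped at position 0."""
    pos = tss(gene)
    w = cfg.tss_window_bp
    return gene.interval.chrom, max(pos - w, 0), pos + w + 1


def call_modified_genes(
    genes: Sequence[GeneRecord],
    peaks: Iterable[PeakRecord],
    cfg: ChipConfig = ChipConfig(),
) -> list[ModificationCall]:
    """One call per (gene, mark, replicate) triple over the observed marks.

    ``modified`` is true iff at least one peak of that mark/replicate
    overlaps the gene's TSS window (half-open overlap logic).
    """
    trees: dict[tuple[str, int], dict[str, IntervalTree]] = {}
    for p in peaks:
        key = (p.mark, p.replicate)
        trees.setdefault(key, {}).setdefault(
            p.interval.chrom, IntervalTree()
        ).addi(p.interval.start, p.interval.end)
    keys = sorted(trees)
    calls: list[ModificationCall] = []
    for g in genes:
        chrom, lo, hi = tss_window(g, cfg)
        for mark, rep in keys:
            tree = trees[(mark, rep)].get(chrom)
            modified = bool(tree is not None and tree.overlaps(lo, hi))
            calls.append(ModificationCall(g.gene_id, mark, rep, modified))
    return calls


def proportion_summary(
    calls: Iterable[ModificationCall],
    gene_classes: Mapping[str, str],
) -> list[ProportionSummary]:
    """Per-(mark, class) replicate percentages from raw modification calls.

    ``gene_classes`` maps gene_id -> class label (e.g. "genic"/"itg");
    classes with no genes raise.
    """
    class_sizes: dict[str, int] = {}
    for cls in gene_classes.values():
        class_sizes[cls] = class_sizes.get(cls, 0) + 1
    if not class_sizes:
        raise ValueError("empty gene-class partition")
    # (mark, class, replicate) -> number of modified genes
    mod_counts: dict[tuple[str, str, int], int] = {}
    marks: set[str] = set()
    reps: set[int] = set()
    for c in calls:
        cls = gene_classes.get(c.gene_id)
        if cls is None:
            continue
        marks.add(c.mark)
        reps.add(c.replicate)
        if c.modified:
            key = (c.mark, cls, c.replicate)
            mod_counts[key] = mod_counts.get(key, 0) + 1
    out = []
    for mark in sorted(marks):
        for cls in sorted(class_sizes):
            pcts = tuple(
                100.0 * mod_counts.get((mark, cls, rep), 0) / class_sizes[cls]
                for rep in sorted(reps)
            )
            out.append(ProportionSummary(mark, cls, pcts))
    return out


def summary_from_replicate_percentages(
    mark: str, gene_class: str, percentages: Sequence[float]
) -> ProportionSummary:
    """Build a summary directly from published per-replicate percentages."""
    return ProportionSummary(mark, gene_class, tuple(float(p) for p in percentages))


def one_way_anova(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Classical one-way ANOVA between two groups of replicate fractions.

    F = MS_between / MS_within with df (k−1, N−k). When both groups have
    zero within-group variance and equal means the test is vacuous and
    (F, p) = (0, 1) by convention (logged). With two groups this is
    equivalent to a two-sample t-test squared.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    groups = [a, b]
    n_total = len(a) + len(b)
    grand = (a.sum() + b.sum()) / n_total
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            logger.warning("one_way_anova: degenerate all-equal input; p = 1")
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(scipy.stats.f.sf(f, df_between, df_within))
    return float(f), p


def metagene_profile(
    coverage: CoverageTrack,
    genes: Sequence[GeneRecord],
    cfg: ChipConfig = ChipConfig(),
    mark: str = "",
    gene_class: str = "",
) -> MetageneProfile:
    """Mean normalized coverage over scaled gene bodies plus fixed flanks.

    The x axis is a composite coordinate: upstream flank bin centers in bp
    (negative), body bin centers as fractions in (0, 1), and downstream
    flank bin centers as 1 + bp offset. Genes shorter than ``body_bins`` bp
    are skipped with a warning.
    """
    n_flank = cfg.flank_bp // cfg.flank_bin_bp
    n_bins = 2 * n_flank + cfg.body_bins
    acc = np.zeros(n_bins)
    n_used = 0
    for g in genes:
        iv = g.interval
        if iv.length < cfg.body_bins:
            logger.warning(
                "metagene_profile: %s shorter than body_bins bp; skipped",
                g.gene_id,
            )
            continue
        vals = np.empty(n_bins)
        # upstream flank (5' side), body, downstream flank in genome order
        left_edges = [
            iv.start - cfg.flank_bp + i * cfg.flank_bin_bp for i in range(n_flank)
        ]
        body_edges = np.linspace(iv.start, iv.end, cfg.body_bins + 1)
        k = 0
        for le in left_edges:
            vals[k] = _mean_cov(coverage, iv.chrom, le, le + cfg.flank_bin_bp)
            k += 1
        for i in range(cfg.body_bins):
            lo = int(round(body_edges[i]))
            hi = max(int(round(body_edges[i + 1])), lo + 1)
            vals[k] = _mean_cov(coverage, iv.chrom, lo, hi)
            k += 1
        for i in range(n_flank):
            le = iv.end + i * cfg.flank_bin_bp
            vals[k] = _mean_cov(coverage, iv.chrom, le, le + cfg.flank_bin_bp)
            k += 1
        if iv.strand == "-":
            vals = vals[::-1]
        acc += vals
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable genes for metagene profile")
    mean_cov = coverage.genome_mean()
    y = acc / n_used
    if mean_cov > 0:
        y = y / mean_cov
    x = np.concatenate(
        [
            -cfg.flank_bp + (np.arange(n_flank) + 0.5) * cfg.flank_bin_bp,
            (np.arange(cfg.body_bins) + 0.5) / cfg.body_bins,
            1.0 + (np.arange(n_flank) + 0.5) * cfg.flank_bin_bp,
        ]
    )
    return MetageneProfile(mark, gene_class, x, y, n_used)


def _mean_cov(track: CoverageTrack, chrom: str, lo: int, hi: int) -> float:
    """Mean coverage with the query clipped at the chromosome start."""
    lo = max(lo, 0)
    if hi <= lo:
        return 0.0
    return track.mean_value(chrom, lo, hi)
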