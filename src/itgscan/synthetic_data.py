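"""Seeded synthetic fixtures with known ground truth for every stage.

The generator lays features out in fixed-pitch *cassettes* (default 20 kb),
one reference gene plus one planted transcript per cassette. Cassettes are
randomly oriented; in a forward cassette the gene sits left with its
transcript downstream and its TE zone upstream, and a reverse cassette is
the mirror image with a minus-strand gene. The pitch and the in-cassette
offsets are chosen so that

* every planted transcript's nearest reference gene is its own cassette's
  gene, making the planted gap the exact classification distance;
* a planted TE's only feature within the 1 kb insertion window is its
  target feature, so per-class insertion probabilities and distances are
  recovered exactly;
* TSS ±2 kb peak windows of genes and of intergenic (u/p) transcripts are
  pairwise disjoint, so planted per-replicate modification states are
  recovered exactly.

Ground truth is returned as data frames alongside the records and is never
consumed by the analysis stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    CoverageTrack,
    GeneRecord,
    GenomicInterval,
    HomologyHit,
    PeakRecord,
    TERecord,
    TranscriptModel,
    write_bedgraph,
    write_fasta,
    write_gtf,
    write_homology_tab,
    write_peak_bed,
    write_te_bed,
)

# headline rates from the cotton study that the defaults emulate:
# LTR insertion 19.9% of genic genes vs 42.3% of ITGs; histone-mark
# modification proportions per Table-3-style means; homoeolog divergence
# epochs near 1.6 and 7.0 Mya at r = 1.5e-8 substitutions/site/year.
_DEFAULT_MOD_PROB = {
    ("H3K27ac", "genic"): 0.630,
    ("H3K27ac", "itg"): 0.658,
    ("H3K4me3", "genic"): 0.627,
    ("H3K4me3", "itg"): 0.651,
    ("H3K4me1", "genic"): 0.748,
    ("H3K4me1", "itg"): 0.440,
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int | None = None  # None: sized to fit the layout
    # planted transcript classes
    n_genic: int = 20
    n_itg_u: int = 15
    n_itg_p: int = 10
    n_proximal: int = 5
    # TE stage
    te_prob_genic: float = 0.199
    te_prob_itg: float = 0.423
    te_distance_law: tuple = ("geometric", 0.997)  # or ("uniform",)
    te_window_bp: int = 1000
    decoy_rate: float = 0.3  # out-of-window decoy TEs per feature
    distractor_rate: float = 0.1  # in-window non-LTR TEs per feature
    # ChIP stage
    mod_prob: dict = field(default_factory=lambda: dict(_DEFAULT_MOD_PROB))
    n_replicates: int = 3
    replicate_noise: float = 0.01
    tss_window_bp: int = 2000
    # dating stage
    n_pairs: int = 500
    divergence_times_years: tuple = (1.6e6, 7.0e6)
    r: float = 1.5e-8
    seq_length_bp: int = 2000
    # layout
    cassette_bp: int = 20000
    gene_length_bp: int = 4000
    exon_count_probs: tuple = ((1, 0.15), (2, 0.45), (3, 0.25), (4, 0.15))

    def __post_init__(self) -> None:
        for p in (self.te_prob_genic, self.te_prob_itg, self.replicate_noise,
                  self.decoy_rate, self.distractor_rate, *self.mod_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.gene_length_bp < 2 * self.tss_window_bp:
            raise ValueError(
                "gene_length_bp must be >= 2x tss_window_bp to keep gene and "
                "transcript TSS windows disjoint"
            )
        if self.cassette_bp < 20000:
            raise ValueError("cassette_bp must be >= 20000 for the fixed layout")
        n_cassettes = self.n_genic + self.n_itg_u + self.n_itg_p + self.n_proximal
        if n_cassettes > 0:
            per_chrom = math.ceil(n_cassettes / self.n_chroms)
            required = per_chrom * self.cassette_bp + 1000
            if self.chrom_length_bp is not None and self.chrom_length_bp < required:
                raise ValueError(
                    f"chrom_length_bp={self.chrom_length_bp} cannot fit "
                    f"{per_chrom} cassettes of {self.cassette_bp} bp"
                )

    @property
    def effective_chrom_length(self) -> int:
        n_cassettes = self.n_genic + self.n_itg_u + self.n_itg_p + self.n_proximal
        per_chrom = math.ceil(max(n_cassettes, 1) / self.n_chroms)
        required = per_chrom * self.cassette_bp + 1000
        return self.chrom_length_bp or required


@dataclass(frozen=True)
class SimAnnotation:
    ref_genes: tuple[GeneRecord, ...]
    transcripts: tuple[TranscriptModel, ...]
    truth: pd.DataFrame  # transcript_id, true_label, planted_gap, cassette fields

    def itg_gene_records(self) -> list[GeneRecord]:
        """u/p transcripts viewed as intergenic-gene loci for TE/ChIP stages."""
        itg_ids = set(
            self.truth.loc[
                self.truth["true_label"].isin(["CLASS_U", "CLASS_P"]),
                "transcript_id",
            ]
        )
        return [
            GeneRecord(t.transcript_id, t.interval, "itg")
            for t in self.transcripts
            if t.transcript_id in itg_ids
        ]


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([stage, cfg.seed]))


def _exon_chain(
    rng: np.random.Generator, start: int, span: int, n_exons: int, chrom: str,
    strand: str,
) -> tuple[GenomicInterval, ...]:
    """Split ``[start, start+span)`` into n sorted non-overlapping exons."""
    if n_exons == 1:
        return (GenomicInterval(chrom, start, start + span, strand),)
    introns = rng.integers(30, 101, size=n_exons - 1)
    exon_total = span - int(introns.sum())
    # random composition of exon_total into n parts of >= 50 bp
    spare = exon_total - 50 * n_exons
    w = rng.dirichlet(np.ones(n_exons))
    extra = np.floor(w * spare).astype(int)
    extra[0] += spare - int(extra.sum())
    lens = 50 + extra
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + int(lens[i]), strand))
        pos += int(lens[i])
        if i < n_exons - 1:
            pos += int(introns[i])
    # stretch the final exon so the chain spans exactly `span`
    last = exons[-1]
    exons[-1] = GenomicInterval(chrom, last.start, start + span, strand)
    return tuple(exons)


def generate_annotation(cfg: SimConfig) -> SimAnnotation:
    """Reference genes plus planted transcripts at controlled gaps.

    Gap regimes: genic overlap (gap 0), p in [500, 1500), u in [1500, 3000],
    proximal in (0, 500). Boundary gaps (1, 499, 500, 1499, 1500) are planted
    deterministically when the class sizes allow, so threshold behaviour is
    always exercised. All realized gaps are recorded in the truth table.
    """
    n_total = cfg.n_genic + cfg.n_itg_u + cfg.n_itg_p + cfg.n_proximal
    if n_total == 0:
        raise ValueError("no features requested")
    rng = _rng(cfg, 1)

    def gaps_for(label: str, n: int) -> list[int]:
        if label == "GENIC_OVERLAP":
            return [0] * n
        if label == "CLASS_P":
            planted = [500, 1499][: min(n, 2)]
            return planted + [int(g) for g in rng.integers(500, 1500, n - len(planted))]
        if label == "CLASS_U":
            planted = [1500][: min(n, 1)]
            return planted + [int(g) for g in rng.integers(1500, 3001, n - len(planted))]
        planted = [499, 1][: min(n, 2)]
        return planted + [int(g) for g in rng.integers(1, 500, n - len(planted))]

    plan = (
        [("GENIC_OVERLAP", g) for g in gaps_for("GENIC_OVERLAP", cfg.n_genic)]
        + [("CLASS_U", g) for g in gaps_for("CLASS_U", cfg.n_itg_u)]
        + [("CLASS_P", g) for g in gaps_for("CLASS_P", cfg.n_itg_p)]
        + [("PROXIMAL_EXCLUDED", g) for g in gaps_for("PROXIMAL_EXCLUDED", cfg.n_proximal)]
    )
    order = rng.permutation(len(plan))
    exon_counts = np.array([k for k, _ in cfg.exon_count_probs])
    exon_probs = np.array([p for _, p in cfg.exon_count_probs])
    exon_probs = exon_probs / exon_probs.sum()

    per_chrom = math.ceil(n_total / cfg.n_chroms)
    genes: list[GeneRecord] = []
    transcripts: list[TranscriptModel] = []
    rows = []
    glen = cfg.gene_length_bp
    for slot, idx in enumerate(order):
        label, gap = plan[idx]
        chrom = f"chr{slot // per_chrom + 1}"
        c = (slot % per_chrom) * cfg.cassette_bp
        forward = bool(rng.integers(0, 2))
        span = int(rng.integers(1200, 1501))
        n_ex = int(rng.choice(exon_counts, p=exon_probs))
        if forward:
            g_start = c + 3000
            gene = GeneRecord(f"G{slot:05d}", GenomicInterval(chrom, g_start, g_start + glen, "+"))
            if label == "GENIC_OVERLAP":
                t_start = g_start + int(rng.integers(0, glen - 200))
            else:
                t_start = g_start + glen + gap
        else:
            g_start = c + cfg.cassette_bp - 3000 - glen
            gene = GeneRecord(f"G{slot:05d}", GenomicInterval(chrom, g_start, g_start + glen, "-"))
            if label == "GENIC_OVERLAP":
                t_start = g_start + int(rng.integers(200, glen)) - span
            else:
                t_start = g_start - gap - span
        t_strand = "+" if rng.random() < 0.8 else "."
        exons = _exon_chain(rng, t_start, span, n_ex, chrom, t_strand)
        tx = TranscriptModel(
            f"TX{slot:05d}", f"XLOC{slot:05d}",
            GenomicInterval(chrom, t_start, t_start + span, t_strand),
            exons,
        )
        genes.append(gene)
        transcripts.append(tx)
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "true_label": label,
                "planted_gap": gap,
                "cassette_gene_id": gene.gene_id,
                "forward_cassette": forward,
            }
        )
    truth = pd.DataFrame(rows)
    return SimAnnotation(tuple(genes), tuple(transcripts), truth)


# ---------------------------------------------------------------------------
# TE fixtures
# ---------------------------------------------------------------------------

def distance_law_probs(law: tuple, window_bp: int) -> np.ndarray:
    """Probability of each integer distance 0..window_bp under a named law."""
    d = np.arange(window_bp + 1)
    if law[0] == "uniform":
        p = np.ones_like(d, dtype=float)
    elif law[0] == "geometric":
        q = float(law[1])
        if not 0.0 < q < 1.0:
            raise ValueError(f"geometric decay must be in (0,1), got {q}")
        p = q ** d.astype(float)
    else:
        raise ValueError(f"unknown distance law: {law[0]!r}")
    return p / p.sum()


def _te_side(feature: GeneRecord, annotation_forward: bool, is_itg: bool) -> str:
    # genes take TEs on their outer (non-transcript) side; ITGs the reverse
    if is_itg:
        return "right" if annotation_forward else "left"
    return "left" if annotation_forward else "right"


def _place_te(
    rng: np.random.Generator, feature: GenomicInterval, side: str, distance: int,
) -> GenomicInterval:
    length = int(rng.integers(200, 501))
    if distance == 0:
        edge = feature.start if side == "left" else feature.end
        start = edge - length // 2
    elif side == "left":
        start = feature.start - distance - length
    else:
        start = feature.end + distance
    return GenomicInterval(feature.chrom, start, start + length, ".")


def generate_te_bed(
    cfg: SimConfig, annotation: SimAnnotation
) -> tuple[list[TERecord], pd.DataFrame]:
    """Plant LTR TEs near genes/ITGs with per-class probabilities.

    Each target feature receives at most one in-window LTR, at a distance
    drawn from ``te_distance_law`` (0 = body overlap); decoy LTRs beyond the
    window and in-window non-LTR distractors are added at stated rates.
    Realized distances are recorded in the truth table.
    """
    rng = _rng(cfg, 2)
    probs = distance_law_probs(cfg.te_distance_law, cfg.te_window_bp)
    forward = dict(
        zip(annotation.truth["cassette_gene_id"], annotation.truth["forward_cassette"])
    )
    fwd_tx = dict(
        zip(annotation.truth["transcript_id"], annotation.truth["forward_cassette"])
    )
    targets: list[tuple[GeneRecord, str, float]] = [
        (g, _te_side(g, forward[g.gene_id], False), cfg.te_prob_genic)
        for g in annotation.ref_genes
    ] + [
        (g, _te_side(g, fwd_tx[g.gene_id], True), cfg.te_prob_itg)
        for g in annotation.itg_gene_records()
    ]

    tes: list[TERecord] = []
    rows = []
    k = 0
    for feature, side, p in targets:
        has_te = rng.random() < p
        distance = None
        if has_te:
            distance = int(rng.choice(len(probs), p=probs))
            iv = _place_te(rng, feature.interval, side, distance)
            tes.append(TERecord(f"LTR{k:06d}", "LTR", iv))
            k += 1
        if rng.random() < cfg.decoy_rate:
            d = int(rng.integers(cfg.te_window_bp + 100, cfg.te_window_bp + 801))
            iv = _place_te(rng, feature.interval, side, d)
            tes.append(TERecord(f"LTR{k:06d}", "LTR", iv))
            k += 1
        if rng.random() < cfg.distractor_rate:
            d = int(rng.integers(0, cfg.te_window_bp + 1))
            iv = _place_te(rng, feature.interval, side, max(d, 1))
            tes.append(TERecord(f"DNA{k:06d}", "DNA", iv))
            k += 1
        rows.append(
            {
                "feature_id": feature.gene_id,
                "feature_class": feature.source_class,
                "has_te": has_te,
                "planted_distance": distance,
            }
        )
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return tes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ChIP fixtures
# ---------------------------------------------------------------------------

def _feature_tss(g: GeneRecord) -> int:
    return g.interval.end - 1 if g.interval.strand == "-" else g.interval.start


def generate_peaks(
    cfg: SimConfig, annotation: SimAnnotation
) -> tuple[list[PeakRecord], CoverageTrack, pd.DataFrame]:
    """Plant per-replicate peaks in TSS windows with per-class probabilities.

    For each (feature, mark) a base modification state is drawn with the
    class's probability; ``replicate_noise`` independently flips the state
    per replicate. A modified replicate receives one 300-500 bp peak placed
    uniformly with its start in the TSS ±2 kb window. The coverage track is
    the sum of triangular kernels over replicate-1 peaks of the first mark.
    """
    rng = _rng(cfg, 3)
    features = list(annotation.ref_genes) + annotation.itg_gene_records()
    marks = sorted({m for m, _ in cfg.mod_prob})
    peaks: list[PeakRecord] = []
    rows = []
    for g in features:
        pos = _feature_tss(g)
        lo = max(pos - cfg.tss_window_bp, 0)
        hi = pos + cfg.tss_window_bp
        for mark in marks:
            p = cfg.mod_prob[(mark, g.source_class)]
            base = rng.random() < p
            for rep in range(1, cfg.n_replicates + 1):
                flip = rng.random() < cfg.replicate_noise
                modified = base != flip
                if modified:
                    length = int(rng.integers(300, 501))
                    start = int(rng.integers(lo, hi + 1))
                    peaks.append(
                        PeakRecord(
                            mark, rep,
                            GenomicInterval(g.interval.chrom, start, start + length),
                            score=float(rng.uniform(5, 50)),
                        )
                    )
                rows.append(
                    {
                        "feature_id": g.gene_id,
                        "feature_class": g.source_class,
                        "mark": mark,
                        "replicate": rep,
                        "modified": modified,
                    }
                )
    coverage = _coverage_from_peaks(
        [p for p in peaks if p.mark == marks[0] and p.replicate == 1]
    )
    return peaks, coverage, pd.DataFrame(rows)


def _coverage_from_peaks(
    peaks: Sequence[PeakRecord], n_steps: int = 10, height: float = 2.0
) -> CoverageTrack:
    """Sum of discretized triangular kernels, one per peak."""
    pieces: dict[str, list[tuple[int, int, float]]] = {}
    for p in peaks:
        iv = p.interval
        edges = np.linspace(iv.start, iv.end, n_steps + 1)
        mid = (iv.start + iv.end) / 2
        half = (iv.end - iv.start) / 2
        for i in range(n_steps):
            lo, hi = int(round(edges[i])), int(round(edges[i + 1]))
            if hi <= lo:
                continue
            center = (edges[i] + edges[i + 1]) / 2
            v = height * max(1.0 - abs(center - mid) / half, 0.0)
            pieces.setdefault(iv.chrom, []).append((lo, hi, v))
    return CoverageTrack(
        {chrom: _merge_steps(chunks) for chrom, chunks in pieces.items()}
    )


def _merge_steps(
    pieces: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Sum possibly-overlapping constant steps into disjoint sorted steps."""
    events: dict[int, float] = {}
    for lo, hi, v in pieces:
        events[lo] = events.get(lo, 0.0) + v
        events[hi] = events.get(hi, 0.0) - v
    out = []
    level = 0.0
    prev = None
    for pos in sorted(events):
        if prev is not None and level > 0 and pos > prev:
            out.append((prev, pos, level))
        level += events[pos]
        prev = pos
    return out


# ---------------------------------------------------------------------------
# Homolog-pair fixtures
# ---------------------------------------------------------------------------

def generate_homolog_pairs(
    cfg: SimConfig,
) -> tuple[list[tuple[str, str]], list[HomologyHit], pd.DataFrame]:
    """Sequence pairs mutated to known divergence times.

    Each pair descends from a random ancestor of ``seq_length_bp``; every
    site of the derived copy substitutes independently with probability
    2·r·T* (uniform choice among the 3 alternatives), so realized identity
    is Binomial(L, 1 − 2rT*)/L — the exact inverse of the uncorrected
    Ks = 1 − identity dating formula. The emitted hit table carries the
    realized identity with e-value 1e-30.
    """
    rng = _rng(cfg, 4)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: list[tuple[str, str]] = []
    hits: list[HomologyHit] = []
    rows = []
    L = cfg.seq_length_bp
    for ei, t_star in enumerate(cfg.divergence_times_years):
        p_sub = 2.0 * cfg.r * t_star
        if p_sub >= 0.75:
            raise ValueError(
                f"2rT* = {p_sub:.3f} >= 0.75: outside the uncorrected-"
                "identity dating regime"
            )
        for i in range(cfg.n_pairs):
            anc = rng.integers(0, 4, size=L)
            der = anc.copy()
            sub = rng.random(L) < p_sub
            # shift by 1..3 (mod 4): substituted site never keeps its base
            der[sub] = (der[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
            ident = 1.0 - sub.mean()
            id_a = f"E{ei}_P{i:04d}_a"
            id_b = f"E{ei}_P{i:04d}_b"
            seqs.append((id_a, bases[anc].tobytes().decode()))
            seqs.append((id_b, bases[der].tobytes().decode()))
            hits.append(HomologyHit(id_a, id_b, 100.0 * ident, L, 1e-30))
            rows.append(
                {
                    "pair": f"E{ei}_P{i:04d}",
                    "t_true_years": t_star,
                    "realized_identity": ident,
                }
            )
    return seqs, hits, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture bundles on disk
# ---------------------------------------------------------------------------

def write_fixture(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Generate every fixture and write it under ``outdir``.

    Truth tables go to a separate ``truth/`` subdirectory that the analysis
    stages never read. Returns a manifest of written paths. Byte-identical
    on repeated calls with the same config.
    """
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)

    ann = generate_annotation(cfg)
    tes, te_truth = generate_te_bed(cfg, ann)
    peaks, coverage, peak_truth = generate_peaks(cfg, ann)
    seqs, hits, pair_truth = generate_homolog_pairs(cfg)

    manifest: dict[str, str] = {}

    def _p(key: str, rel: str) -> Path:
        manifest[key] = str(out / rel)
        return out / rel

    write_gtf(_p("reference_gtf", "reference.gtf"), genes=ann.ref_genes)
    write_gtf(_p("transcripts_gtf", "transcripts.gtf"), transcripts=ann.transcripts)
    write_te_bed(_p("te_bed", "te.bed"), tes)
    marks = sorted({p.mark for p in peaks})
    reps = sorted({p.replicate for p in peaks})
    peak_paths = []
    for mark in marks:
        for rep in reps:
            path = out / "peaks" / f"{mark}_rep{rep}.bed"
            write_peak_bed(path, [p for p in peaks if p.mark == mark and p.replicate == rep])
            peak_paths.append(str(path))
    manifest["peak_beds"] = json.dumps(peak_paths)
    write_bedgraph(_p("coverage_bedgraph", "coverage.bedgraph"), coverage)
    write_fasta(_p("pairs_fasta", "pairs.fa"), seqs)
    write_homology_tab(_p("hits_tsv", "hits.tsv"), hits)

    ann.truth.to_csv(_p("truth_annotation", "truth/annotation.tsv"), sep="\t", index=False)
    te_truth.to_csv(_p("truth_te", "truth/te.tsv"), sep="\t", index=False)
    peak_truth.to_csv(_p("truth_peaks", "truth/peaks.tsv"), sep="\t", index=False)
    pair_truth.to_csv(_p("truth_pairs", "truth/pairs.tsv"), sep="\t", index=False)

    cfg_dict = asdict(cfg)
    cfg_dict["mod_prob"] = {f"{m}|{c}": v for (m, c), v in cfg.mod_prob.items()}
    with open(_p("config_json", "sim_config.json"), "w") as fh:
        json.dump(cfg_dict, fh, indent=2, sort_keys=True, default=str)
    return manifest
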