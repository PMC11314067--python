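"""End-to-end orchestration of the four analysis stages.

Stages run in dependency order: ``classify`` first (it defines the ITG
set), then ``te``, ``chip`` and ``date``, which are mutually independent.
A stage failure halts its dependents but already-written outputs persist.
The combined report (``report.json`` plus per-stage TSVs) is value-identical
across reruns with the same inputs and config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chip_modification import (
    ChipConfig,
    call_modified_genes,
    one_way_anova,
    proportion_summary,
)
from .genomic_io import (
    GeneRecord,
    read_gtf,
    read_homology_tab,
    read_peak_bed,
    read_te_bed,
)
from .gpdf_dating import (
    DatingConfig,
    build_identity_dataset,
    date_peaks,
    find_peaks,
    fit_gpdf,
)
from .itg_classifier import (
    ClassifierConfig,
    classify_transcriptome,
    exon_length_stats,
    exon_number_frequency,
)
from .te_proximity import (
    TEConfig,
    call_valid_insertions,
    distance_frequency,
    insertion_percentage,
)

logger = logging.getLogger("itgscan")


@dataclass
class RunConfig:
    """Inputs, per-stage configs and toggles for a full pipeline run."""

    out_dir: str
    reference_gtf: str | None = None
    transcripts_gtf: str | None = None
    te_bed: str | None = None
    peak_beds: list[str] = field(default_factory=list)
    hits_tsv: str | None = None
    stages: tuple[str, ...] = ("classify", "te", "chip", "date")
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    te: TEConfig = field(default_factory=TEConfig)
    chip: ChipConfig = field(default_factory=ChipConfig)
    dating: DatingConfig = field(default_factory=DatingConfig)
    seed: int = 0

    def required_inputs(self) -> list[str]:
        need = []
        if {"classify", "te", "chip"} & set(self.stages):
            need += [self.reference_gtf]
        if "classify" in self.stages:
            need += [self.transcripts_gtf]
        if "te" in self.stages:
            need += [self.te_bed]
        if "chip" in self.stages:
            need += self.peak_beds
        if "date" in self.stages:
            need += [self.hits_tsv]
        return [p for p in need if p is not None]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run report."""
    missing = [p for p in cfg.required_inputs() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input path(s): {', '.join(missing)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    ref_genes: list[GeneRecord] = []
    itg_genes: list[GeneRecord] = []

    if {"classify", "te", "chip"} & set(cfg.stages):
        ref_genes, _ = read_gtf(cfg.reference_gtf)

    if "classify" in cfg.stages:
        t0 = time.perf_counter()
        _, transcripts = read_gtf(cfg.transcripts_gtf)
        table, counts = classify_transcriptome(transcripts, ref_genes, cfg.classifier)
        table.to_csv(out / "classifications.tsv", sep="\t", index=False)
        with open(out / "class_counts.json", "w") as fh:
            json.dump(counts, fh, indent=2, sort_keys=True)
        itg_ids = set(table.loc[table["label"].isin(["CLASS_P", "CLASS_U"]), "transcript_id"])
        itg_genes = [
            GeneRecord(t.transcript_id, t.interval, "itg")
            for t in transcripts
            if t.transcript_id in itg_ids
        ]
        exon_rows = pd.DataFrame(
            sorted(exon_number_frequency(transcripts).items()),
            columns=["exon_count", "fraction"],
        )
        exon_rows.to_csv(out / "exon_number_frequency.tsv", sep="\t", index=False)
        stats = exon_length_stats(transcripts)
        report["stages"]["classify"] = {
            "counts": counts,
            "exon_length_stats": stats,
            "wall_s": round(time.perf_counter() - t0, 3),
        }

    if "te" in cfg.stages:
        t0 = time.perf_counter()
        tes = read_te_bed(cfg.te_bed)
        te_summary = {}
        for cls, genes in (("genic", ref_genes), ("itg", itg_genes)):
            if not genes:
                continue
            calls = call_valid_insertions(genes, tes, cfg.te)
            summary = insertion_percentage(calls, genes)
            bins = distance_frequency(calls, genes, cfg.te)
            bins.to_csv(out / f"te_distance_bins_{cls}.tsv", sep="\t", index=False)
            pd.DataFrame(
                [(c.gene_id, c.te_id, c.distance_bp) for c in calls],
                columns=["gene_id", "te_id", "distance_bp"],
            ).to_csv(out / f"te_calls_{cls}.tsv", sep="\t", index=False)
            te_summary[cls] = {
                "n_genes_total": summary.n_genes_total,
                "n_genes_with_insertion": summary.n_genes_with_insertion,
                "percentage": summary.percentage_1dp,
            }
        report["stages"]["te"] = {
            "summary": te_summary,
            "wall_s": round(time.perf_counter() - t0, 3),
        }

    if "chip" in cfg.stages:
        t0 = time.perf_counter()
        peaks = [p for path in cfg.peak_beds for p in read_peak_bed(path)]
        features = ref_genes + itg_genes
        gene_classes = {g.gene_id: g.source_class for g in features}
        calls = call_modified_genes(features, peaks, cfg.chip)
        pd.DataFrame(
            [(c.gene_id, c.mark, c.replicate, c.modified) for c in calls],
            columns=["gene_id", "mark", "replicate", "modified"],
        ).to_csv(out / "modification_calls.tsv", sep="\t", index=False)
        summaries = proportion_summary(calls, gene_classes)
        rows = []
        for s in summaries:
            row = {
                "mark": s.mark,
                "gene_class": s.gene_class,
                "mean_pct": round(s.mean_pct, 1),
                "stdev_fraction": round(s.stdev_fraction, 4),
            }
            for i, p in enumerate(s.per_replicate_pct, start=1):
                row[f"rep{i}_pct"] = round(p, 1)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "modification_summary.tsv", sep="\t", index=False)
        anova = {}
        by_key = {(s.mark, s.gene_class): s for s in summaries}
        for mark in sorted({s.mark for s in summaries}):
            a = by_key.get((mark, "genic"))
            b = by_key.get((mark, "itg"))
            if a is None or b is None:
                continue
            f_stat, p_val = one_way_anova(
                [p / 100 for p in a.per_replicate_pct],
                [p / 100 for p in b.per_replicate_pct],
            )
            anova[mark] = {"F": f_stat, "p": p_val}
        with open(out / "anova.json", "w") as fh:
            json.dump(anova, fh, indent=2, sort_keys=True)
        report["stages"]["chip"] = {
            "summary": rows,
            "anova": anova,
            "wall_s": round(time.perf_counter() - t0, 3),
        }

    if "date" in cfg.stages:
        t0 = time.perf_counter()
        hits = read_homology_tab(cfg.hits_tsv, cfg.dating.e_threshold)
        dataset = build_identity_dataset(hits, cfg.dating)
        curve = fit_gpdf(dataset, cfg.dating)
        peaks_found = find_peaks(curve, cfg.dating)
        pd.DataFrame({"identity": curve.grid, "density": curve.density}).to_csv(
            out / "identity_density.tsv", sep="\t", index=False
        )
        peak_rows = date_peaks(peaks_found, cfg.dating)
        pd.DataFrame(peak_rows).to_csv(out / "identity_peaks.tsv", sep="\t", index=False)
        report["stages"]["date"] = {
            "n_pairs": int(dataset.values.size),
            "peaks": peak_rows,
            "wall_s": round(time.perf_counter() - t0, 3),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
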