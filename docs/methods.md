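# Methods

`itgscan` characterizes *intergenic genes* (ITGs) — transcribed loci that
de-novo transcript assembly recovers between annotated genes — in four
stages: distance-based classification, transposable-element (TE) insertion
proximity, histone-modification peak assignment, and sequence-identity-peak
divergence dating. A seeded synthetic-data generator with exact ground
truth backs every stage. This note records the models, the conventions the
package commits to where several readings were possible, and what the
synthetic benchmarks do and do not demonstrate.

## Coordinate and interval conventions

All coordinates are internal 0-based half-open intervals; GTF/GFF3 (1-based
inclusive) is converted only at the I/O boundary, BED and bedGraph pass
through unchanged. The distance between two intervals on one chromosome is
the unsigned gap in bases: 0 for overlap *or* abutment, otherwise
`max(a.start, b.start) − min(a.end, b.end)`. Distances across chromosomes
are undefined (a sentinel, never a large number). Chromosome names match by
exact string equality; no `chr` normalization is applied, because silent
renaming hides input mismatches.

The transcription start site (TSS) is the 5′ end of the feature on its
strand: `start` for `+`, `end − 1` for `−`. Assembler-derived transcripts
may be unstranded (`.`); their TSS falls back to the left end, as for `+`,
and the fallback is logged once per run. This is a documented choice — for
unstranded loci no orientation is knowable — and symmetric analyses
(classification, TE distance) never depend on it.

## ITG classification

Each assembled transcript is scored by the minimum span-to-span gap `d` to
any reference gene on its chromosome, strand-agnostically:

| condition            | label              |
|----------------------|--------------------|
| d = 0                | `GENIC_OVERLAP`    |
| 0 < d < 500 bp       | `PROXIMAL_EXCLUDED`|
| 500 ≤ d < 1500 bp    | `CLASS_P`          |
| d ≥ 1500 bp          | `CLASS_U`          |

The ITG set is `CLASS_P ∪ CLASS_U`. "At least 1.5 kb" includes the
boundary, so `d = 1500` is class u, and the p window is half-open to keep
the classes disjoint. Transcripts closer than 0.5 kb are kept as an
explicit `PROXIMAL_EXCLUDED` class rather than silently dropped, so
per-class counts always sum to the input size. Transcripts on chromosomes
absent from the reference are class u with an undefined distance and a
logged flag. Both thresholds are configurable (`ClassifierConfig`, bp).

Expression uses the standard FPKM definition on the longest transcript per
gene (largest summed exon length; ties break to the lexicographically
smallest transcript id so reruns are stable):
`FPKM = count · 10⁹ / (library_size · exonic_length_bp)`. Exon-length
medians pool all exons across transcripts; even counts take the mean of
the central pair.

## TE insertion proximity

A TE is a *valid insertion* for a feature when their unsigned gap is at
most `window_bp` (default 1000 bp, boundary inclusive); body overlaps
count with distance 0. Upstream and downstream are pooled into one
unsigned axis — a single rule that also covers TEs contained in exons. The
family filter (default `{LTR}`) is applied before any distance logic.

Three summaries are produced per feature class:

* **insertion percentage** — fraction of features with ≥ 1 valid
  insertion; a feature counts once however many TEs hit it; rounding to
  one decimal happens only at report time;
* **distance-binned frequency** — each feature contributes its *nearest*
  valid TE to one of the 100-bp bins `[0,100) … [900,1000]` (last bin
  closed); the denominator is the whole feature class, so bin fractions
  sum to the insertion fraction and are directly comparable to the
  percentage;
* **insertion-count histogram** — features per insertion count, including
  the zero class, so the histogram mass equals the class size.

Nearest-per-feature (rather than per-hit) frequencies were chosen because
they make the binned distribution and the headline percentage share a
denominator; the per-hit variant is recoverable from the calls table.

## Histone-modification assignment

A feature is *modified* for a (mark, replicate) when at least one called
peak of that mark/replicate overlaps the ±2 kb TSS window. The window is
`[tss − w, tss + w + 1)` in half-open coordinates — so the literal
position `tss + 2000` is inside — and is clipped at the chromosome start.
Called peak intervals, not raw coverage, define modification; coverage is
used only for metagene profiles.

Replicate summaries follow a mixed-scale convention: the mean is the
arithmetic mean of per-replicate percentages, while the dispersion is the
sample standard deviation (n−1 denominator) of the per-replicate
*fractions*. Both scales are exposed in the JSON output. Note that when
replicate percentages are themselves rounded to one decimal before
summarizing, the recomputed mean can legitimately differ from a mean taken
on unrounded data by up to 0.05 in the last printed digit; such published
roundings cannot always be reproduced exactly from rounded inputs.

Group comparison uses classical one-way ANOVA, `F = MS_between/MS_within`
with df (k−1, N−k); with exactly two groups this equals the squared
two-sample t statistic. When both groups are constant and equal the test
is vacuous and (F, p) = (0, 1) by convention, logged.

Metagene profiles scale each gene body to 100 equal-width bins with 20
fixed 100-bp bins per 2-kb flank (140 bins total), reverse minus-strand
genes so profiles read 5′→3′, average across genes, and normalize by the
genome-wide mean coverage (track integral over total covered extent).
Genes shorter than one bin per base (100 bp at defaults) are skipped with
a warning.

## Identity-peak divergence dating

Pairwise identities between homologous sequences — from a 12-column
tabular homology scan (E ≤ 10⁻⁵, self-hits removed, one best hit per
unordered pair: lowest e-value, then highest identity) or from internal
global alignment (match +1, mismatch −1, gap −2; identity = matches /
aligned columns, gap columns included) — are pooled as fractions in [0, 1]
and smoothed with a Gaussian-kernel density estimate on a fixed grid (step
0.001). Bandwidth is Silverman's rule by default, or a fixed value in
identity units. "Normalization" of the identities means percent→fraction
conversion plus the area-1 normalization inherent to a density; no other
transform is applied.

Modes are local maxima with topographic prominence ≥ 5% of the density
maximum **and** at least that margin above the median density over the
support (where density ≥ 1% of max). The second condition exists because
the global maximum of *any* density has full topographic prominence — the
curve decays to zero outside the data — so prominence alone would report a
"peak" for a flat distribution. An all-equal dataset yields one delta-like
peak with a warning. A BIC-selected Gaussian-mixture fit is available as
an independent cross-check of peak locations; it never replaces the
kernel-density route.

Each peak identity is dated with the molecular-clock relation

    T = Ks / (2 r),    Ks = 1 − identity_peak,

with r = 1.5 × 10⁻⁸ substitutions · site⁻¹ · year⁻¹ by default. No
multiple-hit (Jukes–Cantor) correction is applied, so Ks is the raw
identity complement and the relation is meaningful only well below
saturation (the generator refuses 2rT* ≥ 0.75 for the same reason).
Identity 0.786 therefore dates to (1 − 0.786)/(3 × 10⁻⁸) ≈ 7.13 × 10⁶
years — 7 Mya to the nearest million — which is what
`scripts/acceptance.py` recomputes.

## Synthetic data: what it emulates and what it does not

The generator plants every feature in a fixed-pitch 20-kb cassette: one
4-kb reference gene plus one transcript at a controlled gap (overlap for
genic; exact boundary gaps 1, 499, 500, 1499, 1500 bp planted
deterministically when class sizes allow). Cassettes are randomly
oriented; the TE zone sits on the gene's outer flank and peaks are
confined to TSS windows that the geometry keeps pairwise disjoint.
Consequences:

* planted class labels, TE distances, and per-replicate modification
  states are *exactly* recoverable — recovery tests assert equality, not
  tolerance;
* planted rates (TE insertion probabilities 0.199 genic / 0.423 ITG;
  per-mark modification probabilities around 0.44–0.75; divergence epochs
  1.6 and 7.0 Mya at 500 pairs × 2000 bp) are recovered within binomial
  sampling error, which the acceptance tests bound at 3 standard errors.

Defaults mirror the headline statistics of intergenic-gene studies in
allotetraploid cotton, so a demo run produces tables with familiar
magnitudes; every value is configurable. TE distances are drawn from a
named law over 0…1000 bp — truncated geometric with per-bp decay 0.997 by
default (a ~3-fold fall across the window, echoing the steep decay seen
for ITGs), or uniform — with exact bin probabilities available for
goodness-of-fit tests. Homolog pairs substitute each site at most once
with probability 2rT*, so realized identity is exactly
Binomial(L, 1 − 2rT*)/L and the dating formula inverts the simulation
analytically.

What the generator does **not** emulate: overlapping or nested real gene
models, strand-biased TE accumulation, replicate-correlated peak-calling
artifacts, input-normalized enrichment, indels in homologs, or genome-scale
feature density. Passing recovery tests therefore demonstrates correctness
of the interval logic and estimators under clean geometry and known noise,
not robustness to the full messiness of real annotations.

## Numerical and degenerate-input choices

* Sample standard deviation over identical replicates returns exactly 0
  (float cancellation noise is suppressed).
* KDE on an (almost) constant dataset — std below 10⁻⁹ — short-circuits to
  a narrow Gaussian instead of a singular covariance fit.
* Density mass outside [0, 1] (edge leakage for identities near 1) is
  warned about, not renormalized.
* Longest-transcript ties, peak ordering, and report serialization are all
  deterministic; reports are value-identical across reruns (wall-clock
  fields excluded).
* All randomness flows from explicit integer seeds through per-stage
  `numpy` generator streams; fixture bundles are byte-identical across
  repeated writes.

Problem sizes in the test suite (up to 10 000 cassettes for TE recovery,
2 000 features for ChIP, 1 000 homolog pairs) were chosen as the smallest
sizes at which the 3-standard-error recovery bounds are informative.

## Known limitations

* Unstranded-TSS orientation is a convention, not an inference; metagene
  profiles for unstranded features inherit it.
* `Ks = 1 − identity` without saturation correction underestimates ages
  as identity drops; the package intentionally reproduces the uncorrected
  convention rather than a codon-aware Ks.
* The internal aligner reports the identity of one optimal alignment;
  co-optimal alignments can differ slightly in identity when indels are
  present (the tests bound this with an independent DP).
* The pipeline consumes standard upstream outputs (GTF, BED, tabular
  homology); it does not align reads, assemble transcripts, or call peaks.
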