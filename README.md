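# itgscan

Characterization of **intergenic genes (ITGs)** — transcribed loci that
de-novo transcript assembly recovers between annotated genes, as in the
allotetraploid cotton (*Gossypium hirsutum*) transcriptome. Given a
reference annotation, assembled transcript models, repeat annotations,
ChIP-seq peak calls, and homology hits, `itgscan`:

1. **classifies** each assembled transcript by its distance to the nearest
   known gene — overlap, class "p" (0.5–1.5 kb away), class "u" (≥ 1.5 kb
   away), or proximal-excluded (< 0.5 kb) — and computes exon and FPKM
   statistics on longest transcripts;
2. **scores TE/LTR insertion proximity**: a TE within 1 kb of (or
   overlapping) a feature is a valid insertion; per-class insertion
   percentages, nearest-TE distance bins, and insertion-count histograms;
3. **assigns histone-modification peaks** (H3K27ac, H3K4me3, H3K4me1, …)
   to features via a ±2 kb TSS window, summarizes per-replicate modified
   proportions (mean in %, SD of fractions, n−1), compares gene classes by
   one-way ANOVA, and builds scaled metagene coverage profiles;
4. **dates divergence events** from sequence-identity distributions: a
   Gaussian-kernel density over pairwise identities, mode detection, and
   the molecular-clock conversion

       T = Ks / (2 r),   Ks = 1 − identity_peak,

   with r = 1.5 × 10⁻⁸ substitutions · site⁻¹ · year⁻¹ by default, so an
   identity peak at 78.6% dates to ≈ 7 Mya (the At/Dt homoeolog split in
   allotetraploid cotton).

A seeded synthetic-data generator (`itgscan.synthetic_data`) emits
standards-compliant GTF/BED/bedGraph/FASTA/tabular fixtures with exact
ground truth for every stage, so the whole pipeline is testable without
any external data. See `docs/methods.md` for conventions and limitations.

## Worked example

Simulate a small dataset (50 transcripts: 20 genic-overlap, 15 class u,
10 class p, 5 proximal; TEs, three marks × three replicates of peaks, and
500 homolog pairs each at 1.6 and 7.0 Mya), then run all four stages:

```sh
itgscan simulate --seed 7 --out fixtures/
itgscan run --fixtures fixtures/ --out results/
```

`results/report.json` then contains (abridged):

```json
"classify": {"counts": {"GENIC_OVERLAP": 20, "CLASS_P": 10, "CLASS_U": 15,
                        "PROXIMAL_EXCLUDED": 5, "ITG": 25}},
"te": {"summary": {"genic": {"n_genes_total": 50, "n_genes_with_insertion": 6,
                             "percentage": 12.0},
                   "itg":   {"n_genes_total": 25, "n_genes_with_insertion": 9,
                             "percentage": 36.0}}},
"chip": {"anova": {"H3K4me1": {"F": 1.66e+31, "p": 2.17e-62}, ...}},
"date": {"peaks": [{"identity": 0.952, "ks": 0.048, "time_mya": 1.6, ...},
                   {"identity": 0.790, "ks": 0.210, "time_mya": 7.0, ...}]}
```

Reading: all 50 planted classification labels are recovered exactly; at
this small n the TE percentages (12.0% of 50 genic genes, 36.0% of 25
ITGs) scatter around the planted probabilities 19.9% and 42.3% within
binomial error; the planted H3K4me1 separation (74.8% of genic features
modified vs 44.0% of ITGs) is overwhelmingly significant; and the two
identity-density peaks at 95.2% and 79.0% date to 1.6 and 7.0 Mya — the
planted divergence times — via T = Ks/2r.

The same operations are available as a library:

```python
from itgscan import divergence_time
divergence_time(0.786, 1.5e-8)   # 7133333.3 years  ->  ~7 Mya
```

Stage-level subcommands (`itgscan classify|te|chip|date`) run each
analysis on your own GTF/BED/tabular inputs; see `--help` for flags.

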