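# hscp

Time-resolved, cross-model analysis of hepatic stellate cell (HSC)
activation transcriptomes.

Quiescent HSCs transdifferentiate into extracellular-matrix-producing
myofibroblasts during liver fibrosis. Profiling that activation over
time in several disease models — diet-induced NASH (Western diet +
fructose, WD), hepatotoxic injury (CCl₄), and in vitro
transdifferentiation (IVT) — raises a chain of analysis questions this
package answers end to end:

1. **Differential expression** per model and time contrast, with a
   conditional negative-binomial exact test. With library sizes
   equalized, each group's count sum `S_g ~ NB(n_g·μ, φ/n_g)`;
   conditional on the gene's total the split probability is
   negative-hypergeometric (the unknown mean μ cancels), so the
   two-sided p is the exact sum of all split probabilities ≤ the
   observed one. φ is a common dispersion estimated by moments.
2. **Common genes**: genes changing ≥ 4-fold (FDR < 0.05) between some
   pair of time points in *every* model, same direction — the
   conserved activation program.
3. **Time-course clustering** of the common genes' scaled
   (log₂(x+1), z-scored) average-RPKM profiles by k-medoids (PAM)
   under Pearson-correlation distance `d = 1 − r`, k chosen by average
   silhouette width, followed by removal of the 10% worst-fitting
   genes (fit = r of a gene to its cluster's mean profile) and of an
   undersized smallest cluster.
4. **Cross-model cluster pairing** by optimal assignment on prototype
   correlations, shared-gene extraction, and hypergeometric overlap
   probabilities.
5. **Promoter motif analysis**: proximal promoters (−300..+50 around
   the TSS, strand-aware) scanned with ETS1 / ETS1-like / RUNX1 / AP-1
   position weight matrices (log₂-odds ≥ 80% of the maximum score, both
   strands), ZOOPS presence tables, hypergeometric motif enrichment,
   and ETS1–RUNX1 spacing.
6. **Motif-conditional induction statistics**: genes grouped by motif
   content (none / ETS1-only / RUNX1-only / both), compared by exact
   pairwise Wilcoxon rank-sum tests with BH correction and a compact
   letter display; rank analysis; cluster × motif enrichment; and
   generic GMT-based over-representation analysis.

A first-class synthetic-data generator emulates the three-model study
design — NB counts with common dispersion, planted temporal programs
(including strongly induced and repressed ones), and promoters in
which ETS1+RUNX1 motif presence is coupled to induction — so every
stage is verifiable against planted truth without any downloads.

## Worked example

```bash
python examples/04_full_pipeline.py
```

runs the whole pipeline on an 800-gene synthetic study and prints:

```
common genes: 189
WD clusters: k=4 (avg prototype Pearson 0.993)
shared genes across paired WD/CCl4 clusters: 96
median log2FC by motif group: {"none": 2.87, "a_only": -2.81, "b_only": 2.78, "both": 5.54}
dual-motif genes: 40, of which 38 fall in the most induced cluster
56 files written under .../run
```

Reading: 189 genes are ≥ 4-fold regulated in all three models; their
WD time courses fall into 4 tight clusters (members correlate 0.993
with their cluster mean); 96 genes stay together when WD and CCl₄
clusterings are paired; and among common genes the dual ETS1+RUNX1
promoter group is far more induced (median log₂FC 5.54) than genes
without these motifs (2.87), with the dual-motif genes concentrated in
the most induced cluster — the planted motif/induction coupling, read
back out by the statistics.

The other examples cover the stages individually
(`01_simulate_and_de.py`, `02_common_genes_and_clustering.py`,
`03_motifs_and_induction.py`). A thin CLI wraps the same library:

```bash
hscp run --config run.yaml        # full pipeline (files or synthetic:)
hscp simulate --out data/ --n-genes 5000 --seed 1
hscp de --counts ... --model WD --contrast 24:0 --out de.tsv
hscp motifs --genome genome.fa --annot annotation.tsv --pwms pwms.jaspar --out hits.tsv
```

## Layout

```
src/hscp/
  synthetic_data.py   generator: planted truth, counts, genome, PWMs, GMT
  data.py             CountMatrix + annotation I/O
  diffexpr.py         CPM/RPKM, dispersion, NB exact test, BH, shift test
  common_genes.py     cross-model regulated-gene selection
  clustering.py       VST/scaling, PAM, silhouette k, fit filter
  cluster_matching.py prototype pairing, shared genes, overlap p
  motifscan.py        promoters, PWM scanning, ZOOPS, enrichment, spacing
  induction_stats.py  motif groups, Wilcoxon/letters, ranks, ORA
  pipeline.py         run_all orchestration + run report
  cli.py              click CLI (`hscp`)
```
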