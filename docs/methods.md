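# Methods

This note documents the models, conventions, and design choices behind
`hscp`, in the order the pipeline runs them.

## Synthetic study design

The generator (`synthetic_data`) emulates a three-model HSC-activation
study: Western diet + fructose feeding sampled at 0/12/16/24 weeks
(n = 4), CCl₄ treatment at 0/1/4/8 weeks (n = 4), and in vitro
transdifferentiation at 0/1/4/8/12 days (n = 3). Key parameters, with
defaults:

- **Baseline expression**: gene means drawn log-normal, log₂ mean 5,
  log₂ sd 2. This spans the dynamic range needed to exercise the
  log₂CPM > 2 testing floor and the RPKM ≥ 10 ORA filter.
- **Counts**: negative binomial with a single common dispersion
  φ = 0.1 (gamma–Poisson draw; Poisson at φ = 0). Per sample,
  mean = baseline · 2^(planted log₂FC at t) · (libsize/10⁶).
- **Library sizes**: uniform in [0.8, 1.2]·10⁶, so CPM ≈ count and
  worked examples stay legible. The drawn target depths are attached
  to the `CountMatrix` rather than recomputed as column sums: the
  planted programs are deliberately asymmetric (net induction), so
  realized column sums drift upward with activation and total-count
  normalization would push every null gene's apparent log₂FC down by
  the library-inflation factor. Real data would need TMM-style
  composition correction (left as a hook); the generator simply knows
  its true depths.
- **Planted programs**: six temporal shapes specified as z-scaled
  control points on unit time and linearly interpolated onto each
  model's normalized time grid — a strongly induced program, a
  repressed program, early-up, transient, late-up, and early-down —
  covering 30% of genes (6 + 6 + 4 × 4.5%); the rest are null. Shapes
  convert to log₂FC trajectories via `amplitude × (z(t) − z(0))` with
  amplitude 1.5, giving peak fold changes of roughly 8–32× —
  comparable to strongly regulated activation genes.
- **Motif coupling**: genes in the induced program receive both an
  ETS1 and a RUNX1 consensus instance with probability 0.8; all other
  placements are independent per-gene background (10% per motif;
  AP-1 at 10%, 30% in the induced program). Dual-motif genes inside
  any planted program additionally gain a +2 log₂FC shift ramped with
  normalized time — the planted analogue of motif-coupled induction
  strength. Null genes never receive the shift, so the null
  distribution stays centered for calibration checks.
- **Genome**: genes tiled on synthetic contigs (100 genes/contig) with
  2 kb flanks around a 350 bp promoter slot; minus-strand genes embed
  the reverse complement so extraction is a strict round trip.
  Promoters are uniform-random sequence with consensus motif
  instances written at recorded positions/strands (non-overlapping;
  optional fixed ETS1–RUNX1 midpoint spacing).

What the generator does **not** emulate: read-level noise and
alignment, isoforms, batch effects, composition bias (see above),
GC/mappability structure, correlated gene programs beyond the planted
shapes, and realistic motif degeneracy (planted sites are consensus
instances, so scanner recall is by construction near 1 — the
false-hit rate is the informative direction). Passing tests therefore
demonstrate correctness of the statistics and bookkeeping, not
robustness to technical artifacts of real libraries.

All randomness flows from one config seed through fixed substreams
(`default_rng([seed, stream])`), making every output byte-identical
across runs.

## Differential expression

- **Normalization**: CPM = count/(libsize/10⁶); RPKM = CPM/length_kb;
  log₂ values add a prior count (default 0.5 on the CPM scale) so zero
  counts map to finite values; log₂FC is computed from
  prior-stabilized group-mean CPM.
- **Dispersion**: method of moments. For each gene × replicated group,
  the ratio (v − m)/(m² − v/n) estimates φ (E[v] = m + φm²; the −v/n
  term unbiases m̂²). The common φ is the 10%-trimmed mean of these
  ratios over expressed genes (mean ≥ 10 when ≥ 50 qualify), floored
  at 0. A plain ratio of pooled sums is dominated by the heaviest
  genes under log-normal means and was measured to swing 0.30–0.56 at
  true φ = 0.4; trimming equalizes gene influence and recovers φ
  stably (0.38–0.40 in the same setting).
- **Exact test**: library sizes are equalized to their geometric mean
  by pseudo-count scaling (rounded). Conditional on a gene's total t,
  the probability of split s is ∝ C(s+r_A−1, s)·C(t−s+r_B−1, t−s)
  with r_g = n_g/φ (binomial with p = n_A/(n_A+n_B) at φ = 0); the
  two-sided p sums all splits with probability ≤ the observed one
  (relative tolerance 1e-12 against float noise). This is checked to
  1e-10 against an independent enumeration that uses explicit NB pmfs
  at an arbitrary mean.
- **Testing floor**: BH-FDR is computed only over genes whose mean
  log₂CPM across the model's samples exceeds the floor (default 2),
  one floor per experiment; untested genes carry NaN FDR.
- **Distribution shift**: paired two-sided Wilcoxon signed-rank on
  per-gene mean log₂ expression, activated vs control; exact by
  sign-flip enumeration for ≤ 15 nonzero differences (average ranks
  handle ties), normal approximation above; all-zero differences
  define p = 1.

## Common genes

A gene is regulated in one model if any later-vs-earlier contrast has
|log₂FC| ≥ log₂(4) (closed bound) at FDR < 0.05 (open bound). "Any two
time points" means all ordered pairs by default; a control-only mode
restricts to t vs t₀. The common set intersects the per-model flags
requiring the same direction everywhere; genes flagged in both
directions anywhere are excluded and counted.

## Clustering

- **VST/scaling**: log₂(x+1) on per-timepoint average RPKM, then
  per-gene z-scoring with the *sample* standard deviation (ddof = 1);
  the convention is fixed so the worked example
  (0,1,3,7) → (−1.1619, −0.3873, 0.3873, 1.1619) is reproducible.
  Constant rows are flagged and excluded from clustering.
- **PAM**: k-medoids under d = 1 − Pearson r. Small instances
  (C(n,k) ≤ 20,000) are solved exactly by vectorized subset
  enumeration — single-swap descent measurably stalls in local optima
  on ~13% of small random instances — and larger instances run the
  deterministic greedy BUILD phase plus steepest-descent SWAP with
  O(n²)-per-iteration swap deltas. No seed is involved anywhere.
- **k selection**: average silhouette width over a k range (default
  2–12), computed directly from the precomputed distance matrix; ties
  resolve to the smallest k.
- **Fit filter**: fit = Pearson r of a gene's profile to its own
  cluster's mean profile. The globally lowest 10% (floor(n·frac),
  ties by gene id) are discarded, then the single smallest cluster is
  removed if its size is below 20 (configurable); prototypes and fits
  are recomputed. The filter is global, not per-cluster.

## Cluster matching

Prototypes from two models are paired one-to-one by maximizing total
Pearson r (Hungarian assignment; deterministic and order-independent).
Unequal time-axis lengths are reconciled by linear interpolation of
the shorter prototype onto the longer ordinal grid. Shared genes are
per-pair member intersections; overlap significance is the upper-tail
hypergeometric probability with the universe defined as genes retained
(post fit-filter) in **both** clusterings — genes discarded in either
model were never eligible for the pair.

## Motif scanning

- **PWMs**: JASPAR count matrices plus a pseudocount of 0.8 split by
  the background composition (default uniform), log₂-odds against the
  background. A site is called when a window's score on either strand
  reaches 80% of the PWM's maximum achievable score (configurable);
  windows containing N are skipped. Reverse-strand scores use the
  reverse-complemented matrix on the forward sequence, so reported
  positions are always forward-promoter window starts.
- **Promoters**: window (−300, +50) around the 0-based TSS; plus
  strand [tss−300, tss+50), minus strand [tss−49, tss+301)
  reverse-complemented; genes whose window leaves the contig are
  excluded with a warning, and sequences > 50% N are flagged.
- **ZOOPS**: gene-level presence is binary (≥ 1 hit); motif families
  (e.g. the ETS1-like set) collapse by OR over member PWMs.
  Enrichment of presence in a target list vs a background is the
  upper-tail hypergeometric p, BH-corrected across PWMs.
- **Spacing**: midpoint-to-midpoint distance of the nearest
  ETS1/RUNX1 hit pair per promoter, averaged over qualifying
  promoters. With placement uniform at random in a 350 bp window the
  expectation is ≈ 117 bp; a planted fixed spacing is recovered
  exactly.
- Position-frequency matrices of hit sequences (minus-strand hits
  reverse-complemented) are available as the text-level analogue of
  motif logos.

## Induction statistics

- **Groups**: none / A-only / B-only / both by presence of two motifs
  (default the ETS1-like family and RUNX1) over the common genes.
- **Comparisons**: two-sided Wilcoxon rank-sum for all group pairs —
  full enumeration (tie-exact) when the combined size is ≤ 16, scipy's
  exact method for tie-free samples ≤ 50 per group, normal
  approximation with continuity correction above — BH across pairs.
  The compact letter display assigns letters by connected components
  of non-significant pairs, so groups not sharing a letter differ at
  the FDR threshold.
- **Ranks**: genes ranked by log₂FC descending (rank 1 = most
  induced, average ranks on ties); medians per group.
- **Cluster × motif**: per cluster (including "no cluster" for
  fit-filtered genes), overlap count, enrichment ratio
  (count/size)/(total/universe), and upper-tail hypergeometric P;
  counts are additive across clusters by construction.
- **ORA**: foreground and background restricted to expressed genes
  (max average RPKM over time points ≥ 10, closed bound); upper-tail
  hypergeometric per gene set, BH across sets, enriched at FDR ≤ 0.01;
  optionally reports each set's member median log₂FC for a chosen
  contrast.

## Numerical and reporting conventions

- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)`; BH via
  statsmodels with NaN masking (NaNs propagate, excluded from m).
- All TSV output uses `%.10g` floats; the run report (`report.json`)
  contains no timestamps, so identical configs produce byte-identical
  run directories (verified by test).
- Degenerate cases: all-zero genes give p = 1; constant profiles are
  excluded from clustering; clusters with zero-variance prototypes
  yield NaN fits and are flagged; empty motif groups are dropped from
  comparisons with a warning.

## Problem sizes

The acceptance script runs the reference study at 5,000 genes
(≈ 40 s on one CPU); the test suite uses 300–800-gene studies for
end-to-end checks, 600-gene instances for planted-cluster recovery,
and 2,000-gene null simulations for calibration — sizes at which the
measured quantities (type-I error, ARI, recall) are stable while the
suite stays fast.

## Known limitations

- The common-dispersion model has no tagwise/trended shrinkage;
  genes with gene-specific overdispersion will be mis-calibrated.
- Total-count normalization only (TMM hook unimplemented); see the
  composition-bias discussion above.
- The silhouette criterion tends to merge planted programs that
  become collinear after z-scoring on few time points (a 4-point
  z-scored profile has 2 effective degrees of freedom), so the
  selected k on 4-timepoint models is often below the number of
  planted shapes; the clusters it does return are tight (average
  prototype r > 0.99 on synthetic data).
- Wilcoxon exact paths enumerate; above the documented cutoffs the
  normal approximation is used without permutation fallback.
- The scanner treats promoter hits independently; no composite
  two-factor motif model is fitted.
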