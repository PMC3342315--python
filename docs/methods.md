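# Methods

`regnet` re-implements, as a tested library, an integrative strategy for
calling the direct target genes of a transcription factor (TF): promoter
ChIP-chip binding filtered against an IgG control, motif enrichment around
binding peaks, a single-array knockdown expression test, hypergeometric
cross-dataset integration, and tumor-cohort co-upregulation scoring.  This
note records the models, the parameters that matter, and the design choices
made where the underlying procedure was open.

## Peak screening and promoter assignment

Peaks are genomic intervals in BED convention (0-based, half-open) carrying
a peak score and a per-peak FDR from the upstream peak caller; the package
consumes these scores and never recomputes them from probe intensities.
The screen is two filters applied in either order (they commute): keep
peaks with FDR ≤ 0.2 (inclusive), then discard any peak sharing ≥ 1 bp with
an IgG-control peak — half-open adjacency is zero overlap and is retained.
Survivors are assigned to every promoter window they overlap by ≥ 1 bp; a
peak spanning two adjacent windows counts for both genes.  The key set of
that assignment is the factor's ChIP target gene set.

Promoter windows default to −2,200/+500 bp around the TSS, emulating a
RefSeq-style promoter tiling array.  Binding-position histograms use the
peak midpoint's strand-corrected offset from the TSS (negative = upstream;
offsets of minus-strand genes are sign-flipped).  Bins default to 100 bp and
are aligned so one bin is centered on offset 0: with edges at multiples of
the bin width, a zero-centered binding distribution splits its mode evenly
between the two bins flanking 0 and "the modal bin" would be a coin flip.

## Motif enrichment

PWMs are 4×w count matrices; log-odds use background-proportional
pseudocounts, entry(b,j) = log2((c_bj + λπ_b)/(Σc_j + λ)/π_b) with λ = 1
and uniform π by default.  Scanning covers both strands of fixed-width
windows (600 bp, centered on peak midpoints); a hit is any placement
scoring ≥ 0.8 × the motif's maximum achievable score, reported in forward
coordinates so a sequence and its reverse complement yield mirrored hit
sets.  Windows overlapping an N are skipped.

Enrichment is a binomial region-hit test: for each motif, the background
rate is the fraction of background windows with ≥ 1 hit (clamped half a
count away from 0 and 1 so the tail probability stays in (0, 1]), and the
p-value is the binomial upper tail of the number of hit-carrying peak
windows at that rate.  The background defaults to dinucleotide-preserving
shuffles of the peak windows (Altschul–Erickson Eulerian-path shuffle,
seeded).  This is a deliberate methodological substitute for rank-based
motif tools whose internal statistic is not published; it is not claimed to
be equivalent to them.  Motifs are ranked by ascending p and flagged at
p < 0.05.  Peak-to-motif distances take, per region with hits, the signed
center offset of the closest hit.

## Differential expression with one array per condition

With a single array per condition there is no within-group variance, so the
per-gene statistic is the log2 fold change itself, LFC = log2(mean kd
intensity / mean control intensity) on the linear scale.  The null is
normal with moments estimated empirically from the control arrays: per-gene
log2 ratios are pooled over all ordered pairs of distinct control arrays
(the pool is antisymmetric, so μ̂ ≈ 0) and σ̂_pair is their standard
deviation, ≈ √2 times the per-array technical noise.

One calibration detail: the pairwise ratio has variance 2σ², but the
statistic, when several control arrays are averaged, has variance
σ²(1/n_kd + 1/n_ctrl).  `run_de` therefore rescales σ̂_pair by
√((1/n_kd + 1/n_ctrl)/2) before computing p-values; for the one-versus-one
design the scale is exactly 1.  Without this the p-values are conservative
(for 1 kd vs 3 controls, KS distance from uniform ≈ 0.10 under a pure
null); with it they pass a KS < 0.05 uniformity check at 10,000 genes.

P-values are two-sided normal tails, adjusted by Benjamini–Hochberg
(step-up, ties broken by stable sort, adjusted values floored at the raw p
to guard float round-off).  Genes with FDR < 0.01 are classified down or up
by the sign of LFC − μ̂; everything else is unchanged.  Intensities are
assumed pre-normalized; an optional per-array median scaling is provided
but off by default.  Log base 2 is used throughout; classification and
(after rescaling σ) p-values are invariant to the base.

## Integration

Gene-set overlap significance is the inclusive hypergeometric upper tail
P(X ≥ k) — the probability of the same number or more shared genes when
both sets are drawn at random from the universe — matching R's
`phyper(k−1, ..., lower.tail=FALSE)`.  Universe sizes are configuration:
18,511 for binding-platform comparisons and 30,500 for the expression
platform by default.  Direct targets are the plain intersection of the
ChIP target set with the DE up/down genes.  Enrichment of ChIP targets
within each regulation class is per-class hypergeometric (not a ranked,
weighted GSEA; the overlap framing keeps all three classes on the same
statistic).  The histone-mark overlay reports, per mark, the exact count
and fraction of target promoters in the mark's gene set.  Gene identifiers
are upper-cased and whitespace-stripped before any set operation.

## Tumor co-upregulation

Expression Z-scores (gene × tumor, standardized against diploid-reference
tumors) are binarized at Z > 1.65 — strictly, so ties at the threshold are
not over-expressed; 1.65 is the ~top-5% point of a normal.  For each gene,
a 2×2 table against the anchor factor over tumors (a = both over, b =
anchor only, c = gene only, d = neither) yields an odds ratio (Haldane
+0.5 on zero-cell tables) and a one-sided Fisher p (the hypergeometric
upper tail of a).  A gene co-upregulates when OR > 1.5 with a ≥ 1 — a gene
never over-expressed together with the anchor is not called co-upregulated
even though the corrected OR of an a=c=0 table can be large — and a "hit"
additionally requires p < 0.05.  Fisher's exact test is conservative at
n = 316, so the realized null hit rate sits below α (~2–3% at α = 5%).

The set-level question — are the factor's targets enriched for hits? —
uses Pearson's chi-square (no continuity correction by default; Yates
available) comparing the target hit rate with the background.  The
background defaults to the disjoint non-target remainder; the overlapping
"all tested genes" construction is available behind a flag.  On the
printed counts of the motivating analysis (18/137 targets vs 873/11,201
overall) the default construction gives p ≈ 0.021 — conventions differ
across chi-square variants (0.019–0.032), and the original convention is
not recoverable.  The anchor gene is excluded from both target and
background sets.

## Synthetic-data generator

The generator emulates the full study with known truth; defaults are the
study's stated conditions where stated, and field-typical values otherwise:

- **Genes/promoters**: 2,000 genes (desk-scale default; tests use up to
  10,000), non-overlapping −2,200/+500 bp windows, mixed strands, uniform
  ACGT window sequences.
- **Binding**: the TF binds 12% of genes (peak centered at TSS + N(0, 200 bp),
  FDR ~ U[0, 0.2]); 10% of unbound genes get decoy peaks with FDR > 0.2;
  10% of true TF peaks are duplicated into the IgG list as shared
  artifacts, and IgG gets non-specific peaks at unbound promoters only, so
  exact recovery algebra holds: the screened gene set equals bound ∖
  artifact-genes.  PolII and H3K4me3 are planted to co-occur with TF
  binding (80%/70% of bound genes vs 35%/45% elsewhere); H3K27me3 is
  planted strictly outside H3K4me3 and covers ~2% of bound genes.
- **Motifs**: a PBX-like consensus (TGATTGAT) is written into 60% of true
  TF peak regions at peak center + N(0, 75 bp), random strand; realized
  offsets are recorded per region.
- **Expression**: log2-uniform baselines, N(0, 0.2) per-array log2
  technical noise, 3 control + 1 knockdown arrays.  Effects are planted in
  units of the statistic's null sd (scale-free z-shifts): direct targets at
  −5.5σ (~2.4-fold knockdown at the default noise — a realistic strong
  siRNA effect), indirect regulated genes at ±5σ.  30% of bound genes are
  direct targets; overall 7% of genes are regulated.
- **Tumor cohort**: 316 tumors; background normal scaled so the Z > 1.65
  rate equals 5% exactly; a latent-active subset (Bernoulli 0.25 per
  tumor) in which the anchor is always over-expressed and each direct
  target independently with penetrance 0.6; activated cells take
  shift + |noise| with shift 3, so penetrant activation deterministically
  clears the threshold.

Every output is a pure function of (config, seed); child streams are keyed
per stage so stages can be regenerated independently.  The truth record
(bound/regulated/artifact genes, motif offsets, active tumors) serializes
to JSON and round-trips.

What the generator does **not** emulate: realistic nucleotide composition
(beyond the dinucleotide-preserving background shuffles), probe-level
array artifacts, normalization residuals, correlated technical noise,
copy-number structure in the tumor cohort, or overlapping promoters.
Passing recovery tests therefore demonstrate the pipeline's correctness
under its own model assumptions, not robustness to real-data pathologies.

## Numerical and degenerate-input choices

- Hypergeometric/Fisher tails via `scipy.stats.hypergeom.sf`; verified
  against exhaustive subset enumeration for every universe ≤ 13.
- Impossible overlap margins, p-values outside [0, 1], non-positive σ,
  zero-margin chi-square tables, identical control arrays (σ̂ = 0), and
  fewer than two control arrays all raise typed errors rather than
  returning sentinel values.
- BH output is deterministic under ties and permutation-equivariant.
- Odds-ratio zero-cell policy is Haldane by default with a strict mode
  that raises on b·c = 0.

## Known limitations

- The motif enrichment statistic is a practical substitute, not a
  reproduction of rank-based motif discovery tools.
- At ~1% prevalence, effects planted at exactly 4× the null sd are near
  the BH(0.01) detection boundary; mean recall there is ~0.5 (the
  threshold |z| under step-up selection sits at ≈3.9–4.1), which is a
  property of the testing problem, not of the implementation.  The
  generator's default effect (−5.5σ) is comfortably detectable.
- Fisher-based co-upregulation flags are conservative at cohort sizes of a
  few hundred tumors.
- Single-array DE has no gene-specific variance; genes with atypical
  technical noise are mis-calibrated by construction.
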