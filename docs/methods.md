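# Methods

## The detection model

A tiling array measures, per 25-mer probe, a hybridization intensity that
is proportional (up to a strong probe-specific affinity factor) to the
abundance of the transcribed sequence it covers. Absolute intensities are
therefore not comparable *between* probes, but the same probe *is*
comparable across arrays. The splicing test exploits exactly this: for each
probe of an intron, a two-sample pooled-variance t-test compares the
probe's replicate intensities between treatment and control, one-sided in
the direction "higher under treatment". That yields p_up per probe, and
p_down = 1 − p_up covers the opposite direction (for a continuous test
statistic the two one-sided p-values are exact complements, so a probe
moving against the tested direction automatically contributes its
complementary value). The per-probe p-values of one intron are combined
with Fisher's method, X² = −2 Σ ln p_i against χ² with 2k degrees of
freedom, once per direction; the intron-level p is the smaller of the two
combined values, and the winning direction is recorded. Benjamini–Hochberg
correction across all tested introns declares significance at FDR 0.1.

Fisher's method assumes independent p-values. The probes of one intron are
non-overlapping by array design; residual correlation from multi-probe
cDNA fragments is deliberately ignored — accounting for it has been shown
to weaken the combined-P approach more than it helps, and the package
replicates that choice.

### Calibration of the min-of-directions rule

The minimum of the two directional combined p-values is a two-sided test
evaluated at twice its nominal level: under the null each directional
combination is Uniform(0,1) and the two are nearly disjoint in their lower
tails, so P(min ≤ x) ≈ 2x. Feeding the raw minimum into BH therefore
controls the FDR only at about twice the stated target; on simulated
null/planted mixtures this is plainly measurable (empirical FDR ≈ 0.15 at
a nominal 0.1). The package consequently doubles the minimum (a Bonferroni
correction over the two directions, capped at 1) before BH by default, so
the stated FDR is actually delivered; `intron_test(double_min_p=False)`
reproduces the uncorrected historical rule. The reported `intron_p` field
is always the raw directional minimum; the correction enters only the
BH step.

### Gating

Only genes where an intron signal is interpretable are tested: a gene must
have at least 9 mapped probes, at least one of them intronic, and — in at
least one condition — an exon mean above the global exon threshold
together with an intron mean below the global background threshold. The
exon threshold is the median log2 intensity of all exon probes; the
background threshold is the median over all mapped probes. The first
separates expressed genes from silent ones, the second flags genes whose
introns are already expressed (or whose locus carries genomic-DNA signal)
in both conditions. A histogram mode of the exon-probe distribution
(Freedman–Diaconis bins, midpoint of the tallest bin) is computed for
diagnostics only. An optional near-exon filter
(`intron_test(near_exon_delta=...)`, disabled by default) additionally
requires a significant intron's mean in its presence condition to come
within δ log2 units of the gene's exon mean; it is off by default because
the requirement is qualitative in origin and no defensible δ exists.

### Splice-type classification

A significant intron is *retained* only if every one of its probes is
individually significant (unadjusted p < 0.05) in the winning direction —
i.e. the whole intron behaves like an exon. Any partial pattern is
*unknown*: at ~35 bp probe resolution an alternative 5'/3' site, a skipped
exon and a partially covered retention are indistinguishable, and events
shorter than the probe spacing are undetectable in principle. The
*presence* call names the condition with the higher intron replicate mean,
i.e. the condition in which the unspliced form is (more) present.

## Gene-level expression

A gene's expression per array is the arithmetic mean of its exon probes'
log2 intensities; genes require more than 3 mapped probes. The
responsive-gene call uses a two-sided pooled t-test on the per-array
expression values, BH at FDR 0.05, and an absolute linear fold-change
filter ≥ 2 (|log2 FC| ≥ 1). Fold change is treatment − control on the log2
scale, so induced genes are positive. The t-test operates on per-array
gene means, not pooled probe values: probe-level affinities cancel in the
per-array mean and replicate arrays are the experimental unit. Degenerate
variance is handled with a pooled-variance floor of 1e-8, which yields
p = 1 for identical groups and p ≈ 0 for constant-but-shifted groups;
a Welch variant is selectable (`welch=True`) but pooled Student is the
default for the small balanced designs (n = 4 per condition) this method
targets.

## Preprocessing

Fixed order: background correction → quantile normalization → log2. The
background model is the normal + exponential convolution (observed =
Exp(α) signal + Normal(μ, σ²) background); parameters are estimated by
moments — the exponential carries the entire third central moment, so
1/α = cbrt(m₃/2), then μ and σ² follow from the mean and variance — and
the corrected value is the strictly positive posterior mean E[signal |
observed]. Moments estimation is deterministic and closed-form; MLE
refinement is out of scope. The default background method is `none`
because the synthetic generator emits background-free intensities; use
`normexp` for raw scanner data. Quantile normalization equalizes the
arrays' empirical distributions (each sorted column becomes the
across-array mean of sorted columns) and preserves within-array ranks;
tied values receive the mean of the reference quantiles they span. The
transform is idempotent for tie-free data and shared tie patterns; ties at
discordant ranks across arrays can move slightly under re-application.

## Probe mapping

Mapping is purely coordinate-based: the package consumes a probe
coordinate table (BED conventions, 0-based half-open) and assigns a probe
to a segment only when fully contained in it. Exclusion reasons, checked
in order: `control` flag, `malformed` length (≠ 25 nt by default),
`multi_location` (same probe id at several genomic positions, or
containment in segments of more than one gene — the conservative choice
for overlapping loci), `border` (overlaps a gene but crosses an
exon/intron or gene boundary), `intergenic` (no gene overlap). Retained +
excluded always partitions the input. Mapping ignores probe strand by
default because double-stranded hybridization targets see both strands;
`stranded=True` restricts assignment to same-strand genes for
strand-specific labelings.

Base-transcript selection takes the isoform with the most exons (ties:
lexicographically smallest transcript id, for determinism); introns are
the gaps between consecutive exons, zero-length gaps between abutting
exons produce no intron. Exon/intron numbering follows transcript
orientation, so minus-strand genes number from the genomic right end.

## The synthetic generator

`simulate(SimulationConfig(...))` emulates the data-generating situation
of a two-condition replicated tiling experiment. Genes are laid out
sequentially on one chromosome, alternating strands, with 2–8 exons
(150–400 bp) and introns of 90–250 bp by default; probes tile each segment
at 35 bp spacing (the real array's average resolution) and are emitted
only when fully contained in a single segment, so coordinate mapping
recovers the generator's own truth assignment exactly. A probe's log2
intensity is its segment level (exon 10.0, intron background 6.0) plus any
planted shift plus Normal noise (sd 0.25 log2 by default, 4 replicates per
condition — the replication level the method is designed for); linear
intensities are 2^x, i.e. log-normal multiplicative noise, the standard
microarray error model. 40% of genes are simulated as transcriptionally
silent (all probes at background): real transcriptomes are strongly
bimodal, and without a silent fraction the global exon-median gate would
degenerate into a coin flip around a single-level population — an artifact
of over-uniform simulation, not a property of the method. Planted
retention raises every probe of the target intron by the effect size in
the target condition; partial 5'/3' events raise only the probes in the
affected intron fraction (transcript orientation); DE genes shift all exon
probes. Border, multi-mapping, control and intergenic probes can be
injected to exercise every exclusion branch. Planted events must reference
expressed, multi-exon genes; everything is driven by one recorded seed and
outputs are byte-identical across runs.

What the generator does **not** emulate: probe-specific affinities
(sequence thermodynamics), cross-hybridization, spatial array artifacts,
partial isoform mixtures (planted events shift probes fully), or
correlated noise between neighboring probes. Passing tests therefore show
the statistical machinery is correct under the stated error model, not
that the method's power on a real hybridization is as high.

## Operating-characteristic experiments

`scripts/acceptance.py` measures the two FDR guarantees on generated data:
2,000 testable introns (300 planted retentions, effects uniform in 2–3
log2) for the intron-level call, and 5,000 genes (500 with 2 log2 shifts,
10 exon probes each) for the gene-level call — sizes chosen to estimate a
proportion of ~0.1 with a standard error of ~0.02 while completing in
seconds. These experiments run the statistical core on the generator's
calibrated log2 intensities without cross-array quantile renormalization:
the simulated arrays already share one distribution in expectation, so
renormalization is a no-op there by design — and planting a substantial
fraction of probes in one condition would otherwise let the rank→value
remapping leak a systematic bias into null probes, measuring an
interaction between normalization and an extreme planting fraction rather
than the test's own error rate. Quantile normalization is verified
separately by its oracle, idempotence and rank-preservation tests and by
the full-pipeline tests at realistic planting fractions.

## Overlap statistics and stress indexes

Event lists are compared as sets of (gene id, intron number) under one
shared annotation. The representation factor is observed/expected overlap
with expected = |A|·|B|/N; significance is the exact upper-tail
hypergeometric probability P(X ≥ k). A stress index is the (up to) 1,000
genes with the largest |log2 FC| among those with unadjusted p < 0.05 in a
reference experiment, stored signed; an experiment is scored against an
index by Pearson correlation over the shared gene set (≥ 3 genes, no
imputation of missing genes — imputation would fabricate agreement). The
original vector-comparison tool's exact correlation variant is not
publicly specified; Pearson on matched signed log2 fold changes satisfies
every property claimed for it (range [−1, 1], 1 for identical direction
and intensity, −1 for exact opposition) and is documented here as an
approximation.

## Numerical choices

- Variance floor 1e-8 on pooled variances (degenerate replicate sets).
- Zero p-values are floored at 1e-300 before log-combination, with a
  warning.
- Quantile-normalization ties average the reference quantiles they span.
- BH adjustment via the standard step-up; verified against a brute-force
  reference in the tests.
- All coordinates are 0-based half-open internally; GFF3 I/O is 1-based
  inclusive, probe TSVs use BED conventions.
- Default seed 20130611; every stochastic component takes an explicit
  seed and run manifests record it.

## Known limitations

- Events shorter than the probe spacing (~35 bp) are invisible.
- All non-retained significant events are "unknown"; the platform cannot
  disambiguate alternative 5'/3' from exon skipping.
- The gate discards genes whose introns are expressed in both conditions,
  so constitutive intron retention is out of reach by design.
- Overlapping gene loci lose their shared probes (conservative
  multi-location exclusion).
- The pooled t-test at n = 4 per condition has limited power for effects
  below ~1 log2 unit at the simulated noise level.
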